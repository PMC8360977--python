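# Methods

## Models

`neulag` works with two linear equations of motion for the hidden states
`z(t) ∈ C^n` of an n-region network:

* **original**: `dz/dt = A z + C v + w`, the first-order linear
  (effective-connectivity) state equation with intrinsic coupling `A`
  (units 1/time), input matrix `C`, exogenous drive `v = u + w_v` and smooth
  state noise `w`. With real `A, C, z0, v` the states stay real and, for a
  stable `A` (all eigenvalue real parts negative), relax without oscillating.
* **modified**: `i dz/dt = A z + C v + w` with complex `z` and Hermitian `A`.
  Multiplying through by `-i` gives the coupled real form
  `d(Re)/dt = A·Im`, `d(Im)/dt = -(A·Re + C v + w)`, so each eigenmode of a
  real symmetric `A` oscillates at its eigenvalue (rad/time) with constant
  amplitude.

The modified equation is the one compatible with stationary action. Its
Lagrangian is

    L = (i/2) Σ_j (z_j* ż_j - z_j ż_j*) - Σ_jk z_j* A_jk z_k
        - 2 Re(z^H C v) - Σ_j w_j (z_j + z_j*),

real whenever `A` is Hermitian and `C, v, w` are real (the input term is
written as `2 Re(z^H C v)`, the only reading that is well defined for a
rectangular real `C` and that makes the Euler–Lagrange equations reproduce
the modified state equation and its adjoint as complex conjugates). The
Legendre transform gives the energy

    H = z^H A z + 2 Re(z^H C v) + 2 Σ_j w_j Re z_j,

conserved exactly in the non-dissipative case (`v = w = 0`), where also the
norm `Σ |z_j|^2` is constant because `exp(-iAt)` is unitary for Hermitian
`A`. The real-variable "embedding" route — differentiating
`dz/dt = A z + d` once to get `d²z/dt² = A² z + A d`, which has a Lagrangian
when `A²` is symmetric — is implemented (`second_order_embedding`,
`real_lagrangian_value`, `spurious_solution_residual`) purely to demonstrate
its failure: the second-order equation has a two-constant solution family of
which only half solves the original dynamics.

## Numerics

* **Integration**: fixed-step classical RK4 on a uniform grid; inputs and
  noise are sampled on the grid and linearly interpolated at half-steps.
  Default display grid dt = 1 "time step", T = 128 points, matching how the
  synthetic study is presented. RK4's amplitude error per step for a mode of
  frequency ω is ≈ (ω dt)⁶/144, so energy/norm conservation checks use
  dt = 0.05 (drift ~1e-8 over 512 steps) or finer.
* **Discrete mechanics**: trajectory derivatives use central differences
  (second-order one-sided at the ends); the action uses trapezoidal
  quadrature. Both are O(dt²), so the tight diagnostics (pointwise
  |L| < 1e-6, Euler–Lagrange residual < 1e-5, first-order action variation
  < 1e-8 at ε = 1e-3) are evaluated on dt = 0.002 grids, and the
  stationarity-ratio check on dt = 0.001; at the network's fastest
  eigenfrequency (0.9 rad/time for perturbed instances) this keeps
  discretization error below the thresholds with margin.
* **Stationarity check**: random differentiable complex perturbations,
  Gaussian-smoothed and windowed to vanish exactly at both endpoints,
  normalized to unit max modulus; ΔS(±ε) is split into odd (first-order) and
  even (second-order) parts; 8 perturbations at a fixed seed by default.
* **Noise**: white Gaussian noise convolved with a Gaussian kernel
  (width = `smoothness` steps, default 4) and rescaled to preserve the
  marginal standard deviation; this realizes "smooth, non-Markovian"
  fluctuations. A given `NoiseSpec` (amplitudes, smoothness, seed) always
  reproduces bit-identical draws; draws are consumed in a fixed order so the
  stream layout does not depend on which amplitudes are zero.

## Synthetic study conditions

`make_three_node_network` builds the symmetric 3×3 coupling with diagonal
−0.5 and off-diagonal 0.2 (eigenvalues −0.1, −0.7, −0.7: stable for the
original variant, oscillation frequencies 0.1 and 0.7 rad/step for the
modified one); the input drives node 1 only. The exogenous input is a
Gaussian bump peaking at T/4 with width T/64 ≈ 2 steps. The width is chosen
so the bump's spectral bandwidth (~0.5 rad/step) excites the network's full
eigenspectrum: a broader bump leaves the 0.7 rad/step modes silent, the
oscillatory response collapses to a single slow sinusoid, and a real
first-order system can mimic it — the two equations of motion would then not
be distinguishable from these data, which is the property the generator
exists to provide. Default noise: smooth state noise sd 0.05
(smoothness 4), observation noise sd 0.05, no input noise — strong enough
that recovery is imperfect, weak enough that identifiability holds with
margin. Observations keep the real component of the states, then each
channel is centred to mean 0 and the whole array is scaled so its largest
magnitude is 1. A single global scale (rather than one per channel) is used
deliberately: it preserves relative amplitudes between channels and keeps
the data→model map smooth — per-channel scaling is scale-invariant and
discontinuous at parameters where a channel response vanishes (exactly the
prior mean, where off-diagonal couplings are zero and nodes 2–3 are silent).

What the generator does **not** emulate: modality-specific structure of real
recordings (hemodynamic convolution, line noise, referencing, channel count
and non-neural artifacts). Passing the identifiability and recovery tests
therefore shows the inversion machinery is correct and the two equations are
distinguishable under these idealized conditions, not that either equation
is the better account of any particular empirical modality.

## Inversion

`variational_laplace` fits either variant to a (T × N) timeseries by
maximizing the Laplace free energy

    F(θ, λ) = -½ e^λ ||y - g(θ)||² + (TN/2)(λ - ln 2π)
              - ½ (θ-μ₀)ᵀ Σ₀⁻¹ (θ-μ₀) - ½ (λ-λ₀)²/σ_λ²
              + ½ ln det(Σ_post Σ₀⁻¹),

with `g(θ)` the deterministic mean (state noise zero; all stochasticity
absorbed into observation noise of estimated log-precision λ), integrated
from z0 = 0 with the real-part observer and standardized with the same rule
as the data. θ holds all n² entries of a real `A` (original) or the
n(n+1)/2 entries of a symmetric real `A` (modified); `C` is fixed and known.
Priors: diagonal of `A` at −1/4, off-diagonals 0, sd 0.25 on every entry;
λ₀ = ln 32, σ_λ = 1. Channels beyond the model's n regions are predicted as
zero (so appending pure-noise channels can only lower F).

θ is updated by Gauss–Newton with Levenberg damping (sensitivities by
batched forward finite differences, step 1e-5 prior-sd units); λ by bounded
scalar maximization (λ₀ ± 20); only F-increasing steps are accepted, so the
returned trace is non-decreasing. Because the oscillatory model's likelihood
is sharply multimodal in frequency (basin width ~2π/T), the ascent is
restarted from a deterministic set of initializations — the prior mean, a
method-of-moments regression start, three diagonal rescalings, and four
seeded prior draws — and the highest-F run is kept (earlier starts win ties
within `tol`). The regression start solves `dx/dt ≈ A x + C u` (original) or
`d²x/dt² ≈ -A² x - A C u` (modified) by least squares with
central-difference derivatives; for the modified variant the recovered
`E = A²` is eigendecomposed and each eigenfrequency de-biased through
`ω = arcsin(√μ·dt)/dt` (double central differencing attenuates a mode at ω
to sin²(ω dt)/dt²), then `A = -Σ ω φφᵀ` adopting the generator's
negative-eigenvalue convention.

`compare_models` converts free energies of candidate fits on the same data
to probabilities by softmax (fixed-effects model selection);
`identifiability_experiment` runs the full 2×2 grid (two generated datasets
× two candidate equations) and reports both comparisons.

Known limitations: the deterministic-mean likelihood treats smooth state
noise as white observation noise, so a flexible model can partially fit the
noise realization — matched-model recovery of the *original* variant at the
default noise level is accordingly coarser (median element-wise error
~0.15) than the modified variant's (~0.02), and the posterior precision is
mildly overstated when residuals are autocorrelated. Hierarchical
(random-effects) comparison across subjects, estimation of z0, and
generalized-coordinate state-noise modelling are out of scope.

## Degenerate inputs and tie-breaks

Non-Hermitian `A` is rejected before integration for the modified variant
(tolerance 1e-10 on max |A − Aᴴ|). A non-finite state aborts integration
naming the first bad step. An all-zero channel standardizes with scale 1.
`a = 0` is rejected in the scalar spurious-solution family. Model-comparison
ties resolve to the lower model index. Non-improving optimizer steps beyond
the retry budget set `converged=False` rather than raising.
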