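"""Linear neuronal state equations and their forward integration.

Two equations of motion are supported for the hidden states ``z`` of an
``n``-region network with intrinsic coupling ``A`` (1/time), extrinsic input
matrix ``C`` and exogenous drive ``v = u + w_v``:

* the *original* first-order equation  ``dz/dt = A z + C v + w_z``, whose
  solutions decay (or grow) without oscillating when ``A``, ``z`` and the
  inputs are real; and
* the *modified* oscillatory equation  ``i dz/dt = A z + C v + w_z`` with
  complex ``z`` and Hermitian ``A``, whose non-dissipative form conserves both
  the state norm and the energy ``z^H A z``.

Both are integrated with a fixed-step classical Runge-Kutta (RK4) scheme on a
uniform grid; state and input noise are smooth (kernel-filtered) Gaussian
paths sampled on the grid and interpolated linearly at the half-steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DivergenceError, ShapeError, ValidationError

__all__ = [
    "HERMITIAN_TOL",
    "LinearModelSpec",
    "InputSignal",
    "NoiseSpec",
    "Trajectory",
    "simulate_original",
    "simulate_modified",
    "split_real_imag_rhs",
    "observe",
    "check_stability",
    "smoothed_gaussian_noise",
]

HERMITIAN_TOL = 1e-10

Variant = Literal["original", "modified"]


def _as_complex_matrix(A) -> np.ndarray:
    A = np.asarray(A, dtype=complex)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"A must be a square matrix, got shape {A.shape}")
    return A


def hermitian_deviation(A: np.ndarray) -> float:
    """Max element-wise magnitude of ``A - A^H``."""
    return float(np.max(np.abs(A - A.conj().T))) if A.size else 0.0


@dataclass(frozen=True)
class LinearModelSpec:
    """Coupling structure of one equation of motion.

    Parameters
    ----------
    A
        Intrinsic coupling matrix, n x n (complex allowed; units 1/time).
    C
        Extrinsic input matrix, n x m, real.
    variant
        ``"original"`` for dz/dt = Az + Cv + w, ``"modified"`` for
        i dz/dt = Az + Cv + w.
    non_dissipative
        When true, inputs and noise are dropped during simulation so that the
        modified equation conserves energy.
    symmetric_real
        For the modified variant, restrict A to be real and symmetric (the
        default working regime; a real symmetric matrix is Hermitian).
    """

    A: np.ndarray
    C: np.ndarray
    variant: Variant = "original"
    non_dissipative: bool = False
    symmetric_real: bool = True

    def __post_init__(self):
        A = _as_complex_matrix(self.A)
        C = np.asarray(self.C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.ndim != 2 or C.shape[0] != A.shape[0]:
            raise ShapeError(
                f"C must have {A.shape[0]} rows to match A, got shape {C.shape}"
            )
        if self.variant not in ("original", "modified"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.variant == "modified":
            dev = hermitian_deviation(A)
            if dev > HERMITIAN_TOL:
                raise ValidationError(
                    f"modified variant requires Hermitian A (max |A - A^H| = {dev:.3e})"
                )
            if self.symmetric_real:
                if np.max(np.abs(A.imag)) > HERMITIAN_TOL:
                    raise ValidationError(
                        "symmetric-real restriction requires imag(A) = 0"
                    )
                if np.max(np.abs(A - A.T)) > HERMITIAN_TOL:
                    raise ValidationError(
                        "symmetric-real restriction requires A = A^T"
                    )
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "C", C)

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]

    def with_(self, **kw) -> "LinearModelSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class InputSignal:
    """Exogenous drive sampled on a time grid (one column per input channel)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if t.ndim != 1 or v.ndim != 2 or v.shape[0] != t.shape[0]:
            raise ShapeError(
                f"times (shape {t.shape}) and values (shape {v.shape}) are inconsistent"
            )
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValidationError("input times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValidationError("input values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``times`` (clamped at the endpoints)."""
        times = np.asarray(times, dtype=float)
        out = np.empty((times.size, self.n_channels))
        for j in range(self.n_channels):
            out[:, j] = np.interp(times, self.times, self.values[:, j])
        return out

    @staticmethod
    def zeros(times: np.ndarray, n_channels: int = 1) -> "InputSignal":
        times = np.asarray(times, dtype=float)
        return InputSignal(times, np.zeros((times.size, n_channels)))


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes and smoothness of the stochastic terms.

    ``smoothness`` is the Gaussian kernel width (standard deviation, in time
    steps) used to correlate the state/input noise in time; 0 gives white
    noise. ``obs_sd`` is added after the observer function. The same seed and
    parameters always reproduce bit-identical draws.
    """

    state_sd: float = 0.0
    input_sd: float = 0.0
    smoothness: float = 0.0
    obs_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("state_sd", "input_sd", "obs_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.smoothness < 0:
            raise ValidationError("smoothness must be non-negative")


def smoothed_gaussian_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, smoothness: float
) -> np.ndarray:
    """Gaussian noise with temporal autocorrelation along axis 0.

    White noise is convolved with a Gaussian kernel of width ``smoothness``
    (in samples) and rescaled so the marginal standard deviation stays ``sd``;
    the draw is consumed from ``rng`` even when ``sd`` is zero so that the
    stream layout does not depend on the amplitudes.
    """
    white = rng.standard_normal(shape)
    if sd == 0.0:
        return np.zeros(shape)
    if smoothness > 0:
        smooth = gaussian_filter1d(white, sigma=smoothness, axis=0, mode="reflect")
        # variance gain of the truncated kernel, measured on an impulse
        half = int(4.0 * smoothness + 0.5)
        impulse = np.zeros(2 * half + 1)
        impulse[half] = 1.0
        kernel = gaussian_filter1d(impulse, sigma=smoothness, mode="constant")
        gain = np.sqrt(np.sum(kernel**2))
        smooth = smooth / gain
    else:
        smooth = white
    return sd * smooth


@dataclass(frozen=True)
class Trajectory:
    """Integration result: time grid, complex states and real observations."""

    times: np.ndarray
    states: np.ndarray
    observations: np.ndarray
    inputs_used: InputSignal | None = None
    noise_realization: dict | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=complex)
        o = np.asarray(self.observations, dtype=float)
        if s.ndim != 2 or o.shape != s.shape or t.shape[0] != s.shape[0]:
            raise ShapeError(
                f"inconsistent trajectory shapes: times {t.shape}, "
                f"states {s.shape}, observations {o.shape}"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "observations", o)

    @property
    def n_regions(self) -> int:
        return self.states.shape[1]

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    def effective_input(self) -> np.ndarray:
        """Realized drive u + w_v on the grid (T x m)."""
        if self.inputs_used is None:
            m = 1
            u = np.zeros((self.n_steps, m))
        else:
            u = self.inputs_used.sample(self.times)
        if self.noise_realization and "input" in self.noise_realization:
            u = u + self.noise_realization["input"]
        return u

    def state_noise(self) -> np.ndarray:
        if self.noise_realization and "state" in self.noise_realization:
            return self.noise_realization["state"]
        return np.zeros((self.n_steps, self.n_regions))


def _draw_noise(noise: NoiseSpec, T: int, n: int, m: int) -> dict:
    rng = np.random.default_rng(noise.seed)
    w_state = smoothed_gaussian_noise(rng, (T, n), noise.state_sd, noise.smoothness)
    w_input = smoothed_gaussian_noise(rng, (T, m), noise.input_sd, noise.smoothness)
    w_obs = noise.obs_sd * rng.standard_normal((T, n))
    return {"state": w_state, "input": w_input, "obs": w_obs}


def _integrate(spec: LinearModelSpec, z0, input: InputSignal | None,
               noise: NoiseSpec, T: int, dt: float) -> Trajectory:
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if T < 2:
        raise ValidationError("T must be at least 2")
    n, m = spec.n_regions, spec.n_inputs
    z0 = np.asarray(z0, dtype=complex).reshape(-1)
    if z0.shape[0] != n:
        raise ShapeError(f"z0 has length {z0.shape[0]}, expected {n}")
    times = np.arange(T) * dt

    if input is None:
        input = InputSignal.zeros(times, m)
    if input.n_channels != m:
        raise ShapeError(
            f"input has {input.n_channels} channels but C has {m} columns"
        )
    draws = _draw_noise(noise, T, n, m)
    if spec.non_dissipative:
        u_grid = np.zeros((T, m))
        w_state = np.zeros((T, n))
        draws = {"state": w_state, "input": np.zeros((T, m)), "obs": np.zeros((T, n))}
    else:
        u_grid = input.sample(times) + draws["input"]
        w_state = draws["state"]

    # forcing term C v(t) + w_z(t) sampled on the grid
    forcing = u_grid @ spec.C.T + w_state
    factor = -1j if spec.variant == "modified" else 1.0
    A = spec.A

    states = np.empty((T, n), dtype=complex)
    states[0] = z0
    z = z0
    # overflow inside a diverging step is reported via DivergenceError
    with np.errstate(over="ignore", invalid="ignore"):
        return _rk4_loop(spec, z, states, forcing, factor, A, T, dt, times, input, draws)


def _rk4_loop(spec, z, states, forcing, factor, A, T, dt, times, input, draws):
    for k in range(T - 1):
        f_k = forcing[k]
        f_k1 = forcing[k + 1]
        f_half = 0.5 * (f_k + f_k1)
        k1 = factor * (A @ z + f_k)
        k2 = factor * (A @ (z + 0.5 * dt * k1) + f_half)
        k3 = factor * (A @ (z + 0.5 * dt * k2) + f_half)
        k4 = factor * (A @ (z + dt * k3) + f_k1)
        z = z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(z.view(float))):
            raise DivergenceError(f"non-finite state at step {k + 1}")
        states[k + 1] = z

    observations = states.real + draws["obs"]
    return Trajectory(times, states, observations, input, draws)


def simulate_original(spec: LinearModelSpec, z0, input: InputSignal | None,
                      noise: NoiseSpec, T: int, dt: float) -> Trajectory:
    """Integrate dz/dt = Az + Cv + w_z on a fixed grid of ``T`` points."""
    if spec.variant != "original":
        raise ValidationError("simulate_original requires variant='original'")
    return _integrate(spec, z0, input, noise, T, dt)


def simulate_modified(spec: LinearModelSpec, z0, input: InputSignal | None,
                      noise: NoiseSpec, T: int, dt: float) -> Trajectory:
    """Integrate i dz/dt = Az + Cv + w_z, i.e. dz/dt = -i (Az + Cv + w_z)."""
    if spec.variant != "modified":
        raise ValidationError("simulate_modified requires variant='modified'")
    # Hermiticity is already enforced by the spec invariant.
    return _integrate(spec, z0, input, noise, T, dt)


def simulate(spec: LinearModelSpec, z0, input: InputSignal | None,
             noise: NoiseSpec, T: int, dt: float) -> Trajectory:
    """Dispatch to the simulator matching ``spec.variant``."""
    if spec.variant == "original":
        return simulate_original(spec, z0, input, noise, T, dt)
    return simulate_modified(spec, z0, input, noise, T, dt)


def split_real_imag_rhs(spec: LinearModelSpec, re, im, v, w):
    """Right-hand sides of the coupled real/imaginary form of the modified
    equation:  d(Re)/dt = A Im  and  d(Im)/dt = -(A Re + C v + w).

    Only valid for the real-symmetric restriction of the modified variant
    (multiplying the complex equation through by -i and equating components).
    """
    if spec.variant != "modified":
        raise ValidationError("split form applies to the modified variant only")
    if np.max(np.abs(spec.A.imag)) > HERMITIAN_TOL:
        raise ValidationError("split form requires a real (symmetric) A")
    A = spec.A.real
    re = np.asarray(re, dtype=float).reshape(-1)
    im = np.asarray(im, dtype=float).reshape(-1)
    v = np.asarray(v, dtype=float).reshape(-1)
    w = np.asarray(w, dtype=float).reshape(-1)
    if re.shape != im.shape or re.shape[0] != spec.n_regions:
        raise ShapeError("re/im must have length n_regions")
    d_re = A @ im
    d_im = -(A @ re + spec.C @ v + w)
    return d_re, d_im


def observe(traj_states, observer: str, spec: LinearModelSpec | None = None):
    """Apply an observer function to a complex state history.

    ``"real_part"`` returns Re(z) (T x n); ``"hamiltonian"`` returns the
    scalar energy z^H A z per time point (T,), real by Hermiticity of A.
    """
    states = np.asarray(traj_states, dtype=complex)
    if observer == "real_part":
        return states.real
    if observer == "hamiltonian":
        if spec is None:
            raise ValidationError("hamiltonian observer requires a model spec")
        A = spec.A
        if hermitian_deviation(A) > HERMITIAN_TOL:
            raise ValidationError("hamiltonian observer requires Hermitian A")
        H = np.einsum("ti,ij,tj->t", states.conj(), A, states)
        return H.real
    from .errors import ConfigError

    raise ConfigError(f"unknown observer {observer!r}")


def check_stability(A) -> tuple[bool, np.ndarray]:
    """Eigenvalues of the Jacobian; stable iff all real parts are negative."""
    A = _as_complex_matrix(A)
    eig = np.linalg.eigvals(A)
    return bool(np.max(eig.real) < 0), eig
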