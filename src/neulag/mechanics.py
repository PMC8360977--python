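"""Lagrangian/Hamiltonian mechanics of the linear state equations.

The modified (complex, oscillatory) equation  i dz/dt = Az + Cv + w  derives
from the Lagrangian

    L = (i/2) sum_j (z_j* zdot_j - z_j zdot_j*)
        - sum_jk (z_j* A_jk z_k) - 2 Re(z^H C v) - sum_j w_j (z_j + z_j*),

which is real whenever A is Hermitian and C, v, w are real. Its Legendre
transform gives the energy

    H = z^H A z + 2 Re(z^H C v) + 2 sum_j w_j Re(z_j),

conserved along non-dissipative trajectories (v = w = 0). This module
evaluates L, H, the action S = int L dt, Euler-Lagrange residuals, and
discrete stationarity checks on sampled trajectories, plus the real-variable
second-order embedding that demonstrates why a real first-order equation has
no faithful Lagrangian (the embedded equation acquires spurious solutions).

Time derivatives on sampled trajectories use central differences (one-sided
at the ends); the action uses trapezoidal quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, ValidationError
from .models import (
    HERMITIAN_TOL,
    InputSignal,
    LinearModelSpec,
    Trajectory,
    hermitian_deviation,
)

__all__ = [
    "MechanicsReport",
    "SecondOrderEmbedding",
    "lagrangian_value",
    "hamiltonian_value",
    "hamiltonian_series",
    "hamiltonian_drift",
    "action_value",
    "action_stationarity_check",
    "euler_lagrange_residual",
    "adjoint_conjugacy_deviation",
    "second_order_embedding",
    "spurious_solution_residual",
    "real_lagrangian_value",
    "mechanics_report",
    "make_perturbations",
]


# ---------------------------------------------------------------------------
# pointwise evaluations


def _check_vectors(spec: LinearModelSpec, z, v, w):
    z = np.asarray(z, dtype=complex).reshape(-1)
    v = np.asarray(v, dtype=float).reshape(-1)
    w = np.asarray(w, dtype=float).reshape(-1)
    if z.shape[0] != spec.n_regions:
        raise ShapeError(f"z has length {z.shape[0]}, expected {spec.n_regions}")
    if v.shape[0] != spec.n_inputs:
        raise ShapeError(f"v has length {v.shape[0]}, expected {spec.n_inputs}")
    if w.shape[0] != spec.n_regions:
        raise ShapeError(f"w has length {w.shape[0]}, expected {spec.n_regions}")
    return z, v, w


def lagrangian_value(z, zdot, spec: LinearModelSpec, v, w) -> complex:
    """Evaluate L at a single phase point; complex in general, real for
    Hermitian A with real C, v, w (the caller may inspect the imaginary
    part as a diagnostic)."""
    z, v, w = _check_vectors(spec, z, v, w)
    zdot = np.asarray(zdot, dtype=complex).reshape(-1)
    if zdot.shape != z.shape:
        raise ShapeError("zdot must match z in length")
    kinetic = 0.5j * np.sum(z.conj() * zdot - z * zdot.conj())
    cv = spec.C @ v
    potential = z.conj() @ spec.A @ z + np.sum(cv * (z + z.conj()))
    noise_term = np.sum(w * (z + z.conj()))
    return complex(kinetic - potential - noise_term)


def hamiltonian_value(z, spec: LinearModelSpec, v=None, w=None) -> float:
    """Energy H = z^H A z (+ input and noise terms unless non-dissipative)."""
    if hermitian_deviation(spec.A) > HERMITIAN_TOL:
        raise ValidationError("Hamiltonian requires Hermitian A")
    n, m = spec.n_regions, spec.n_inputs
    v = np.zeros(m) if v is None else v
    w = np.zeros(n) if w is None else w
    z, v, w = _check_vectors(spec, z, v, w)
    core = (z.conj() @ spec.A @ z).real
    if spec.non_dissipative:
        return float(core)
    cv = spec.C @ v
    return float(core + 2.0 * np.sum(cv * z.real) + 2.0 * np.sum(w * z.real))


# ---------------------------------------------------------------------------
# trajectory-level helpers


def _velocities(states: np.ndarray, times: np.ndarray) -> np.ndarray:
    if states.shape[0] < 3:
        raise ValidationError("need at least 3 grid points for derivatives")
    return np.gradient(states, times, axis=0, edge_order=2)


def _grid_terms(traj: Trajectory, spec: LinearModelSpec,
                input: InputSignal | None):
    """Effective drive C v(t) and state noise w(t) on the trajectory grid."""
    T = traj.n_steps
    if input is not None:
        u = input.sample(traj.times)
        if traj.noise_realization and "input" in traj.noise_realization:
            u = u + traj.noise_realization["input"]
    elif traj.inputs_used is not None:
        u = traj.effective_input()
    else:
        u = np.zeros((T, spec.n_inputs))
    w = traj.state_noise()
    if spec.non_dissipative:
        u = np.zeros_like(u)
        w = np.zeros_like(w)
    return u, w


def _lagrangian_series(states, zdot, spec, u_grid, w_grid) -> np.ndarray:
    kinetic = 0.5j * np.sum(states.conj() * zdot - states * zdot.conj(), axis=1)
    coupling = np.einsum("ti,ij,tj->t", states.conj(), spec.A, states)
    cv = u_grid @ spec.C.T
    drive = np.sum(cv * (states + states.conj()), axis=1)
    noise = np.sum(w_grid * (states + states.conj()), axis=1)
    return kinetic - coupling - drive - noise


def hamiltonian_series(traj: Trajectory, spec: LinearModelSpec,
                       input: InputSignal | None = None) -> np.ndarray:
    """H(t) along a trajectory (real vector of length T)."""
    if hermitian_deviation(spec.A) > HERMITIAN_TOL:
        raise ValidationError("Hamiltonian requires Hermitian A")
    states = traj.states
    core = np.einsum("ti,ij,tj->t", states.conj(), spec.A, states).real
    if spec.non_dissipative:
        return core
    u_grid, w_grid = _grid_terms(traj, spec, input)
    cv = u_grid @ spec.C.T
    return core + 2.0 * np.sum((cv + w_grid) * states.real, axis=1)


def hamiltonian_drift(traj: Trajectory, spec: LinearModelSpec) -> float:
    """Max_t |H(t) - H(0)|; zero (to integrator accuracy) for trajectories of
    the non-dissipative modified equation, growing for the original one."""
    H = hamiltonian_series(traj, spec)
    return float(np.max(np.abs(H - H[0])))


def action_value(traj: Trajectory, spec: LinearModelSpec,
                 input: InputSignal | None = None) -> float:
    """Trapezoidal action S = int L dt (real part; the imaginary part is a
    rounding diagnostic for Hermitian A)."""
    if traj.n_steps < 3:
        raise ValidationError("action needs at least 3 grid points")
    u_grid, w_grid = _grid_terms(traj, spec, input)
    zdot = _velocities(traj.states, traj.times)
    L = _lagrangian_series(traj.states, zdot, spec, u_grid, w_grid)
    return float(np.trapezoid(L.real, traj.times))


def _action_of_states(states, times, spec, u_grid, w_grid) -> float:
    zdot = _velocities(states, times)
    L = _lagrangian_series(states, zdot, spec, u_grid, w_grid)
    return float(np.trapezoid(L.real, times))


def make_perturbations(T: int, n: int, n_perturbations: int, seed: int) -> np.ndarray:
    """Random differentiable complex perturbations (P, T, n) vanishing exactly
    at both endpoints, normalised to unit max modulus."""
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_perturbations, T, n)) + 1j * rng.standard_normal(
        (n_perturbations, T, n)
    )
    smooth = gaussian_filter1d(raw.real, sigma=max(T / 16, 2), axis=1, mode="reflect")
    smooth = smooth + 1j * gaussian_filter1d(
        raw.imag, sigma=max(T / 16, 2), axis=1, mode="reflect"
    )
    window = np.sin(np.pi * np.arange(T) / (T - 1))[None, :, None]
    eta = smooth * window
    eta[:, 0, :] = 0.0
    eta[:, -1, :] = 0.0
    scale = np.max(np.abs(eta), axis=(1, 2), keepdims=True)
    scale[scale == 0] = 1.0
    return eta / scale


def action_stationarity_check(
    traj: Trajectory,
    spec: LinearModelSpec,
    input: InputSignal | None = None,
    perturbation_scale: float = 1e-3,
    seed: int = 0,
    n_perturbations: int = 8,
    perturbations: np.ndarray | None = None,
) -> tuple[float, float]:
    """Finite-difference test of stationarity of the action.

    For each endpoint-pinned perturbation eta, computes
    dS(+eps) = S[z + eps*eta] - S[z] and dS(-eps), and splits them into odd
    (first-order) and even (second-order) components in eps. Returns the
    maxima of |first-order| and |second-order| over the perturbation set.
    Trajectories solving the modified equation have a vanishing first-order
    component; generic non-solutions do not.
    """
    if perturbation_scale <= 0:
        raise ValidationError("perturbation_scale must be positive")
    T, n = traj.states.shape
    u_grid, w_grid = _grid_terms(traj, spec, input)
    if perturbations is None:
        perturbations = make_perturbations(T, n, n_perturbations, seed)
    perturbations = np.asarray(perturbations, dtype=complex)
    if perturbations.ndim == 2:
        perturbations = perturbations[None]
    S0 = _action_of_states(traj.states, traj.times, spec, u_grid, w_grid)
    eps = perturbation_scale
    first = 0.0
    second = 0.0
    for eta in perturbations:
        Sp = _action_of_states(traj.states + eps * eta, traj.times, spec, u_grid, w_grid)
        Sm = _action_of_states(traj.states - eps * eta, traj.times, spec, u_grid, w_grid)
        odd = 0.5 * (Sp - Sm)
        even = 0.5 * (Sp + Sm) - S0
        first = max(first, abs(odd))
        second = max(second, abs(even))
    return first, second


def euler_lagrange_residual(traj: Trajectory, spec: LinearModelSpec,
                            input: InputSignal | None = None) -> np.ndarray:
    """Residual r(t) = i zdot - A z - C v - w of the modified equation,
    with zdot from central differences (T x n complex)."""
    u_grid, w_grid = _grid_terms(traj, spec, input)
    zdot = _velocities(traj.states, traj.times)
    cv = u_grid @ spec.C.T
    return 1j * zdot - traj.states @ spec.A.T - cv - w_grid


def adjoint_conjugacy_deviation(traj: Trajectory, spec: LinearModelSpec,
                                input: InputSignal | None = None) -> float:
    """Max |r_adjoint - conj(r)| where r_adjoint is the residual of the
    adjoint equation -i zdot* = A^T z* + C v + w; zero for Hermitian A."""
    u_grid, w_grid = _grid_terms(traj, spec, input)
    zdot = _velocities(traj.states, traj.times)
    cv = u_grid @ spec.C.T
    r = 1j * zdot - traj.states @ spec.A.T - cv - w_grid
    r_adj = -1j * zdot.conj() - traj.states.conj() @ spec.A - cv - w_grid
    return float(np.max(np.abs(r_adj - r.conj())))


# ---------------------------------------------------------------------------
# the real-variable second-order embedding ("failed attempt")


@dataclass(frozen=True)
class SecondOrderEmbedding:
    """Coefficients of d2z/dt2 = E z + f obtained by differentiating the
    constant-input real equation dz/dt = A z + d once: E = A^2, f = A d."""

    E: np.ndarray
    f: np.ndarray


def second_order_embedding(A, d) -> SecondOrderEmbedding:
    A = np.asarray(A, dtype=float)
    d = np.asarray(d, dtype=float).reshape(-1)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"A must be square, got {A.shape}")
    if d.shape[0] != A.shape[0]:
        raise ShapeError("d must have length n")
    return SecondOrderEmbedding(E=A @ A, f=A @ d)


def spurious_solution_residual(a: float, d: float, k1: float, k2: float,
                               t: float) -> float:
    """First-order residual zdot - a z - d of the two-constant family
    z(t) = k1 e^{at} + k2 e^{-at} - d/a that solves the embedded second-order
    equation; analytically -2 a k2 e^{-at}, i.e. zero only when k2 = 0."""
    if a == 0:
        raise ValidationError("a must be non-zero (degenerate system)")
    z = k1 * np.exp(a * t) + k2 * np.exp(-a * t) - d / a
    zdot = a * k1 * np.exp(a * t) - a * k2 * np.exp(-a * t)
    return float(zdot - a * z - d)


def real_lagrangian_value(z, zdot, E, f) -> float:
    """The real-variable Lagrangian sum_j (zdot_j^2/2 + f_j z_j) + z^T E z / 2
    of the embedded equation; requires symmetric E."""
    z = np.asarray(z, dtype=float).reshape(-1)
    zdot = np.asarray(zdot, dtype=float).reshape(-1)
    E = np.asarray(E, dtype=float)
    f = np.asarray(f, dtype=float).reshape(-1)
    if E.ndim != 2 or E.shape[0] != E.shape[1]:
        raise ShapeError("E must be square")
    if np.max(np.abs(E - E.T)) > 1e-12:
        raise ValidationError("E must be symmetric for a Lagrangian to exist")
    if z.shape != zdot.shape or z.shape[0] != E.shape[0] or f.shape != z.shape:
        raise ShapeError("z, zdot, f must all have length n")
    return float(0.5 * np.sum(zdot**2) + f @ z + 0.5 * z @ E @ z)


# ---------------------------------------------------------------------------
# report


@dataclass(frozen=True)
class MechanicsReport:
    """L(t), H(t), action, Euler-Lagrange residuals for one trajectory."""

    lagrangian: np.ndarray
    hamiltonian: np.ndarray
    action: float
    el_residual: np.ndarray
    max_imag_lagrangian: float
    adjoint_max_deviation: float


def mechanics_report(traj: Trajectory, spec: LinearModelSpec,
                     input: InputSignal | None = None) -> MechanicsReport:
    u_grid, w_grid = _grid_terms(traj, spec, input)
    zdot = _velocities(traj.states, traj.times)
    L = _lagrangian_series(traj.states, zdot, spec, u_grid, w_grid)
    H = hamiltonian_series(traj, spec, input)
    S = float(np.trapezoid(L.real, traj.times))
    r = euler_lagrange_residual(traj, spec, input)
    adj = adjoint_conjugacy_deviation(traj, spec, input)
    return MechanicsReport(
        lagrangian=L.real,
        hamiltonian=H,
        action=S,
        el_residual=r,
        max_imag_lagrangian=float(np.max(np.abs(L.imag))),
        adjoint_max_deviation=adj,
    )
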