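"""Synthetic three-node networks, inputs, and labelled datasets.

The default generator emulates the simulation study both state equations are
exercised on: a three-node network with symmetric off-diagonal coupling and a
negative leading diagonal (stable for the original variant), a Gaussian
"bump" of exogenous input driving node 1, smooth (temporally correlated)
Gaussian state noise, and an observer that keeps the real component of the
states. Observations are standardized to "normalized intensity": each channel
is centred to mean zero and the whole array scaled so its largest magnitude
is 1 (a single global scale preserves the relative amplitudes between
channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .models import (
    InputSignal,
    LinearModelSpec,
    NoiseSpec,
    Trajectory,
    check_stability,
    simulate,
    smoothed_gaussian_noise,
)

__all__ = [
    "SyntheticDataset",
    "make_three_node_network",
    "gaussian_bump",
    "random_input",
    "generate_dataset",
    "standardize",
    "DEFAULT_NOISE",
]

#: study-condition defaults: modest smooth state noise plus observation noise
DEFAULT_NOISE = NoiseSpec(state_sd=0.05, input_sd=0.0, smoothness=4.0,
                          obs_sd=0.05, seed=0)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre each channel to mean 0 and scale the array to max |value| = 1.

    Returns ``(standardized, centers, scale)``; an (all-zero) degenerate
    array gets scale 1 so the transform is always invertible.
    """
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    Y = X - centers
    scale = float(np.max(np.abs(Y))) if Y.size else 1.0
    if scale < 1e-12:
        scale = 1.0
    return Y / scale, centers, scale


def make_three_node_network(diag: float = -0.5, off: float = 0.2,
                            variant: str = "original") -> LinearModelSpec:
    """Symmetric 3x3 coupling with ``diag`` on the leading diagonal and
    ``off`` everywhere else; the exogenous input drives node 1 only.

    The defaults give eigenvalues {diag + 2*off, diag - off (x2)} =
    {-0.1, -0.7, -0.7}, i.e. stable dynamics for the original variant.
    """
    if not (np.isfinite(diag) and np.isfinite(off)):
        raise ValidationError("network parameters must be finite")
    A = np.full((3, 3), off, dtype=float)
    np.fill_diagonal(A, diag)
    C = np.array([[1.0], [0.0], [0.0]])
    spec = LinearModelSpec(A=A, C=C, variant=variant)
    if variant == "original":
        stable, _ = check_stability(A)
        if not stable:
            warnings.warn(
                "three-node network is unstable for the original variant",
                stacklevel=2,
            )
    return spec


def gaussian_bump(T: int, center: float | None = None, width: float | None = None,
                  amplitude: float = 1.0, dt: float = 1.0) -> InputSignal:
    """Single-channel Gaussian bump u(t) = amplitude * exp(-(t-center)^2 / 2 width^2)
    on a grid of ``T`` points; defaults peak at T/4 with width T/64 (a brief stimulus whose spectral bandwidth covers the network's eigenfrequencies)."""
    if T < 2:
        raise ValidationError("T must be at least 2")
    times = np.arange(T) * dt
    if center is None:
        center = T * dt / 4.0
    if width is None:
        width = T * dt / 64.0
    if width <= 0:
        raise ValidationError("width must be positive")
    u = amplitude * np.exp(-((times - center) ** 2) / (2.0 * width**2))
    return InputSignal(times, u[:, None])


def random_input(T: int, n_channels: int, sd: float, smoothness: float,
                 seed: int, dt: float = 1.0) -> InputSignal:
    """Kernel-smoothed Gaussian drive, one column per channel (models ongoing
    fluctuations feeding every node); deterministic per seed."""
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = smoothed_gaussian_noise(rng, (T, n_channels), sd, smoothness)
    return InputSignal(np.arange(T) * dt, values)


@dataclass(frozen=True)
class SyntheticDataset:
    """A labelled synthetic recording with its generating ground truth."""

    spec_true: LinearModelSpec
    input: InputSignal
    noise: NoiseSpec
    trajectory: Trajectory
    observations: np.ndarray
    label: str
    seed: int
    centers: np.ndarray
    scale: float

    @property
    def times(self) -> np.ndarray:
        return self.trajectory.times


def generate_dataset(variant: str, seed: int, T: int = 128,
                     noise: NoiseSpec | None = None, dt: float = 1.0,
                     diag: float = -0.5, off: float = 0.2,
                     bump_amplitude: float = 1.0) -> SyntheticDataset:
    """Generate one labelled dataset: network + bump input + simulation +
    real-part observer + standardization."""
    if variant not in ("original", "modified"):
        raise ValidationError(f"unknown variant {variant!r}")
    if noise is None:
        noise = DEFAULT_NOISE
    noise = replace(noise, seed=int(seed))
    spec = make_three_node_network(diag=diag, off=off, variant=variant)
    bump = gaussian_bump(T, amplitude=bump_amplitude, dt=dt)
    z0 = np.zeros(3, dtype=complex)
    traj = simulate(spec, z0, bump, noise, T, dt)
    obs_std, centers, scale = standardize(traj.observations)
    return SyntheticDataset(
        spec_true=spec,
        input=bump,
        noise=noise,
        trajectory=traj,
        observations=obs_std,
        label=variant,
        seed=int(seed),
        centers=centers,
        scale=scale,
    )
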