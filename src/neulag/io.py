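"""Delimited-text timeseries readers and structured JSON reports.

Timeseries come in as plain delimited text (CSV/TSV/whitespace), time-major
or channel-major, with an optional single header row that is auto-detected.
Fits, comparisons, mechanics reports and datasets serialize to versioned JSON
whose numeric fields round-trip losslessly (Python's JSON float formatting is
shortest-round-trip for binary64).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigError, ShapeError, ValidationError
from .inversion import ModelComparison, PosteriorFit
from .mechanics import MechanicsReport
from .models import InputSignal, LinearModelSpec, NoiseSpec, Trajectory
from .synth import SyntheticDataset

__all__ = [
    "read_timeseries",
    "write_report",
    "read_report",
    "write_dataset",
    "read_dataset",
    "RunConfig",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# timeseries


def _detect_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any whitespace


def read_timeseries(path, orientation: str = "time_major",
                    delimiter: str | None = None,
                    n_channels_limit: int | None = None,
                    n_time_limit: int | None = None) -> np.ndarray:
    """Read a delimited numeric table and return a time-major (T x n) matrix.

    ``orientation`` states how the *file* is laid out; a channel-major file is
    transposed after reading. Optional limits keep the first K channels and
    first T time points. A single leading header row of non-numeric labels is
    skipped automatically.
    """
    if orientation not in ("time_major", "channel_major"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path} is empty")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])

    def split(line):
        return line.split(delimiter) if delimiter else line.split()

    start = 0
    first = split(lines[0])
    try:
        [float(c) for c in first]
    except ValueError:
        start = 1
        if len(lines) == 1:
            raise ValidationError(f"{path} has a header row but no data")

    rows = []
    width = None
    for i, line in enumerate(lines[start:], start=start + 1):
        cells = split(line)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValidationError(
                f"{path}: ragged row {i}: expected {width} cells, got {len(cells)}"
            )
        row = []
        for j, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                ) from None
        rows.append(row)
    data = np.asarray(rows, dtype=float)
    if orientation == "channel_major":
        data = data.T
    if n_channels_limit is not None:
        data = data[:, :n_channels_limit]
    if n_time_limit is not None:
        data = data[:n_time_limit]
    return data


# ---------------------------------------------------------------------------
# JSON helpers


def _encode_array(a: np.ndarray):
    a = np.asarray(a)
    if np.iscomplexobj(a):
        return {"__complex__": True, "real": a.real.tolist(), "imag": a.imag.tolist()}
    return a.tolist()


def _decode_array(obj):
    if isinstance(obj, dict) and obj.get("__complex__"):
        return np.asarray(obj["real"]) + 1j * np.asarray(obj["imag"])
    return np.asarray(obj, dtype=float)


# ---------------------------------------------------------------------------
# reports


def write_report(obj, path) -> None:
    """Serialize a PosteriorFit, ModelComparison or MechanicsReport."""
    if isinstance(obj, PosteriorFit):
        doc = {
            "kind": "posterior_fit",
            "variant": obj.variant,
            "theta_mean": _encode_array(obj.theta_mean),
            "theta_cov": _encode_array(obj.theta_cov),
            "A_posterior": _encode_array(obj.A_posterior),
            "free_energy": obj.free_energy,
            "log_precision": obj.log_precision,
            "predicted": _encode_array(obj.predicted),
            "iterations": obj.iterations,
            "converged": obj.converged,
            "trace": _encode_array(obj.trace),
            "damping": obj.damping,
            "centers": _encode_array(obj.centers),
            "scale": obj.scale,
            "data_shape": list(obj.data_shape),
        }
    elif isinstance(obj, ModelComparison):
        doc = {
            "kind": "model_comparison",
            "labels": list(obj.labels),
            "free_energies": _encode_array(obj.free_energies),
            "probabilities": _encode_array(obj.probabilities),
        }
    elif isinstance(obj, MechanicsReport):
        doc = {
            "kind": "mechanics_report",
            "lagrangian": _encode_array(obj.lagrangian),
            "hamiltonian": _encode_array(obj.hamiltonian),
            "action": obj.action,
            "el_residual": _encode_array(obj.el_residual),
            "max_imag_lagrangian": obj.max_imag_lagrangian,
            "adjoint_max_deviation": obj.adjoint_max_deviation,
        }
    else:
        raise ConfigError(f"cannot serialize object of type {type(obj).__name__}")
    doc["schema_version"] = SCHEMA_VERSION
    Path(path).write_text(json.dumps(doc, indent=1))


def read_report(path):
    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "posterior_fit":
        return PosteriorFit(
            variant=doc["variant"],
            theta_mean=_decode_array(doc["theta_mean"]),
            theta_cov=_decode_array(doc["theta_cov"]),
            A_posterior=_decode_array(doc["A_posterior"]),
            free_energy=doc["free_energy"],
            log_precision=doc["log_precision"],
            predicted=_decode_array(doc["predicted"]),
            iterations=doc["iterations"],
            converged=doc["converged"],
            trace=_decode_array(doc["trace"]),
            damping=doc["damping"],
            centers=_decode_array(doc["centers"]),
            scale=doc["scale"],
            data_shape=tuple(doc["data_shape"]),
        )
    if kind == "model_comparison":
        return ModelComparison(
            labels=doc["labels"],
            free_energies=_decode_array(doc["free_energies"]),
            probabilities=_decode_array(doc["probabilities"]),
        )
    if kind == "mechanics_report":
        return MechanicsReport(
            lagrangian=_decode_array(doc["lagrangian"]),
            hamiltonian=_decode_array(doc["hamiltonian"]),
            action=doc["action"],
            el_residual=_decode_array(doc["el_residual"]),
            max_imag_lagrangian=doc["max_imag_lagrangian"],
            adjoint_max_deviation=doc["adjoint_max_deviation"],
        )
    raise ConfigError(f"unknown report kind {kind!r} in {path}")


# ---------------------------------------------------------------------------
# datasets


def write_dataset(ds: SyntheticDataset, directory) -> None:
    """Write observations as CSV plus a JSON sidecar with the full trajectory
    and ground truth (enough to reproduce mechanics and inversion)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = ",".join(f"node{i + 1}" for i in range(ds.observations.shape[1]))
    body = "\n".join(
        ",".join(repr(float(x)) for x in row) for row in ds.observations
    )
    (directory / "observations.csv").write_text(header + "\n" + body + "\n")
    traj = ds.trajectory
    doc = {
        "kind": "synthetic_dataset",
        "schema_version": SCHEMA_VERSION,
        "label": ds.label,
        "seed": ds.seed,
        "A_true": _encode_array(ds.spec_true.A),
        "C": _encode_array(ds.spec_true.C),
        "variant": ds.spec_true.variant,
        "non_dissipative": ds.spec_true.non_dissipative,
        "noise": {
            "state_sd": ds.noise.state_sd,
            "input_sd": ds.noise.input_sd,
            "smoothness": ds.noise.smoothness,
            "obs_sd": ds.noise.obs_sd,
            "seed": ds.noise.seed,
        },
        "times": _encode_array(traj.times),
        "states": _encode_array(traj.states),
        "observations_raw": _encode_array(traj.observations),
        "observations_std": _encode_array(ds.observations),
        "input_times": _encode_array(ds.input.times),
        "input_values": _encode_array(ds.input.values),
        "noise_state": _encode_array(traj.state_noise()),
        "noise_input": _encode_array(
            traj.noise_realization.get("input")
            if traj.noise_realization
            else np.zeros((traj.n_steps, ds.input.n_channels))
        ),
        "centers": _encode_array(ds.centers),
        "scale": ds.scale,
    }
    (directory / "dataset.json").write_text(json.dumps(doc, indent=1))


def read_dataset(directory) -> SyntheticDataset:
    doc = json.loads((Path(directory) / "dataset.json").read_text())
    if doc.get("kind") != "synthetic_dataset":
        raise ConfigError(f"{directory} does not contain a dataset sidecar")
    spec = LinearModelSpec(
        A=_decode_array(doc["A_true"]),
        C=_decode_array(doc["C"]),
        variant=doc["variant"],
        non_dissipative=doc["non_dissipative"],
    )
    inp = InputSignal(_decode_array(doc["input_times"]), _decode_array(doc["input_values"]))
    noise = NoiseSpec(**doc["noise"])
    traj = Trajectory(
        times=_decode_array(doc["times"]),
        states=_decode_array(doc["states"]),
        observations=_decode_array(doc["observations_raw"]),
        inputs_used=inp,
        noise_realization={
            "state": _decode_array(doc["noise_state"]),
            "input": _decode_array(doc["noise_input"]),
        },
    )
    return SyntheticDataset(
        spec_true=spec,
        input=inp,
        noise=noise,
        trajectory=traj,
        observations=_decode_array(doc["observations_std"]),
        label=doc["label"],
        seed=doc["seed"],
        centers=_decode_array(doc["centers"]),
        scale=doc["scale"],
    )


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_DEFAULTS = {
    "schema_version": SCHEMA_VERSION,
    "dt": 1.0,
    "T": 128,
    "seed": 0,
    "variant": "original",
    "diag": -0.5,
    "off": 0.2,
    "bump_amplitude": 1.0,
    "state_sd": 0.05,
    "input_sd": 0.0,
    "smoothness": 4.0,
    "obs_sd": 0.05,
    "prior_diag": -0.25,
    "prior_sd": 0.25,
    "log_precision_mean": float(np.log(32.0)),
    "log_precision_sd": 1.0,
    "max_iter": 64,
    "tol": 1e-4,
}


class RunConfig:
    """Flat run configuration mirroring every tunable default.

    Unknown keys are rejected; a fully-defaulted config round-trips through
    ``to_dict``/``from_dict`` unchanged.
    """

    def __init__(self, **kwargs):
        unknown = set(kwargs) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, default in _CONFIG_DEFAULTS.items():
            setattr(self, key, kwargs.get(key, default))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _CONFIG_DEFAULTS}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(
            state_sd=self.state_sd,
            input_sd=self.input_sd,
            smoothness=self.smoothness,
            obs_sd=self.obs_sd,
            seed=self.seed,
        )

    def __eq__(self, other):
        return isinstance(other, RunConfig) and self.to_dict() == other.to_dict()
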