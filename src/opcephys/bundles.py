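"""Sweep bundles: the on-disk and in-memory unit of voltage-clamp data.

A bundle is one cell's set of current sweeps under a shared step protocol,
plus metadata and (for simulated cells) the generator's ground truth. On
disk a bundle is a directory with a YAML manifest and one two-column
(time s, current pA) TSV per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["StepProtocol", "SweepBundle", "write_bundle", "read_bundle"]


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step protocol: hold at ``holding_mv``, step to each of
    ``step_potentials_mv`` between ``step_start_ms`` and ``step_end_ms``.

    The default is the standard OPC characterization protocol: 20 mV steps
    from −134 to +26 mV, sampled at 50 kHz. Potentials are in
    junction-corrected coordinates.
    """

    holding_mv: float = -74.0
    step_start_ms: float = 100.0
    step_end_ms: float = 600.0
    step_potentials_mv: tuple = tuple(float(v) for v in range(-134, 27, 20))
    sweep_duration_ms: float = 700.0
    sampling_rate_hz: float = 50_000.0

    def __post_init__(self) -> None:
        v = np.asarray(self.step_potentials_mv)
        if len(v) == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("step potentials must be strictly increasing")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0 <= self.step_start_ms < self.step_end_ms <= self.sweep_duration_ms:
            raise ValueError("step window must lie inside the sweep")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_duration_ms / self.dt_ms)) + 1

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def command_waveforms(self) -> np.ndarray:
        """(n_sweeps, n_samples) command voltage matrix; the step is active
        for step_start <= t < step_end (onset sample included)."""
        t = self.time_ms()
        in_step = (t >= self.step_start_ms) & (t < self.step_end_ms)
        cmds = np.full((len(self.step_potentials_mv), self.n_samples), self.holding_mv)
        for i, v in enumerate(self.step_potentials_mv):
            cmds[i, in_step] = v
        return cmds


@dataclass
class SweepBundle:
    """One cell's sweeps (pA), one row per step potential, plus metadata.

    ``ground_truth`` is populated by the simulator (true membrane
    parameters, true inward conductance, labels) and absent for real data.
    """

    protocol: StepProtocol
    sweeps_pa: np.ndarray  # (n_sweeps, n_samples)
    cell_id: str = "cell"
    metadata: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.sweeps_pa = np.asarray(self.sweeps_pa, dtype=float)
        expected = (len(self.protocol.step_potentials_mv), self.protocol.n_samples)
        if self.sweeps_pa.shape != expected:
            raise ValueError(
                f"sweep array shape {self.sweeps_pa.shape} does not match protocol {expected}"
            )


def _to_native(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_bundle(bundle: SweepBundle, directory: str | Path) -> Path:
    """Write a bundle as manifest.yaml + sweep_NN.tsv files; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cell_id": bundle.cell_id,
        "protocol": asdict(bundle.protocol) | {
            "step_potentials_mv": list(bundle.protocol.step_potentials_mv)
        },
        "metadata": bundle.metadata,
        "ground_truth": bundle.ground_truth,
        "n_sweeps": len(bundle.protocol.step_potentials_mv),
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_to_native(manifest), fh, sort_keys=False)
    t_s = bundle.protocol.time_ms() / 1000.0
    for i, sweep in enumerate(bundle.sweeps_pa):
        np.savetxt(
            directory / f"sweep_{i:02d}.tsv",
            np.column_stack([t_s, sweep]),
            delimiter="\t",
            header="time_s\tcurrent_pA",
            comments="",
        )
    return directory


def read_bundle(directory: str | Path) -> SweepBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {directory}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    proto_dict = dict(manifest["protocol"])
    proto_dict["step_potentials_mv"] = tuple(proto_dict["step_potentials_mv"])
    protocol = StepProtocol(**proto_dict)
    sweeps = []
    for i in range(manifest["n_sweeps"]):
        path = directory / f"sweep_{i:02d}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"bundle {directory}: missing sweep file {path.name}")
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        if data.ndim != 2 or data.shape[0] != protocol.n_samples:
            raise ValueError(
                f"bundle {directory}: sweep {i} has {data.shape[0]} samples, "
                f"expected {protocol.n_samples}"
            )
        sweeps.append(data[:, 1])
    return SweepBundle(
        protocol=protocol,
        sweeps_pa=np.asarray(sweeps),
        cell_id=manifest.get("cell_id", directory.name),
        metadata=manifest.get("metadata") or {},
        ground_truth=manifest.get("ground_truth"),
    )
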