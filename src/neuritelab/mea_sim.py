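"""Synthetic multielectrode-array recordings.

Cells are simulated as inhomogeneous Poisson processes: a constant
baseline firing rate everywhere, plus — for responder cells — a
stimulus-locked rate elevation whose amplitude follows a saturating
dose-response curve on log10 irradiance.  The superposition property of
Poisson processes makes the generator exact: baseline spikes over the
whole recording plus independent evoked spikes inside each stimulus
window together form the intended inhomogeneous process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StimulusProtocol:
    """Full-field light stimulation protocol.

    onsets_s : stimulus start times, sorted, seconds
    durations_s : stimulus durations, seconds
    irradiances : photon flux per stimulus, photons/cm^2/s, strictly increasing
    wavelength_nm : stimulation wavelength
    recording_length_s : total recording span
    """

    onsets_s: tuple[float, ...]
    durations_s: tuple[float, ...]
    irradiances: tuple[float, ...]
    wavelength_nm: float
    recording_length_s: float
    baseline_window_s: float = 30.0

    def __post_init__(self) -> None:
        n = len(self.onsets_s)
        if not (len(self.durations_s) == len(self.irradiances) == n):
            raise ValueError("onsets, durations and irradiances must align")
        if n == 0:
            raise ValueError("protocol needs at least one stimulus")
        onsets = np.asarray(self.onsets_s)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if onsets[0] < self.baseline_window_s:
            raise ValueError("first onset must leave room for a baseline window")
        offs = onsets + np.asarray(self.durations_s)
        if np.any(onsets[1:] - offs[:-1] < self.baseline_window_s):
            raise ValueError("inter-stimulus gap shorter than the baseline window")
        if offs[-1] > self.recording_length_s:
            raise ValueError("last stimulus exceeds the recording")
        irr = np.asarray(self.irradiances)
        if np.any(np.diff(irr) <= 0):
            raise ValueError("irradiances must be strictly increasing")

    @property
    def n_stimuli(self) -> int:
        return len(self.onsets_s)

    def to_dict(self) -> dict:
        return {
            "onsets_s": list(self.onsets_s),
            "durations_s": list(self.durations_s),
            "irradiances": list(self.irradiances),
            "wavelength_nm": self.wavelength_nm,
            "recording_length_s": self.recording_length_s,
            "baseline_window_s": self.baseline_window_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            onsets_s=tuple(d["onsets_s"]),
            durations_s=tuple(d["durations_s"]),
            irradiances=tuple(d["irradiances"]),
            wavelength_nm=d["wavelength_nm"],
            recording_length_s=d["recording_length_s"],
            baseline_window_s=d.get("baseline_window_s", 30.0),
        )

    @classmethod
    def uv_four(cls) -> "StimulusProtocol":
        """Four 30-s UV flashes of increasing irradiance (365 nm)."""
        irr = tuple(np.geomspace(1.17e11, 1.02e14, 4))
        onsets = tuple(30.0 + 120.0 * i for i in range(4))
        return cls(
            onsets_s=onsets,
            durations_s=(30.0,) * 4,
            irradiances=irr,
            wavelength_nm=365.0,
            recording_length_s=onsets[-1] + 120.0,
        )

    @classmethod
    def blue_five(cls) -> "StimulusProtocol":
        """Five 30-s blue flashes of increasing irradiance (470 nm)."""
        irr = tuple(np.geomspace(4.82e11, 9.01e15, 5))
        onsets = tuple(30.0 + 120.0 * i for i in range(5))
        return cls(
            onsets_s=onsets,
            durations_s=(30.0,) * 5,
            irradiances=irr,
            wavelength_nm=470.0,
            recording_length_s=onsets[-1] + 120.0,
        )


@dataclass(frozen=True)
class ResponseModel:
    """Dose-response model of one cell.

    Evoked rate at irradiance I (photons/cm^2/s) is a Hill-type
    saturating function of log10(I):

        r(I) = max_evoked_rate / (1 + 10^(-slope * (log10 I - log_ec50)))

    applied for ``evoked_duration_s`` seconds from each stimulus onset
    (capped at the stimulus duration), on top of the baseline rate.
    Non-responders never deviate from baseline.
    """

    baseline_rate: float = 5.0
    max_evoked_rate: float = 25.0
    log_ec50: float = 12.5
    slope: float = 1.0
    evoked_duration_s: float = 10.0
    responder: bool = True

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.max_evoked_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.evoked_duration_s < 0:
            raise ValueError("evoked duration must be non-negative")

    def evoked_rate(self, irradiance: float) -> float:
        """Rate elevation (spikes/s) at the given irradiance."""
        if not self.responder or self.max_evoked_rate == 0:
            return 0.0
        x = np.log10(irradiance)
        return float(self.max_evoked_rate / (1.0 + 10.0 ** (-self.slope * (x - self.log_ec50))))


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one cell."""

    cell_id: str
    times_s: np.ndarray
    recording_length_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size and (
            np.any(np.diff(self.times_s) < 0)
            or self.times_s[0] < 0
            or self.times_s[-1] > self.recording_length_s
        ):
            raise ValueError("timestamps must be sorted within [0, recording_length]")

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


@dataclass
class Recording:
    """A population of spike trains plus the protocol and generation metadata."""

    trains: list[SpikeTrain]
    protocol: StimulusProtocol
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"cell_id": t.cell_id, "timestamp_s": ts}
            for t in self.trains
            for ts in t.times_s
        ]
        pd.DataFrame(rows, columns=["cell_id", "timestamp_s"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, spikes_path: str | Path, protocol_path: str | Path) -> "Recording":
        protocol = StimulusProtocol.from_dict(json.loads(Path(protocol_path).read_text()))
        df = pd.read_csv(spikes_path)
        trains = []
        for cell_id, grp in df.groupby("cell_id", sort=True):
            trains.append(
                SpikeTrain(
                    cell_id=str(cell_id),
                    times_s=np.sort(grp["timestamp_s"].to_numpy()),
                    recording_length_s=protocol.recording_length_s,
                )
            )
        return cls(trains=trains, protocol=protocol)


def _homogeneous_spikes(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    if rate < 0:
        raise ValueError("negative rate")
    span = t1 - t0
    if rate == 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_spike_train(
    protocol: StimulusProtocol,
    model: ResponseModel,
    seed: int,
    cell_id: str = "cell_0",
) -> SpikeTrain:
    """Draw one inhomogeneous-Poisson spike train for one cell."""
    rng = np.random.default_rng(seed)
    parts = [_homogeneous_spikes(rng, model.baseline_rate, 0.0, protocol.recording_length_s)]
    for onset, duration, irr in zip(
        protocol.onsets_s, protocol.durations_s, protocol.irradiances
    ):
        extra = model.evoked_rate(irr)
        if extra > 0:
            evoked_end = onset + min(model.evoked_duration_s, duration)
            parts.append(_homogeneous_spikes(rng, extra, onset, evoked_end))
    times = np.sort(np.concatenate(parts))
    return SpikeTrain(cell_id=cell_id, times_s=times, recording_length_s=protocol.recording_length_s)


DEFAULT_MODEL_RANGES = {
    "baseline_rate": (2.0, 8.0),
    "max_evoked_rate": (15.0, 35.0),
    "log_ec50": (12.0, 13.0),
    "slope": (0.8, 1.5),
    "evoked_duration_s": (8.0, 15.0),
}


def generate_population(
    protocol: StimulusProtocol,
    n_cells: int,
    responder_fraction: float,
    model_ranges: dict | None = None,
    seed: int = 0,
) -> Recording:
    """Simulate a seeded population with a fixed responder fraction.

    Exactly ``round(n_cells * responder_fraction)`` cells are responders;
    which cells respond, and each cell's model parameters, are drawn from
    ``model_ranges`` (uniform within each (lo, hi) pair).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be within [0, 1]")
    ranges = dict(DEFAULT_MODEL_RANGES)
    if model_ranges:
        ranges.update(model_ranges)
    rng = np.random.default_rng(seed)
    n_resp = int(round(n_cells * responder_fraction))
    responder_idx = set(rng.choice(n_cells, size=n_resp, replace=False).tolist())
    trains, meta = [], []
    for i in range(n_cells):
        params = {k: rng.uniform(*v) for k, v in ranges.items()}
        model = ResponseModel(responder=i in responder_idx, **params)
        train_seed = int(rng.integers(0, 2**31 - 1))
        cell_id = f"cell_{i:04d}"
        trains.append(generate_spike_train(protocol, model, train_seed, cell_id=cell_id))
        meta.append({"cell_id": cell_id, "responder": model.responder, **params})
    return Recording(trains=trains, protocol=protocol, metadata=pd.DataFrame(meta))


def write_recording(out_dir: str | Path, recording: Recording) -> dict:
    """Write spikes CSV, protocol JSON and generation metadata CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": out_dir / "spikes.csv",
        "protocol": out_dir / "protocol.json",
        "metadata": out_dir / "generation_metadata.csv",
    }
    recording.to_csv(paths["spikes"])
    paths["protocol"].write_text(json.dumps(recording.protocol.to_dict(), indent=2))
    if recording.metadata is not None and len(recording.metadata):
        recording.metadata.to_csv(paths["metadata"], index=False)
    return {k: str(v) for k, v in paths.items()}
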