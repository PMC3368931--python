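"""Plain-text file formats: spike/trigger/burst CSVs and configuration files.

All event times are stored in seconds at full double precision (17
significant digits), so a write/read roundtrip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import Burst, SpikeTrain, StimulusEvent
from .synth import GroundTruth, Recording, SynthConfig

__all__ = [
    "read_spike_csv",
    "write_spike_csv",
    "read_trigger_csv",
    "write_trigger_csv",
    "read_bursts_csv",
    "write_bursts_csv",
    "read_ground_truth_csv",
    "write_ground_truth_csv",
    "load_config",
]

_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FMT % x


def read_spike_csv(path, duration: float | None = None) -> SpikeTrain:
    """Read a one-column ``time_s`` CSV into a validated spike train.

    Duplicate or decreasing times are rejected with the offending line
    number (header = line 1).  If ``duration`` is not given it is taken
    as the last spike time plus a nanosecond.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        line = int(np.argmax(~np.isfinite(t))) + 2
        raise ValueError(f"{path}: non-finite time at line {line}, column time_s")
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        line = int(bad[0]) + 3  # +2 header/1-based, +1 second of the pair
        raise ValueError(
            f"{path}: non-increasing time at line {line}, column time_s"
        )
    if duration is None:
        duration = float(t[-1]) + 1e-9 if t.size else 0.0
    return SpikeTrain(times=t, duration=duration, id=path.stem)


def write_spike_csv(path, train: SpikeTrain) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\n")
        for t in train.times:
            fh.write(_fmt(t) + "\n")


def read_trigger_csv(path) -> list[StimulusEvent]:
    """Read a ``time_s,class`` CSV into sorted stimulus events."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(StimulusEvent(onset=float(row["time_s"]),
                                        class_id=int(row["class"])))
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {err}") from err
    return sorted(events, key=lambda e: e.onset)


def write_trigger_csv(path, events: list[StimulusEvent]) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,class\n")
        for e in events:
            fh.write(f"{_fmt(e.onset)},{e.class_id}\n")


def write_bursts_csv(path, bursts: list[Burst]) -> None:
    """Bursts as ``recording_id,onset_s,label,rel_times`` (semicolon-joined s)."""
    with open(path, "w") as fh:
        fh.write("recording_id,onset_s,label,rel_times\n")
        for b in bursts:
            rel = ";".join(_fmt(t) for t in b.rel_times)
            label = b.label if b.label is not None else ""
            fh.write(f"{b.recording_id},{_fmt(b.onset)},{label},{rel}\n")


def read_bursts_csv(path) -> list[Burst]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"label": str, "recording_id": str},
                     keep_default_na=False, float_precision="round_trip")
    bursts = []
    for i, row in df.iterrows():
        try:
            rel = np.array([float(x) for x in str(row["rel_times"]).split(";") if x])
            bursts.append(Burst(
                onset=float(row["onset_s"]), rel_times=rel,
                label=row["label"] or None, recording_id=row["recording_id"],
            ))
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {err}") from err
    return bursts


def write_ground_truth_csv(path, gt: GroundTruth) -> None:
    df = gt.frame.copy()
    df["onset_s"] = df["onset_s"].map(_fmt)
    df.to_csv(path, index=False)


def read_ground_truth_csv(path) -> GroundTruth:
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    return GroundTruth(frame=df)


def write_recording(outdir, rec: Recording, gt: GroundTruth | None = None,
                    prefix: str = "recording") -> dict:
    """Write spikes/triggers/ground-truth CSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"spikes": outdir / f"{prefix}_spikes.csv"}
    write_spike_csv(paths["spikes"], rec.train)
    if rec.triggers:
        paths["triggers"] = outdir / f"{prefix}_triggers.csv"
        write_trigger_csv(paths["triggers"], rec.triggers)
    if gt is not None:
        paths["ground_truth"] = outdir / f"{prefix}_truth.csv"
        write_ground_truth_csv(paths["ground_truth"], gt)
    return {k: str(v) for k, v in paths.items()}


def load_config(path) -> dict:
    """Load a JSON or YAML key-value configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def synth_config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    if "stimulus_classes" in d:
        d["stimulus_classes"] = tuple(d["stimulus_classes"])
    return SynthConfig(**d)
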