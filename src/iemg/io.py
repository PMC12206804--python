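"""On-disk formats for recordings, electrode maps, annotations and impedance logs.

A recording is stored as two sibling files sharing a stem: ``<stem>.csv``
holds the sample matrix (one column per channel, 17 significant digits so
doubles round-trip exactly) and ``<stem>.json`` is a sidecar carrying the
sampling rate, channel map, electrode records, movement-group tags and
interval annotations.  Impedance logs are plain CSV.  Everything is
human-inspectable text.

Conventions: time in seconds, 0-based sample indexing, half-open annotation
intervals ``[start, end)``; the first sample of a window at ``start_s`` is
``floor(start_s * fs)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .impedance import ImpedanceMeasurement

REST_LABEL = "rest"

ELECTRODE_TYPES = ("epimysial", "intramuscular")
POLARITIES = ("monopolar", "bipolar")
CONSTRUCTS = ("none", "TMR", "RPNI")


@dataclass(frozen=True)
class ElectrodeRecord:
    """Metadata for one implanted electrode."""

    electrode_id: str
    etype: str                      # epimysial | intramuscular
    polarity: str = "monopolar"     # monopolar | bipolar
    target_muscle: str = ""
    neuromuscular_construct: str = "none"   # none | TMR | RPNI

    def __post_init__(self):
        if self.etype not in ELECTRODE_TYPES:
            raise ValueError(f"unknown electrode type {self.etype!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.neuromuscular_construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.neuromuscular_construct!r}")


@dataclass(frozen=True)
class Annotation:
    """Half-open labeled interval ``[start_s, end_s)``.

    ``label`` is a movement class or ``"rest"``; movement annotations carry
    a 1-based repetition index (rest uses 0).
    """

    start_s: float
    end_s: float
    label: str
    repetition: int = 0

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")
        if self.label != REST_LABEL and self.repetition < 1:
            raise ValueError(f"movement annotation {self.label!r} needs repetition >= 1")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def sample_range(self, fs: float) -> tuple[int, int]:
        return (math.floor(self.start_s * fs), math.floor(self.end_s * fs))


@dataclass
class LabeledRecording:
    """Multi-channel EMG samples with an electrode map and interval labels.

    ``samples`` is channels x time (arbitrary amplitude units).
    ``movement_groups`` tags each movement label as ``"gross"`` or
    ``"finger"``; labels absent from the map simply belong to no group.
    """

    samples: np.ndarray
    sampling_rate_hz: int
    channel_map: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    electrode_records: list[ElectrodeRecord] = field(default_factory=list)
    movement_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_map) != self.samples.shape[0]:
            raise ValueError(
                f"channel map has {len(self.channel_map)} entries for "
                f"{self.samples.shape[0]} channels")
        self._validate_annotations()

    def _validate_annotations(self):
        dur = self.duration_s
        eps = 1e-9
        ordered = sorted(self.annotations, key=lambda a: a.start_s)
        prev_end = -math.inf
        for a in ordered:
            if a.start_s < -eps or a.end_s > dur + eps:
                raise ValueError(
                    f"annotation [{a.start_s}, {a.end_s}) outside signal [0, {dur})")
            if a.start_s < prev_end - eps:
                raise ValueError(f"overlapping annotations at {a.start_s}")
            prev_end = a.end_s

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz

    @property
    def movement_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.annotations:
            if a.label != REST_LABEL:
                seen.setdefault(a.label)
        return list(seen)

    def channel_index(self, electrode_id: str) -> int:
        try:
            return self.channel_map.index(electrode_id)
        except ValueError:
            raise KeyError(f"electrode {electrode_id!r} not in channel map") from None

    def intervals(self, label: str | None = None) -> list[Annotation]:
        if label is None:
            return list(self.annotations)
        return [a for a in self.annotations if a.label == label]

    def electrode_type(self, electrode_id: str) -> str:
        for rec in self.electrode_records:
            if rec.electrode_id == electrode_id:
                return rec.etype
        raise KeyError(f"no electrode record for {electrode_id!r}")


# ---------------------------------------------------------------------------
# Recording I/O  (CSV samples + JSON sidecar)
# ---------------------------------------------------------------------------

def write_recording(rec: LabeledRecording, path: str | Path) -> Path:
    """Write *rec* to ``<stem>.json`` (metadata) + ``<stem>.csv`` (samples).

    *path* may carry either suffix or none; the JSON sidecar path is
    returned and is what :func:`read_recording` expects.
    """
    base = Path(path)
    if base.suffix in (".json", ".csv"):
        base = base.with_suffix("")
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")

    frame = pd.DataFrame(rec.samples.T, columns=rec.channel_map)
    frame.to_csv(csv_path, index=False, float_format="%.17g")

    sidecar = {
        "format": "iemg-recording",
        "version": 1,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_map": list(rec.channel_map),
        "movement_groups": dict(rec.movement_groups),
        "electrode_records": [asdict(e) for e in rec.electrode_records],
        "annotations": [
            {"start_s": a.start_s, "end_s": a.end_s,
             "label": a.label, "repetition": a.repetition}
            for a in rec.annotations
        ],
        "samples_csv": csv_path.name,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return json_path


def read_recording(path: str | Path) -> LabeledRecording:
    """Read a recording written by :func:`write_recording`."""
    json_path = Path(path)
    if json_path.suffix != ".json":
        json_path = json_path.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    if meta.get("format") != "iemg-recording":
        raise ValueError(f"{json_path} is not an iemg recording sidecar")
    csv_path = json_path.parent / meta["samples_csv"]
    frame = pd.read_csv(csv_path)
    if list(frame.columns) != list(meta["channel_map"]):
        raise ValueError("sample CSV columns do not match the sidecar channel map")
    return LabeledRecording(
        samples=frame.to_numpy().T,
        sampling_rate_hz=int(meta["sampling_rate_hz"]),
        channel_map=list(meta["channel_map"]),
        movement_groups=dict(meta.get("movement_groups", {})),
        electrode_records=[ElectrodeRecord(**e) for e in meta.get("electrode_records", [])],
        annotations=[Annotation(**a) for a in meta.get("annotations", [])],
    )


# ---------------------------------------------------------------------------
# Impedance log I/O
# ---------------------------------------------------------------------------

IMPEDANCE_LOG_COLUMNS = ["participant", "frequency_hz", "connector_a",
                         "connector_b", "current_A", "voltage_V", "open_flag"]


def write_impedance_log(measurements, path: str | Path) -> Path:
    path = Path(path)
    rows = [{
        "participant": m.participant if m.participant is not None else "",
        "frequency_hz": m.frequency_hz,
        "connector_a": m.connector_a,
        "connector_b": m.connector_b,
        "current_A": m.current_amp_A,
        "voltage_V": m.voltage_amp_V,
        "open_flag": m.open_flag,
    } for m in measurements]
    pd.DataFrame(rows, columns=IMPEDANCE_LOG_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")
    return path


def read_impedance_log(path: str | Path) -> list[ImpedanceMeasurement]:
    """Parse an impedance log CSV into measurements.

    Duplicated (participant, frequency, pair) rows are an error: silently
    averaging them could mask instrument faults.
    """
    frame = pd.read_csv(Path(path), keep_default_na=False)
    missing = [c for c in IMPEDANCE_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"impedance log missing columns: {missing}")
    out: list[ImpedanceMeasurement] = []
    seen: set[tuple] = set()
    for row in frame.itertuples(index=False):
        participant = str(row.participant) or None
        open_flag = str(row.open_flag).strip().lower() in ("true", "1", "yes")
        m = ImpedanceMeasurement(
            frequency_hz=float(row.frequency_hz),
            connector_a=str(row.connector_a),
            connector_b=str(row.connector_b),
            current_amp_A=float(row.current_A),
            voltage_amp_V=float(row.voltage_V),
            open_flag=open_flag,
            participant=participant,
        )
        key = (participant, m.frequency_hz, m.pair)
        if key in seen:
            raise ValueError(f"duplicate impedance log row for {key}")
        seen.add(key)
        out.append(m)
    return out
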