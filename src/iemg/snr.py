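"""Movement-vs-rest signal-to-noise ratio per electrode.

SNR compares the RMS amplitude of an electrode's signal while the target
muscle contracts against its RMS at rest:

    SNR_dB = 10 * log10( RMS_movement^2 / RMS_rest^2 )

Steady-state signal is isolated by trimming a fixed fraction (default 25%)
of each movement interval from both ends, discarding the contraction ramp
and release.  The rest reference is the pooled RMS over all rest intervals
of the session -- one noise floor per electrode.  Per-electrode results are
reduced to the maximum SNR within the gross-movement group and within the
finger-movement group separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import LabeledRecording, Annotation, REST_LABEL

GROUPS = ("gross", "finger")


@dataclass(frozen=True)
class SnrRecord:
    """SNR of one electrode for one movement class."""

    electrode_id: str
    movement: str
    group: str          # gross | finger
    snr_db: float
    is_max: bool = False


def isolate_steady_state(interval: tuple[float, float],
                         trim_fraction: float = 0.25) -> tuple[float, float]:
    """Central portion of (start_s, end_s) after symmetric fractional trim."""
    if not (0 <= trim_fraction < 0.5):
        raise ValueError(f"trim fraction must be in [0, 0.5), got {trim_fraction}")
    start, end = interval
    dur = end - start
    if dur <= 0:
        raise ValueError(f"empty interval {interval}")
    cut = trim_fraction * dur
    out = (start + cut, end - cut)
    if not out[1] > out[0]:
        raise ValueError(f"steady-state sub-interval of {interval} is empty")
    return out


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.sqrt(np.mean(x ** 2)))


def snr_db(rms_movement: float, rms_rest: float) -> float:
    """10*log10(RMS_movement^2 / RMS_rest^2)."""
    if rms_rest <= 0:
        raise ValueError("rest RMS must be positive (degenerate noiseless input)")
    if rms_movement < 0:
        raise ValueError("movement RMS must be >= 0")
    if rms_movement == 0:
        return -math.inf
    return 10.0 * math.log10(rms_movement ** 2 / rms_rest ** 2)


def _slice(rec: LabeledRecording, channel: int, interval: tuple[float, float]) -> np.ndarray:
    fs = rec.sampling_rate_hz
    lo = math.floor(interval[0] * fs)
    hi = math.floor(interval[1] * fs)
    return rec.samples[channel, lo:hi]


def _pooled_rest_rms(rec: LabeledRecording, channel: int) -> float:
    chunks = [_slice(rec, channel, (a.start_s, a.end_s))
              for a in rec.intervals(REST_LABEL)]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        raise ValueError("recording has no rest annotation")
    return rms(np.concatenate(chunks))


def snr_records(rec: LabeledRecording,
                trim_fraction: float = 0.25,
                min_steady_s: float = 0.2) -> list[SnrRecord]:
    """Per-electrode, per-movement SNR records with group maxima flagged.

    A movement is *viable* for an electrode when its annotations provide at
    least ``min_steady_s`` seconds of steady-state signal in total (one
    analysis window by default).  Movements whose label has no group tag in
    ``rec.movement_groups`` are skipped.
    """
    if not rec.intervals(REST_LABEL):
        raise ValueError("recording has no rest annotation")
    out: list[SnrRecord] = []
    for ch, electrode in enumerate(rec.channel_map):
        rest = _pooled_rest_rms(rec, ch)
        per_movement: list[SnrRecord] = []
        for movement in rec.movement_labels:
            group = rec.movement_groups.get(movement)
            if group not in GROUPS:
                continue
            chunks = []
            total_s = 0.0
            for ann in rec.intervals(movement):
                steady = isolate_steady_state((ann.start_s, ann.end_s), trim_fraction)
                chunks.append(_slice(rec, ch, steady))
                total_s += steady[1] - steady[0]
            if total_s < min_steady_s or not chunks:
                continue
            value = snr_db(rms(np.concatenate(chunks)), rest)
            per_movement.append(SnrRecord(electrode, movement, group, value))
        # flag the per-group maxima
        for group in GROUPS:
            group_recs = [r for r in per_movement if r.group == group]
            if not group_recs:
                continue
            best = max(group_recs, key=lambda r: r.snr_db)
            per_movement[per_movement.index(best)] = SnrRecord(
                best.electrode_id, best.movement, best.group, best.snr_db, is_max=True)
        out.extend(per_movement)
    return out


def max_snr_per_electrode(rec: LabeledRecording,
                          trim_fraction: float = 0.25,
                          min_steady_s: float = 0.2) -> dict[str, dict[str, float]]:
    """Map electrode -> {group -> max SNR_dB over the group's viable movements}.

    Groups with no viable movement for an electrode are absent from its map.
    """
    result: dict[str, dict[str, float]] = {e: {} for e in rec.channel_map}
    for r in snr_records(rec, trim_fraction, min_steady_s):
        if r.is_max:
            result[r.electrode_id][r.group] = r.snr_db
    return result
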