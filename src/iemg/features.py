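"""Sliding-window time-domain EMG features (Hudgins set).

EMG pattern-recognition pipelines work on short overlapping analysis
windows (here 200 ms windows advanced in 50 ms steps) and the four classic
time-domain features per channel:

* **MAV** -- mean absolute value, an amplitude proxy;
* **WL** -- waveform length, total variation of the signal, mixing
  amplitude and frequency content;
* **ZC** -- zero crossings, a cheap frequency proxy;
* **SSC** -- slope sign changes, a second frequency proxy.

ZC and SSC accept a deadband threshold to ignore noise-induced crossings;
the default is 0 (no deadband).  Windows never span annotation boundaries:
each labeled interval is windowed independently, so no window mixes two
movement classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabeledRecording, REST_LABEL

FEATURE_NAMES = ("MAV", "SSC", "ZC", "WL")


@dataclass(frozen=True)
class WindowingSpec:
    window_s: float = 0.2
    increment_s: float = 0.05

    def __post_init__(self):
        if not (0 < self.increment_s <= self.window_s):
            raise ValueError(
                f"need 0 < increment ({self.increment_s}) <= window ({self.window_s})")

    def in_samples(self, fs: float) -> tuple[int, int]:
        return (round(self.window_s * fs), round(self.increment_s * fs))


def n_windows(n_samples: int, window: int, increment: int) -> int:
    """floor((N - W)/inc) + 1, the count of full windows (trailing partial dropped)."""
    if n_samples < window:
        return 0
    return (n_samples - window) // increment + 1


def segment_windows(samples: np.ndarray, fs: float,
                    spec: WindowingSpec = WindowingSpec()) -> list[tuple[int, int]]:
    """Half-open sample ranges [k*inc, k*inc + W) covering *samples*.

    The interval must fit at least one window; a trailing partial window is
    discarded.
    """
    n = np.asarray(samples).shape[-1]
    window, inc = spec.in_samples(fs)
    count = n_windows(n, window, inc)
    if count == 0:
        raise ValueError(f"interval of {n} samples shorter than one {window}-sample window")
    return [(k * inc, k * inc + window) for k in range(count)]


# ---------------------------------------------------------------------------
# The four features
# ---------------------------------------------------------------------------

def mav(window: np.ndarray) -> float:
    """Mean absolute value."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def wl(window: np.ndarray) -> float:
    """Waveform length: sum of absolute successive differences."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sum(np.abs(np.diff(x))))


def zc(window: np.ndarray, threshold: float = 0.0) -> int:
    """Zero crossings: sign changes whose step exceeds the deadband."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sign_change = x[:-1] * x[1:] < 0
    big_step = np.abs(np.diff(x)) > threshold
    return int(np.sum(sign_change & big_step))


def ssc(window: np.ndarray, threshold: float = 0.0) -> int:
    """Slope sign changes: interior samples that are a local extremum
    beyond the deadband, i.e. (x[t]-x[t-1])*(x[t]-x[t+1]) > threshold."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if x.size < 3:
        return 0
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return int(np.sum(left * right > threshold))


def window_features(window: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """The (MAV, SSC, ZC, WL) vector for one single-channel window."""
    return np.array([mav(window), ssc(window, threshold),
                     zc(window, threshold), wl(window)], dtype=float)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Windows x (channels x 4 features) with per-window class labels.

    ``columns`` maps each column index to (electrode id, feature name), in
    channel-major order.  ``movement`` and ``repetition`` label each row
    with the annotation it came from.
    """

    X: np.ndarray
    columns: list[tuple[str, str]]
    movement: np.ndarray
    repetition: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.movement = np.asarray(self.movement, dtype=object)
        self.repetition = np.asarray(self.repetition, dtype=int)
        if self.X.shape != (len(self.movement), len(self.columns)):
            raise ValueError("feature matrix shape disagrees with labels/columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def electrodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e, _ in self.columns:
            seen.setdefault(e)
        return list(seen)

    @property
    def movements(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.movement:
            seen.setdefault(m)
        return list(seen)

    def select_channels(self, subset) -> "FeatureMatrix":
        """Restrict to columns of the given electrodes (order preserved)."""
        subset = list(subset)
        if not subset:
            raise ValueError("empty channel subset")
        unknown = set(subset) - set(self.electrodes)
        if unknown:
            raise KeyError(f"electrodes not in feature matrix: {sorted(unknown)}")
        keep = [i for i, (e, _) in enumerate(self.columns) if e in set(subset)]
        return FeatureMatrix(
            X=self.X[:, keep],
            columns=[self.columns[i] for i in keep],
            movement=self.movement,
            repetition=self.repetition,
        )

    def drop_electrode(self, electrode_id: str) -> "FeatureMatrix":
        rest = [e for e in self.electrodes if e != electrode_id]
        if not rest:
            raise ValueError("dropping the only electrode leaves no columns")
        return self.select_channels(rest)

    def select_movements(self, labels) -> "FeatureMatrix":
        labels = set(labels)
        keep = np.array([m in labels for m in self.movement], dtype=bool)
        return FeatureMatrix(
            X=self.X[keep],
            columns=list(self.columns),
            movement=self.movement[keep],
            repetition=self.repetition[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["electrode", "feature"])
        idx = pd.MultiIndex.from_arrays(
            [self.movement, self.repetition], names=["movement", "repetition"])
        return pd.DataFrame(self.X, index=idx, columns=cols)


def extract_features(rec: LabeledRecording,
                     spec: WindowingSpec = WindowingSpec(),
                     channel_subset=None,
                     threshold: float = 0.0,
                     include_rest: bool = False) -> FeatureMatrix:
    """Windowed feature matrix over all annotated movement intervals.

    Each annotated interval is segmented independently (windows never cross
    a boundary), each window of each selected channel yields the four
    time-domain features, and rows inherit the interval's movement label and
    repetition index.  Intervals shorter than one window contribute no rows.
    """
    if channel_subset is None:
        channel_subset = list(rec.channel_map)
    channel_subset = list(channel_subset)
    if not channel_subset:
        raise ValueError("empty channel subset")
    ch_idx = [rec.channel_index(e) for e in channel_subset]

    columns = [(e, f) for e in channel_subset for f in FEATURE_NAMES]
    rows: list[np.ndarray] = []
    movements: list[str] = []
    repetitions: list[int] = []
    fs = rec.sampling_rate_hz
    window, inc = spec.in_samples(fs)
    for ann in rec.annotations:
        if ann.label == REST_LABEL and not include_rest:
            continue
        lo, hi = ann.sample_range(fs)
        seg = rec.samples[:, lo:hi]
        if seg.shape[1] < window:
            continue
        for (a, b) in segment_windows(seg, fs, spec):
            feats = np.concatenate(
                [window_features(seg[c, a:b], threshold) for c in ch_idx])
            rows.append(feats)
            movements.append(ann.label)
            repetitions.append(ann.repetition)
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(columns)))
    return FeatureMatrix(X=X, columns=columns,
                         movement=np.array(movements, dtype=object),
                         repetition=np.array(repetitions, dtype=int))
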