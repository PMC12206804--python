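"""Feature-space separability (IDNN) and repeatability (WD).

Movement classes live in the windowed time-domain feature space.  For two
classes i and j the two *directed half-Mahalanobis* statistics are

    dist_ji = 1/2 * (mu_i - mu_j)^T S_i^{-1} (mu_i - mu_j)
    dist_ij = 1/2 * (mu_j - mu_i)^T S_j^{-1} (mu_j - mu_i)

each using one class's own covariance, so the pair is asymmetric whenever
the covariances differ.  The two directions are combined by the harmonic
composition a*b/(a+b) (half the harmonic mean; never larger than either
direction).

* **IDNN** (inter-class distance, nearest neighbour) for movement i is the
  minimum combined term over all other movements: separability is only as
  good as the closest confusable class.  Higher is better.
* **WD** (within-class distance) for movement j applies the same combined
  term between repetitions of j and averages it over all unordered
  repetition pairs: lower means more repeatable.

Both are invariant under invertible affine maps of the feature space, a
property of the Mahalanobis quadratic form that the tests rely on.

Covariances estimated from few windows can be singular (200 ms / 50 ms
windowing of a short repetition yields fewer windows than feature
dimensions).  Inversion then falls back to shrinkage toward the diagonal,
(1-lambda)*S + lambda*diag(S) with lambda = 1e-3, escalating to a ridge
lambda*I when the diagonal itself is degenerate.  Well-conditioned
covariances are inverted exactly, keeping the affine invariance intact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

#: shrinkage weight used only when the sample covariance is not positive definite
REGULARIZATION_LAMBDA = 1e-3


@dataclass
class ClassStats:
    """Mean vector and covariance of one class (movement or repetition)."""

    label: tuple
    mu: np.ndarray
    S: np.ndarray
    n: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape disagrees with mean dimension")
        if self.n < 2:
            raise ValueError(f"class {self.label} has {self.n} windows; need >= 2")


@dataclass
class SeparabilityReport:
    """Per-movement IDNN and/or WD on a channel subset."""

    channel_subset: list[str]
    excluded_electrode: str | None = None
    idnn: dict[str, float] = field(default_factory=dict)
    wd: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Class statistics
# ---------------------------------------------------------------------------

def class_stats(fm: FeatureMatrix, grouping: str = "movement") -> list[ClassStats]:
    """Sample mean and covariance per movement, or per repetition within movement.

    ``grouping="movement"`` keys classes by movement label; ``"repetition"``
    keys them by (movement, repetition index).  Groups need at least two
    windows for a covariance to exist.
    """
    if grouping not in ("movement", "repetition"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if fm.X.shape[1] < 1:
        raise ValueError("feature matrix has no columns")
    keys: list[tuple] = []
    for m, r in zip(fm.movement, fm.repetition):
        key = (m,) if grouping == "movement" else (m, int(r))
        if key not in keys:
            keys.append(key)
    out: list[ClassStats] = []
    for key in keys:
        if grouping == "movement":
            mask = fm.movement == key[0]
        else:
            mask = (fm.movement == key[0]) & (fm.repetition == key[1])
        block = fm.X[mask]
        if block.shape[0] < 2:
            raise ValueError(f"group {key} has {block.shape[0]} windows; need >= 2")
        mu = block.mean(axis=0)
        S = np.cov(block, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        out.append(ClassStats(label=key, mu=mu, S=S, n=block.shape[0]))
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _regularized(S: np.ndarray) -> np.ndarray:
    """Shrink a non-PD covariance toward its diagonal, then to a ridge."""
    lam = REGULARIZATION_LAMBDA
    d = np.diag(np.diag(S))
    S2 = (1 - lam) * S + lam * d
    try:
        np.linalg.cholesky(S2)
        return S2
    except np.linalg.LinAlgError:
        pass
    scale = np.mean(np.diag(S))
    if scale <= 0:
        scale = 1.0
    return S + lam * scale * np.eye(S.shape[0])


def _solve_spd(S: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """S^{-1} delta via Cholesky, regularizing only on failure."""
    from scipy.linalg import cho_solve
    try:
        c = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S = _regularized(S)
        try:
            c = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "covariance singular even after regularization") from None
    return cho_solve((c, True), delta)


def half_mahalanobis(mu_i: np.ndarray, mu_j: np.ndarray, S_i: np.ndarray,
                     sqrt_distance: bool = False) -> float:
    """dist_ji = 1/2 * (mu_i - mu_j)^T S_i^{-1} (mu_i - mu_j).

    With ``sqrt_distance=True`` the square root of the quadratic form is
    halved instead (the metric rather than its square); the default is the
    plain quadratic form.
    """
    delta = np.asarray(mu_i, dtype=float) - np.asarray(mu_j, dtype=float)
    q = float(delta @ _solve_spd(np.asarray(S_i, dtype=float), delta))
    q = max(q, 0.0)
    if sqrt_distance:
        return 0.5 * np.sqrt(q)
    return 0.5 * q


def combined_term(a: float, b: float) -> float:
    """a*b/(a+b): half the harmonic mean of the two directed distances.

    Zero when both directions vanish (coincident classes).  Bounded above
    by min(a, b).
    """
    if a < 0 or b < 0:
        raise ValueError("directed distances must be >= 0")
    if a + b == 0:
        return 0.0
    return a * b / (a + b)


def pairwise_combined(stats_i: ClassStats, stats_j: ClassStats,
                      sqrt_distance: bool = False) -> float:
    a = half_mahalanobis(stats_i.mu, stats_j.mu, stats_i.S, sqrt_distance)
    b = half_mahalanobis(stats_j.mu, stats_i.mu, stats_j.S, sqrt_distance)
    return combined_term(a, b)


# ---------------------------------------------------------------------------
# IDNN and WD
# ---------------------------------------------------------------------------

def idnn(stats: list[ClassStats], movement, sqrt_distance: bool = False) -> float:
    """Nearest-neighbour separability of one movement against all others."""
    if len(stats) < 2:
        raise ValueError("IDNN needs at least 2 movement classes")
    key = (movement,) if not isinstance(movement, tuple) else movement
    by_label = {s.label: s for s in stats}
    if key not in by_label:
        raise KeyError(f"movement {movement!r} not among class stats")
    me = by_label[key]
    terms = [pairwise_combined(me, other, sqrt_distance)
             for other in stats if other.label != key]
    return min(terms)


def idnn_all(stats: list[ClassStats], sqrt_distance: bool = False) -> dict:
    """IDNN for every movement class, keyed by label."""
    return {s.label[0]: idnn(stats, s.label, sqrt_distance) for s in stats}


def wd(rep_stats: list[ClassStats], sqrt_distance: bool = False) -> float:
    """Within-class distance: mean combined term over unordered repetition pairs.

    *rep_stats* are the per-repetition statistics of one movement.  The
    pairwise term is averaged so that WD does not depend on an arbitrary
    reference repetition.
    """
    if len(rep_stats) < 2:
        raise ValueError("WD needs at least 2 repetitions")
    movements = {s.label[0] for s in rep_stats}
    if len(movements) != 1:
        raise ValueError(f"rep_stats mixes movements {sorted(movements)}")
    terms = [pairwise_combined(a, b, sqrt_distance)
             for a, b in itertools.combinations(rep_stats, 2)]
    return float(np.mean(terms))


def wd_all(fm: FeatureMatrix, sqrt_distance: bool = False) -> dict:
    """WD per movement from per-repetition statistics, keyed by movement."""
    rep_stats = class_stats(fm, grouping="repetition")
    out = {}
    for movement in fm.movements:
        mine = [s for s in rep_stats if s.label[0] == movement]
        if len(mine) >= 2:
            out[movement] = wd(mine, sqrt_distance)
    return out


# ---------------------------------------------------------------------------
# Leave-one-electrode-out contribution analysis
# ---------------------------------------------------------------------------

def leave_one_electrode_out(fm: FeatureMatrix, electrode: str,
                            metric: str = "idnn",
                            sqrt_distance: bool = False) -> SeparabilityReport:
    """Metric per movement on all channels except *electrode*.

    The drop in separability (or rise in WD) relative to the full set
    measures the excluded electrode's contribution.
    """
    if metric not in ("idnn", "wd"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(fm.electrodes) < 2:
        raise ValueError("need >= 2 electrodes to leave one out")
    sub = fm.drop_electrode(electrode)
    report = SeparabilityReport(channel_subset=sub.electrodes,
                                excluded_electrode=electrode)
    if metric == "idnn":
        report.idnn = idnn_all(class_stats(sub, "movement"), sqrt_distance)
    else:
        report.wd = wd_all(sub, sqrt_distance)
    return report


def full_set_report(fm: FeatureMatrix, sqrt_distance: bool = False) -> SeparabilityReport:
    """IDNN and WD per movement on the complete channel set."""
    report = SeparabilityReport(channel_subset=fm.electrodes)
    report.idnn = idnn_all(class_stats(fm, "movement"), sqrt_distance)
    report.wd = wd_all(fm, sqrt_distance)
    return report
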