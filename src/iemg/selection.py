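"""Electrode ranking by sequential forward selection (SFS).

Which electrodes carry the class-discriminative information?  SFS answers
greedily: start from the single electrode with the best set separability,
then repeatedly add the electrode whose inclusion yields the best new
value.  Set separability is the mean per-movement IDNN over the channel
subset's feature columns (median and min aggregates are available).

Greedy improvement is *not* assumed monotone: under regularized
covariances an added electrode can lower the mean IDNN, and the greedy
step simply takes the best available candidate either way.

``greedy_oracle`` is a deliberately naive, separately coded transcription
of the same procedure (explicit loops, plain matrix inverses) kept for
cross-checking the vectorized path on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .separability import class_stats, idnn_all

AGGREGATES = ("mean", "median", "min")


@dataclass
class SelectionRanking:
    """Greedy electrode order with the separability achieved at each step."""

    order: list[tuple[str, float]] = field(default_factory=list)
    group: str | None = None        # movement group analyzed, if any
    aggregate: str = "mean"

    @property
    def electrodes(self) -> list[str]:
        return [e for e, _ in self.order]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.order]


def _aggregate(values, how: str) -> float:
    vals = np.asarray(list(values), dtype=float)
    if how == "mean":
        return float(vals.mean())
    if how == "median":
        return float(np.median(vals))
    if how == "min":
        return float(vals.min())
    raise ValueError(f"unknown aggregate {how!r}")


def set_separability(fm: FeatureMatrix, subset, aggregate: str = "mean") -> float:
    """Aggregate per-movement IDNN over the given electrode subset's columns."""
    sub = fm.select_channels(subset)
    per_movement = idnn_all(class_stats(sub, "movement"))
    return _aggregate(per_movement.values(), aggregate)


def sfs_rank(fm: FeatureMatrix, electrodes=None, aggregate: str = "mean",
             group: str | None = None) -> SelectionRanking:
    """Greedy forward ranking of electrodes by set separability.

    At each step every remaining electrode is evaluated joined to the
    current subset and the best is taken; ties break toward the electrode
    earliest in the candidate order (lowest index), making rankings
    deterministic.
    """
    if electrodes is None:
        electrodes = fm.electrodes
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("need at least 1 electrode")
    ranking = SelectionRanking(group=group, aggregate=aggregate)
    chosen: list[str] = []
    remaining = list(electrodes)
    while remaining:
        best_e, best_v = None, -np.inf
        for e in remaining:   # candidate order = tie-break order
            v = set_separability(fm, chosen + [e], aggregate)
            if v > best_v:
                best_e, best_v = e, v
        chosen.append(best_e)
        remaining.remove(best_e)
        ranking.order.append((best_e, best_v))
    return ranking


# ---------------------------------------------------------------------------
# Naive oracle
# ---------------------------------------------------------------------------

def _naive_set_separability(fm: FeatureMatrix, subset, aggregate: str) -> float:
    """Direct-transcription separability: explicit loops and plain inverses."""
    from .separability import _regularized

    cols = [i for i, (e, _) in enumerate(fm.columns) if e in set(subset)]
    movements = fm.movements
    mus, invs = {}, {}
    for m in movements:
        block = fm.X[np.array([lbl == m for lbl in fm.movement])][:, cols]
        mu = block.mean(axis=0)
        S = np.atleast_2d(np.cov(block, rowvar=False, ddof=1))
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            S = _regularized(S)
        mus[m], invs[m] = mu, np.linalg.inv(S)
    per_movement = []
    for i in movements:
        best = np.inf
        for j in movements:
            if j == i:
                continue
            d_ji = 0.5 * float((mus[i] - mus[j]) @ invs[i] @ (mus[i] - mus[j]))
            d_ij = 0.5 * float((mus[j] - mus[i]) @ invs[j] @ (mus[j] - mus[i]))
            term = 0.0 if d_ji + d_ij == 0 else d_ji * d_ij / (d_ji + d_ij)
            best = min(best, term)
        per_movement.append(best)
    if aggregate == "mean":
        return float(np.mean(per_movement))
    if aggregate == "median":
        return float(np.median(per_movement))
    return float(np.min(per_movement))


def greedy_oracle(fm: FeatureMatrix, electrodes=None,
                  aggregate: str = "mean") -> SelectionRanking:
    """Brute-force greedy ranking re-evaluating every candidate at every step.

    Limited to 8 electrodes; exists to cross-check :func:`sfs_rank`.
    """
    if electrodes is None:
        electrodes = fm.electrodes
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("need at least 1 electrode")
    if len(electrodes) > 8:
        raise ValueError("greedy oracle limited to 8 electrodes")
    ranking = SelectionRanking(aggregate=aggregate)
    chosen: list[str] = []
    remaining = list(electrodes)
    while remaining:
        scores = [_naive_set_separability(fm, chosen + [e], aggregate)
                  for e in remaining]
        k = int(np.argmax(scores))      # argmax takes the first max: lowest index
        ranking.order.append((remaining[k], float(scores[k])))
        chosen.append(remaining.pop(k))
    return ranking
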