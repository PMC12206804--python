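"""Nonparametric group comparison and cohort-level reporting.

Electrode-type comparisons (epimysial vs intramuscular) use the Wilcoxon
rank-sum test.  The sample sizes in this setting are tiny, so the exact
permutation distribution of the rank-sum statistic is enumerated whenever
the pooled size allows (here up to 12 observations, ties handled with
midranks); larger samples use the normal approximation with tie and
continuity corrections.  All comparisons within one report form a single
family for Holm-Bonferroni adjustment -- the conservative choice when no
family is prescribed.

Open-circuit impedances (OPEN) participate in rank tests as the largest
ranks: rank statistics need only ordinal structure, and an open circuit
is ordinally larger than any finite impedance.

``analyze_cohort`` runs the whole pipeline on a synthetic (or loaded)
cohort: impedance matrices and ratios, per-electrode max SNR, per-electrode
leave-one-out IDNN/WD, sequential-forward-selection rankings, then pools
electrodes across participants per electrode type and builds the report.
Pooling electrodes (rather than treating participants as units) is flagged
in the report itself.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import impedance as imp
from .features import WindowingSpec, extract_features
from .selection import sfs_rank
from .separability import class_stats, idnn_all, leave_one_electrode_out, wd_all
from .snr import max_snr_per_electrode
from .synth import CohortEntry

EXACT_LIMIT = 12        # pooled size up to which the rank-sum null is enumerated
ELECTRODE_TYPES = ("epimysial", "intramuscular")


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------

def _to_float(values) -> np.ndarray:
    """Map possibly-OPEN values onto the extended real line for ranking."""
    return np.array([math.inf if v is imp.OPEN else float(v) for v in values])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p-value; exact by enumeration for small samples.

    For pooled sizes up to 12 the permutation distribution of the x-group
    rank sum is enumerated over all C(n, n_x) group assignments of the
    pooled midranks, so ties (including ties among OPEN values) are exact.
    Larger samples use the normal approximation with tie correction and a
    0.5 continuity correction.
    """
    x = _to_float(x)
    y = _to_float(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)       # midranks; inf ties mid-ranked on top
    nx, n = x.size, pooled.size
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0

    if n <= EXACT_LIMIT:
        dev = abs(w_obs - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), nx):
            total += 1
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= dev - 1e-12:
                hits += 1
        return hits / total

    # normal approximation with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    ny = n - nx
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * sstats.norm.sf(z))


def holm_bonferroni(pvals) -> list[float]:
    """Step-down Holm adjustment, returned in the input order."""
    p = list(pvals)
    for v in p:
        if not (0 <= v <= 1):
            raise ValueError(f"p-value outside [0, 1]: {v}")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for k, i in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[i]))
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    metric: str
    summaries: dict = field(default_factory=dict)   # etype -> (median, q1, q3)
    n: dict = field(default_factory=dict)           # etype -> group size
    p_raw: float | None = None
    p_adjusted: float | None = None


def build_report(metrics: dict[str, dict[str, list]],
                 extras: dict | None = None) -> dict:
    """Per-metric summaries and type comparisons, Holm-adjusted as one family.

    *metrics* maps metric name -> {electrode type -> list of values}
    (values may be OPEN).  Metrics with a single electrode type get
    summaries only; the comparison is skipped and listed under
    ``"skipped"``.  The output is a plain JSON-serializable dict.
    """
    if not metrics:
        raise ValueError("no metrics to report")
    comparisons: list[ComparisonResult] = []
    skipped: list[dict] = []
    for name in sorted(metrics):
        groups = {t: v for t, v in metrics[name].items() if len(v)}
        result = ComparisonResult(metric=name)
        for t, values in sorted(groups.items()):
            result.summaries[t] = imp.summarize(values)
            result.n[t] = len(values)
        if len(groups) >= 2:
            result.p_raw = wilcoxon_rank_sum(groups["epimysial"],
                                             groups["intramuscular"])
        else:
            skipped.append({"metric": name,
                            "reason": "single electrode type present"})
        comparisons.append(result)

    tested = [c for c in comparisons if c.p_raw is not None]
    for c, adj in zip(tested, holm_bonferroni([c.p_raw for c in tested])):
        c.p_adjusted = adj

    report = {
        "schema": "iemg-report/1",
        "pooling": "electrodes pooled across participants",
        "metrics": {},
        "skipped": skipped,
    }
    for c in comparisons:
        entry: dict = {"n": c.n, "summaries": {}}
        for t, (med, q1, q3) in c.summaries.items():
            entry["summaries"][t] = {"median": imp.to_json_value(med),
                                     "q1": imp.to_json_value(q1),
                                     "q3": imp.to_json_value(q3)}
        if c.p_raw is not None:
            entry["p_raw"] = c.p_raw
            entry["p_adjusted"] = c.p_adjusted
        report["metrics"][c.metric] = entry
    if extras:
        report.update(extras)
    return report


def render_report(report: dict) -> str:
    """Plain-text table rendering of a report dict."""
    lines = [f"{'metric':34s} {'type':14s} {'n':>4s} {'median':>12s} "
             f"{'q1':>12s} {'q3':>12s} {'p':>8s} {'p_adj':>8s}"]
    for name, entry in report["metrics"].items():
        p = entry.get("p_raw")
        padj = entry.get("p_adjusted")
        for t, s in entry["summaries"].items():
            fmt = lambda v: f"{v:12.4g}" if isinstance(v, (int, float)) else f"{v:>12s}"
            lines.append(
                f"{name:34s} {t:14s} {entry['n'][t]:4d} {fmt(s['median'])} "
                f"{fmt(s['q1'])} {fmt(s['q3'])} "
                f"{p if p is None else format(p, '8.3g')} "
                f"{padj if padj is None else format(padj, '8.3g')}")
    for s in report.get("skipped", []):
        lines.append(f"# skipped {s['metric']}: {s['reason']}")
    return "\n".join(lines)


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a report."""
    return json.dumps(report, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Whole-cohort analysis
# ---------------------------------------------------------------------------

def _median_finite_or_open(values: dict) -> float:
    med, _, _ = imp.summarize(list(values.values()))
    return med


def analyze_cohort(cohort: dict[str, CohortEntry],
                   windowing: WindowingSpec = WindowingSpec(),
                   trim_fraction: float = 0.25,
                   include_sfs: bool = True) -> dict:
    """Run every analysis stage on a cohort and build the pooled report.

    Per participant: impedance matrices at each measured frequency,
    cross/direct ratios, per-electrode max SNR per movement group,
    per-electrode leave-one-out IDNN and WD per movement group (each
    reduced to the median across the group's movements), and optionally
    the SFS ranking per group.  Values are pooled across participants by
    electrode type.
    """
    metrics: dict[str, dict[str, list]] = {}

    def add(metric: str, etype: str, value):
        metrics.setdefault(metric, {t: [] for t in ELECTRODE_TYPES})
        metrics[metric][etype].append(value)

    sfs_results: dict = {}
    for pid in sorted(cohort):
        entry = cohort[pid]
        rec = entry.recording
        etype_of = {e.electrode_id: e.etype for e in entry.electrode_map}

        # --- impedance ---
        freqs = sorted({m.frequency_hz for m in entry.measurements})
        for f in freqs:
            matrix = imp.build_impedance_matrix(entry.measurements, f)
            tag = f"{int(f)}hz"
            for e, z in matrix.direct_ohm.items():
                add(f"direct_impedance_ohm_{tag}", etype_of[e], z)
            for (a, b), z in matrix.cross_ohm.items():
                if etype_of[a] == etype_of[b]:
                    add(f"cross_impedance_ohm_{tag}", etype_of[a], z)
            ratios = imp.impedance_ratio(matrix)
            for (i, _j), r in ratios.ratios.items():
                add(f"impedance_ratio_{tag}", etype_of[i], r)

        # --- SNR ---
        snr = max_snr_per_electrode(rec, trim_fraction,
                                    min_steady_s=windowing.window_s)
        for e, groups in snr.items():
            for group, value in groups.items():
                add(f"snr_db_{group}", etype_of[e], value)

        # --- separability / repeatability (leave-one-electrode-out) ---
        groups = sorted(set(rec.movement_groups.values()))
        for group in groups:
            labels = [m for m, g in rec.movement_groups.items() if g == group]
            fm = extract_features(rec, windowing).select_movements(labels)
            if len(set(fm.movement)) < 2 or len(fm.electrodes) < 2:
                continue
            for e in fm.electrodes:
                loo_idnn = leave_one_electrode_out(fm, e, metric="idnn")
                add(f"idnn_{group}", etype_of[e],
                    _median_finite_or_open(loo_idnn.idnn))
                loo_wd = leave_one_electrode_out(fm, e, metric="wd")
                if loo_wd.wd:
                    add(f"wd_{group}", etype_of[e],
                        _median_finite_or_open(loo_wd.wd))
            if include_sfs:
                ranking = sfs_rank(fm, group=group)
                sfs_results.setdefault(pid, {})[group] = [
                    {"electrode": e, "etype": etype_of[e], "separability": v}
                    for e, v in ranking.order]

    extras = {"sfs_rankings": sfs_results} if include_sfs else None
    return build_report(metrics, extras=extras)
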