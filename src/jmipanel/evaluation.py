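"""Downstream panel assessments.

Per-gene ROC/AUC (tumor-positive orientation, rank-based with tie halving),
a quantitative two-cluster purity score standing in for visual separation
displays, stage-trend monotonicity screening, Kaplan-Meier product-limit
estimation and the 1-df log-rank test on expression splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.cluster import AgglomerativeClustering

from .diffexpr import as_tumor_mask
from .io_tables import ExpressionMatrix, SampleAnnotation


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """AUC = P(score_tumor > score_normal) + 0.5 P(tie), tumor-positive.

    Rank-based (Mann-Whitney U); the orientation is fixed, no auto-flip.
    """
    mask = as_tumor_mask(labels)
    scores = np.asarray(scores, dtype=float)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cluster_purity(matrix: ExpressionMatrix, labels: Sequence) -> float:
    """Two-cluster agreement with the class labels on a gene panel.

    Rows are standardized per gene, samples are clustered by Ward-linkage
    agglomerative clustering (Euclidean) cut at 2 clusters, and purity is the
    best fraction of correctly grouped samples over the two label-to-cluster
    assignments (so always >= 0.5).  Ward is used rather than average linkage
    because the latter routinely isolates a single outlier sample, collapsing
    the score to ~0.5 regardless of class separation.
    """
    mask = as_tumor_mask(labels)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    x = matrix.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    assign = AgglomerativeClustering(
        n_clusters=2, linkage="ward", metric="euclidean"
    ).fit_predict(z.T)
    acc = float(np.mean((assign == 1) == mask))
    return max(acc, 1.0 - acc)


def stage_trend_monotone(
    stage_means: Sequence[float],
) -> tuple[bool, tuple[float, ...]]:
    """Whether 4 stage means (I-IV) are monotone non-decreasing or non-increasing."""
    means = tuple(float(m) for m in stage_means)
    if len(means) != 4 or not all(np.isfinite(means)):
        raise ValueError("need 4 finite stage means")
    diffs = np.diff(means)
    mono = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return mono, means


def median_split(values: Sequence[float]) -> np.ndarray:
    """Boolean high/low split: high iff value > median (median itself is low)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 samples")
    return values > np.median(values)


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimator (right censoring).

    All-censored input yields an empty event grid, i.e. S == 1 everywhere.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size:
        raise ValueError("times and events length mismatch")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size
    ev_times, surv, risk = [], [], []
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += events[j]
            j += 1
        if d > 0:
            n_risk = n - i
            s *= 1.0 - d / n_risk
            ev_times.append(t)
            surv.append(s)
            risk.append(n_risk)
        i = j
    return KaplanMeierEstimate(
        event_times=np.asarray(ev_times, dtype=float),
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(risk, dtype=int),
    )


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple[float, float]:
    """Standard 1-df log-rank test between two groups.

    Returns (chi-square statistic, p-value).  At each distinct event time the
    observed-minus-expected events in group 1 and the hypergeometric variance
    are accumulated.  Raises if there are no events or a group is missing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups).astype(bool)
    if not (times.size == events.size == groups.size):
        raise ValueError("times/events/groups length mismatch")
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be present")
    if events.sum() == 0:
        raise ValueError("log-rank statistic undefined with no events")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & groups).sum())
        died = (times == t) & (events == 1)
        d_tot = int(died.sum())
        d1 = int((died & groups).sum())
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * \
                   (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def stage_means(
    values: Sequence[float],
    annotations: Sequence[SampleAnnotation],
) -> Optional[tuple[float, float, float, float]]:
    """Mean expression per stage I-IV over tumor samples with known stage.

    Returns None unless every stage is represented.
    """
    values = np.asarray(values, dtype=float)
    means = []
    for stage in (1, 2, 3, 4):
        idx = [i for i, a in enumerate(annotations)
               if a.is_tumor and a.stage == stage]
        if not idx:
            return None
        means.append(float(values[idx].mean()))
    return tuple(means)


def evaluate_panel(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    genes: Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """Per-gene metrics for a panel plus the panel-level cluster purity.

    The per-gene table reports the fixed-orientation AUC, the orientation-free
    max(AUC, 1-AUC), stage means and the monotone flag (NaN/None when stage
    data are absent), and the median-split log-rank statistic and p-value on
    the tumor samples with survival data.
    """
    missing = [g for g in genes if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    labels = [a.class_label for a in annotations]
    panel = matrix.subset_genes(list(genes))

    surv_idx = [i for i, a in enumerate(annotations)
                if a.is_tumor and a.os_time is not None]
    surv_times = np.array([annotations[i].os_time for i in surv_idx])
    surv_events = np.array([annotations[i].os_event for i in surv_idx])

    rows = []
    for g in genes:
        vals = panel.row(g)
        auc = roc_auc(vals, labels)
        sm = stage_means(vals, annotations)
        mono = stage_trend_monotone(sm)[0] if sm is not None else None
        lr_stat = lr_p = np.nan
        if len(surv_idx) >= 2 and surv_events.sum() > 0:
            high = median_split(vals[surv_idx])
            if 0 < high.sum() < high.size:
                lr_stat, lr_p = logrank_test(surv_times, surv_events, high)
        rows.append({
            "gene": g,
            "auc": auc,
            "auc_oriented": max(auc, 1.0 - auc),
            "stage_mean_I": np.nan if sm is None else sm[0],
            "stage_mean_II": np.nan if sm is None else sm[1],
            "stage_mean_III": np.nan if sm is None else sm[2],
            "stage_mean_IV": np.nan if sm is None else sm[3],
            "stage_monotone": mono,
            "logrank_stat": lr_stat,
            "logrank_p": lr_p,
        })
    table = pd.DataFrame(rows).set_index("gene")
    purity = cluster_purity(panel, labels)
    return table, purity
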