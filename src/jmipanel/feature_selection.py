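"""Greedy forward feature selection under the JMI and mRMR criteria.

Both criteria score a candidate feature f against the already-selected set S
and the class C:

* mRMR:  I(f;C) - (1/|S|) * sum over s in S of I(f;s)
* JMI:   sum over s in S of I(f,s;C)

The first step (S empty) selects argmax I(f;C) under either criterion; ties
are broken by ascending gene id.  Selection is a pure function of
(matrix, labels, k, criterion, n_bins): candidates are discretized once and
cached, and no randomness is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .diffexpr import as_tumor_mask
from .infotheory import (
    DiscreteFeature,
    discretize,
    from_labels,
    joint_mutual_information,
    mutual_information,
)
from .io_tables import ExpressionMatrix

CRITERIA = ("jmi", "mrmr")


def mrmr_score(
    candidate: DiscreteFeature,
    selected: Sequence[DiscreteFeature],
    c: DiscreteFeature,
) -> float:
    """Relevance minus mean pairwise redundancy; I(f;C) when S is empty."""
    relevance = mutual_information(candidate, c)
    if not selected:
        return relevance
    redundancy = sum(mutual_information(candidate, s) for s in selected)
    return relevance - redundancy / len(selected)


def jmi_score(
    candidate: DiscreteFeature,
    selected: Sequence[DiscreteFeature],
    c: DiscreteFeature,
) -> float:
    """Sum of joint informations with each selected feature; I(f;C) when S empty."""
    if not selected:
        return mutual_information(candidate, c)
    return sum(joint_mutual_information(candidate, s, c) for s in selected)


_SCORERS = {"jmi": jmi_score, "mrmr": mrmr_score}


@dataclass(frozen=True)
class SelectionStep:
    gene: str
    score: float
    candidate_scores: Optional[dict[str, float]] = None


@dataclass
class SelectionTrace:
    """Ordered record of a greedy selection run."""

    criterion: str
    n_bins: int
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return [s.gene for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": range(1, len(self.steps) + 1),
            "gene": self.genes,
            "score": [s.score for s in self.steps],
        })


def greedy_select(
    matrix: ExpressionMatrix,
    labels: Sequence,
    k: int,
    criterion: str = "jmi",
    n_bins: int = 4,
    store_candidates: bool = True,
    plateau_eps: Optional[float] = None,
) -> SelectionTrace:
    """Greedy forward selection of ``k`` genes.

    ``plateau_eps``, if set, stops early once the best score's relative gain
    is below eps for two consecutive steps (off by default).  Ties at any step
    are broken by ascending gene id, so the output is deterministic.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if not 1 <= k <= matrix.n_genes:
        raise ValueError(f"k must be in [1, {matrix.n_genes}], got {k}")
    mask = as_tumor_mask(labels)
    if len(mask) != matrix.n_samples:
        raise ValueError("labels length does not match sample count")
    c = from_labels(mask)
    features = {
        g: discretize(matrix.values[i], n_bins=n_bins)
        for i, g in enumerate(matrix.gene_ids)
    }
    scorer = _SCORERS[criterion]

    trace = SelectionTrace(criterion=criterion, n_bins=n_bins)
    remaining = sorted(features)
    selected: list[DiscreteFeature] = []
    prev_gain_small = False
    prev_score: Optional[float] = None
    for _ in range(k):
        best_gene, best_score = None, None
        scores: dict[str, float] = {}
        for g in remaining:  # ascending id order; strict '>' keeps first on ties
            s = scorer(features[g], selected, c)
            scores[g] = s
            if best_score is None or s > best_score:
                best_gene, best_score = g, s
        trace.steps.append(SelectionStep(
            gene=best_gene,
            score=best_score,
            candidate_scores=scores if store_candidates else None,
        ))
        remaining.remove(best_gene)
        selected.append(features[best_gene])
        if plateau_eps is not None and prev_score is not None:
            rel_gain = abs(best_score - prev_score) / max(abs(prev_score), 1e-300)
            if rel_gain < plateau_eps and prev_gain_small:
                break
            prev_gain_small = rel_gain < plateau_eps
        prev_score = best_score
    return trace


def rank_by_relevance(
    matrix: ExpressionMatrix,
    labels: Sequence,
    n_bins: int = 4,
) -> pd.Series:
    """Marginal relevance I(f;C) per gene, sorted descending (ties by gene id).

    The naive top-k baseline the greedy criteria are compared against.
    """
    mask = as_tumor_mask(labels)
    c = from_labels(mask)
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    scores = {
        g: mutual_information(discretize(matrix.values[pos[g]], n_bins=n_bins), c)
        for g in sorted(pos)
    }
    ser = pd.Series(scores, name="relevance")
    return ser.sort_values(ascending=False, kind="stable")
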