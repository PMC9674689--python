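"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: entropies and mutual
informations are computed by explicit counting over contingency tables, and
the greedy-selection oracle re-evaluates every candidate exhaustively at each
step using those counting oracles.
"""

from collections import Counter
from math import log2

import numpy as np


def entropy_oracle(codes) -> float:
    n = len(codes)
    return -sum((c / n) * log2(c / n) for c in Counter(codes).values())


def mi_oracle(x, y) -> float:
    """I(X;Y) by direct summation over the joint table."""
    assert len(x) == len(y)
    n = len(x)
    pxy = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in pxy.items():
        pj = c / n
        total += pj * log2(pj / ((px[a] / n) * (py[b] / n)))
    return total


def jmi_oracle(x, y, c) -> float:
    """I(X,Y;C) via the paired variable, by direct summation."""
    paired = list(zip(x, y))
    return mi_oracle(paired, list(c))


def discretize_oracle(values, n_bins):
    """Sort stably, slice into n_bins contiguous blocks, map codes back."""
    values = list(values)
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    codes = [0] * n
    for rank, idx in enumerate(order):
        codes[idx] = (rank * n_bins) // n
    return codes


def mrmr_oracle(cand, selected, c) -> float:
    rel = mi_oracle(cand, c)
    if not selected:
        return rel
    return rel - sum(mi_oracle(cand, s) for s in selected) / len(selected)


def jmi_score_oracle(cand, selected, c) -> float:
    if not selected:
        return mi_oracle(cand, c)
    return sum(jmi_oracle(cand, s, c) for s in selected)


def greedy_oracle(feature_codes: dict, c, k: int, criterion: str):
    """Exhaustive greedy selection over discretized features.

    ``feature_codes`` maps gene id -> list of integer codes.  Ties break by
    ascending gene id.  Returns the ordered list of (gene, score).
    """
    scorer = {"mrmr": mrmr_oracle, "jmi": jmi_score_oracle}[criterion]
    remaining = sorted(feature_codes)
    selected_codes = []
    trace = []
    for _ in range(k):
        best = None
        for g in remaining:
            s = scorer(list(feature_codes[g]), selected_codes, list(c))
            if best is None or s > best[1]:
                best = (g, s)
        trace.append(best)
        remaining.remove(best[0])
        selected_codes.append(list(feature_codes[best[0]]))
    return trace


def duplicate_pairs(panel, truth) -> int:
    """Number of panel pairs belonging to the same planted family."""
    fam = Counter(truth.redundant_map.get(g, g) for g in panel)
    return sum(v * (v - 1) // 2 for v in fam.values())


def family_coverage(panel, truth) -> int:
    """Distinct planted informative genes represented in the panel, counting a
    selected duplicate as representing its parent."""
    fams = {truth.redundant_map.get(g, g) for g in panel}
    return len(fams & truth.informative_genes)


def empirical_survival(times):
    """Empirical survival function values after each distinct time (no censoring)."""
    times = np.sort(np.asarray(times, dtype=float))
    n = times.size
    uniq = np.unique(times)
    surv = [(times > t).sum() / n for t in uniq]
    return uniq, np.asarray(surv)
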