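"""Two-group differential expression with empirical-Bayes moderated t-statistics.

The model is the two-group linear contrast: per gene, logFC is the difference
of class means, the residual variance is the pooled within-group variance, and
the moderated t shrinks per-gene variances toward a prior fitted by the method
of moments on log-variances (digamma/trigamma moment matching).  Adjusted
p-values use Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .io_tables import ExpressionMatrix


@dataclass(frozen=True)
class TwoGroupFit:
    """Per-gene statistics of the two-group linear fit (shared residual df)."""

    logfc: np.ndarray      # mean(tumor) - mean(normal), log2 units
    s2: np.ndarray         # pooled within-group variance
    df: int                # residual degrees of freedom, n1 + n2 - 2
    n_tumor: int
    n_normal: int


@dataclass(frozen=True)
class ModeratedVariance:
    """Empirical-Bayes variance shrinkage result."""

    prior_df: float        # d0; np.inf when no excess variance is detected
    prior_var: float       # s0^2
    s2_post: np.ndarray    # (d0*s0^2 + d*s2) / (d0 + d)


def as_tumor_mask(labels: Sequence) -> np.ndarray:
    """Coerce labels (bools or 'tumor'/'normal' strings) to a tumor mask."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    lowered = np.array([str(x).strip().lower() for x in arr])
    bad = set(lowered) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"invalid class labels: {sorted(bad)}")
    return lowered == "tumor"


def fit_two_group(matrix: ExpressionMatrix, labels: Sequence) -> TwoGroupFit:
    """Fit the per-gene two-group model (both classes need >= 2 samples)."""
    mask = as_tumor_mask(labels)
    if len(mask) != matrix.n_samples:
        raise ValueError("labels length does not match sample count")
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"each class needs >= 2 samples (tumor={n1}, normal={n0})"
        )
    x1 = matrix.values[:, mask]
    x0 = matrix.values[:, ~mask]
    logfc = x1.mean(axis=1) - x0.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((x0 - x0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    return TwoGroupFit(logfc=logfc, s2=ss / df, df=df, n_tumor=n1, n_normal=n0)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on 1/trigamma, as in standard eBayes implementations.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def ebayes_moderate(
    s2: np.ndarray,
    df: int,
    prior_df: Optional[float] = None,
    prior_var: Optional[float] = None,
) -> ModeratedVariance:
    """Estimate (d0, s0^2) and shrink per-gene variances.

    Method of moments on z = log(s2): the excess of var(z) over trigamma(d/2)
    identifies d0 via the inverse trigamma; the mean identifies s0^2.  When no
    excess variance remains (e.g. all variances equal) d0 = inf and every
    posterior variance collapses to s0^2 (the geometric mean of s2, which for
    identical inputs is exactly the common value).

    ``prior_df``/``prior_var`` override estimation (``prior_df=0`` disables
    moderation entirely, recovering the ordinary pooled-t pipeline).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is not None:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else float("nan")
        if d0 == 0:
            return ModeratedVariance(0.0, s02, s2.copy())
        if np.isinf(d0):
            return ModeratedVariance(d0, s02, np.full_like(s2, s02))
        return ModeratedVariance(d0, s02, (d0 * s02 + df * s2) / (d0 + df))

    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 genes with positive variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s02 = float(np.exp(e.mean() + digamma(half_d0) - np.log(half_d0)))
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        return ModeratedVariance(d0, s02, s2_post)
    # No detectable between-gene variance heterogeneity: fully shrink.
    s02 = float(np.exp(z.mean()))
    return ModeratedVariance(np.inf, s02, np.full_like(s2, s02))


def moderated_t(
    fit: TwoGroupFit,
    moderation: ModeratedVariance,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated t-statistics, total df, and two-sided p-values.

    Genes with zero posterior variance and zero logFC get t=0, p=1 (avoids
    0/0); zero variance with nonzero logFC gives +-inf and p=0.
    """
    scale = 1.0 / fit.n_tumor + 1.0 / fit.n_normal
    denom = np.sqrt(moderation.s2_post * scale)
    t = np.zeros_like(fit.logfc)
    nz = denom > 0
    t[nz] = fit.logfc[nz] / denom[nz]
    t[~nz & (fit.logfc > 0)] = np.inf
    t[~nz & (fit.logfc < 0)] = -np.inf
    df_total = fit.df + moderation.prior_df
    if np.isinf(df_total):
        from scipy.stats import norm
        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    p[~nz & (fit.logfc == 0)] = 1.0
    return t, df_total, np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def deg_table(
    matrix: ExpressionMatrix,
    labels: Sequence,
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
    prior_df: Optional[float] = None,
    prior_var: Optional[float] = None,
) -> pd.DataFrame:
    """Full differential-expression table with the pass/fail DEG flag.

    Columns: gene (index), logfc, t_mod, df_total, p_raw, p_adj, passed.
    ``passed`` is True iff |logfc| > logfc_threshold and p_adj < alpha
    (both strict).
    """
    fit = fit_two_group(matrix, labels)
    mod = ebayes_moderate(fit.s2, fit.df, prior_df=prior_df, prior_var=prior_var)
    t, df_total, p_raw = moderated_t(fit, mod)
    p_adj = bh_adjust(p_raw)
    table = pd.DataFrame({
        "logfc": fit.logfc,
        "t_mod": t,
        "df_total": df_total,
        "p_raw": p_raw,
        "p_adj": p_adj,
    }, index=pd.Index(matrix.gene_ids, name="gene"))
    table["passed"] = (np.abs(table["logfc"]) > logfc_threshold) & \
                      (table["p_adj"] < alpha)
    table.attrs["prior_df"] = mod.prior_df
    table.attrs["prior_var"] = mod.prior_var
    return table


def filter_degs(
    table: pd.DataFrame,
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> set[str]:
    """Gene ids with |logfc| > threshold and p_adj < alpha (strict)."""
    keep = (table["logfc"].abs() > logfc_threshold) & (table["p_adj"] < alpha)
    return set(table.index[keep])
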