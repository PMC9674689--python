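"""Plug-in entropy and mutual information on discretized features.

Continuous expression vectors are discretized by equal-frequency binning
(default B=4); entropies and mutual informations are plug-in (maximum
likelihood) estimates in bits.  The joint mutual information I(X,Y;C) is
computed as I(Z;C) where Z is the product-alphabet pairing of (X,Y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class DiscreteFeature:
    """Integer-coded feature; codes lie in {0..n_bins-1}, one per sample."""

    codes: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size == 0:
            raise ValueError("codes must be a non-empty 1-d vector")
        if codes.min() < 0 or codes.max() >= self.n_bins:
            raise ValueError("codes out of range for n_bins")

    def __len__(self) -> int:
        return self.codes.size


def discretize(values: Sequence[float], n_bins: int = 4) -> DiscreteFeature:
    """Equal-frequency binning into ``n_bins`` codes.

    Samples are sorted (stably, so ties keep original order) and split into B
    contiguous blocks of near-equal size; block index is the code.  A constant
    vector maps to all zeros.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = values.size
    if values.min() == values.max():
        return DiscreteFeature(np.zeros(n, dtype=np.int64), n_bins)
    order = np.argsort(values, kind="stable")
    codes = np.empty(n, dtype=np.int64)
    codes[order] = (np.arange(n) * n_bins) // n
    return DiscreteFeature(codes, n_bins)


def from_labels(labels: Sequence) -> DiscreteFeature:
    """Encode arbitrary labels as a discrete feature (alphabet = sorted uniques)."""
    arr = np.asarray(labels)
    uniques, codes = np.unique(arr, return_inverse=True)
    return DiscreteFeature(codes.astype(np.int64), len(uniques))


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy(x: DiscreteFeature) -> float:
    """Plug-in Shannon entropy H(X) in bits (0 log 0 = 0)."""
    return _entropy_from_counts(np.bincount(x.codes, minlength=x.n_bins))


def _pair_codes(x: DiscreteFeature, y: DiscreteFeature) -> DiscreteFeature:
    if len(x) != len(y):
        raise ValueError("feature length mismatch")
    return DiscreteFeature(x.codes * y.n_bins + y.codes, x.n_bins * y.n_bins)


def mutual_information(x: DiscreteFeature, y: DiscreteFeature) -> float:
    """Plug-in I(X;Y) = H(X) + H(Y) - H(X,Y), in bits; symmetric, >= 0."""
    return entropy(x) + entropy(y) - entropy(_pair_codes(x, y))


def joint_mutual_information(
    x: DiscreteFeature,
    y: DiscreteFeature,
    c: DiscreteFeature,
) -> float:
    """Plug-in joint mutual information I(X,Y;C) in bits."""
    return mutual_information(_pair_codes(x, y), c)
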