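"""Tabular I/O for expression matrices and sample phenotype tables.

Expression matrices are plain TSV: first row holds sample ids, first column
holds gene ids, body is numeric (log2 scale).  Phenotype tables are TSV with a
header row: ``sample_id``, ``class`` and optionally ``stage``, ``os_time``,
``os_event``.  Gzipped variants are accepted transparently by extension.
Values are taken as already log2-normalized; no normalization is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_TUMOR = "tumor"
CLASS_NORMAL = "normal"
_VALID_CLASSES = (CLASS_TUMOR, CLASS_NORMAL)

# Roman numerals tested longest-first so "Stage IIB" collapses to II, not I.
_STAGE_ORDER = (("IV", 4), ("III", 3), ("II", 2), ("I", 1))


class TableFormatError(ValueError):
    """Raised for malformed expression or phenotype tables."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise TableFormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableFormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids),
                                self.values[rows, :].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, cols].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample clinical annotation.

    ``stage`` is an ordinal 1-4 (stages I-IV) or None when unknown.
    ``os_time`` (days) and ``os_event`` (0=censored, 1=event) are present
    together or not at all.
    """

    sample_id: str
    class_label: str
    stage: Optional[int] = None
    os_time: Optional[float] = None
    os_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.class_label not in _VALID_CLASSES:
            raise TableFormatError(
                f"sample {self.sample_id!r}: class {self.class_label!r} "
                f"not in {_VALID_CLASSES}"
            )
        if self.stage is not None and self.stage not in (1, 2, 3, 4):
            raise TableFormatError(
                f"sample {self.sample_id!r}: stage must be 1-4, got {self.stage}"
            )
        if (self.os_time is None) != (self.os_event is None):
            raise TableFormatError(
                f"sample {self.sample_id!r}: os_time and os_event must be "
                "present together"
            )
        if self.os_time is not None:
            if self.os_time < 0:
                raise TableFormatError(
                    f"sample {self.sample_id!r}: negative os_time"
                )
            if self.os_event not in (0, 1):
                raise TableFormatError(
                    f"sample {self.sample_id!r}: os_event must be 0 or 1"
                )

    @property
    def is_tumor(self) -> bool:
        return self.class_label == CLASS_TUMOR


def parse_stage(text: object) -> Optional[int]:
    """Collapse a free-text stage string to an ordinal 1-4, or None.

    The string is upper-cased and tested for the substrings IV, III, II, I in
    that order; the first hit wins (so "Stage IIB" -> 2, "not reported" ->
    None).
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).upper()
    for roman, ordinal in _STAGE_ORDER:
        if roman in s:
            return ordinal
    return None


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample ids, first column gene ids).

    Raises :class:`TableFormatError` naming the offending id or cell on
    duplicate ids, missing values, or non-numeric cells.  Row and column order
    are preserved.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    bad = raw.isna().to_numpy()
    values = np.empty(raw.shape, dtype=float)
    if not bad.any():
        try:
            # str -> float via Python's exact parser (to_numeric can be 1 ulp off)
            values = raw.to_numpy(dtype=str).astype(float)
        except ValueError:
            numeric = raw.apply(pd.to_numeric, errors="coerce")
            bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = raw.iat[i, j]
        what = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
        raise TableFormatError(
            f"{what} value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the same TSV layout ``read_expression_tsv`` reads."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, str) and x.strip() == "") or pd.isna(x):
        return None
    return float(x)


def read_phenotype_tsv(path) -> list[SampleAnnotation]:
    """Read a phenotype TSV into a list of :class:`SampleAnnotation`.

    Required columns: ``sample_id``, ``class`` (tumor/normal,
    case-insensitive).  Optional: ``stage`` (free text, collapsed to I-IV),
    ``os_time`` (days), ``os_event`` (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise TableFormatError(f"phenotype table missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        label = str(row["class"]).strip().lower()
        if label not in _VALID_CLASSES:
            raise TableFormatError(
                f"sample {row['sample_id']!r}: invalid class {row['class']!r}"
            )
        stage = parse_stage(row["stage"]) if "stage" in df.columns else None
        os_time = _opt_float(row["os_time"]) if "os_time" in df.columns else None
        os_event = _opt_float(row["os_event"]) if "os_event" in df.columns else None
        if os_time is None or os_event is None:
            os_time = os_event = None
        out.append(SampleAnnotation(
            sample_id=str(row["sample_id"]),
            class_label=label,
            stage=stage,
            os_time=os_time,
            os_event=None if os_event is None else int(os_event),
        ))
    return out


def write_phenotype_tsv(annotations: Sequence[SampleAnnotation], path) -> None:
    roman = {1: "I", 2: "II", 3: "III", 4: "IV"}
    df = pd.DataFrame({
        "sample_id": [a.sample_id for a in annotations],
        "class": [a.class_label for a in annotations],
        "stage": [roman.get(a.stage, "") if a.stage else "" for a in annotations],
        "os_time": [("" if a.os_time is None else repr(float(a.os_time)))
                    for a in annotations],
        "os_event": [("" if a.os_event is None else a.os_event)
                     for a in annotations],
    })
    df.to_csv(path, sep="\t", index=False)


def align(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Restrict matrix and annotations to their shared samples.

    Output order follows the matrix column order.  Raises
    :class:`TableFormatError` when no sample id is shared.
    """
    by_id = {a.sample_id: a for a in annotations}
    shared = [s for s in matrix.sample_ids if s in by_id]
    if not shared:
        raise TableFormatError("no shared sample ids between matrix and annotations")
    dropped_m = matrix.n_samples - len(shared)
    dropped_a = len(by_id) - len(shared)
    if dropped_m or dropped_a:
        logger.info("align: dropped %d matrix samples, %d annotations",
                    dropped_m, dropped_a)
    if dropped_m == 0:
        sub = matrix
    else:
        sub = matrix.subset_samples(shared)
    return sub, [by_id[s] for s in shared]


def tumor_mask(annotations: Sequence[SampleAnnotation]) -> np.ndarray:
    """Boolean mask, True for tumor samples, in annotation order."""
    return np.array([a.is_tumor for a in annotations], dtype=bool)
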