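"""Synthetic two-class log-expression cohorts with known ground truth.

The generative model is Gaussian on the log2 scale: every gene has a fixed
baseline plus i.i.d. noise; informative genes get a mean shift in tumor
samples with alternating sign; redundant genes are noisy copies of an
informative parent built to hit a target correlation; optional stage-trend
and survival-linked genes support the downstream evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_tables import CLASS_NORMAL, CLASS_TUMOR, ExpressionMatrix, SampleAnnotation

DEFAULT_STAGE_PROBS = (0.15, 0.30, 0.40, 0.15)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    informative_genes: set[str]
    redundant_map: dict[str, str]  # redundant gene id -> parent informative id
    stage_trend_genes: set[str] = field(default_factory=set)
    survival_genes: set[str] = field(default_factory=set)
    effect_size: float = 0.0
    noise_sd: float = 1.0
    redundancy_rho: float = 0.0
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = set(self.redundant_map)
        if self.informative_genes & dup:
            raise ValueError("informative and redundant gene sets overlap")
        if not 0.0 <= self.redundancy_rho < 1.0:
            raise ValueError("redundancy_rho must be in [0, 1)")

    @property
    def null_genes(self) -> set[str]:
        return set(self.gene_ids) - self.informative_genes - set(self.redundant_map)


def generate_cohort(
    n_genes: int,
    n_tumor: int,
    n_normal: int,
    n_informative: int,
    n_redundant_per: int = 0,
    effect_size: float = 2.0,
    redundancy_rho: float = 0.95,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_stage_trend: int = 0,
    n_survival: int = 0,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Simulate a two-class cohort; the same seed gives bit-identical output.

    Gene layout: the first ``n_informative`` genes carry a tumor mean shift of
    ``±effect_size`` (sign alternating, first gene up); the next
    ``n_informative * n_redundant_per`` genes are correlated duplicates of
    those parents at target correlation ``redundancy_rho``; the remainder are
    null.  Stage-trend and survival genes are drawn from the null pool and
    only become active after :func:`attach_stage_and_survival`.
    """
    if min(n_genes, n_tumor, n_normal) < 1:
        raise ValueError("n_genes, n_tumor and n_normal must all be >= 1")
    if n_informative < 0 or n_redundant_per < 0:
        raise ValueError("gene counts must be non-negative")
    if not 0.0 <= redundancy_rho < 1.0:
        raise ValueError("redundancy_rho must be in [0, 1)")
    n_dup = n_informative * n_redundant_per
    if n_informative + n_dup > n_genes:
        raise ValueError(
            f"need {n_informative + n_dup} informative+redundant genes "
            f"but n_genes={n_genes}"
        )
    n_null = n_genes - n_informative - n_dup
    if n_stage_trend + n_survival > n_null:
        raise ValueError("not enough null genes for stage/survival planting")

    rng = np.random.default_rng(seed)
    n = n_tumor + n_normal
    width = max(5, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    sample_ids = [f"T{j:04d}" for j in range(n_tumor)] + \
                 [f"N{j:04d}" for j in range(n_normal)]
    is_tumor = np.zeros(n, dtype=bool)
    is_tumor[:n_tumor] = True

    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    values = baseline[:, None] + noise_sd * rng.standard_normal((n_genes, n))

    informative = gene_ids[:n_informative]
    for idx in range(n_informative):
        sign = 1.0 if idx % 2 == 0 else -1.0
        values[idx, is_tumor] += sign * effect_size

    redundant_map: dict[str, str] = {}
    for d in range(n_dup):
        row = n_informative + d
        parent = d % n_informative
        z = values[parent] - values[parent].mean()
        z /= z.std()
        eps = rng.standard_normal(n)
        values[row] = baseline[row] + noise_sd * (
            redundancy_rho * z + math.sqrt(1.0 - redundancy_rho**2) * eps
        )
        redundant_map[gene_ids[row]] = gene_ids[parent]

    null_start = n_informative + n_dup
    stage_trend = set(gene_ids[null_start:null_start + n_stage_trend])
    survival = set(gene_ids[null_start + n_stage_trend:
                            null_start + n_stage_trend + n_survival])

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    annotations = [
        SampleAnnotation(sample_id=s,
                         class_label=CLASS_TUMOR if t else CLASS_NORMAL)
        for s, t in zip(sample_ids, is_tumor)
    ]
    truth = GroundTruth(
        informative_genes=set(informative),
        redundant_map=redundant_map,
        stage_trend_genes=stage_trend,
        survival_genes=survival,
        effect_size=effect_size,
        noise_sd=noise_sd,
        redundancy_rho=redundancy_rho,
        gene_ids=gene_ids,
    )
    return matrix, annotations, truth


def attach_stage_and_survival(
    annotations: list[SampleAnnotation],
    truth: GroundTruth,
    matrix: ExpressionMatrix,
    seed: int = 0,
    stage_delta: float = 0.5,
    stage_probs: tuple[float, float, float, float] = DEFAULT_STAGE_PROBS,
    survival_log_hr: float = math.log(2.0),
    baseline_scale: float = 1000.0,
    censor_scale: float = 2500.0,
) -> list[SampleAnnotation]:
    """Assign tumor stages and survival outcomes to the tumor samples.

    Mutates ``matrix.values`` in place: every gene in
    ``truth.stage_trend_genes`` gains ``stage_delta * (stage - 1)`` in tumor
    samples, so its population stage means increase strictly by
    ``stage_delta`` per stage.  Survival times are exponential with log-hazard
    ``survival_log_hr`` per standard deviation of the mean survival-gene
    expression (higher expression -> shorter survival); censoring is
    independent Uniform(0, ``censor_scale``).  Returns a new annotation list;
    normal samples are passed through unchanged.
    """
    tumor_idx = [i for i, a in enumerate(annotations) if a.is_tumor]
    if not tumor_idx:
        raise ValueError("no tumor samples to annotate")
    rng = np.random.default_rng(seed)

    stages = rng.choice([1, 2, 3, 4], size=len(tumor_idx), p=list(stage_probs))

    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    cols = [matrix.sample_ids.index(annotations[i].sample_id) for i in tumor_idx]
    for g in sorted(truth.stage_trend_genes):
        r = gene_pos[g]
        matrix.values[r, cols] += stage_delta * (stages - 1)

    if truth.survival_genes:
        rows = [gene_pos[g] for g in sorted(truth.survival_genes)]
        expr = matrix.values[np.ix_(rows, cols)]
        z = (expr - expr.mean(axis=1, keepdims=True)) / \
            expr.std(axis=1, keepdims=True)
        score = z.mean(axis=0)
    else:
        score = np.zeros(len(tumor_idx))

    hazard = np.exp(survival_log_hr * score) / baseline_scale
    event_time = rng.exponential(1.0 / hazard)
    if censor_scale > 0:
        censor_time = rng.uniform(0.0, censor_scale, size=len(tumor_idx))
    else:
        censor_time = np.zeros(len(tumor_idx))
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    out = list(annotations)
    for k, i in enumerate(tumor_idx):
        a = annotations[i]
        out[i] = SampleAnnotation(
            sample_id=a.sample_id,
            class_label=a.class_label,
            stage=int(stages[k]),
            os_time=float(os_time[k]),
            os_event=int(os_event[k]),
        )
    return out
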