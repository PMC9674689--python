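import numpy as np
import pytest

from jmipanel import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(3)],
        sample_ids=[f"s{j}" for j in range(4)],
        values=rng.uniform(2, 10, size=(3, 4)),
    )


@pytest.fixture
def four_sample_annotations() -> list[SampleAnnotation]:
    return [
        SampleAnnotation("s0", "tumor"),
        SampleAnnotation("s1", "tumor"),
        SampleAnnotation("s2", "normal"),
        SampleAnnotation("s3", "normal"),
    ]


def make_two_group_matrix(tumor_rows, normal_rows, gene_ids=None):
    """Build an ExpressionMatrix from per-gene tumor/normal value lists."""
    tumor_rows = np.atleast_2d(np.asarray(tumor_rows, dtype=float))
    normal_rows = np.atleast_2d(np.asarray(normal_rows, dtype=float))
    n_genes = tumor_rows.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    values = np.hstack([tumor_rows, normal_rows])
    n1, n0 = tumor_rows.shape[1], normal_rows.shape[1]
    sample_ids = [f"t{j}" for j in range(n1)] + [f"n{j}" for j in range(n0)]
    labels = ["tumor"] * n1 + ["normal"] * n0
    return ExpressionMatrix(gene_ids, sample_ids, values), labels


@pytest.fixture
def two_group():
    return make_two_group_matrix
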