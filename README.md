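# jmipanel

Biomarker panel discovery from two-class (tumor/normal) log2 expression
matrices. The pipeline combines a filter stage — per-gene two-group linear
models with empirical-Bayes moderated t-statistics and Benjamini–Hochberg
adjustment (DEG criterion: |logFC| > 1, adj. P < 0.05) — with greedy
information-theoretic feature selection under the joint mutual information
(JMI) criterion (mRMR available as a comparator), and evaluates the resulting
gene panel with per-gene ROC/AUC, a two-cluster purity score, tumor-stage
trend screening, and Kaplan–Meier / log-rank survival splits.

A synthetic-cohort generator with planted ground truth (differential genes,
correlated duplicates, stage-monotone genes, expression-linked survival) makes
every stage testable without external data.

## Modules

| module | contents |
| --- | --- |
| `jmipanel.io_tables` | TSV expression/phenotype readers and writers, sample alignment |
| `jmipanel.synthetic_data` | seeded cohort generator + clinical attachment, `GroundTruth` |
| `jmipanel.diffexpr` | two-group fit, eBayes variance moderation, BH adjustment, DEG filter |
| `jmipanel.infotheory` | equal-frequency discretization, plug-in entropy/MI/joint MI (bits) |
| `jmipanel.feature_selection` | `jmi_score`, `mrmr_score`, deterministic `greedy_select` |
| `jmipanel.evaluation` | ROC/AUC, cluster purity, stage monotonicity, KM estimator, log-rank test |
| `jmipanel.cli` | `simulate` / `deg` / `select` / `evaluate` / `run` subcommands, `run_pipeline` |

## CLI

```bash
# generate a synthetic cohort with planted structure
jmipanel simulate --n-genes 2000 --n-tumor 200 --n-normal 200 \
    --n-informative 5 --n-redundant-per 2 --effect-size 2 \
    --n-stage-trend 1 --n-survival 1 --seed 7 --out-dir scratch/sim

# full pipeline: DEG filter -> JMI selection -> panel evaluation
jmipanel run --expression scratch/sim/expression.tsv \
    --phenotype scratch/sim/phenotype.tsv --k 5 --out-dir scratch/out
```

`run` writes `degs.tsv`, `selection.tsv`, `evaluation.tsv` and a
deterministic `report.json` (identical inputs and config give byte-identical
reports). The stages are also available individually (`deg`, `select`,
`evaluate`); `evaluate` defaults to the bundled 11-gene gastric-cancer panel
(`jmipanel.load_reference_panel()`) when no gene list is given. Expression
input is a genes × samples TSV (first row sample ids, first column gene ids,
log2 values, `.gz` accepted); the phenotype TSV needs `sample_id` and `class`
(tumor/normal) columns plus optional `stage`, `os_time`, `os_event`.

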