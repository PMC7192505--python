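# tdrscan

Systematic scanning of **translational drug-response modeling pipelines**:
models trained on cell-line drug screens (expression → ln(IC50)) and applied
to patient cohorts (expression → responder / non-responder), together with
the robustness diagnostics that reveal how much of a pipeline's apparent
performance is noise.

## Who this is for

Computational biologists benchmarking in-vitro-to-in-vivo drug sensitivity
prediction. Rather than optimizing one pipeline, `tdrscan` enumerates the
full Cartesian product of modeling choices and measures the whole
performance landscape:

| stage | options |
|---|---|
| cell response transform | none, logarithm, powertransform, binarization_cutoff, binarization_kmeans |
| train/test homogenization | none, quantile, combat, limma, ruv4, ruv, yugene |
| feature filter | all, landmarkgenes, variance, pvalue |
| feature preprocessing | none, zscore_samplewise, zscore_genewise, pca |
| black box | linear, lasso, elasticnet, ridge, rf, rf_ranger, svm |

5 · 7 · 4 · 4 · 7 = **3,920 pipelines**. Each pipeline runs the same stage
order: select all cell lines with a response to the drug → remove duplicated
gene names from both sides → intersect features → transform the response →
homogenize train/test expression → filter features → preprocess features →
fit → predict the cohort → orient scores (lower predicted ln(IC50) = more
likely responder) → evaluate.

Evaluation uses the Mann–Whitney form of the ROC AUC
(`AUC = U / (n₁·n₀)`, ties ½), the step-interpolated PR AUC, and a
two-sided pooled t-test between predicted responder and non-responder
scores.

Robustness diagnostics:

* **random-response null** — AUCs of Bernoulli(½) score vectors against the
  true labels (shows the cohort-size effect on the null spread),
* **gene-permutation null** — every pipeline re-predicts cohorts whose gene
  labels were shuffled,
* **drug-specificity ranking** — a pipeline sample trained with every drug
  of a multi-drug screen; if the administered drug does not rank first, the
  models exploit general rather than drug-specific sensitivity,
* **setting enrichment** — one-sided hypergeometric test per stage option
  for over-representation in the best 5% of pipelines,
* **cell2cell baseline** — in-vitro 5-fold cross-validation, and a
  train/validation/test **transfer experiment** asking whether in-vitro
  pipeline selection transfers to patients.

A seeded synthetic-data generator produces paired screens and cohorts with
planted signal genes, housekeeping (negative-control) genes, landmark
subsets, train-vs-patient batch shifts, and multi-drug response tables that
mix a shared sensitivity factor with drug-specific factors — so every stage
is testable without downloading anything.

## Worked example

```python
from tdrscan import PipelineConfig, SimulationParams, generate_paired_datasets
from tdrscan.scan_engine import enumerate_grid, run_pipeline, run_scan
from tdrscan.models import ModelParams

params = SimulationParams(
    n_genes=300, n_cell_lines=120, n_patients=24,
    effect_size=3.0, batch_shift_sd=0.0, batch_scale_sd=0.0, seed=11,
)
screen, cohort, truth = generate_paired_datasets(params)

config = PipelineConfig(
    drug="drug_000", homogenization="limma",
    feature_filter="landmarkgenes", black_box="lasso", seed=0,
)
res = run_pipeline(config, screen, cohort)
print(f"AUC-ROC {res.auc_roc:.3f}  AUC-PR {res.auc_pr:.3f}  p {res.separation_p:.2e}")
```

prints

```
AUC-ROC 0.979  AUC-PR 0.979  p 4.38e-06
```

i.e. on a cohort of 24 patients with strong planted signal and no batch
gap, the landmark-filtered lasso pipeline separates responders from
non-responders almost perfectly (AUC-ROC 0.98), and the predicted scores of
the two groups differ significantly (t-test p ≈ 4e-6). A full scan is one
call:

```python
result = run_scan(enumerate_grid(drug="drug_000"), screen, cohort,
                  model_params=ModelParams(n_trees_rf=25, n_trees_ranger=50))
print(result.summary())
```

The command line mirrors the library: `tdrscan simulate`, `tdrscan scan`,
`tdrscan cv`, `tdrscan transfer`, `tdrscan diagnostics null-random`,
`tdrscan diagnostics enrichment`, and `tdrscan run config.yaml` for
config-driven runs (results TSV + reproducible run metadata JSON).

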