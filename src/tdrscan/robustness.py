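"""Noise and specificity diagnostics for pipeline scans.

Four analyses quantify how much of a scan's apparent performance could be
noise:

* a random-response null — AUCs of i.i.d. Bernoulli(1/2) score vectors
  against the true labels, exposing the cohort-size effect on the null
  spread;
* a gene-permutation null — each pipeline re-predicts cohorts whose gene
  labels were shuffled (values untouched), destroying any real
  gene-to-response mapping;
* a drug-specificity scan — a random sample of pipelines is trained on
  every drug of a multi-drug screen; if the administered drug does not
  systematically rank first, the models are keyed to general rather than
  drug-specific sensitivity;
* a setting-enrichment report — a one-sided hypergeometric test per stage
  option for over-representation among the top fraction of pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import evaluation
from .core_data import CellScreen, DataError, ExpressionMatrix, PatientCohort, PipelineConfig
from .models import DEFAULT_MODEL_PARAMS, ModelParams
from .scan_engine import ScanResult, _run_group, _STAGE_ORDER, enumerate_grid

__all__ = [
    "NullDistribution",
    "EnrichmentReport",
    "random_response_null",
    "permuted_gene_null",
    "sample_configs",
    "drug_specificity_scan",
    "setting_enrichment",
]


@dataclass
class NullDistribution:
    draws: np.ndarray
    generator: str  # "random_binary" | "gene_permutation"
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        finite = self.draws[np.isfinite(self.draws)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise DataError("null AUC draws must lie in [0, 1]")

    def mean(self) -> float:
        return float(np.nanmean(self.draws))

    def sd(self) -> float:
        return float(np.nanstd(self.draws, ddof=1))


def random_response_null(
    labels: pd.Series, n_draws: int = 10_000, seed: int = 0, permute: bool = False
) -> NullDistribution:
    """AUC null from random binary score vectors against the true labels.

    Each draw scores the cohort with an i.i.d. Bernoulli(1/2) binary vector
    (ties counted one half); ``permute=True`` instead shuffles the true
    label vector as the score.  Under either null E[AUC] = 1/2, and the
    spread shrinks with the cohort size.
    """
    labels = pd.Series(labels).astype(int)
    if labels.nunique() < 2:
        raise DataError("both classes must be present")
    y = labels.to_numpy()
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    # AUC of a binary score vector has closed form from the 2x2 table:
    # wins = a1 * (n0 - a0'), ties at equal scores count one half.
    for i in range(n_draws):
        if permute:
            scores = rng.permutation(y)
        else:
            scores = rng.integers(0, 2, size=len(y))
        pos_hi = int(scores[y == 1].sum())  # responders scored 1
        neg_hi = int(scores[y == 0].sum())  # non-responders scored 1
        wins = pos_hi * (n0 - neg_hi)
        ties = pos_hi * neg_hi + (n1 - pos_hi) * (n0 - neg_hi)
        draws[i] = (wins + 0.5 * ties) / (n1 * n0)
    return NullDistribution(draws, "random_binary", n_draws, seed)


def permuted_gene_null(
    configs: Sequence[PipelineConfig],
    screen: CellScreen,
    cohort: PatientCohort,
    n_perm: int = 1000,
    seed: int = 0,
    model_params: ModelParams = DEFAULT_MODEL_PARAMS,
) -> dict[str, NullDistribution]:
    """Re-run each pipeline on cohorts with randomly permuted gene labels.

    Per permutation the cohort's gene ids are shuffled while the value
    matrix stays untouched, then the full test-side pipeline (including
    homogenization) re-runs.  Returns one AUC null per pipeline id.
    """
    configs = list(configs)
    cohort.require_both_classes()
    rng = np.random.default_rng(seed)
    per_config: dict[str, list[float]] = {}
    ids = []
    for cfg in configs:
        key = "|".join(cfg.stage_tuple())
        ids.append(key)
        per_config.setdefault(key, [])
    values = cohort.expression.values
    for _ in range(n_perm):
        shuffled = values.copy()
        shuffled.index = rng.permutation(np.asarray(values.index))
        permuted = ExpressionMatrix(shuffled)
        results = _run_group(configs, screen, permuted, cohort.response, model_params)
        for key, res in zip(ids, results):
            per_config[key].append(res.auc_roc)
    return {
        key: NullDistribution(np.array(vals), "gene_permutation", n_perm, seed)
        for key, vals in per_config.items()
    }


def sample_configs(
    n: int = 100, seed: int = 0, drug: str = "drug_000", grid=None
) -> list[PipelineConfig]:
    """Uniform seeded sample (without replacement) from the pipeline grid."""
    grid = list(grid) if grid is not None else enumerate_grid(drug=drug, seed=seed)
    if n > len(grid):
        raise DataError(f"cannot sample {n} configs from a grid of {len(grid)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=n, replace=False)
    return [grid[i] for i in sorted(idx)]


def drug_specificity_scan(
    sampled_configs: Sequence[PipelineConfig],
    screen: CellScreen,
    cohort: PatientCohort,
    administered_drug: Optional[str] = None,
    min_responses: int = 10,
    model_params: ModelParams = DEFAULT_MODEL_PARAMS,
) -> tuple[pd.Series, float]:
    """Train the sampled pipelines with every drug; rank the drugs.

    Every drug of the screen (with at least ``min_responses`` measured
    responses) trains the same sampled pipelines, which are then evaluated
    on the cohort.  Drugs are ranked by their mean AUC (rank 1 = best,
    average ranks on ties); returns the per-drug mean AUCs and the rank of
    the administered drug.
    """
    sampled_configs = list(sampled_configs)
    if screen.response.shape[0] < 2:
        raise DataError("drug specificity needs a multi-drug screen")
    administered = administered_drug or sampled_configs[0].drug
    cohort.require_both_classes()
    mean_auc = {}
    for drug in screen.drugs:
        y = screen.drug_response(drug)
        if len(y) < min_responses:
            warnings.warn(f"drug {drug} skipped: only {len(y)} responses")
            continue
        drug_configs = [
            PipelineConfig(
                drug=drug,
                response_transform=c.response_transform,
                homogenization=c.homogenization,
                feature_filter=c.feature_filter,
                feature_preprocess=c.feature_preprocess,
                black_box=c.black_box,
                seed=c.seed,
            )
            for c in sampled_configs
        ]
        results = _run_group(
            drug_configs, screen, cohort.expression, cohort.response, model_params
        )
        aucs = [r.auc_roc for r in results if r.ok]
        mean_auc[drug] = float(np.mean(aucs)) if aucs else float("nan")
    means = pd.Series(mean_auc, name="mean_auc_roc")
    if administered not in means.index:
        raise DataError(f"administered drug {administered!r} was skipped or absent")
    ranks = evaluation.assign_ranks(means.dropna())
    return means, float(ranks.loc[administered])


@dataclass
class EnrichmentReport:
    """Per stage-option enrichment among the top-performing pipelines."""

    table: pd.DataFrame  # stage, option, n_universe, n_top, p_value, significant, mean_auc
    top_frac: float
    alpha: float
    n_top: int
    n_universe: int

    def significant_options(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def setting_enrichment(
    scan: ScanResult, top_frac: float = 0.05, alpha: float = 0.01
) -> EnrichmentReport:
    """Hypergeometric over-representation of stage options in the top set.

    The top set is the best ceil(top_frac * N) pipelines by AUC of ROC
    (ties resolved by average rank, then stable row order).  For an option
    occurring K times in the universe of N pipelines and x times in the top
    n, the one-sided p-value is P(X >= x) under the hypergeometric law.
    Also reports the per-option mean AUC over the whole universe.
    """
    table = scan.table
    ok = table[table["failure"].isna() & table["auc_roc"].notna()].reset_index(drop=True)
    n_universe = len(ok)
    if n_universe < int(np.ceil(1.0 / top_frac)):
        raise DataError("scan too small for the requested top fraction")
    n_top = int(np.ceil(top_frac * n_universe))
    ranks = evaluation.assign_ranks(ok["auc_roc"])
    top_pos = ranks.sort_values(kind="stable").index[:n_top]
    top = ok.loc[top_pos]
    rows = []
    for stage in _STAGE_ORDER:
        for option in ok[stage].unique():
            k_universe = int((ok[stage] == option).sum())
            x_top = int((top[stage] == option).sum())
            p = float(stats.hypergeom.sf(x_top - 1, n_universe, k_universe, n_top))
            rows.append(
                {
                    "stage": stage,
                    "option": option,
                    "n_universe": k_universe,
                    "n_top": x_top,
                    "p_value": p,
                    "significant": p < alpha,
                    "mean_auc": float(ok.loc[ok[stage] == option, "auc_roc"].mean()),
                }
            )
    report = pd.DataFrame(rows)
    return EnrichmentReport(
        table=report,
        top_frac=top_frac,
        alpha=alpha,
        n_top=n_top,
        n_universe=n_universe,
    )
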