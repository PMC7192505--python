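"""Pipeline grid enumeration and execution.

A pipeline runs its stages in a fixed order: select training samples (all
tissues), remove duplicated gene names, intersect features, transform the
response, homogenize train/test expression, filter features, preprocess
features, fit the black box, predict the test cohort, orient the scores and
evaluate.  ``run_scan`` executes a whole configuration grid; stage outputs
that several pipelines share (homogenized matrices, filtered gene sets,
preprocessed feature blocks) are computed once per scan, which leaves the
per-pipeline results identical to independent runs because every stage is a
deterministic pure function of the configuration and seed.

Besides the translational (cell-to-patient) scan the module provides the
in-vitro baseline (cell-to-cell 5-fold cross-validation) and the
train/validation/test transfer experiment that asks whether pipelines
selected in vitro keep their advantage on patients.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import evaluation, models
from .core_data import (
    BLACK_BOXES,
    FEATURE_FILTERS,
    FEATURE_PREPROCESSES,
    HOMOGENIZATION_METHODS,
    RESPONSE_TRANSFORMS,
    CellScreen,
    DataError,
    ExpressionMatrix,
    PatientCohort,
    PipelineConfig,
    PipelineResult,
    intersect_features,
    remove_duplicate_genes,
)
from .feature_engineering import FeatureSpec, filter_features, preprocess_features
from .homogenization import HomogenizationSpec, homogenize
from .models import DEFAULT_MODEL_PARAMS, ModelParams
from .response_transform import transform_binarize_cutoff, transform_response

__all__ = [
    "DEFAULT_STAGE_OPTIONS",
    "ScanResult",
    "TransferReport",
    "enumerate_grid",
    "pipeline_id",
    "run_pipeline",
    "run_scan",
    "crossvalidate_cell2cell",
    "transfer_experiment",
]

DEFAULT_STAGE_OPTIONS = {
    "response_transform": RESPONSE_TRANSFORMS,
    "homogenization": HOMOGENIZATION_METHODS,
    "feature_filter": FEATURE_FILTERS,
    "feature_preprocess": FEATURE_PREPROCESSES,
    "black_box": BLACK_BOXES,
}

_STAGE_ORDER = (
    "response_transform",
    "homogenization",
    "feature_filter",
    "feature_preprocess",
    "black_box",
)


def enumerate_grid(
    stage_options: Optional[dict] = None, drug: str = "drug_000", seed: int = 0
) -> list[PipelineConfig]:
    """Full Cartesian product of the per-stage option lists.

    Deterministic lexicographic order over the stage vocabularies; the
    defaults reproduce the 5*7*4*4*7 = 3,920 pipeline grid.
    """
    options = dict(DEFAULT_STAGE_OPTIONS)
    if stage_options:
        options.update(stage_options)
    lists = []
    for stage in _STAGE_ORDER:
        opts = list(options[stage])
        if not opts:
            raise DataError(f"empty option list for stage {stage!r}")
        lists.append(opts)
    return [
        PipelineConfig(
            drug=drug,
            response_transform=rt,
            homogenization=hm,
            feature_filter=ff,
            feature_preprocess=fp,
            black_box=bb,
            seed=seed,
        )
        for rt, hm, ff, fp, bb in itertools.product(*lists)
    ]


def pipeline_id(config: PipelineConfig) -> str:
    return "|".join(config.stage_tuple())


_STAGE_KEYS = {"response": 1, "fit": 2, "heldout": 3}


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    """Stable per-stage 31-bit seed derived from the pipeline seed."""
    ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, _STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class _ScanContext:
    """Cached stage outputs for one (screen, test side, drug, seed) setting.

    The test side is any expression matrix with binary truth labels — a
    patient cohort or a held-out fold of cell lines.
    """

    def __init__(
        self,
        screen: CellScreen,
        test_expression: ExpressionMatrix,
        test_labels: pd.Series,
        drug: str,
        model_params: ModelParams = DEFAULT_MODEL_PARAMS,
    ):
        self.model_params = model_params
        self.labels = test_labels
        y = screen.drug_response(drug)
        train_expr = screen.expression.subset_samples(list(y.index))
        train_expr, test_expr = remove_duplicate_genes(train_expr, test_expression)
        shared = intersect_features(train_expr, test_expr)
        self.train = train_expr.subset_genes(shared).values
        self.test = test_expr.subset_genes(shared).values
        self.y = y
        self.controls = frozenset(g for g in shared if g in screen.housekeeping_genes)
        self.landmarks = frozenset(g for g in shared if g in screen.landmark_genes)
        self._responses: dict = {}
        self._homogenized: dict = {}
        self._filters: dict = {}
        self._features: dict = {}

    def response(self, method: str, seed: int):
        key = method
        if key not in self._responses:
            self._responses[key] = transform_response(self.y, method, seed=seed)
        return self._responses[key]

    def homogenized(self, method: str):
        if method not in self._homogenized:
            # yugene_shift: inside a scan, log-scale data with an incidental
            # negative value is min-shifted rather than failing the pipeline.
            spec = HomogenizationSpec(
                method=method, control_genes=self.controls, yugene_shift=True
            )
            self._homogenized[method] = homogenize(self.train, self.test, spec)
        return self._homogenized[method]

    def _filter_key(self, config: PipelineConfig):
        # The p-value filter ranks genes against the transformed response;
        # all other filters are response-independent.
        rt = config.response_transform if config.feature_filter == "pvalue" else None
        return (config.homogenization, config.feature_filter, rt)

    def gene_set(self, config: PipelineConfig):
        key = self._filter_key(config)
        if key not in self._filters:
            train_h, _ = self.homogenized(config.homogenization)
            response = None
            if config.feature_filter == "pvalue":
                response = self.response(
                    config.response_transform, _stage_seed(config, "response")
                )
            spec = FeatureSpec(
                filter=config.feature_filter, landmark_list=self.landmarks
            )
            self._filters[key] = filter_features(train_h, response, spec)
        return self._filters[key]

    def feature_matrices(self, config: PipelineConfig):
        key = self._filter_key(config) + (config.feature_preprocess,)
        if key not in self._features:
            train_h, test_h = self.homogenized(config.homogenization)
            genes = self.gene_set(config)
            spec = FeatureSpec(
                filter=config.feature_filter,
                preprocess=config.feature_preprocess,
                landmark_list=self.landmarks,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._features[key] = preprocess_features(
                    train_h.loc[genes], test_h.loc[genes], spec
                )
        return self._features[key]

    def run(self, config: PipelineConfig) -> PipelineResult:
        try:
            response = self.response(
                config.response_transform, _stage_seed(config, "response")
            )
            train_x, test_x, _ = self.feature_matrices(config)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = models.fit(
                    train_x,
                    response,
                    config.black_box,
                    seed=_stage_seed(config, "fit"),
                    params=self.model_params,
                )
            raw = models.predict(model, test_x)
            scores = models.orient_scores(raw, model.target_orientation)
            return PipelineResult(
                config=config,
                auc_roc=evaluation.roc_auc(scores, self.labels),
                auc_pr=evaluation.pr_auc(scores, self.labels),
                separation_p=evaluation.separation_ttest(scores, self.labels),
                predictions=scores,
            )
        except Exception as exc:  # captured, never raised out of a scan
            return PipelineResult(config=config, failure=f"{type(exc).__name__}: {exc}")


def run_pipeline(
    config: PipelineConfig,
    screen: CellScreen,
    cohort: PatientCohort,
    model_params: ModelParams = DEFAULT_MODEL_PARAMS,
) -> PipelineResult:
    """Execute one full translational pipeline; stage errors are captured.

    The drug must be present in the screen; any downstream stage failure
    is recorded in the result's ``failure`` field instead of raising.
    """
    if config.drug not in screen.response.index:
        raise DataError(f"drug {config.drug!r} not present in the screen")
    cohort.require_both_classes()
    ctx = _ScanContext(
        screen, cohort.expression, cohort.response, config.drug, model_params
    )
    return ctx.run(config)


@dataclass
class ScanResult:
    """Per-pipeline performance table for one dataset and scenario."""

    table: pd.DataFrame
    dataset_id: str = "synthetic"
    scenario: str = "cell2patient"

    @staticmethod
    def columns() -> list[str]:
        return [
            "pipeline_id",
            "drug",
            *_STAGE_ORDER,
            "seed",
            "auc_roc",
            "auc_pr",
            "separation_p",
            "failure",
        ]

    def performances(self, metric: str = "auc_roc") -> pd.Series:
        return pd.Series(
            self.table[metric].to_numpy(), index=self.table["pipeline_id"], name=self.dataset_id
        )

    def summary(self) -> dict:
        ok = self.table[self.table["failure"].isna()]
        out = {
            "n_pipelines": int(len(self.table)),
            "n_failed": int(self.table["failure"].notna().sum()),
            "median_auc_roc": float(ok["auc_roc"].median()) if len(ok) else float("nan"),
        }
        if len(ok):
            best = ok.loc[ok["auc_roc"].idxmax()]
            out["best_pipeline_id"] = str(best["pipeline_id"])
            out["best_auc_roc"] = float(best["auc_roc"])
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_results(
        cls,
        results: Sequence[PipelineResult],
        dataset_id: str = "synthetic",
        scenario: str = "cell2patient",
    ) -> "ScanResult":
        rows = []
        for res in results:
            cfg = res.config
            rows.append(
                {
                    "pipeline_id": pipeline_id(cfg),
                    "drug": cfg.drug,
                    **dict(zip(_STAGE_ORDER, cfg.stage_tuple())),
                    "seed": cfg.seed,
                    "auc_roc": res.auc_roc,
                    "auc_pr": res.auc_pr,
                    "separation_p": res.separation_p,
                    "failure": res.failure,
                }
            )
        table = pd.DataFrame(rows, columns=cls.columns())
        return cls(table=table, dataset_id=dataset_id, scenario=scenario)


def _run_group(
    configs: list[PipelineConfig],
    screen: CellScreen,
    test_expression: ExpressionMatrix,
    test_labels: pd.Series,
    model_params: ModelParams,
) -> list[PipelineResult]:
    out = []
    contexts: dict = {}
    for config in configs:
        key = (config.drug, config.seed)
        if key not in contexts:
            try:
                contexts[key] = _ScanContext(
                    screen, test_expression, test_labels, config.drug, model_params
                )
            except Exception as exc:
                contexts[key] = exc
        ctx = contexts[key]
        if isinstance(ctx, Exception):
            out.append(
                PipelineResult(config=config, failure=f"{type(ctx).__name__}: {ctx}")
            )
        else:
            out.append(ctx.run(config))
    return out


def run_scan(
    configs: Sequence[PipelineConfig],
    screen: CellScreen,
    cohort: PatientCohort,
    n_workers: int = 1,
    model_params: ModelParams = DEFAULT_MODEL_PARAMS,
    dataset_id: str = "synthetic",
) -> ScanResult:
    """Run a configuration grid against one patient cohort.

    Results are independent of ``n_workers`` and of config order: workers
    receive whole homogenization groups (so cached stages never cross a
    worker boundary) and the output table is reassembled in input order.
    """
    cohort.require_both_classes()
    configs = list(configs)
    if not configs:
        return ScanResult(
            table=pd.DataFrame(columns=ScanResult.columns()), dataset_id=dataset_id
        )
    # Group by homogenization method (the most expensive shared stage).
    groups: dict[str, list[int]] = {}
    for i, cfg in enumerate(configs):
        groups.setdefault(cfg.homogenization, []).append(i)
    group_lists = list(groups.values())
    if n_workers > 1 and len(group_lists) > 1:
        chunks = Parallel(n_jobs=n_workers, backend="loky")(
            delayed(_run_group)(
                [configs[i] for i in idx],
                screen,
                cohort.expression,
                cohort.response,
                model_params,
            )
            for idx in group_lists
        )
    else:
        chunks = [
            _run_group(
                [configs[i] for i in idx],
                screen,
                cohort.expression,
                cohort.response,
                model_params,
            )
            for idx in group_lists
        ]
    ordered: list[Optional[PipelineResult]] = [None] * len(configs)
    for idx, chunk in zip(group_lists, chunks):
        for i, res in zip(idx, chunk):
            ordered[i] = res
    return ScanResult.from_results(ordered, dataset_id=dataset_id)


def _binarize_heldout(y: pd.Series, response_transform: str, seed: int) -> pd.Series:
    """Truth labels for held-out cell lines: 1 = sensitive.

    Binarizing transforms reuse their own rule on the held-out ln(IC50)
    values; continuous transforms fall back to a median split, which keeps
    ROC well defined for every pipeline.
    """
    if response_transform in ("binarization_cutoff", "binarization_kmeans"):
        return transform_response(y, response_transform, seed=seed).values
    return transform_binarize_cutoff(y).values


def crossvalidate_cell2cell(
    config: PipelineConfig,
    screen: CellScreen,
    k: int = 5,
    seed: int = 0,
    model_params: ModelParams = DEFAULT_MODEL_PARAMS,
) -> float:
    """Mean in-vitro AUC of a k-fold cross-validation on the cell screen.

    Cell lines with a response to the configured drug are split into k
    seeded folds; each fold is held out as the test side (its true ln(IC50)
    binarized into sensitive/resistant) while the remaining folds train the
    full pipeline.  Folds whose held-out truth is single-class are skipped
    with a warning; the mean is over valid folds.
    """
    y = screen.drug_response(config.drug)
    cells = list(y.index)
    if k < 2 or k > len(cells):
        raise DataError(f"k={k} folds infeasible for {len(cells)} cell lines")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    folds = np.array_split(order, k)
    aucs = []
    for fold in folds:
        held = [cells[i] for i in fold]
        kept = [c for c in cells if c not in set(held)]
        try:
            labels = _binarize_heldout(
                y.loc[held], config.response_transform, _stage_seed(config, "heldout")
            )
        except DataError:
            warnings.warn("fold with single-class truth skipped")
            continue
        if labels.nunique() < 2:
            warnings.warn("fold with single-class truth skipped")
            continue
        sub_screen = CellScreen(
            expression=screen.expression.subset_samples(kept),
            response=screen.response.loc[[config.drug], kept],
            tissues=screen.tissues.loc[kept] if screen.tissues is not None else None,
            landmark_genes=screen.landmark_genes,
            housekeeping_genes=screen.housekeeping_genes,
        )
        held_expr = screen.expression.subset_samples(held)
        ctx = _ScanContext(sub_screen, held_expr, labels, config.drug, model_params)
        res = ctx.run(config)
        if res.ok:
            aucs.append(res.auc_roc)
        else:
            warnings.warn(f"fold failed: {res.failure}")
    if not aucs:
        raise DataError("no valid folds in cross-validation")
    return float(np.mean(aucs))


@dataclass
class TransferReport:
    """Outcome of the train/validation/test transfer experiment."""

    table: pd.DataFrame  # per config: auc_validation, auc_test, auc_patient
    top_ids: list[str]
    p_test: float
    p_patient: float
    n_top: int

    def top_improves(self, surface: str, alpha: float = 0.01) -> bool:
        p = self.p_test if surface == "test" else self.p_patient
        table = self.table
        top = table.loc[table["pipeline_id"].isin(self.top_ids), f"auc_{surface}"]
        return bool(p < alpha and top.mean() > table[f"auc_{surface}"].mean())


def transfer_experiment(
    configs: Sequence[PipelineConfig],
    screen: CellScreen,
    cohort: PatientCohort,
    n_top: int = 300,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    model_params: ModelParams = DEFAULT_MODEL_PARAMS,
) -> TransferReport:
    """Select pipelines in vitro and check whether the advantage transfers.

    The screen's cell lines are split into training, validation and test
    parts.  Every pipeline is trained on the training part and scored on
    the validation part; the ``n_top`` pipelines by validation AUC are then
    compared (two-sided t-tests, top subset vs all pipelines) on the held
    out in-vitro test part and on the patient cohort.
    """
    configs = list(configs)
    if len(configs) < n_top:
        raise DataError(f"need >= n_top={n_top} configs, got {len(configs)}")
    drugs = {c.drug for c in configs}
    if len(drugs) != 1:
        raise DataError("transfer experiment expects a single training drug")
    drug = drugs.pop()
    y = screen.drug_response(drug)
    cells = list(y.index)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    n = len(cells)
    n_train = int(round(proportions[0] * n))
    n_val = int(round(proportions[1] * n))
    if min(n_train, n_val, n - n_train - n_val) < 5:
        raise DataError("transfer splits too small")
    part_train = [cells[i] for i in order[:n_train]]
    part_val = [cells[i] for i in order[n_train: n_train + n_val]]
    part_test = [cells[i] for i in order[n_train + n_val:]]

    train_screen = CellScreen(
        expression=screen.expression.subset_samples(part_train),
        response=screen.response.loc[[drug], part_train],
        tissues=screen.tissues.loc[part_train] if screen.tissues is not None else None,
        landmark_genes=screen.landmark_genes,
        housekeeping_genes=screen.housekeeping_genes,
    )

    surfaces = {}
    for name, part in (("validation", part_val), ("test", part_test)):
        labels = transform_binarize_cutoff(y.loc[part]).values
        surfaces[name] = (screen.expression.subset_samples(part), labels)
    surfaces["patient"] = (cohort.expression, cohort.response)

    records: dict[str, dict] = {pipeline_id(c): {"pipeline_id": pipeline_id(c)} for c in configs}
    for name, (expr, labels) in surfaces.items():
        results = _run_group(configs, train_screen, expr, labels, model_params)
        for cfg, res in zip(configs, results):
            records[pipeline_id(cfg)][f"auc_{name}"] = res.auc_roc
    table = pd.DataFrame(list(records.values()))

    valid = table.dropna(subset=["auc_validation"])
    ranks = evaluation.assign_ranks(
        pd.Series(valid["auc_validation"].to_numpy(), index=valid.index)
    )
    top_idx = ranks.sort_values(kind="stable").index[:n_top]
    top_ids = list(valid.loc[top_idx, "pipeline_id"])

    def _surface_p(surface: str) -> float:
        col = table[f"auc_{surface}"].dropna()
        top = table.loc[table["pipeline_id"].isin(top_ids), f"auc_{surface}"].dropna()
        if len(top) < 2 or len(col) < 2 or col.var(ddof=1) == 0:
            return 1.0
        return float(stats.ttest_ind(top, col, equal_var=True)[1])

    return TransferReport(
        table=table,
        top_ids=top_ids,
        p_test=_surface_p("test"),
        p_patient=_surface_p("patient"),
        n_top=n_top,
    )
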