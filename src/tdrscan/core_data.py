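"""Domain containers and I/O for translational drug-response modeling.

The two sides of a translational experiment are a cell-line screen (the
training side: expression plus per-drug ln(IC50) response) and a patient
cohort (the test side: expression plus a binary responder label).  Both carry
their expression as a genes-in-rows matrix.  This module also owns the two
pre-modeling data hygiene steps shared by every pipeline — removal of
duplicated gene names and train/test feature intersection — and the clinical
label / survival binarization used to produce patient responder classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellScreen",
    "PatientCohort",
    "PipelineConfig",
    "PipelineResult",
    "RESPONSE_TRANSFORMS",
    "HOMOGENIZATION_METHODS",
    "FEATURE_FILTERS",
    "FEATURE_PREPROCESSES",
    "BLACK_BOXES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_cohort_sidecar",
    "write_cohort_sidecar",
    "remove_duplicate_genes",
    "intersect_features",
    "binarize_clinical_labels",
    "median_split_survival",
]

# Stage vocabularies of the pipeline grid (5 * 7 * 4 * 4 * 7 = 3,920).
RESPONSE_TRANSFORMS = (
    "none",
    "logarithm",
    "powertransform",
    "binarization_cutoff",
    "binarization_kmeans",
)
HOMOGENIZATION_METHODS = (
    "none",
    "quantile",
    "combat",
    "limma",
    "ruv4",
    "ruv",
    "yugene",
)
FEATURE_FILTERS = ("all", "landmarkgenes", "variance", "pvalue")
FEATURE_PREPROCESSES = ("none", "zscore_samplewise", "zscore_genewise", "pca")
BLACK_BOXES = ("linear", "lasso", "elasticnet", "ridge", "rf", "rf_ranger", "svm")


class DataError(ValueError):
    """Raised on malformed or degenerate inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values.

    ``values`` is a pandas DataFrame with gene ids on the index and sample
    ids on the columns.  Sample ids must be unique and all entries finite;
    gene ids may be duplicated until :func:`remove_duplicate_genes` has run.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise DataError(f"duplicate sample ids: {list(dupes)[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise DataError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass
class CellScreen:
    """A drug screen on cell lines: expression, ln(IC50) responses, tissues.

    ``response`` is a drug x cell-line DataFrame of ln(IC50) values (natural
    log molar concentration; lower = more sensitive), possibly with missing
    entries per drug.  ``landmark_genes`` and ``housekeeping_genes`` flag the
    gene subsets used by the landmark feature filter and by the RUV-style
    negative-control homogenizations respectively.
    """

    expression: ExpressionMatrix
    response: pd.DataFrame
    tissues: Optional[pd.Series] = None
    landmark_genes: frozenset = frozenset()
    housekeeping_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        missing = set(self.response.columns) - set(self.expression.sample_ids)
        if missing:
            raise DataError(
                f"response columns not in expression samples: {sorted(missing)[:5]}"
            )
        universe = set(self.expression.gene_ids)
        for name, gene_set in (
            ("landmark", self.landmark_genes),
            ("housekeeping", self.housekeeping_genes),
        ):
            extra = set(gene_set) - universe
            if extra:
                raise DataError(f"{name} genes outside gene universe: {sorted(extra)[:5]}")
        counts = self.response.notna().sum(axis=1)
        bad = counts[counts < 2]
        if len(bad):
            raise DataError(f"drugs with <2 responses: {list(bad.index)[:5]}")

    @property
    def drugs(self) -> list[str]:
        return list(self.response.index)

    def drug_response(self, drug: str) -> pd.Series:
        """Non-missing ln(IC50) values of one drug, indexed by cell line."""
        if drug not in self.response.index:
            raise DataError(f"drug {drug!r} not in screen")
        return self.response.loc[drug].dropna().astype(float)


@dataclass
class PatientCohort:
    """A patient cohort: expression plus a binary responder annotation."""

    expression: ExpressionMatrix
    response: pd.Series
    raw_labels: Optional[pd.Series] = None
    survival_months: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        samples = self.expression.sample_ids
        missing = set(samples) - set(self.response.index)
        if missing:
            raise DataError(f"response missing for samples: {sorted(missing)[:5]}")
        self.response = self.response.loc[samples].astype(int)
        bad = set(self.response.unique()) - {0, 1}
        if bad:
            raise DataError(f"response values must be 0/1, got {sorted(bad)}")

    @property
    def n_patients(self) -> int:
        return self.expression.n_samples

    def require_both_classes(self) -> None:
        if self.response.nunique() < 2:
            raise DataError("cohort has a single response class; cannot evaluate")


@dataclass(frozen=True)
class PipelineConfig:
    """One choice per modeling stage plus the drug and the seed."""

    drug: str
    response_transform: str = "none"
    homogenization: str = "none"
    feature_filter: str = "all"
    feature_preprocess: str = "none"
    black_box: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = (
            ("response_transform", RESPONSE_TRANSFORMS),
            ("homogenization", HOMOGENIZATION_METHODS),
            ("feature_filter", FEATURE_FILTERS),
            ("feature_preprocess", FEATURE_PREPROCESSES),
            ("black_box", BLACK_BOXES),
        )
        for name, options in checks:
            value = getattr(self, name)
            if value not in options:
                raise DataError(f"{name}={value!r} not one of {options}")

    def stage_tuple(self) -> tuple[str, str, str, str, str]:
        return (
            self.response_transform,
            self.homogenization,
            self.feature_filter,
            self.feature_preprocess,
            self.black_box,
        )


@dataclass
class PipelineResult:
    """Evaluated performance of one pipeline on one test cohort."""

    config: PipelineConfig
    auc_roc: float = float("nan")
    auc_pr: float = float("nan")
    separation_p: float = float("nan")
    predictions: Optional[pd.Series] = None
    failure: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.failure is None


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path, orientation: str = "genes_in_rows", sep: Optional[str] = None
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The file must have one header row of sample ids and a first column of
    gene ids.  ``orientation`` declares how the file is laid out; the
    in-memory convention is always genes in rows.  Any non-numeric cell
    (including ``NA``) is a parse error naming the offending row and column.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    sep = sep or _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dupes):
        raise DataError(f"duplicate sample ids in header: {list(dupes.unique())[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        rows = mask.any(axis=1)
        row = mask.index[rows][0]
        col = mask.columns[mask.loc[row]][0]
        raise DataError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
    if orientation == "samples_in_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path, sep: Optional[str] = None) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=sep or _sep_for(path))


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_cohort_sidecar(path) -> dict:
    """JSON sidecar holding cohort response / raw labels / survival."""
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    if "response" in payload:
        out["response"] = pd.Series(payload["response"], dtype=int)
    if "raw_labels" in payload:
        out["raw_labels"] = pd.Series(payload["raw_labels"], dtype=str)
    if "survival_months" in payload:
        out["survival_months"] = pd.Series(payload["survival_months"], dtype=float)
    return out


def write_cohort_sidecar(cohort: PatientCohort, path) -> None:
    payload: dict = {"response": {k: int(v) for k, v in cohort.response.items()}}
    if cohort.raw_labels is not None:
        payload["raw_labels"] = {k: str(v) for k, v in cohort.raw_labels.items()}
    if cohort.survival_months is not None:
        payload["survival_months"] = {
            k: float(v) for k, v in cohort.survival_months.items()
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Pre-modeling hygiene


def remove_duplicate_genes(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Drop every gene name occurring more than once in either matrix.

    Duplicated names are removed entirely from both matrices (all of their
    rows — not collapsed to a single row), so the surviving ids are unique
    on both sides.  Idempotent.  Raises if nothing survives.
    """
    dup: set[str] = set()
    for mat in (train, test):
        idx = pd.Index(mat.gene_ids)
        dup |= set(idx[idx.duplicated(keep=False)])
    out = []
    for mat in (train, test):
        keep = [g for g in mat.gene_ids if g not in dup]
        if not keep:
            raise DataError("all genes removed by duplication handling")
        out.append(ExpressionMatrix(mat.values.loc[keep]))
    return out[0], out[1]


def intersect_features(train: ExpressionMatrix, test: ExpressionMatrix) -> list[str]:
    """Overlapping genes between train and test, in train order.

    Expects duplicate handling to have run already (unique ids each side).
    """
    test_set = set(test.gene_ids)
    shared = [g for g in train.gene_ids if g in test_set]
    if not shared:
        raise DataError("no overlapping genes between train and test")
    return shared


#: Clinical categories accepted as non-responders when no explicit
#: non-responder set is configured: stable disease, progressive disease,
#: no change, and their "clinical" variants.
DEFAULT_NONRESPONDER_LABELS = frozenset({"SD", "PD", "NC", "cSD", "cPD"})


def binarize_clinical_labels(
    labels: Mapping[str, str] | pd.Series,
    responder_set: set[str],
    nonresponder_set: Optional[set[str]] = None,
) -> pd.Series:
    """Map clinical response categories to 1 (responder) / 0 (non-responder).

    Typical responder sets are {cCR, cPR} for clinical complete/partial
    response, or {CR, PR, MR} when minimal response counts as response;
    SD/PD/NC style labels fall to the non-responder class.  A label outside
    both configured sets is an error listing the offenders.
    """
    labels = pd.Series(labels, dtype=str)
    if nonresponder_set is None:
        nonresponder_set = set(DEFAULT_NONRESPONDER_LABELS)
    known = set(responder_set) | set(nonresponder_set)
    unknown = sorted(set(labels.unique()) - known)
    if unknown:
        raise DataError(f"unclassified clinical labels: {unknown}")
    return labels.isin(set(responder_set)).astype(int)


def median_split_survival(months: Mapping[str, float] | pd.Series) -> pd.Series:
    """Binarize progression-free survival at the cohort median.

    Patients strictly above the median are responders (1); values at or
    below the median — including exact ties at the median — are
    non-responders (0).  All-identical inputs admit no split and raise.
    """
    months = pd.Series(months, dtype=float)
    if len(months) < 2:
        raise DataError("need at least two samples for a median split")
    if months.nunique() == 1:
        raise DataError("all survival values identical; no median split possible")
    med = float(months.median())
    return (months > med).astype(int)
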