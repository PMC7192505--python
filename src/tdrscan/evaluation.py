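"""Performance metrics and comparison statistics.

ROC AUC (Mann-Whitney form with ties counted one half), step-interpolated
precision-recall AUC, the responder/non-responder separation t-test,
average-rank assignment across pipelines, and Pearson correlation of
performance vectors across datasets.
"""

from __future__ import annotations

import sys
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .core_data import DataError

__all__ = [
    "roc_auc",
    "pr_auc",
    "separation_ttest",
    "assign_ranks",
    "performance_correlation",
]


def _check_classes(scores: pd.Series, labels: pd.Series):
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).astype(int).loc[scores.index]
    if labels.nunique() < 2:
        raise DataError("both responder classes must be present for evaluation")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, as the normalized Mann-Whitney U statistic.

    A responder/non-responder score pair contributes 1 when the responder
    scores higher, 1/2 on a tie; the rank-sum form (average ranks for ties)
    realizes exactly that convention.
    """
    if isinstance(scores, pd.Series) and isinstance(labels, pd.Series):
        labels = labels.loc[scores.index]
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DataError("both responder classes must be present for evaluation")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def pr_auc(scores, labels) -> float:
    """Step-interpolated area under the precision-recall curve.

    Constant score vectors yield the positive prevalence (the uninformative
    baseline of the PR curve).
    """
    scores, labels = _check_classes(pd.Series(scores, dtype=float), pd.Series(labels))
    return float(average_precision_score(labels.to_numpy(), scores.to_numpy()))


def separation_ttest(scores, labels, welch: bool = False) -> float:
    """Two-sided t-test p-value between responder and non-responder scores.

    Pooled-variance by default; Welch behind the flag.  Degenerate groups
    with zero pooled variance return p = 1 for identical means and the
    smallest positive float otherwise (a perfect separation).
    """
    scores, labels = _check_classes(pd.Series(scores, dtype=float), pd.Series(labels))
    a = scores[labels == 1].to_numpy()
    b = scores[labels == 0].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise DataError("separation t-test needs >=2 samples per class")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else sys.float_info.min
    with warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; the p-value is still the documented answer
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(p)


def assign_ranks(performances) -> pd.Series:
    """Rank pipelines: 1 = best (highest metric), ties get the average rank."""
    perf = pd.Series(performances, dtype=float)
    if perf.empty:
        raise DataError("cannot rank an empty performance vector")
    return perf.rank(method="average", ascending=False)


def performance_correlation(vectors: list[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of per-pipeline performance vectors.

    Vectors must share the pipeline universe.  A zero-variance vector has
    no defined correlation; its entries are NaN and flagged with a warning.
    """
    if isinstance(vectors, pd.DataFrame):
        frame = vectors
    else:
        if len(vectors) < 2:
            raise DataError("need at least two performance vectors")
        index = vectors[0].index
        for v in vectors[1:]:
            if not v.index.equals(index):
                raise DataError("performance vectors must share the pipeline universe")
        frame = pd.concat(vectors, axis=1)
        frame.columns = [
            getattr(v, "name", None) or f"v{i}" for i, v in enumerate(vectors)
        ]
    degenerate = frame.std(ddof=0) == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance performance vectors: {list(frame.columns[degenerate])}"
        )
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, np.where(degenerate, np.nan, 1.0))
    return corr
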