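"""Cell-response preprocessing: the five training-target transforms.

Three transforms keep the ln(IC50) target continuous (identity, offset log,
Box-Cox power transform) and two binarize it (median cutoff, exact 1-D
2-means).  Every transform records its orientation so downstream evaluation
knows which direction means "sensitive": continuous targets stay on the
ln(IC50) scale where *lower* is more sensitive; binary targets encode the
sensitive class as 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError

__all__ = [
    "TransformedResponse",
    "transform_none",
    "transform_logarithm",
    "transform_powertransform",
    "transform_binarize_cutoff",
    "transform_binarize_kmeans",
    "transform_response",
]


@dataclass
class TransformedResponse:
    values: pd.Series
    kind: str  # "continuous" | "binary"
    orientation: str  # "lower_is_sensitive" | "higher_is_sensitive"
    offset: float = 0.0
    boxcox_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "binary" and self.orientation != "higher_is_sensitive":
            raise DataError("binary responses must encode the sensitive class as 1")
        if self.kind == "continuous" and self.orientation != "lower_is_sensitive":
            raise DataError("continuous responses stay on the ln(IC50) scale")


def _as_series(y) -> pd.Series:
    y = pd.Series(y, dtype=float)
    if len(y) < 2:
        raise DataError("need at least two response values")
    if not np.isfinite(y.to_numpy()).all():
        raise DataError("response values must be finite")
    return y


def _log_offset(y: pd.Series) -> float:
    # Shift applied whenever min(y) <= 0 so the log argument is positive.
    # The published rule states the negative-value case only; we extend it
    # to an exact zero minimum, which would otherwise hit log(0).
    m = float(y.min())
    return -m + 1.0 if m <= 0 else 0.0


def transform_none(y) -> TransformedResponse:
    """Use the reported ln(IC50) values untouched."""
    y = _as_series(y)
    return TransformedResponse(y, kind="continuous", orientation="lower_is_sensitive")


def transform_logarithm(y) -> TransformedResponse:
    """Natural log of the response, shifted positive first if needed.

    When the minimum response is <= 0, an offset of (-min + 1) is added to
    every value before taking logs; the offset is recorded.
    """
    y = _as_series(y)
    offset = _log_offset(y)
    shifted = y + offset
    if (shifted <= 0).any():
        raise DataError("non-positive values after offset; cannot take log")
    return TransformedResponse(
        np.log(shifted), kind="continuous", orientation="lower_is_sensitive", offset=offset
    )


def transform_powertransform(y) -> TransformedResponse:
    """Box-Cox power transform with maximum-likelihood exponent.

    Same positivity offset rule as :func:`transform_logarithm`; the fitted
    exponent lambda is recorded.  lambda = 0 degenerates to the natural log.
    """
    y = _as_series(y)
    if y.nunique() < 3:
        raise DataError("power transform needs at least three distinct values")
    offset = _log_offset(y)
    shifted = (y + offset).to_numpy()
    if (shifted <= 0).any():
        raise DataError("non-positive values after offset; cannot power-transform")
    transformed, lam = stats.boxcox(shifted)
    return TransformedResponse(
        pd.Series(transformed, index=y.index),
        kind="continuous",
        orientation="lower_is_sensitive",
        offset=offset,
        boxcox_lambda=float(lam),
    )


def transform_binarize_cutoff(y) -> TransformedResponse:
    """Split at the median: values <= median are the sensitive class (1).

    Ties at the median go to the sensitive class, which keeps the rule
    deterministic.  A degenerate input where one class would be empty raises.
    """
    y = _as_series(y)
    med = float(y.median())
    classes = (y <= med).astype(int)
    if classes.nunique() < 2:
        raise DataError("median cutoff produced a single class")
    return TransformedResponse(classes, kind="binary", orientation="higher_is_sensitive")


def _best_two_means_split(sorted_vals: np.ndarray) -> int:
    """Index i of the optimal 1-D 2-means partition [:i] | [i:].

    Exhaustive scan over the n-1 contiguous splits of the sorted values;
    contiguity of optimal 1-D k-means clusters makes this the global
    optimum of the within-cluster sum of squares.
    """
    n = len(sorted_vals)
    csum = np.cumsum(sorted_vals)
    csq = np.cumsum(sorted_vals**2)
    best_i, best_ss = 1, np.inf
    for i in range(1, n):
        left_ss = csq[i - 1] - csum[i - 1] ** 2 / i
        right_n = n - i
        right_sum = csum[-1] - csum[i - 1]
        right_ss = (csq[-1] - csq[i - 1]) - right_sum**2 / right_n
        ss = left_ss + right_ss
        if ss < best_ss - 1e-12:
            best_ss, best_i = ss, i
    return best_i


def transform_binarize_kmeans(y, seed: int = 0) -> TransformedResponse:
    """Two-class 1-D k-means; the lower-center cluster is sensitive (1).

    The 1-D problem is solved exactly by scanning all contiguous splits of
    the sorted values, so the result is deterministic and ``seed`` is
    accepted only for interface uniformity.
    """
    y = _as_series(y)
    if y.nunique() < 2:
        raise DataError("k-means binarization needs two distinct values")
    order = np.argsort(y.to_numpy(), kind="stable")
    sorted_vals = y.to_numpy()[order]
    i = _best_two_means_split(sorted_vals)
    threshold = (sorted_vals[i - 1] + sorted_vals[i]) / 2.0
    classes = (y <= threshold).astype(int)
    if classes.nunique() < 2:  # pragma: no cover - split guarantees both sides
        raise DataError("k-means binarization produced a single class")
    return TransformedResponse(classes, kind="binary", orientation="higher_is_sensitive")


_TRANSFORMS = {
    "none": transform_none,
    "logarithm": transform_logarithm,
    "powertransform": transform_powertransform,
    "binarization_cutoff": transform_binarize_cutoff,
    "binarization_kmeans": transform_binarize_kmeans,
}


def transform_response(y, method: str, seed: int = 0) -> TransformedResponse:
    """Dispatch a response transform by its grid name."""
    if method not in _TRANSFORMS:
        raise DataError(f"unknown response transform {method!r}")
    if method == "binarization_kmeans":
        return transform_binarize_kmeans(y, seed=seed)
    return _TRANSFORMS[method](y)
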