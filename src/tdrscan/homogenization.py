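"""Train/test homogenization and batch-effect correction.

All seven methods map a (train, test) pair of genes-in-rows expression
matrices on a shared gene set to adjusted matrices of identical shape and
ordering.  The batch variable is always the binary train-vs-test contrast.

Methods
-------
none
    Identity; the no-correction baseline.
quantile
    Pooled quantile normalization: every sample (train and test together)
    is mapped onto the mean quantile distribution of the pooled collection,
    after which all sorted sample vectors coincide.
combat
    Two-batch parametric empirical-Bayes adjustment (location shrunk under
    a normal prior, scale under an inverse-gamma prior) in the style of
    Johnson et al.'s batch correction.
limma
    Per-gene linear batch model: subtract the fitted batch effect, i.e.
    center each batch to the pooled gene mean.  Exact post-condition: equal
    per-gene batch means.
ruv
    Remove unwanted variation via PCA on the housekeeping (negative
    control) genes of the pooled data; the expression of every gene is
    regressed on the first k component scores and replaced by the residual
    (gene mean restored).
ruv4
    SVD variant: unwanted factors from the singular vectors of the centered
    control submatrix, loadings for all genes by regression, corrected data
    = data - W alpha.
yugene
    Per-sample cumulative-proportion transform onto [0, 1); scale invariant
    within a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DataError

__all__ = [
    "HomogenizationSpec",
    "homogenize_none",
    "homogenize_quantile",
    "homogenize_combat",
    "homogenize_limma",
    "homogenize_ruv_custom",
    "homogenize_ruv4",
    "homogenize_yugene",
    "homogenize",
]


@dataclass
class HomogenizationSpec:
    method: str = "none"
    n_unwanted_factors: int = 10
    control_genes: frozenset = frozenset()
    yugene_shift: bool = False  # auto-shift negative input for yugene

    def __post_init__(self) -> None:
        if self.n_unwanted_factors < 1:
            raise DataError("n_unwanted_factors must be >= 1")


def _check_genes(train: pd.DataFrame, test: pd.DataFrame) -> None:
    if list(train.index) != list(test.index):
        raise DataError("train and test must share the same gene set and order")


def homogenize_none(train: pd.DataFrame, test: pd.DataFrame):
    return train, test


def homogenize_quantile(train: pd.DataFrame, test: pd.DataFrame):
    """Quantile-normalize the pooled samples to their mean quantile curve."""
    _check_genes(train, test)
    pooled = pd.concat([train, test], axis=1)
    arr = pooled.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)  # mean value at each rank
    g = arr.shape[0]
    out = np.empty_like(arr)
    positions = np.arange(1, g + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, positions, ref)
    normalized = pd.DataFrame(out, index=pooled.index, columns=pooled.columns)
    return normalized[train.columns], normalized[test.columns]


def homogenize_limma(train: pd.DataFrame, test: pd.DataFrame):
    """Remove the fitted per-gene batch effect; restore the pooled mean."""
    _check_genes(train, test)
    grand = pd.concat([train, test], axis=1).mean(axis=1)
    train_adj = train.sub(train.mean(axis=1), axis=0).add(grand, axis=0)
    test_adj = test.sub(test.mean(axis=1), axis=0).add(grand, axis=0)
    return train_adj, test_adj


def _combat_it_sol(sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                   g_bar: float, t2: float, a_prior: float, b_prior: float,
                   conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB solution for batch location/scale (parametric priors)."""
    n = (~np.isnan(sdat)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_location_estimates(train: pd.DataFrame, test: pd.DataFrame) -> pd.DataFrame:
    """Raw vs EB-shrunk batch location estimates (standardized scale).

    Diagnostic companion to :func:`homogenize_combat`: for each batch, the
    per-gene raw location ``g_hat``, the shrunk location ``g_star`` and the
    batch-level prior mean ``g_bar``.  Shrinkage moves ``g_hat`` toward
    ``g_bar`` (a convex combination), which is the property tests assert.
    """
    frames = []
    for batch, (g_hat, g_star, g_bar) in _combat_core(train, test, diagnostics=True):
        frames.append(
            pd.DataFrame(
                {"batch": batch, "g_hat": g_hat, "g_star": g_star, "g_bar": g_bar},
                index=train.index,
            )
        )
    return pd.concat(frames)


def _combat_core(train: pd.DataFrame, test: pd.DataFrame, diagnostics: bool = False):
    _check_genes(train, test)
    for name, df in (("train", train), ("test", test)):
        if df.shape[1] < 2:
            raise DataError(f"combat needs >=2 samples per batch; {name} has {df.shape[1]}")
    batches = [train.to_numpy(dtype=float), test.to_numpy(dtype=float)]
    n_b = [b.shape[1] for b in batches]
    n_total = sum(n_b)
    data = np.concatenate(batches, axis=1)

    # Per-gene batch-design fit: grand mean weighted by batch sizes,
    # pooled residual variance after removing batch means.
    batch_means = np.stack([b.mean(axis=1) for b in batches], axis=1)  # G x 2
    weights = np.array(n_b, dtype=float) / n_total
    grand_mean = batch_means @ weights
    resid = np.concatenate(
        [b - batch_means[:, i][:, None] for i, b in enumerate(batches)], axis=1
    )
    var_pooled = (resid**2).sum(axis=1) / n_total
    degenerate = var_pooled <= 0
    if degenerate.any() and not diagnostics:
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes passed through uncorrected"
        )
    safe_sd = np.sqrt(np.where(degenerate, 1.0, var_pooled))

    stand = (data - grand_mean[:, None]) / safe_sd[:, None]
    adjusted = stand.copy()
    diag = []
    offset = 0
    for i, nb in enumerate(n_b):
        block = stand[:, offset:offset + nb]
        g_hat = block.mean(axis=1)
        d_hat = block.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        # Method-of-moments inverse-gamma hyperpriors on the scale.
        m, v = float(d_hat.mean()), float(d_hat.var(ddof=1))
        a_prior = (2 * v + m**2) / v if v > 0 else 2.0
        b_prior = (m * v + m**3) / v if v > 0 else m
        g_star, d_star = _combat_it_sol(block, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        diag.append(("train" if i == 0 else "test", (g_hat, g_star, g_bar)))
        adjusted[:, offset:offset + nb] = (block - g_star[:, None]) / np.sqrt(
            d_star[:, None]
        )
        offset += nb
    if diagnostics:
        return diag
    result = adjusted * safe_sd[:, None] + grand_mean[:, None]
    result[degenerate, :] = data[degenerate, :]
    train_adj = pd.DataFrame(result[:, : n_b[0]], index=train.index, columns=train.columns)
    test_adj = pd.DataFrame(result[:, n_b[0]:], index=test.index, columns=test.columns)
    return train_adj, test_adj


def homogenize_combat(train: pd.DataFrame, test: pd.DataFrame):
    """Two-batch parametric empirical-Bayes batch adjustment.

    Genes with zero pooled variance cannot be standardized; they pass
    through uncorrected with a warning.
    """
    return _combat_core(train, test, diagnostics=False)


def _control_scores(pooled: pd.DataFrame, spec: HomogenizationSpec) -> np.ndarray:
    """First-k unwanted-variation scores from the control-gene submatrix.

    Samples are the observations; the control submatrix is column-centered
    (per gene) and its left singular vectors over samples give the scores.
    """
    controls = [g for g in pooled.index if g in spec.control_genes]
    if len(controls) < 2:
        raise DataError("need at least two control genes present in the shared gene set")
    k = spec.n_unwanted_factors
    n_samples = pooled.shape[1]
    if k >= n_samples:
        raise DataError(
            f"n_unwanted_factors={k} must be < number of pooled samples ({n_samples})"
        )
    sub = pooled.loc[controls].to_numpy(dtype=float).T  # samples x controls
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :k] * s[:k]  # sample scores on the first k factors


def _regress_out(pooled: pd.DataFrame, w: np.ndarray) -> pd.DataFrame:
    """Residualize every gene on the factor scores W, restoring gene means."""
    x = pooled.to_numpy(dtype=float)
    means = x.mean(axis=1, keepdims=True)
    centered = (x - means).T  # samples x genes
    wc = w - w.mean(axis=0, keepdims=True)
    coef, *_ = np.linalg.lstsq(wc, centered, rcond=None)
    resid = centered - wc @ coef
    return pd.DataFrame(resid.T + means, index=pooled.index, columns=pooled.columns)


def homogenize_ruv_custom(train: pd.DataFrame, test: pd.DataFrame, spec: HomogenizationSpec):
    """PCA-on-controls homogenization.

    Principal component scores of the pooled housekeeping-gene submatrix
    (first k=10 by default) estimate the unwanted variation; the residual of
    every gene after linear regression on those scores is the homogenized
    expression.  Residuals are orthogonal to each factor.
    """
    _check_genes(train, test)
    pooled = pd.concat([train, test], axis=1)
    w = _control_scores(pooled, spec)
    cleaned = _regress_out(pooled, w)
    return cleaned[train.columns], cleaned[test.columns]


def homogenize_ruv4(train: pd.DataFrame, test: pd.DataFrame, spec: HomogenizationSpec):
    """SVD-on-negative-controls homogenization (simplified RUV-4).

    Factor scores W come from the SVD of the centered control submatrix;
    loadings alpha for all genes are estimated by least squares and the
    corrected data is data - W alpha (gene means restored).
    """
    _check_genes(train, test)
    pooled = pd.concat([train, test], axis=1)
    w = _control_scores(pooled, spec)
    cleaned = _regress_out(pooled, w)
    return cleaned[train.columns], cleaned[test.columns]


def _yugene_one(sample: np.ndarray) -> np.ndarray:
    order = np.argsort(-sample, kind="stable")  # descending, ties by gene index
    total = sample.sum()
    cum = np.cumsum(sample[order])
    transformed = 1.0 - cum / total
    out = np.empty_like(sample, dtype=float)
    out[order] = transformed
    return out


def homogenize_yugene(train: pd.DataFrame, test: pd.DataFrame, shift_negative: bool = False):
    """Cumulative-proportion transform applied to each sample independently.

    With values sorted descending, the transformed value at rank r is
    1 - cumsum(r)/total, landing in [0, 1) and preserving the within-sample
    ordering.  Requires non-negative input with a positive per-sample sum;
    ``shift_negative`` subtracts the pooled minimum first instead of
    raising.  Descending ties are broken by gene index.
    """
    _check_genes(train, test)
    if shift_negative:
        pooled_min = min(float(train.min().min()), float(test.min().min()))
        if pooled_min < 0:
            train = train - pooled_min
            test = test - pooled_min
    out = []
    for df in (train, test):
        arr = df.to_numpy(dtype=float)
        if (arr < 0).any():
            raise DataError(
                "yugene requires non-negative expression; shift the data first"
            )
        sums = arr.sum(axis=0)
        if (sums <= 0).any():
            raise DataError("yugene: sample with zero total expression")
        cols = [_yugene_one(arr[:, j]) for j in range(arr.shape[1])]
        out.append(pd.DataFrame(np.column_stack(cols), index=df.index, columns=df.columns))
    return out[0], out[1]


def homogenize(train: pd.DataFrame, test: pd.DataFrame, spec: HomogenizationSpec):
    """Dispatch a homogenization method by its grid name."""
    method = spec.method
    if method == "none":
        return homogenize_none(train, test)
    if method == "quantile":
        return homogenize_quantile(train, test)
    if method == "combat":
        return homogenize_combat(train, test)
    if method == "limma":
        return homogenize_limma(train, test)
    if method == "ruv":
        return homogenize_ruv_custom(train, test, spec)
    if method == "ruv4":
        return homogenize_ruv4(train, test, spec)
    if method == "yugene":
        return homogenize_yugene(train, test, shift_negative=spec.yugene_shift)
    raise DataError(f"unknown homogenization method {method!r}")
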