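"""Feature selection and feature preprocessing.

Filters pick the gene subset using training data only (plus fixed gene
lists); preprocessors are fitted on training samples and applied unchanged
to the test side, except for the sample-wise z-score which is by definition
self-referential within each sample.

Filters: ``all`` (identity), ``landmarkgenes`` (intersect with a landmark
list), ``variance`` (drop the 20% least variant training genes), ``pvalue``
(drop the 20% of genes with the highest t-test p-values between the most
sensitive and most resistant training samples).

Preprocessors: ``none``, ``zscore_samplewise``, ``zscore_genewise``
(training statistics applied to both sides), ``pca`` (training-fitted
centering and rotation, first 10 components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core_data import DataError
from .response_transform import TransformedResponse

__all__ = ["FeatureSpec", "FittedPreprocessor", "filter_features", "preprocess_features"]


@dataclass
class FeatureSpec:
    filter: str = "all"
    preprocess: str = "none"
    drop_fraction: float = 0.20
    n_components: int = 10
    extreme_fraction: float = 0.25
    landmark_list: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise DataError("drop_fraction must be in (0, 1)")
        if self.n_components < 1:
            raise DataError("n_components must be >= 1")
        if not 0 < self.extreme_fraction <= 0.5:
            raise DataError("extreme_fraction must be in (0, 0.5]")


def _extreme_groups(response: TransformedResponse, frac: float):
    """Sample ids of the most sensitive / most resistant training groups.

    Binary targets use the two classes directly; continuous targets (on the
    ln(IC50) scale, lower = sensitive) take the bottom/top ``frac`` tails.
    """
    y = response.values
    if response.kind == "binary":
        sensitive = y.index[y == 1]
        resistant = y.index[y == 0]
    else:
        n = max(2, int(np.floor(frac * len(y))))
        order = y.sort_values(kind="stable")
        sensitive = order.index[:n]
        resistant = order.index[-n:]
    if len(sensitive) < 2 or len(resistant) < 2:
        raise DataError("p-value filter needs >=2 samples per extreme group")
    return list(sensitive), list(resistant)


def filter_features(
    train: pd.DataFrame,
    response: Optional[TransformedResponse],
    spec: FeatureSpec,
) -> list[str]:
    """Select the modeling gene set from the training matrix.

    Depends only on training data and fixed lists, never on the test side.
    Ties in the variance / p-value rankings are broken by stable gene order.
    """
    genes = list(train.index)
    if spec.filter == "all":
        selected = genes
    elif spec.filter == "landmarkgenes":
        selected = [g for g in genes if g in spec.landmark_list]
        if not selected:
            raise DataError("landmark filter: no landmark genes in the shared gene set")
    elif spec.filter == "variance":
        variances = train.var(axis=1, ddof=1).to_numpy()
        n_drop = int(np.floor(spec.drop_fraction * len(genes)))
        order = np.argsort(variances, kind="stable")  # ascending, stable ties
        dropped = set(order[:n_drop])
        selected = [g for i, g in enumerate(genes) if i not in dropped]
    elif spec.filter == "pvalue":
        if response is None:
            raise DataError("p-value filter requires the transformed response")
        sensitive, resistant = _extreme_groups(response, spec.extreme_fraction)
        a = train[sensitive].to_numpy(dtype=float)
        b = train[resistant].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvals = stats.ttest_ind(a, b, axis=1)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance genes: uninformative
        n_drop = int(np.floor(spec.drop_fraction * len(genes)))
        order = np.argsort(-pvals, kind="stable")  # descending p, stable ties
        dropped = set(order[:n_drop])
        selected = [g for i, g in enumerate(genes) if i not in dropped]
    else:
        raise DataError(f"unknown feature filter {spec.filter!r}")
    if not selected:
        raise DataError("feature filter removed every gene")
    return selected


@dataclass
class FittedPreprocessor:
    """Serializable fitted state of a feature preprocessor."""

    kind: str
    feature_ids: list[str]
    center: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None
    rotation: Optional[np.ndarray] = None  # components x genes

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind, "feature_ids": list(self.feature_ids)}
        for name in ("center", "scale", "rotation"):
            val = getattr(self, name)
            if val is not None:
                out[name] = np.asarray(val).tolist()
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedPreprocessor":
        return cls(
            kind=payload["kind"],
            feature_ids=list(payload["feature_ids"]),
            center=np.asarray(payload["center"]) if "center" in payload else None,
            scale=np.asarray(payload["scale"]) if "scale" in payload else None,
            rotation=np.asarray(payload["rotation"]) if "rotation" in payload else None,
        )

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Apply to a genes x samples matrix; returns samples x features."""
        if list(matrix.index) != self.feature_ids:
            sub = matrix.loc[self.feature_ids]
        else:
            sub = matrix
        x = sub.to_numpy(dtype=float).T  # samples x genes
        if self.kind in ("none",):
            out = x
            cols = self.feature_ids
        elif self.kind == "zscore_samplewise":
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, ddof=0, keepdims=True)
            if (sd == 0).any():
                raise DataError("sample with zero expression variance")
            out = (x - mu) / sd
            cols = self.feature_ids
        elif self.kind == "zscore_genewise":
            out = (x - self.center) / self.scale
            cols = self.feature_ids
        elif self.kind == "pca":
            out = (x - self.center) @ self.rotation.T
            cols = [f"PC{i + 1}" for i in range(self.rotation.shape[0])]
        else:
            raise DataError(f"unknown preprocessor {self.kind!r}")
        return pd.DataFrame(out, index=sub.columns, columns=cols)


def preprocess_features(
    train: pd.DataFrame, test: pd.DataFrame, spec: FeatureSpec
) -> tuple[pd.DataFrame, pd.DataFrame, FittedPreprocessor]:
    """Fit the preprocessor on training data and apply it to both sides.

    Returns samples x features matrices for train and test plus the fitted,
    JSON-serializable transform.  Gene-wise z-scoring drops zero-variance
    training genes with a warning; PCA reduces the component count with a
    warning when the training rank cannot support 10 components.
    """
    if list(train.index) != list(test.index):
        raise DataError("train and test must share the filtered gene set")
    genes = list(train.index)
    kind = spec.preprocess
    if kind == "none" or kind == "zscore_samplewise":
        fitted = FittedPreprocessor(kind=kind, feature_ids=genes)
    elif kind == "zscore_genewise":
        mu = train.mean(axis=1).to_numpy()
        sd = train.std(axis=1, ddof=0).to_numpy()
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance genes for gene-wise z-score"
            )
            genes = [g for g, k in zip(genes, keep) if k]
            if not genes:
                raise DataError("no genes left after dropping zero-variance genes")
            mu, sd = mu[keep], sd[keep]
        fitted = FittedPreprocessor(
            kind=kind, feature_ids=genes, center=mu, scale=sd
        )
    elif kind == "pca":
        n_train = train.shape[1]
        n_comp = min(spec.n_components, n_train - 1, len(genes))
        if n_comp < spec.n_components:
            warnings.warn(
                f"reducing PCA components from {spec.n_components} to {n_comp}"
            )
        if n_comp < 1:
            raise DataError("cannot fit PCA with fewer than 2 training samples")
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(train.to_numpy(dtype=float).T)
        fitted = FittedPreprocessor(
            kind=kind,
            feature_ids=genes,
            center=pca.mean_,
            rotation=pca.components_,
        )
    else:
        raise DataError(f"unknown feature preprocess {kind!r}")
    train_x = fitted.apply(train)
    test_x = fitted.apply(test)
    return train_x, test_x, fitted
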