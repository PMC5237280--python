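"""Multi-class Fisher linear discriminant analysis with a 2D latent space.

The projection solves the generalized eigenproblem S_b v = lambda S_w v
(between- vs pooled within-class scatter) on the selected feature
columns and keeps the top C-1 = 2 eigenvectors.  New spectra are
projected into the latent plane and assigned the class of the nearest
centroid (Euclidean by default, Mahalanobis behind a flag); exact
distance ties go to the first class in declared order.  When the
within-class scatter is ill-conditioned a small ridge proportional to
its mean diagonal is added and recorded on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .core import Cohort, FeatureSet, SpectrumRecord, ValidationError

__all__ = ["FisherModel", "fit_fisher_lda", "fit_fisher_lda_matrix", "classify", "predict", "confusion"]

_RIDGE_EPS = 1e-6
_COND_LIMIT = 1e10


@dataclass
class FisherModel:
    features: Optional[FeatureSet]
    class_names: list
    class_means: np.ndarray  # (C, k) per-class means in feature space
    within_scatter: np.ndarray  # (k, k)
    between_scatter: np.ndarray  # (k, k)
    projection: np.ndarray  # (k, d) generalized eigenvectors, decreasing eigenvalue
    eigenvalues: np.ndarray  # (d,)
    centroids: np.ndarray  # (C, d) class centroids in latent space
    ridge: float = 0.0
    latent_cov_inv: np.ndarray = field(default=None, repr=False)

    @property
    def latent_dim(self) -> int:
        return self.projection.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.projection


def fit_fisher_lda_matrix(
    X: np.ndarray, y: np.ndarray, class_names, n_components: Optional[int] = None
) -> FisherModel:
    """Fit Fisher LDA on an (n_cases x k_features) matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_names = list(class_names)
    n, k = X.shape
    C = len(class_names)
    d = n_components if n_components is not None else min(C - 1, k)

    means, Sw = [], np.zeros((k, k))
    grand = X.mean(axis=0)
    Sb = np.zeros((k, k))
    for c in class_names:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 cases")
        mc = Xc.mean(axis=0)
        means.append(mc)
        D = Xc - mc
        Sw += D.T @ D
        dm = (mc - grand)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    means = np.vstack(means)

    ridge = 0.0
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        ridge = _RIDGE_EPS * np.trace(Sw) / k
        if ridge <= 0:
            ridge = _RIDGE_EPS
    Sw_reg = Sw + ridge * np.eye(k)

    evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1][:d]
    W = evecs[:, order]
    # deterministic sign: largest-magnitude loading of each column positive
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]

    centroids = means @ W
    # pooled within-class covariance in latent space (for the Mahalanobis rule)
    Zw = W.T @ (Sw_reg / max(n - C, 1)) @ W
    latent_cov_inv = np.linalg.pinv(Zw)
    return FisherModel(
        features=None,
        class_names=class_names,
        class_means=means,
        within_scatter=Sw,
        between_scatter=Sb,
        projection=W,
        eigenvalues=evals[order],
        centroids=centroids,
        ridge=ridge,
        latent_cov_inv=latent_cov_inv,
    )


def fit_fisher_lda(train: Cohort, features: FeatureSet) -> FisherModel:
    """Fit the 3-class Fisher LDA on a normalized training cohort."""
    for r in train.records:
        if not r.normalized:
            raise ValidationError(f"{r.spectrum_id}: training spectra must be normalized")
    X, y = train.matrix()
    model = fit_fisher_lda_matrix(X[:, features.indices], y, train.class_labels)
    model.features = features
    return model


def _latent_distances(model: FisherModel, Z: np.ndarray, metric: str) -> np.ndarray:
    diff = Z[:, None, :] - model.centroids[None, :, :]  # (n, C, d)
    if metric == "euclidean":
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "mahalanobis":
        return np.sqrt(np.einsum("ncd,de,nce->nc", diff, model.latent_cov_inv, diff))
    raise ValueError(f"unknown metric {metric!r}")


def predict(model: FisherModel, X: np.ndarray, metric: str = "euclidean"):
    """Classify feature-space rows; returns (labels, latent coordinates).

    Ties on exact centroid distance resolve to the first class in
    `model.class_names` order (argmin keeps the first minimum).
    """
    Z = model.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    D = _latent_distances(model, Z, metric)
    idx = np.argmin(D, axis=1)
    labels = [model.class_names[i] for i in idx]
    return labels, Z


def classify(
    model: FisherModel, spectrum: SpectrumRecord, metric: str = "euclidean"
) -> tuple[str, np.ndarray]:
    """Classify one normalized spectrum; returns (class name, latent coords)."""
    if not spectrum.normalized:
        raise ValidationError(f"{spectrum.spectrum_id}: spectrum must be normalized")
    if model.features is None:
        raise ValidationError("model carries no FeatureSet; classify from matrices instead")
    x = spectrum.intensities[model.features.indices]
    labels, Z = predict(model, x[None, :], metric=metric)
    return labels[0], Z[0]


def confusion(model: FisherModel, cohort: Cohort, metric: str = "euclidean"):
    """3x3 confusion matrix of the model on a normalized cohort."""
    from .evaluate import ConfusionMatrix3  # local import avoids a cycle

    X, y = cohort.matrix()
    if model.features is None:
        raise ValidationError("model carries no FeatureSet")
    labels, _ = predict(model, X[:, model.features.indices], metric=metric)
    return ConfusionMatrix3.from_predictions(y, labels, model.class_names)
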