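"""Extension of the behavioural embedding to arbitrary images.

The behavioural embedding assigns 66 dimension values to the images it was
trained on; to score new exemplars, each dimension is regressed onto a
feature representation of the images (here, any image-level feature
matrix) with ridge regression, the penalty chosen per dimension by
cross-validation. Predictions are *not* rectified at zero: rectification
belongs to the downstream tuning-profile and sparseness analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from ._utils import check_count, held_out_r2, spawn_rng
from .synth import DimensionEmbedding

__all__ = ["DimensionPredictor", "fit_dimension_predictor", "predict_dimensions",
           "DEFAULT_PENALTIES"]

DEFAULT_PENALTIES = np.logspace(-3, 3, 9)


@dataclass(frozen=True)
class DimensionPredictor:
    """Per-dimension ridge maps from image features to dimension values.

    Coefficients act on standardized features (training mean/scale stored);
    ``cv_score`` is the held-out explained variance of the *chosen* penalty,
    never the best in-sample score.
    """

    coefficients: np.ndarray  # features x dims, standardized feature space
    intercepts: np.ndarray
    chosen_penalty: np.ndarray
    cv_score: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    dim_labels: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[0]


def _standardize(F, mean=None, scale=None):
    if mean is None:
        mean = F.mean(axis=0)
        scale = F.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    return (F - mean) / scale, mean, scale


def fit_dimension_predictor(
    features: np.ndarray,
    dims: DimensionEmbedding | np.ndarray,
    penalties: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> DimensionPredictor:
    """Fit ridge maps from features to each dimension independently.

    For every dimension the penalty maximizing the mean cross-validated
    explained variance (held-out R^2) is selected from the grid, ties broken
    toward the larger penalty; the final model is refitted on all images at
    the chosen penalty. Features are standardized with training statistics
    inside each fold and on the full data for the final fit.
    """
    F = np.asarray(features, dtype=float)
    if isinstance(dims, DimensionEmbedding):
        D = dims.values
        labels = dims.dim_labels
    else:
        D = np.asarray(dims, dtype=float)
        labels = tuple(f"dim_{d:02d}" for d in range(D.shape[1]))
    if F.shape[0] != D.shape[0]:
        raise ValueError("features and dimension table must have equal image counts")
    check_count("n_folds", n_folds, 2)
    penalties = DEFAULT_PENALTIES if penalties is None else np.sort(np.asarray(penalties, float))
    if np.any(penalties <= 0):
        raise ValueError("penalties must be positive")
    if np.linalg.matrix_rank(F) == 0:
        raise ValueError("feature matrix has rank 0")

    n_dims = D.shape[1]
    scores = np.zeros((len(penalties), n_dims))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    for train, test in kf.split(F):
        Ftr, mean, scale = _standardize(F[train])
        Fte = (F[test] - mean) / scale
        for i, alpha in enumerate(penalties):
            model = Ridge(alpha=alpha).fit(Ftr, D[train])
            scores[i] += held_out_r2(model.predict(Fte), D[test])
    scores /= n_folds
    # ties toward the larger penalty: last index achieving the maximum
    best = np.array([
        np.flatnonzero(scores[:, d] == scores[:, d].max()).max() for d in range(n_dims)
    ])
    chosen = penalties[best]
    Fz, mean, scale = _standardize(F)
    final = Ridge(alpha=chosen).fit(Fz, D)
    return DimensionPredictor(
        coefficients=final.coef_.T,
        intercepts=final.intercept_,
        chosen_penalty=chosen,
        cv_score=scores[best, np.arange(n_dims)],
        feature_mean=mean,
        feature_scale=scale,
        dim_labels=labels,
    )


def predict_dimensions(predictor: DimensionPredictor, features: np.ndarray) -> np.ndarray:
    """Predicted dimension values (images x dims); may be negative."""
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[1] != predictor.n_features:
        raise ValueError(
            f"expected {predictor.n_features} features, got shape {F.shape}"
        )
    Fz = (F - predictor.feature_mean) / predictor.feature_scale
    return Fz @ predictor.coefficients + predictor.intercepts
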