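"""Variance partitioning: dimensions versus categories.

Compares a dimension-based and a category-based encoding model of the same
responses. For each category the most diagnostic dimension is the one with
the highest ROC AUC for category membership; the distinct selected
dimensions form the (deliberately smaller) dimension model. Unique
variance of one model is the cross-validated R^2 after orthogonalizing
both that model and the data with respect to the other; shared variance is
the combined model's R^2 minus both unique terms, exactly by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._utils import held_out_r2

__all__ = [
    "dimension_auc",
    "select_diagnostic_dimensions",
    "orthogonalize",
    "cv_r2",
    "partition_variance",
    "DiagnosticMapping",
    "VariancePartition",
]


def dimension_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both positive and negative labels")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class DiagnosticMapping:
    """Per-category most diagnostic dimension and the distinct set."""

    best_dimension: np.ndarray
    auc: np.ndarray
    unique_dimensions: np.ndarray


def select_diagnostic_dimensions(embedding, categories) -> DiagnosticMapping:
    """Argmax-AUC dimension per category (ties toward the lower index).

    ``embedding`` may be a DimensionEmbedding or a raw (images x dims)
    array; ``categories`` a CategoryLabels or binary (images x categories)
    matrix. Several categories may map to one dimension; the distinct
    selected dimensions form ``unique_dimensions``.
    """
    values = getattr(embedding, "values", embedding)
    membership = np.asarray(getattr(categories, "membership", categories))
    n_img, n_dims = values.shape
    if membership.shape[0] != n_img:
        raise ValueError("image counts of embedding and labels differ")
    ranks = np.apply_along_axis(rankdata, 0, values)  # midranks per dimension
    best = np.empty(membership.shape[1], dtype=int)
    aucs = np.empty(membership.shape[1])
    for c in range(membership.shape[1]):
        y = membership[:, c].astype(bool)
        n1 = int(y.sum())
        n0 = n_img - n1
        if n1 == 0 or n0 == 0:
            raise ValueError(f"category {c} has a single class")
        auc_c = (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)
        best[c] = int(np.argmax(auc_c))  # first maximum = lowest index
        aucs[c] = auc_c[best[c]]
    return DiagnosticMapping(best, aucs, np.unique(best))


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), np.asarray(X, dtype=float)])


def orthogonalize(
    target_X: np.ndarray, other_X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize ``target_X`` and ``Y`` against ``other_X`` (+ intercept).

    Removes the other model's span — hence any variance shared with it —
    from both the target model and the data.
    """
    other1 = _with_intercept(other_X)
    rank = np.linalg.matrix_rank(other1)
    if rank < other1.shape[1]:
        from .trial import _collinear_columns

        names = ["intercept"] + [f"col_{j}" for j in range(other_X.shape[1])]
        raise np.linalg.LinAlgError(
            "other model is rank deficient; collinear columns: "
            f"{_collinear_columns(other1, names)}"
        )
    Q, _ = np.linalg.qr(other1)
    target_X = np.asarray(target_X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    res_t = target_X - Q @ (Q.T @ target_X)
    res_y = Y - Q @ (Q.T @ Y)
    return res_t, res_y


def _fold_indices(session_folds: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(session_folds)
    return [np.flatnonzero(labels == s) for s in np.unique(labels)]


def cv_r2(X: np.ndarray, Y: np.ndarray, session_folds: np.ndarray) -> np.ndarray:
    """Between-session cross-validated R^2 per voxel (may be negative).

    Folds are defined by the ``session_folds`` label of each trial; OLS
    (pseudoinverse, so duplicated predictors are harmless) is fitted with
    an intercept on the training folds and scored on the held-out fold
    against the held-out mean; fold R^2 values are averaged.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    folds = _fold_indices(session_folds)
    if len(folds) < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    r2s = []
    for f, test in enumerate(folds):
        train = np.concatenate([g for j, g in enumerate(folds) if j != f])
        X1 = _with_intercept(X[train])
        if X1.shape[0] < X1.shape[1]:
            raise ValueError(
                f"fold {f}: {X1.shape[0]} training trials for {X1.shape[1]} predictors"
            )
        beta, *_ = np.linalg.lstsq(X1, Y[train], rcond=None)
        pred = _with_intercept(X[test]) @ beta
        r2s.append(held_out_r2(pred, Y[test]))
    return np.mean(r2s, axis=0)


def _cv_r2_foldwise_orth(target_X, other_X, Y, folds):
    """Leakage-safe unique variance: the orthogonalizing projection is
    estimated on the training folds only and applied to the test fold."""
    r2s = []
    for f, test in enumerate(folds):
        train = np.concatenate([g for j, g in enumerate(folds) if j != f])
        other1 = _with_intercept(other_X[train])
        gamma_t, *_ = np.linalg.lstsq(other1, target_X[train], rcond=None)
        gamma_y, *_ = np.linalg.lstsq(other1, Y[train], rcond=None)
        rt_train = target_X[train] - other1 @ gamma_t
        ry_train = Y[train] - other1 @ gamma_y
        X1 = _with_intercept(rt_train)
        beta, *_ = np.linalg.lstsq(X1, ry_train, rcond=None)
        other1_te = _with_intercept(other_X[test])
        rt_test = target_X[test] - other1_te @ gamma_t
        ry_test = Y[test] - other1_te @ gamma_y
        pred = _with_intercept(rt_test) @ beta
        r2s.append(held_out_r2(pred, ry_test))
    return np.mean(r2s, axis=0)


@dataclass(frozen=True)
class VariancePartition:
    """Cross-validated unique/shared/combined R^2 per voxel."""

    unique_dim: np.ndarray
    unique_cat: np.ndarray
    combined: np.ndarray
    shared: np.ndarray
    unique_dim_nc: np.ndarray | None = None
    unique_cat_nc: np.ndarray | None = None
    combined_nc: np.ndarray | None = None
    shared_nc: np.ndarray | None = None


def partition_variance(
    dim_X: np.ndarray,
    cat_X: np.ndarray,
    Y: np.ndarray,
    session_folds: np.ndarray,
    nc: np.ndarray | None = None,
    nc_floor: float = 0.02,
    *,
    foldwise_orthogonalization: bool = False,
) -> VariancePartition:
    """Partition cross-validated explained variance between two models.

    ``unique_dim`` (``unique_cat``) is the CV R^2 of the dimension
    (category) model after both it and the data are orthogonalized against
    the other model; ``combined`` is the CV R^2 of the concatenated model;
    ``shared = combined - unique_dim - unique_cat`` holds exactly.
    Orthogonalization uses the full data by default (the literal
    procedure); ``foldwise_orthogonalization=True`` re-estimates the
    projection within each training fold. Negative values are reported as
    computed. When ``nc`` is given, noise-ceiling-normalized copies are
    attached wherever nc >= ``nc_floor``.
    """
    dim_X = np.asarray(dim_X, dtype=float)
    cat_X = np.asarray(cat_X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    if not (dim_X.shape[0] == cat_X.shape[0] == Y.shape[0]):
        raise ValueError("dim_X, cat_X and Y must have matching rows")
    folds = _fold_indices(session_folds)
    if foldwise_orthogonalization:
        unique_dim = _cv_r2_foldwise_orth(dim_X, cat_X, Y, folds)
        unique_cat = _cv_r2_foldwise_orth(cat_X, dim_X, Y, folds)
    else:
        rd, ryd = orthogonalize(dim_X, cat_X, Y)
        unique_dim = cv_r2(rd, ryd, session_folds)
        rc, ryc = orthogonalize(cat_X, dim_X, Y)
        unique_cat = cv_r2(rc, ryc, session_folds)
    combined = cv_r2(np.column_stack([dim_X, cat_X]), Y, session_folds)
    shared = combined - unique_dim - unique_cat
    kwargs = {}
    if nc is not None:
        from .trial import nc_correct

        kwargs = {
            "unique_dim_nc": nc_correct(unique_dim, nc, nc_floor),
            "unique_cat_nc": nc_correct(unique_cat, nc, nc_floor),
            "combined_nc": nc_correct(combined, nc, nc_floor),
            "shared_nc": nc_correct(shared, nc, nc_floor),
        }
    return VariancePartition(unique_dim, unique_cat, combined, shared, **kwargs)
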