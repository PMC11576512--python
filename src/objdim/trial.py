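"""Single-trial encoding of object dimensions.

Ordinary least squares maps the 66 dimension values of each presented
image to the trial's response amplitude in every voxel. Prediction
performance is assessed by leave-one-session-out cross-validation
(fold-mean Pearson correlation and R^2), significance by a permutation
null of the held-out data with FDR correction, and explainable variance by
a noise ceiling estimated from images presented repeatedly in every
session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._utils import columnwise_pearson, held_out_r2, spawn_rng
from .synth import DimensionEmbedding, VoxelResponses

__all__ = [
    "fit_ols",
    "loso_cv_predict",
    "permutation_pvalues",
    "bh_fdr",
    "estimate_noise_ceiling",
    "nc_correct",
    "repeat_response_array",
    "CVPredictions",
    "NoiseCeiling",
]


def _collinear_columns(X1: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns implicated in a rank deficiency (QR with pivoting)."""
    from scipy.linalg import qr

    _, R, piv = qr(X1, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X1.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag <= tol)]
    bad = np.concatenate([bad, piv[len(diag):]]) if len(diag) < X1.shape[1] else bad
    return [names[int(j)] for j in sorted(bad)]


def fit_ols(
    X: np.ndarray,
    Y: np.ndarray,
    *,
    column_names: list[str] | None = None,
    return_intercept: bool = False,
):
    """Least-squares encoding weights (voxels x dims), intercept included
    in the fit but excluded from the returned weight matrix.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} trials to fit {p} dims + intercept")
    X1 = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X1) < p + 1:
        names = ["intercept"] + (
            column_names if column_names is not None else [f"col_{j}" for j in range(p)]
        )
        bad = _collinear_columns(X1, names)
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    weights = beta[1:].T
    if return_intercept:
        return weights, beta[0]
    return weights


@dataclass(frozen=True)
class CVPredictions:
    """Leave-one-session-out predictions and per-voxel summaries."""

    cv_correlation: np.ndarray
    cv_r2: np.ndarray
    fold_sessions: tuple[int, ...]
    fold_predicted: tuple[np.ndarray, ...]
    fold_observed: tuple[np.ndarray, ...]


def loso_cv_predict(
    embedding: DimensionEmbedding,
    events: pd.DataFrame,
    responses: VoxelResponses | np.ndarray,
) -> CVPredictions:
    """Leave-one-session-out encoding-model evaluation.

    Per fold: fit OLS on all other sessions, predict the held-out session,
    and score each voxel by Pearson r and R^2 (against the held-out mean).
    Reported values are fold means.
    """
    Y = responses.amplitudes if isinstance(responses, VoxelResponses) else np.asarray(responses)
    if len(events) != Y.shape[0]:
        raise ValueError("event count must match trial count")
    index = embedding.row_index()
    X = embedding.values[[index[i] for i in events["image_id"]]]
    sessions = sorted(int(s) for s in events["session_id"].unique())
    if len(sessions) < 2:
        raise ValueError("leave-one-session-out needs at least 2 sessions")
    rs, r2s, preds, obss = [], [], [], []
    sess_arr = events["session_id"].to_numpy()
    for s in sessions:
        test = sess_arr == s
        if test.sum() < 2:
            raise ValueError(f"session {s} has fewer than 2 trials")
        W, b0 = fit_ols(X[~test], Y[~test], return_intercept=True)
        pred = X[test] @ W.T + b0
        rs.append(columnwise_pearson(pred, Y[test]))
        r2s.append(held_out_r2(pred, Y[test]))
        preds.append(pred)
        obss.append(Y[test])
    return CVPredictions(
        cv_correlation=np.mean(rs, axis=0),
        cv_r2=np.mean(r2s, axis=0),
        fold_sessions=tuple(sessions),
        fold_predicted=tuple(preds),
        fold_observed=tuple(obss),
    )


def permutation_pvalues(
    cv: CVPredictions,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    pooled: bool = False,
) -> np.ndarray:
    """Permutation p-values for the fold-mean CV correlation.

    Within each fold the held-out trial order of the *observed* data is
    permuted (one shared permutation sequence across voxels, preserving
    the across-voxel dependence); the null statistic is the fold-mean
    correlation, or the pooled across-fold distribution when
    ``pooled=True``. p uses the add-one estimator, so p >= 1/(1+n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = spawn_rng(np.random.SeedSequence([int(seed), 606]))
    n_vox = cv.cv_correlation.shape[0]
    n_folds = len(cv.fold_sessions)
    null = np.zeros((n_perm, n_vox))
    fold_nulls = []
    for pred, obs in zip(cv.fold_predicted, cv.fold_observed):
        n_t = obs.shape[0]
        zp = pred - pred.mean(axis=0)
        zp_sd = zp.std(axis=0)
        zo = obs - obs.mean(axis=0)
        zo_sd = zo.std(axis=0)
        const = (zp_sd == 0) | (zo_sd == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            zp = np.where(zp_sd == 0, 0.0, zp / zp_sd)
            zo = np.where(zo_sd == 0, 0.0, zo / zo_sd)
        fold_null = np.empty((n_perm, n_vox))
        for k in range(n_perm):
            perm = rng.permutation(n_t)
            fold_null[k] = (zp * zo[perm]).mean(axis=0)
        fold_null[:, const] = 0.0
        null += fold_null / n_folds
        if pooled:
            fold_nulls.append(fold_null)
    observed = cv.cv_correlation.copy()
    const_obs = ~np.isfinite(observed)
    if const_obs.any():
        warnings.warn("constant observed responses in some voxels; p set to 1")
        observed[const_obs] = np.inf
    if pooled:
        null = np.concatenate(fold_nulls, axis=0)
    n_null = null.shape[0]
    p = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n_null)
    p[const_obs] = 1.0
    return p


def bh_fdr(p: np.ndarray, q: float = 0.01, *, method: str = "bh") -> np.ndarray:
    """Step-up FDR rejection flags (Benjamini-Hochberg, or BY with
    ``method='by'``)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, *_ = multipletests(p, alpha=q, method=sm_method)
    return reject


@dataclass(frozen=True)
class NoiseCeiling:
    """Per-voxel proportion of explainable single-trial response variance."""

    nc: np.ndarray
    signal_var: np.ndarray
    noise_var: np.ndarray


def estimate_noise_ceiling(repeat_responses: np.ndarray) -> NoiseCeiling:
    """Noise ceiling from responses to repeatedly presented images.

    ``repeat_responses`` is (n_repeats, n_images, n_voxels). The noise
    variance is the across-repeat variance averaged over images; the signal
    variance is the variance of image means minus the noise variance
    attributable to averaging (rectified at zero); the ceiling is
    signal_var / (signal_var + noise_var).
    """
    arr = np.asarray(repeat_responses, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 repeats of >= 2 images, shaped "
                         "(repeats, images, voxels)")
    n_rep = arr.shape[0]
    noise_var = arr.var(axis=0, ddof=1).mean(axis=0)
    means = arr.mean(axis=0)
    signal_var = np.maximum(0.0, means.var(axis=0, ddof=1) - noise_var / n_rep)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = signal_var / (signal_var + noise_var)
    nc = np.where(signal_var + noise_var == 0, np.nan, nc)
    return NoiseCeiling(nc=nc, signal_var=signal_var, noise_var=noise_var)


def repeat_response_array(responses: VoxelResponses) -> np.ndarray:
    """Stack repeat-image responses to (n_sessions, n_repeat_images, n_vox).

    Requires every repeat image to occur exactly once per session, the
    design convention of the synthetic generator.
    """
    ev = responses.events
    rep = ev[ev["is_repeat"]]
    images = sorted(rep["image_id"].unique())
    sessions = sorted(rep["session_id"].unique())
    out = np.empty((len(sessions), len(images), responses.amplitudes.shape[1]))
    lookup = {(r.session_id, r.image_id): i for i, r in rep.iterrows()}
    for si, s in enumerate(sessions):
        for ii, img in enumerate(images):
            try:
                out[si, ii] = responses.amplitudes[lookup[(s, img)]]
            except KeyError:
                raise ValueError(
                    f"repeat image {img!r} missing from session {s}"
                ) from None
    return out


def nc_correct(cv_r2: np.ndarray, nc: np.ndarray, floor: float = 0.02) -> np.ndarray:
    """Noise-ceiling-corrected R^2: cv_r2 / nc where nc >= floor, NaN
    elsewhere (never +/- inf)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    cv_r2 = np.asarray(cv_r2, dtype=float)
    nc = np.asarray(nc, dtype=float)
    valid = np.isfinite(nc) & (nc >= floor)
    out = np.full(cv_r2.shape, np.nan)
    out[valid] = cv_r2[valid] / nc[valid]
    return out
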