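"""Parametric-modulation model of voxel time series.

The model explains each voxel's BOLD series with a general onset regressor
(the mean response to any stimulus) plus one parametric modulator per
object dimension, each mean-centred at the event level so it is orthogonal
to the onset regressor, convolved with a candidate HRF on a microtime grid
and downsampled to scans. Per voxel, the best (HRF, ridge fraction) pair is
chosen by between-session cross-validation, and the final weights come
from a whole-data fit at that pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .hrf import HRFLibrary
from .ridge import DEFAULT_FRACTIONS, fractional_ridge
from .synth import DimensionEmbedding, TimeSeries

__all__ = [
    "DesignMatrix",
    "ModulationSelection",
    "ModulationFit",
    "build_design_matrix",
    "cv_select_hyperparams",
    "fit_modulation_weights",
]


@dataclass(frozen=True)
class DesignMatrix:
    """Scan-level design: onset regressor, modulators, session intercepts."""

    X: np.ndarray
    column_names: tuple[str, ...]
    session_ids: np.ndarray
    penalized: np.ndarray  # bool per column; intercepts are unpenalized
    event_modulators: pd.DataFrame  # event-level centred modulator values

    @property
    def n_dims(self) -> int:
        return self.event_modulators.shape[1]


def _session_regressors(
    events_sess: pd.DataFrame,
    mod_values: np.ndarray,
    kernel: np.ndarray,
    tr: float,
    n_scans: int,
    event_duration: float,
    microtime_factor: int,
) -> np.ndarray:
    """Convolved (scans x (1 + n_dims)) block for one session."""
    dt = tr / microtime_factor
    n_micro = n_scans * microtime_factor
    n_dims = mod_values.shape[1]
    sticks = np.zeros((n_micro, 1 + n_dims))
    onsets = events_sess["onset_seconds"].to_numpy()
    for i, onset in enumerate(onsets):
        a = int(round(onset / dt))
        b = max(a + 1, int(round((onset + event_duration) / dt)))
        if a < 0 or b > n_micro:
            raise ValueError(
                f"event at {onset:.2f}s falls outside the {n_scans}-scan window"
            )
        sticks[a:b, 0] += 1.0
        sticks[a:b, 1:] += mod_values[i]
    conv = fftconvolve(sticks, kernel[:, None], mode="full", axes=0)[:n_micro]
    return conv[::microtime_factor]


def build_design_matrix(
    events: pd.DataFrame,
    embedding: DimensionEmbedding,
    kernel: np.ndarray,
    *,
    tr: float,
    scan_counts: dict[int, int],
    event_duration: float = 0.5,
    microtime_factor: int = 10,
    include_session_intercepts: bool = True,
    center: np.ndarray | None = None,
) -> DesignMatrix:
    """Build the concatenated modulation design for a set of sessions.

    Modulators are centred by the mean dimension values over *all* events in
    ``events`` (pass ``center`` to impose the centring of a different run
    set, e.g. when applying a training-fold model to held-out scans).
    """
    index = embedding.row_index()
    rows = np.array([index[i] for i in events["image_id"]])
    values = embedding.values[rows]
    mu = values.mean(axis=0) if center is None else np.asarray(center, float)
    centred = values - mu

    sessions = sorted(int(s) for s in events["session_id"].unique())
    missing = [s for s in sessions if s not in scan_counts]
    if missing:
        raise ValueError(f"no scan count for session(s) {missing}")
    blocks, sess_ids = [], []
    for s in sessions:
        in_sess = (events["session_id"] == s).to_numpy()
        block = _session_regressors(
            events[in_sess], centred[in_sess], kernel, tr,
            scan_counts[s], event_duration, microtime_factor,
        )
        blocks.append(block)
        sess_ids.append(np.full(block.shape[0], s))
    X = np.vstack(blocks)
    session_ids = np.concatenate(sess_ids)
    names = ["onset", *embedding.dim_labels]
    penalized = [True] * len(names)
    if include_session_intercepts:
        for s in sessions:
            X = np.column_stack([X, (session_ids == s).astype(float)])
            names.append(f"intercept_s{s}")
            penalized.append(False)
    mods = pd.DataFrame(centred, index=events.index, columns=list(embedding.dim_labels))
    return DesignMatrix(X, tuple(names), session_ids, np.array(penalized), mods)


@dataclass(frozen=True)
class ModulationSelection:
    """Per-voxel hyperparameter choice from between-session CV."""

    hrf_index: np.ndarray
    fraction: np.ndarray
    cv_r2: np.ndarray
    fractions_grid: np.ndarray
    n_folds: int


@dataclass(frozen=True)
class ModulationFit:
    """Final whole-data modulation weights with the selection metadata."""

    weights: np.ndarray  # voxels x n_dims
    chosen_hrf: np.ndarray
    chosen_fraction: np.ndarray
    cv_r2: np.ndarray
    dim_labels: tuple[str, ...]


def _session_centred_r2(pred, obs, sess_ids):
    """R^2 with per-session centring of both prediction and data (held-out
    session intercepts are unidentified, so means carry no credit)."""
    pred = pred.copy()
    obs = obs.copy()
    for s in np.unique(sess_ids):
        sel = sess_ids == s
        pred[..., sel, :] -= pred[..., sel, :].mean(axis=-2, keepdims=True)
        obs[sel] -= obs[sel].mean(axis=0, keepdims=True)
    ss_res = ((obs - pred) ** 2).sum(axis=-2)
    ss_tot = (obs**2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


def _precompute_blocks(timeseries, events, embedding, hrfs, event_duration=0.5):
    """Per (hrf, session) convolved blocks with *uncentred* modulators.

    Centring by mean mu is linear: centred block = raw block minus
    outer(onset column, mu), so fold-specific centring never needs to redo
    the convolution.
    """
    slices = timeseries.session_slices()
    index = embedding.row_index()
    blocks: dict[tuple[int, int], np.ndarray] = {}
    for s, sl in slices.items():
        in_sess = (events["session_id"] == s).to_numpy()
        ev = events[in_sess]
        rows = np.array([index[i] for i in ev["image_id"]])
        raw = embedding.values[rows]
        for h in range(len(hrfs)):
            blocks[(h, s)] = _session_regressors(
                ev, raw, hrfs.kernels[h], timeseries.tr_seconds,
                sl.stop - sl.start, event_duration, hrfs.microtime_factor,
            )
    return slices, blocks


def _assemble(blocks, sessions, h, mu, with_intercepts):
    parts = [blocks[(h, s)] for s in sessions]
    X = np.vstack(parts)
    X[:, 1:] -= np.outer(X[:, 0], mu)
    sess_ids = np.concatenate(
        [np.full(blocks[(h, s)].shape[0], s) for s in sessions]
    )
    if with_intercepts:
        intercepts = np.column_stack(
            [(sess_ids == s).astype(float) for s in sessions]
        )
        X = np.column_stack([X, intercepts])
    return X, sess_ids


def cv_select_hyperparams(
    timeseries: TimeSeries,
    events: pd.DataFrame,
    embedding: DimensionEmbedding,
    hrfs: HRFLibrary,
    fractions: np.ndarray | None = None,
    n_folds: int = 12,
    event_duration: float = 0.5,
) -> ModulationSelection:
    """Exhaustive per-voxel search over (HRF, ridge fraction).

    Sessions are partitioned into ``n_folds`` groups (one session per fold
    when the counts match); each fold's model is fitted on the remaining
    sessions with training-set modulator centring and session intercepts,
    and scored by R^2 on the held-out scans (session-centred, since the
    held-out session's intercept is not identified). Ties are broken toward
    the smaller time-to-peak, then the larger fraction.
    """
    fractions = DEFAULT_FRACTIONS if fractions is None else np.asarray(fractions, float)
    sessions = sorted(timeseries.session_slices())
    if len(sessions) < n_folds:
        raise ValueError(f"{len(sessions)} sessions cannot form {n_folds} folds")
    if len(sessions) % n_folds:
        raise ValueError("session count must divide evenly into folds")
    per_fold = len(sessions) // n_folds
    folds = [sessions[i * per_fold : (i + 1) * per_fold] for i in range(n_folds)]

    slices, blocks = _precompute_blocks(timeseries, events, embedding, hrfs, event_duration)
    index = embedding.row_index()
    all_rows = np.array([index[i] for i in events["image_id"]])
    values = embedding.values[all_rows]
    sess_of_event = events["session_id"].to_numpy()

    n_vox = timeseries.data.shape[1]
    n_pm = 1 + embedding.n_dims
    scores = np.zeros((len(hrfs), len(fractions), n_vox))
    for test_sessions in folds:
        train_sessions = [s for s in sessions if s not in test_sessions]
        train_ev = np.isin(sess_of_event, train_sessions)
        mu = values[train_ev].mean(axis=0)
        Ytr = np.vstack([timeseries.data[slices[s]] for s in train_sessions])
        Yte = np.vstack([timeseries.data[slices[s]] for s in test_sessions])
        te_ids = np.concatenate(
            [np.full(slices[s].stop - slices[s].start, s) for s in test_sessions]
        )
        for h in range(len(hrfs)):
            Xtr, _ = _assemble(blocks, train_sessions, h, mu, with_intercepts=True)
            unpen = np.arange(n_pm, Xtr.shape[1])
            coefs = fractional_ridge(Xtr, Ytr, fractions, unpenalized=unpen)
            Xte, _ = _assemble(blocks, test_sessions, h, mu, with_intercepts=False)
            pred = np.einsum("np,fpm->fnm", Xte, coefs[:, :n_pm, :])
            scores[h] += _session_centred_r2(pred, Yte, te_ids)
    scores /= n_folds

    # argmax with ties toward smaller time-to-peak (library order), then
    # larger fraction: scan fractions in descending order so the first
    # maximum wins
    frac_order = np.argsort(-fractions, kind="stable")
    flat = scores[:, frac_order, :].reshape(-1, n_vox)
    best = np.argmax(flat, axis=0)
    h_idx = best // len(fractions)
    f_idx = frac_order[best % len(fractions)]
    return ModulationSelection(
        hrf_index=h_idx,
        fraction=fractions[f_idx],
        cv_r2=flat[best, np.arange(n_vox)],
        fractions_grid=fractions,
        n_folds=n_folds,
    )


def fit_modulation_weights(
    timeseries: TimeSeries,
    events: pd.DataFrame,
    embedding: DimensionEmbedding,
    hrfs: HRFLibrary,
    selection: ModulationSelection,
    event_duration: float = 0.5,
) -> ModulationFit:
    """Whole-data fit at each voxel's selected (HRF, fraction) pair."""
    n_vox = timeseries.data.shape[1]
    if selection.hrf_index.shape != (n_vox,):
        raise ValueError("selection does not cover every voxel")
    slices, blocks = _precompute_blocks(timeseries, events, embedding, hrfs, event_duration)
    sessions = sorted(slices)
    index = embedding.row_index()
    values = embedding.values[[index[i] for i in events["image_id"]]]
    mu = values.mean(axis=0)
    n_pm = 1 + embedding.n_dims
    weights = np.zeros((n_vox, embedding.n_dims))
    for h in np.unique(selection.hrf_index):
        X, _ = _assemble(blocks, sessions, h, mu, with_intercepts=True)
        unpen = np.arange(n_pm, X.shape[1])
        vox_h = np.flatnonzero(selection.hrf_index == h)
        for f in np.unique(selection.fraction[vox_h]):
            vox = vox_h[selection.fraction[vox_h] == f]
            coefs = fractional_ridge(
                X, timeseries.data[:, vox], np.array([f]), unpenalized=unpen
            )
            weights[vox] = coefs[0, 1:n_pm, :].T
    return ModulationFit(
        weights=weights,
        chosen_hrf=selection.hrf_index.copy(),
        chosen_fraction=selection.fraction.copy(),
        cv_r2=selection.cv_r2.copy(),
        dim_labels=embedding.dim_labels,
    )
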