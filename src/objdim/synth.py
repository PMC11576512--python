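"""Synthetic study generator.

Emulates the statistical structure of a rapid event-related object-vision
fMRI study: a sparse, non-negative 66-dimensional object embedding; a
session-structured design with a fixed set of images repeated in every
session; voxels with sparse, dense or absent dimension tuning laid out on an
abstract 3-D lattice; and BOLD time series built by HRF convolution on a
microtime grid, with additive Gaussian (optionally AR(1)) noise.

Every generator is deterministic given its configuration and seed, and each
returns the ground truth needed for recovery testing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import check_count, check_positive, spawn_rng

__all__ = [
    "SyntheticConfig",
    "DimensionEmbedding",
    "GroundTruth",
    "CategoryLabels",
    "generate_embedding",
    "generate_events",
    "generate_ground_truth",
    "simulate_single_trial",
    "simulate_timeseries",
    "generate_categories",
    "calibrate_noise_sd",
    "VoxelResponses",
    "TimeSeries",
]

EVENT_COLUMNS = ["trial_index", "session_id", "onset_seconds", "image_id", "is_repeat"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic study.

    Defaults mirror the acquisition this generator emulates: 12 sessions,
    100 images repeated once per session, 500 ms stimulus presentations
    followed by 4 s of fixation, at a repetition time of 1.5 s. Trial and
    voxel counts default to desk-scale values rather than the full study.
    """

    n_images: int
    n_voxels: int
    n_dims: int = 66
    n_sessions: int = 12
    trials_per_session: int = 120
    n_repeat_images: int = 100
    tr_seconds: float = 1.5
    event_duration_seconds: float = 0.5
    isi_seconds: float = 4.0
    frac_sparse_voxels: float = 0.2
    frac_dense_voxels: float = 0.2
    frac_noise_voxels: float = 0.6
    noise_sd: float = 1.0
    onset_amplitude: float = 1.0
    ar_rho: float = 0.0
    microtime_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_images", "n_voxels", "n_dims", "n_sessions",
                     "trials_per_session", "n_repeat_images", "microtime_factor"):
            check_count(name, getattr(self, name))
        for name in ("tr_seconds", "event_duration_seconds", "onset_amplitude"):
            check_positive(name, getattr(self, name))
        if self.isi_seconds < 0 or self.noise_sd < 0:
            raise ValueError("isi_seconds and noise_sd must be non-negative")
        fracs = (self.frac_sparse_voxels, self.frac_dense_voxels, self.frac_noise_voxels)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("voxel class proportions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"voxel class proportions must sum to 1, got {sum(fracs)}")
        if self.n_repeat_images > self.n_images:
            raise ValueError("n_repeat_images cannot exceed n_images")
        if not (-1 < self.ar_rho < 1):
            raise ValueError("ar_rho must lie in (-1, 1)")

    @property
    def trial_spacing_seconds(self) -> float:
        return self.event_duration_seconds + self.isi_seconds


@dataclass(frozen=True)
class DimensionEmbedding:
    """Images x dimensions matrix of non-negative object-dimension values."""

    values: np.ndarray
    image_ids: tuple[str, ...]
    dim_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "image_ids", tuple(self.image_ids))
        object.__setattr__(self, "dim_labels", tuple(self.dim_labels))
        if values.ndim != 2:
            raise ValueError("embedding values must be 2-D (images x dimensions)")
        if values.shape != (len(self.image_ids), len(self.dim_labels)):
            raise ValueError("embedding shape does not match id/label counts")
        if np.any(values < 0):
            raise ValueError("embedding values must be non-negative")
        if np.any(np.all(values == 0, axis=1)):
            raise ValueError("embedding contains an all-zero image row")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {img: i for i, img in enumerate(self.image_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.image_ids),
                            columns=list(self.dim_labels))


@dataclass(frozen=True)
class GroundTruth:
    """True voxel tuning underlying a simulation.

    ``voxel_class`` is one of ``sparse`` (<= 2 nonzero weights), ``dense``
    (>= ceil(n_dims / 3) nonzero weights) or ``noise`` (all-zero weights).
    Voxels live on an abstract 3-D lattice (``grid_shape``/``voxel_coords``)
    with the sparse and dense classes planted as compact blobs, so that the
    spatial smoothing and cluster-discovery stages have realistic structure
    to find.
    """

    true_weights: np.ndarray
    voxel_class: np.ndarray
    true_hrf_index: np.ndarray
    noise_sd: np.ndarray
    onset_amplitude: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_coords: np.ndarray

    def __post_init__(self) -> None:
        noise = self.voxel_class == "noise"
        if np.any(self.true_weights[noise] != 0):
            raise ValueError("noise-class voxels must have all-zero true weights")
        nnz = np.count_nonzero(self.true_weights, axis=1)
        n_dims = self.true_weights.shape[1]
        if np.any(nnz[self.voxel_class == "sparse"] > 2):
            raise ValueError("sparse-class voxels must have <= 2 nonzero weights")
        if np.any(nnz[self.voxel_class == "dense"] < int(np.ceil(n_dims / 3))):
            raise ValueError("dense-class voxels must have >= ceil(n_dims/3) nonzero weights")

    @property
    def n_voxels(self) -> int:
        return self.true_weights.shape[0]

    def mask_volume(self) -> np.ndarray:
        """Boolean 3-D volume flagging lattice sites occupied by voxels."""
        vol = np.zeros(self.grid_shape, dtype=bool)
        vol[tuple(self.voxel_coords.T)] = True
        return vol


@dataclass(frozen=True)
class CategoryLabels:
    """Binary image-by-category membership with the generating dimension."""

    membership: np.ndarray
    category_names: tuple[str, ...]
    generating_dimension: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("membership entries must be 0 or 1")
        n_member = m.sum(axis=0)
        if np.any(n_member < 2) or np.any(m.shape[0] - n_member < 2):
            raise ValueError("every category needs >= 2 members and >= 2 non-members")


@dataclass(frozen=True)
class VoxelResponses:
    """Single-trial response amplitudes (trials x voxels) tied to an event table."""

    amplitudes: np.ndarray
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.events) != self.amplitudes.shape[0]:
            raise ValueError("trial count must equal event count")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")


@dataclass(frozen=True)
class TimeSeries:
    """Scan-by-scan BOLD series, sessions concatenated along axis 0."""

    data: np.ndarray
    session_ids: np.ndarray  # per-scan session label
    tr_seconds: float

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    def session_slices(self) -> dict[int, slice]:
        out: dict[int, slice] = {}
        for sess in pd.unique(self.session_ids):
            idx = np.flatnonzero(self.session_ids == sess)
            out[int(sess)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


# ---------------------------------------------------------------------------
# generators


def generate_embedding(
    n_images: int,
    n_dims: int = 66,
    seed: int = 0,
    *,
    zero_fraction: float = 0.6,
    decay: float = 1.0,
) -> DimensionEmbedding:
    """Generate a sparse, non-negative object-dimension embedding.

    Entries are exponential draws with exponentially decaying column scales
    (dimensions ordered by importance), soft-thresholded at each column's
    ``zero_fraction`` quantile so that roughly that fraction of entries is
    exactly zero. Columns are re-ordered by decreasing standard deviation so
    the importance ordering holds exactly in every finite sample.
    """
    check_count("n_images", n_images, 2)
    check_count("n_dims", n_dims, 2)
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must lie in [0, 1)")
    rng = spawn_rng(seed)
    scales = np.exp(-decay * np.arange(n_dims) / (n_dims - 1))
    raw = rng.exponential(1.0, size=(n_images, n_dims)) * scales
    thresh = np.quantile(raw, zero_fraction, axis=0)
    values = np.maximum(0.0, raw - thresh)
    # an image must express at least one dimension
    dead = np.flatnonzero(np.all(values == 0, axis=1))
    for row in dead:
        d = int(rng.integers(0, min(5, n_dims)))
        values[row, d] = rng.exponential(scales[d])
    order = np.argsort(-values.std(axis=0), kind="stable")
    values = values[:, order]
    image_ids = tuple(f"img_{i:05d}" for i in range(n_images))
    dim_labels = tuple(f"dim_{d:02d}" for d in range(n_dims))
    return DimensionEmbedding(values, image_ids, dim_labels)


def generate_events(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the trial table of a session-structured design.

    The first ``n_repeat_images`` image ids are designated repeat images and
    occur exactly once in every session; the remaining trials draw from the
    non-repeat pool without replacement across the whole experiment. Trial
    order is shuffled within session; onsets are equally spaced by
    ``event_duration + isi`` seconds from the session start.

    Returns a DataFrame with columns
    ``trial_index, session_id, onset_seconds, image_id, is_repeat``.
    """
    cfg = config
    if cfg.trials_per_session < cfg.n_repeat_images:
        raise ValueError("trials_per_session must be >= n_repeat_images")
    n_fill = cfg.trials_per_session - cfg.n_repeat_images
    n_unique_needed = cfg.n_sessions * n_fill
    if cfg.n_repeat_images + n_unique_needed > cfg.n_images:
        raise ValueError(
            f"need {cfg.n_repeat_images + n_unique_needed} images "
            f"({cfg.n_repeat_images} repeats + {n_unique_needed} singles) "
            f"but only {cfg.n_images} available"
        )
    rng = spawn_rng(np.random.SeedSequence([cfg.seed, 101]))
    ids = np.array([f"img_{i:05d}" for i in range(cfg.n_images)])
    repeat_ids = ids[: cfg.n_repeat_images]
    pool = ids[cfg.n_repeat_images :].copy()
    rng.shuffle(pool)
    rows = []
    trial = 0
    for sess in range(cfg.n_sessions):
        fill = pool[sess * n_fill : (sess + 1) * n_fill]
        sess_imgs = np.concatenate([repeat_ids, fill])
        is_rep = np.concatenate(
            [np.ones(cfg.n_repeat_images, bool), np.zeros(n_fill, bool)]
        )
        order = rng.permutation(cfg.trials_per_session)
        for k, j in enumerate(order):
            rows.append(
                (trial, sess, k * cfg.trial_spacing_seconds, sess_imgs[j], bool(is_rep[j]))
            )
            trial += 1
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events


def _lattice_layout(n_sparse, n_dense, n_noise):
    """Voxel coordinates and classes on the abstract lattice.

    Signal voxels occupy one slab with the sparse and dense classes as
    compact blobs around separate centres; noise voxels occupy a second
    slab separated by empty lattice planes. The separation mirrors the
    anatomy the generator emulates: voxels the model cannot predict (the
    later noise pool) lie overwhelmingly far from modelled cortex, so
    spatial smoothing does not bleed signal tuning into them.
    """
    n_vox = n_sparse + n_dense + n_noise
    side = max(2, int(np.ceil(max(n_sparse, n_dense, n_noise, 1) ** (1 / 3))))
    gap = 3  # > smoothing reach, so class slabs do not bleed into each other
    coords = np.zeros((n_vox, 3), dtype=int)
    classes = np.empty(n_vox, dtype=object)
    z_offset = 0
    row = 0
    for name, count in (("sparse", n_sparse), ("dense", n_dense),
                        ("noise", n_noise)):
        if count == 0:
            continue
        z_depth = int(np.ceil(count / side**2))
        sites = np.argwhere(np.ones((side, side, z_depth), dtype=bool))
        centre = np.array([side / 2, side / 2, z_depth / 2]) - 0.5
        order = np.argsort(np.linalg.norm(sites - centre, axis=1), kind="stable")
        chosen = sites[order[:count]]
        chosen[:, 2] += z_offset
        coords[row : row + count] = chosen
        classes[row : row + count] = name
        row += count
        z_offset += z_depth + gap
    grid_shape = (side, side, max(1, z_offset - gap))
    return grid_shape, coords, classes.astype(str)


def generate_ground_truth(
    config: SyntheticConfig, embedding: DimensionEmbedding
) -> GroundTruth:
    """Draw per-voxel true tuning weights, HRF indices and noise levels.

    Class counts follow the configured proportions (largest-remainder
    rounding, exact to +/- 1). Nonzero weights are Normal(1.0, 0.5) — a
    positive-mean distribution, so signal voxels are predominantly
    positively tuned to their dimensions, as rectified tuning-profile
    analyses assume. Noise-class voxels emulate visually unresponsive
    cortex: they carry neither dimension tuning nor a stimulus-onset
    response, which is what makes them a valid empirical null pool for the
    sparseness analysis.
    """
    cfg = config
    n_dims = embedding.n_dims
    rng = spawn_rng(np.random.SeedSequence([cfg.seed, 202]))
    # largest-remainder allocation of voxel counts
    raw = np.array([cfg.frac_sparse_voxels, cfg.frac_dense_voxels, cfg.frac_noise_voxels])
    exact = raw * cfg.n_voxels
    counts = np.floor(exact).astype(int)
    rem = cfg.n_voxels - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:rem]] += 1
    n_sparse, n_dense, n_noise = counts
    grid_shape, coords, classes = _lattice_layout(n_sparse, n_dense, n_noise)

    weights = np.zeros((cfg.n_voxels, n_dims))
    min_dense = int(np.ceil(n_dims / 3))
    for v in range(cfg.n_voxels):
        if classes[v] == "sparse":
            k = int(rng.integers(1, 3))
        elif classes[v] == "dense":
            k = int(rng.integers(min_dense, n_dims + 1))
        else:
            continue
        dims = rng.choice(n_dims, size=k, replace=False)
        weights[v, dims] = rng.normal(1.0, 0.5, size=k)
        if np.all(weights[v] == 0):  # pathological draw of exact zeros
            weights[v, dims[0]] = 1.0
    hrf_index = rng.integers(0, 20, size=cfg.n_voxels)
    noise_sd = np.full(cfg.n_voxels, float(cfg.noise_sd))
    onset_amp = np.where(classes == "noise", 0.0, float(cfg.onset_amplitude))
    return GroundTruth(weights, classes, hrf_index, noise_sd, onset_amp,
                       grid_shape, coords)


def calibrate_noise_sd(
    signal: np.ndarray,
    *,
    snr: float | None = None,
    noise_ceiling: float | None = None,
) -> np.ndarray:
    """Per-voxel noise SD matching a target SNR or single-trial noise ceiling.

    SNR is defined as signal SD over noise SD; a noise ceiling ``nc`` (the
    proportion of explainable response variance, signal_var / (signal_var +
    noise_var)) maps to ``noise_sd = signal_sd * sqrt((1 - nc) / nc)``.
    Voxels without signal variance (e.g. noise-class voxels) receive the
    median noise SD of the voxels that have some.
    """
    if (snr is None) == (noise_ceiling is None):
        raise ValueError("specify exactly one of snr or noise_ceiling")
    sd = np.asarray(signal, dtype=float).std(axis=0)
    if snr is not None:
        check_positive("snr", snr)
        out = sd / snr
    else:
        if not 0 < noise_ceiling < 1:
            raise ValueError("noise_ceiling must lie in (0, 1)")
        out = sd * np.sqrt((1 - noise_ceiling) / noise_ceiling)
    positive = out[sd > 0]
    if positive.size == 0:
        raise ValueError("no voxel has signal variance; cannot calibrate")
    return np.where(sd > 0, out, np.median(positive))


def simulate_single_trial(
    embedding: DimensionEmbedding,
    events: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    *,
    noise_sd: np.ndarray | None = None,
) -> VoxelResponses:
    """Simulate single-trial response amplitudes: Y = X W' + noise.

    The trial-by-dimension design X stacks the embedding rows of the
    presented images in event order; noise is iid Gaussian per trial with
    per-voxel SD (``truth.noise_sd`` unless overridden).
    """
    index = embedding.row_index()
    try:
        rows = np.array([index[i] for i in events["image_id"]])
    except KeyError as exc:
        raise KeyError(f"image id {exc.args[0]!r} not present in embedding") from None
    X = embedding.values[rows]
    signal = X @ truth.true_weights.T
    sd = truth.noise_sd if noise_sd is None else np.broadcast_to(noise_sd, (truth.n_voxels,))
    rng = spawn_rng(np.random.SeedSequence([int(seed), 303]))
    noise = rng.standard_normal(signal.shape) * sd
    return VoxelResponses(signal + noise, events.reset_index(drop=True))


def _session_scan_count(events_sess: pd.DataFrame, cfg: SyntheticConfig, tail_seconds: float = 20.0) -> int:
    end = events_sess["onset_seconds"].max() + cfg.event_duration_seconds + tail_seconds
    return int(np.ceil(end / cfg.tr_seconds))


def simulate_timeseries(
    embedding: DimensionEmbedding,
    events: pd.DataFrame,
    truth: GroundTruth,
    hrfs,
    config: SyntheticConfig,
    seed: int = 0,
    *,
    noise_sd: np.ndarray | None = None,
) -> TimeSeries:
    """Simulate session-wise BOLD time series under the modulation model.

    Per session the noiseless signal of voxel v with library HRF h is
    ``onset_amplitude * (onset boxcars (*) h) + sum_d w_vd * (centred
    modulator_d (*) h)``, built on a microtime grid of TR / microtime_factor
    and downsampled to scans. Modulators are mean-centred over all trials of
    the experiment, matching the design-matrix convention. Noise is iid
    Gaussian per scan, or AR(1) when ``config.ar_rho`` is nonzero.
    """
    from .modulation import build_design_matrix  # local import avoids a cycle

    n_vox = truth.n_voxels
    if truth.true_hrf_index.max() >= len(hrfs.kernels):
        raise IndexError("true_hrf_index exceeds HRF library size")
    scan_counts = {
        int(s): _session_scan_count(g, config)
        for s, g in events.groupby("session_id", sort=True)
    }
    sessions = sorted(scan_counts)
    total_scans = sum(scan_counts.values())
    data = np.zeros((total_scans, n_vox))
    session_ids = np.concatenate(
        [np.full(scan_counts[s], s, dtype=int) for s in sessions]
    )
    for h in np.unique(truth.true_hrf_index):
        vox = np.flatnonzero(truth.true_hrf_index == h)
        design = build_design_matrix(
            events,
            embedding,
            hrfs.kernels[h],
            tr=config.tr_seconds,
            scan_counts=scan_counts,
            event_duration=config.event_duration_seconds,
            microtime_factor=config.microtime_factor,
            include_session_intercepts=False,
        )
        coef = np.vstack(
            [truth.onset_amplitude[None, vox], truth.true_weights[vox].T]
        )
        data[:, vox] = design.X @ coef
    sd = truth.noise_sd if noise_sd is None else np.broadcast_to(noise_sd, (n_vox,))
    rng = spawn_rng(np.random.SeedSequence([int(seed), 404]))
    eps = rng.standard_normal(data.shape)
    if config.ar_rho != 0.0:
        rho = config.ar_rho
        start = 0
        for s in sessions:
            stop = start + scan_counts[s]
            block = eps[start:stop]
            for t in range(1, block.shape[0]):
                block[t] = rho * block[t - 1] + np.sqrt(1 - rho**2) * block[t]
            start = stop
    data = data + eps * sd
    return TimeSeries(data, session_ids, config.tr_seconds)


def generate_categories(
    embedding: DimensionEmbedding,
    n_categories: int,
    seed: int = 0,
    *,
    top_quantile: float = 0.2,
    flip_rate: float = 0.0,
    generating_dims: np.ndarray | None = None,
    max_attempts: int = 10,
) -> CategoryLabels:
    """Generate binary category labels tied to single diagnostic dimensions.

    Category c's members are the images in the top ``top_quantile`` of a
    designated dimension's values, with labels flipped independently at
    ``flip_rate``. Several categories may share one generating dimension (a
    one-to-many dimension-to-category mapping); pass ``generating_dims`` to
    control the assignment explicitly.
    """
    check_count("n_categories", n_categories)
    if n_categories > embedding.n_dims:
        raise ValueError("n_categories cannot exceed the number of dimensions "
                         "unless generating_dims is supplied with reuse")
    if not 0 < top_quantile < 0.5:
        raise ValueError("top_quantile must lie in (0, 0.5)")
    rng = spawn_rng(np.random.SeedSequence([int(seed), 505]))
    n_images = embedding.n_images
    if generating_dims is None:
        generating_dims = rng.choice(embedding.n_dims, size=n_categories, replace=False)
    generating_dims = np.asarray(generating_dims, dtype=int)
    if generating_dims.shape != (n_categories,):
        raise ValueError("generating_dims must have one entry per category")
    k = max(2, int(round(top_quantile * n_images)))
    membership = np.zeros((n_images, len(generating_dims)), dtype=np.int8)
    for c, d in enumerate(generating_dims):
        vals = embedding.values[:, d]
        # deterministic ranking; ties broken by image index
        top = np.argsort(-vals, kind="stable")[:k]
        base = np.zeros(n_images, dtype=np.int8)
        base[top] = 1
        for attempt in range(max_attempts):
            labels = base.copy()
            if flip_rate > 0:
                flips = rng.random(n_images) < flip_rate
                labels[flips] = 1 - labels[flips]
            if 2 <= labels.sum() <= n_images - 2:
                break
            warnings.warn(f"category {c}: degenerate after label flips, regenerating")
        else:
            raise ValueError(f"category {c}: could not generate valid labels "
                             f"after {max_attempts} attempts")
        membership[:, c] = labels
    names = tuple(f"cat_{c:02d}" for c in range(len(generating_dims)))
    return CategoryLabels(membership, names, generating_dims)
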