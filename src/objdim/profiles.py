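"""Regional tuning profiles and representative-image ranking.

A region's tuning profile is the mean dimension-weight vector over its
voxels, averaged within participant, then across participants, then
rectified at zero (in that order — cancellation across participants
happens before rectification). Profiles are matched against the embedding
by cosine similarity to rank the most representative images, and
dimension maps are compared across participants via ROI-mean weight
patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import columnwise_pearson
from .synth import DimensionEmbedding

__all__ = ["TuningProfile", "regional_profile", "representative_images",
           "interparticipant_consistency"]


@dataclass(frozen=True)
class TuningProfile:
    region: str
    values: np.ndarray  # non-negative, one magnitude per dimension
    n_voxels_used: tuple[int, ...]  # per participant

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("profile values must be rectified (non-negative)")


def regional_profile(
    weights: np.ndarray | list[np.ndarray],
    roi: np.ndarray,
    nc: np.ndarray | list[np.ndarray] | None = None,
    nc_floor: float = 0.02,
    *,
    region: str = "region",
) -> TuningProfile:
    """Rectified mean tuning profile of an ROI.

    ``weights`` is one (voxels x dims) array per participant (a single
    array is treated as one participant). Voxels with a noise ceiling below
    ``nc_floor`` are excluded when ``nc`` maps are given. Averaging order:
    within participant, across participants, then negatives set to zero.
    """
    if isinstance(weights, np.ndarray):
        weights = [weights]
    if nc is not None and isinstance(nc, np.ndarray):
        nc = [nc]
    roi = np.asarray(roi, dtype=bool)
    per_part, used = [], []
    for p, W in enumerate(weights):
        keep = roi.copy()
        if nc is not None:
            keep &= np.nan_to_num(nc[p], nan=-np.inf) >= nc_floor
        if not keep.any():
            raise ValueError(
                f"region {region!r}: no voxel survives the noise-ceiling floor "
                f"for participant {p}"
            )
        per_part.append(W[keep].mean(axis=0))
        used.append(int(keep.sum()))
    mean = np.mean(per_part, axis=0)
    values = np.maximum(0.0, mean)
    if not values.any():
        warnings.warn(f"region {region!r}: profile is all-zero after rectification")
    return TuningProfile(region=region, values=values, n_voxels_used=tuple(used))


def representative_images(
    profile: TuningProfile,
    embedding: DimensionEmbedding,
    k: int = 10,
) -> pd.DataFrame:
    """Images ranked by cosine similarity between profile and embedding row.

    All-zero image rows are excluded with a warning (cosine undefined);
    ties are broken by image id for determinism. Returns columns
    ``rank, image_id, cosine``.
    """
    v = profile.values
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot rank images against an all-zero profile")
    E = embedding.values
    row_norms = np.linalg.norm(E, axis=1)
    dead = row_norms == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} all-zero image rows excluded from ranking")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (E @ v) / (row_norms * norm)
    ids = np.asarray(embedding.image_ids)
    keep = ~dead
    order = np.lexsort((ids[keep], -cos[keep]))
    top = order[: int(k)]
    return pd.DataFrame({
        "rank": np.arange(1, len(top) + 1),
        "image_id": ids[keep][top],
        "cosine": cos[keep][top],
    })


def interparticipant_consistency(
    weights: list[np.ndarray],
    roi_set: dict[str, np.ndarray],
    nc: list[np.ndarray] | None = None,
    nc_floor: float = 0.02,
    *,
    dim_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Across-participant consistency of each dimension's ROI-mean pattern.

    For every dimension each participant contributes a vector of ROI-mean
    weights (one entry per ROI in ``roi_set``; split category-selective
    ROIs by hemisphere upstream if desired); consistency is the mean
    Pearson correlation over participant pairs. A participant whose ROI
    pattern is constant yields NaN for that dimension's pairs.
    """
    if len(weights) < 2:
        raise ValueError("consistency needs at least 2 participants")
    if len(roi_set) < 3:
        raise ValueError("consistency needs at least 3 ROIs")
    n_dims = weights[0].shape[1]
    patterns = np.empty((len(weights), len(roi_set), n_dims))
    for p, W in enumerate(weights):
        for r, (name, mask) in enumerate(roi_set.items()):
            mask = np.asarray(mask, dtype=bool)
            keep = mask.copy()
            if nc is not None:
                keep &= np.nan_to_num(nc[p], nan=-np.inf) >= nc_floor
            if not keep.any():
                raise ValueError(f"ROI {name!r} empty after exclusion "
                                 f"for participant {p}")
            patterns[p, r] = W[keep].mean(axis=0)
    pair_rs = []
    for a, b in combinations(range(len(weights)), 2):
        pair_rs.append(columnwise_pearson(patterns[a], patterns[b]))
    mean_r = np.nanmean(pair_rs, axis=0) if pair_rs else np.full(n_dims, np.nan)
    labels = dim_labels or tuple(f"dim_{d:02d}" for d in range(n_dims))
    return pd.DataFrame({"dimension": list(labels), "consistency": mean_r})
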