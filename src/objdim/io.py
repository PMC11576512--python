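"""Readers and writers for the pipeline's tabular and volumetric formats.

Tables travel as TSV with a header row (embedding, events, category
labels, per-voxel statistics); volumes as NIfTI-1 reconstructed into a
mask geometry with NaN outside the mask; bundles (ground truth, fitted
predictors) as a JSON header plus an .npz of arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import EVENT_COLUMNS, DimensionEmbedding, GroundTruth

__all__ = [
    "read_embedding_tsv",
    "write_embedding_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "write_stat_maps",
    "read_stat_map_nifti",
    "write_ground_truth",
    "read_ground_truth",
    "write_predictor",
    "read_predictor",
]

BACKGROUND = np.nan


def write_embedding_tsv(embedding: DimensionEmbedding, path: str | Path) -> None:
    df = embedding.to_frame()
    df.index.name = "image_id"
    df.to_csv(path, sep="\t")


def read_embedding_tsv(path: str | Path, *, allow_negative: bool = False) -> pd.DataFrame:
    """Read an image-by-dimension table.

    Rejects negative values unless ``allow_negative`` (predicted dimension
    values may legitimately be negative). Parse failures report the
    offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from None
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        for col in bad:
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            line = int(df.index.get_loc(row)) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric cell in column {col!r}, line {line}")
    if not allow_negative and (df.to_numpy() < 0).any():
        idx = np.argwhere(df.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative value at image {df.index[idx[0]]!r}, "
            f"column {df.columns[idx[1]]!r}; pass allow_negative=True for raw "
            "predicted dimension values"
        )
    return df


def as_embedding(df: pd.DataFrame) -> DimensionEmbedding:
    return DimensionEmbedding(df.to_numpy(float), tuple(map(str, df.index)),
                              tuple(map(str, df.columns)))


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Write a BIDS-style events table (onset, duration, plus study columns)."""
    out = pd.DataFrame({
        "onset": events["onset_seconds"],
        "duration": events.get("duration", 0.5),
        "image_id": events["image_id"],
        "session_id": events["session_id"],
        "is_repeat": events["is_repeat"].astype(int),
        "trial_index": events["trial_index"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    events = pd.DataFrame({
        "trial_index": df["trial_index"],
        "session_id": df["session_id"],
        "onset_seconds": df["onset"],
        "image_id": df["image_id"],
        "is_repeat": df["is_repeat"].astype(bool),
    })
    return events[EVENT_COLUMNS]


def write_stat_maps(
    values: pd.DataFrame | dict[str, np.ndarray],
    path: str | Path,
    *,
    mask: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    format: str = "tsv",
    affine: np.ndarray | None = None,
) -> list[Path]:
    """Write per-voxel statistics as TSV, plus NIfTI volumes on request.

    The TSV has one row per in-mask voxel and one column per statistic.
    With ``format='nifti'`` each statistic is additionally reconstructed
    into the mask geometry (NaN background) as ``<stem>_<name>.nii``.
    """
    if isinstance(values, dict):
        values = pd.DataFrame(values)
    path = Path(path)
    written = []
    df = values.copy()
    df.insert(0, "voxel_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)
    written.append(path)
    if format == "nifti":
        if mask is None:
            raise ValueError("NIfTI output requires a mask volume")
        mask = np.asarray(mask, dtype=bool)
        if coords is None:
            coords = np.argwhere(mask)
        if len(values) != coords.shape[0]:
            raise ValueError(
                f"{len(values)} value rows for {coords.shape[0]} in-mask voxels"
            )
        aff = np.eye(4) if affine is None else affine
        idx = tuple(coords.T)
        for name in values.columns:
            vol = np.full(mask.shape, BACKGROUND, dtype=np.float32)
            vol[idx] = values[name].to_numpy(dtype=np.float32)
            img = nib.Nifti1Image(vol, aff)
            out = path.with_name(f"{path.stem}_{name}.nii")
            nib.save(img, out)
            written.append(out)
        mask_img = nib.Nifti1Image(mask.astype(np.uint8), aff)
        mask_path = path.with_name(f"{path.stem}_mask.nii")
        nib.save(mask_img, mask_path)
        written.append(mask_path)
    elif format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    return written


def read_stat_map_nifti(path: str | Path, mask: np.ndarray | None = None) -> np.ndarray:
    """In-mask values of a statistic volume (mask defaults to finite sites)."""
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if mask is None:
        mask = np.isfinite(vol)
    return vol[np.asarray(mask, bool)]


def write_ground_truth(truth: GroundTruth, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    meta = {
        "grid_shape": list(truth.grid_shape),
        "n_voxels": int(truth.n_voxels),
        "classes": sorted(set(truth.voxel_class.tolist())),
    }
    json_path = stem.with_suffix(".json")
    npz_path = stem.with_suffix(".npz")
    json_path.write_text(json.dumps(meta, indent=1))
    np.savez(
        npz_path,
        true_weights=truth.true_weights,
        voxel_class=truth.voxel_class.astype("U"),
        true_hrf_index=truth.true_hrf_index,
        noise_sd=truth.noise_sd,
        onset_amplitude=truth.onset_amplitude,
        voxel_coords=truth.voxel_coords,
    )
    return json_path, npz_path


def write_predictor(predictor, stem: str | Path) -> tuple[Path, Path]:
    """Serialize a fitted dimension predictor as JSON header + array bundle."""
    stem = Path(stem)
    meta = {
        "n_features": int(predictor.n_features),
        "dim_labels": list(predictor.dim_labels),
    }
    json_path = stem.with_suffix(".json")
    npz_path = stem.with_suffix(".npz")
    json_path.write_text(json.dumps(meta, indent=1))
    np.savez(
        npz_path,
        coefficients=predictor.coefficients,
        intercepts=predictor.intercepts,
        chosen_penalty=predictor.chosen_penalty,
        cv_score=predictor.cv_score,
        feature_mean=predictor.feature_mean,
        feature_scale=predictor.feature_scale,
    )
    return json_path, npz_path


def read_predictor(stem: str | Path):
    from .embed import DimensionPredictor

    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    arrs = np.load(stem.with_suffix(".npz"))
    return DimensionPredictor(
        coefficients=arrs["coefficients"],
        intercepts=arrs["intercepts"],
        chosen_penalty=arrs["chosen_penalty"],
        cv_score=arrs["cv_score"],
        feature_mean=arrs["feature_mean"],
        feature_scale=arrs["feature_scale"],
        dim_labels=tuple(meta["dim_labels"]),
    )


def read_ground_truth(stem: str | Path) -> GroundTruth:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    arrs = np.load(stem.with_suffix(".npz"))
    return GroundTruth(
        true_weights=arrs["true_weights"],
        voxel_class=arrs["voxel_class"].astype(str),
        true_hrf_index=arrs["true_hrf_index"],
        noise_sd=arrs["noise_sd"],
        onset_amplitude=arrs["onset_amplitude"],
        grid_shape=tuple(meta["grid_shape"]),
        voxel_coords=arrs["voxel_coords"],
    )
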