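"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes the enabled stages in dependency order —
simulate -> embedding extension -> single-trial encoding / parametric
modulation -> profiles / sparseness / variance partitioning — on fully
synthetic data, writing each stage's tables to the output directory plus
a run manifest (resolved configuration, seeds, artifact checksums,
wall times) that fully determines every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from ._utils import derive_seed
from .embed import fit_dimension_predictor
from .hrf import build_hrf_library
from .modulation import cv_select_hyperparams, fit_modulation_weights
from .partition import partition_variance, select_diagnostic_dimensions
from .profiles import regional_profile, representative_images
from .sparseness import (hoyer_sparseness, noise_pool_mask, rectify_weights,
                         smooth_volume, sparse_clusters, sparseness_zmap)
from .synth import (SyntheticConfig, calibrate_noise_sd, generate_categories,
                    generate_embedding, generate_events, generate_ground_truth,
                    simulate_single_trial, simulate_timeseries)
from .trial import (bh_fdr, estimate_noise_ceiling, loso_cv_predict, nc_correct,
                    permutation_pvalues, repeat_response_array)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("synth", "embed", "encode", "modulate", "profiles", "sparseness", "partition")
DEPENDENCIES = {
    "embed": ("synth",),
    "encode": ("synth",),
    "modulate": ("synth",),
    "profiles": ("modulate",),
    "sparseness": ("modulate",),
    "partition": ("synth", "encode"),
}


def _strict_kwargs(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return data


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys are rejected on load; every random stage consumes a seed
    derived from ``seed`` so the manifest reproduces the run exactly.
    """

    output_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_images: int = 580
    n_voxels: int = 1000
    n_dims: int = 66
    n_sessions: int = 12
    trials_per_session: int = 120
    n_repeat_images: int = 100
    snr: float = 1.0
    n_perm: int = 1000
    fdr_q: float = 0.01
    n_categories: int = 20
    nc_floor: float = 0.02
    fwhm_mm: float = 4.0
    voxel_mm: float = 2.0
    min_noise_pool: int = 100
    n_features: int = 128
    output_format: str = "tsv"

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        for stage in self.stages:
            missing = [d for d in DEPENDENCIES.get(stage, ()) if d not in self.stages]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires disabled stage(s) {missing}"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**_strict_kwargs(cls, data, "config"))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seeds": {},
        "stages": {},
        "artifacts": {},
    }
    state: dict = {}

    def finish_stage(name: str, started: float, paths: list[Path]) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - started, 3)}
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)

    cfg = SyntheticConfig(
        n_images=config.n_images,
        n_voxels=config.n_voxels,
        n_dims=config.n_dims,
        n_sessions=config.n_sessions,
        trials_per_session=config.trials_per_session,
        n_repeat_images=config.n_repeat_images,
        seed=derive_seed(config.seed, 1),
    )

    if "synth" in config.stages:
        t = time.time()
        seed = derive_seed(config.seed, 2)
        manifest["seeds"]["synth"] = seed
        emb = generate_embedding(cfg.n_images, cfg.n_dims, cfg.seed)
        events = generate_events(cfg)
        truth = generate_ground_truth(cfg, emb)
        noiseless = simulate_single_trial(emb, events, truth, seed, noise_sd=0.0)
        noise_sd = calibrate_noise_sd(noiseless.amplitudes, snr=config.snr)
        responses = simulate_single_trial(emb, events, truth, seed, noise_sd=noise_sd)
        state.update(emb=emb, events=events, truth=truth, responses=responses,
                     noise_sd=noise_sd, synth_cfg=cfg)
        paths = [out / "embedding.tsv", out / "events.tsv"]
        oio.write_embedding_tsv(emb, paths[0])
        oio.write_events_tsv(events, paths[1])
        paths += list(oio.write_ground_truth(truth, out / "ground_truth"))
        finish_stage("synth", t, paths)

    if "embed" in config.stages:
        t = time.time()
        seed = derive_seed(config.seed, 3)
        manifest["seeds"]["embed"] = seed
        emb = state["emb"]
        rng = np.random.default_rng(seed)
        mixing = rng.normal(size=(emb.n_dims, config.n_features))
        features = emb.values @ mixing + 0.1 * rng.standard_normal(
            (emb.n_images, config.n_features)
        )
        predictor = fit_dimension_predictor(features, emb, seed=seed)
        df = pd.DataFrame({
            "dimension": list(emb.dim_labels),
            "chosen_penalty": predictor.chosen_penalty,
            "cv_score": predictor.cv_score,
        })
        p = out / "dimension_predictor_cv.tsv"
        df.to_csv(p, sep="\t", index=False)
        finish_stage("embed", t, [p])

    if "encode" in config.stages:
        t = time.time()
        seed = derive_seed(config.seed, 4)
        manifest["seeds"]["encode"] = seed
        emb, events, responses = state["emb"], state["events"], state["responses"]
        cv = loso_cv_predict(emb, events, responses)
        pvals = permutation_pvalues(cv, n_perm=config.n_perm, seed=seed)
        sig = bh_fdr(pvals, q=config.fdr_q)
        ceiling = estimate_noise_ceiling(repeat_response_array(responses))
        corrected = nc_correct(cv.cv_r2, ceiling.nc, config.nc_floor)
        state.update(cv=cv, ceiling=ceiling)
        paths = oio.write_stat_maps(
            {
                "cv_r": cv.cv_correlation, "cv_r2": cv.cv_r2, "p": pvals,
                "significant": sig.astype(int), "nc": ceiling.nc,
                "nc_corrected_r2": corrected,
            },
            out / "single_trial_encoding.tsv",
            mask=state["truth"].mask_volume(),
            coords=state["truth"].voxel_coords,
            format=config.output_format,
        )
        finish_stage("encode", t, paths)

    if "modulate" in config.stages:
        t = time.time()
        seed = derive_seed(config.seed, 5)
        manifest["seeds"]["modulate"] = seed
        emb, events, truth = state["emb"], state["events"], state["truth"]
        hrfs = build_hrf_library(cfg.tr_seconds, microtime_factor=cfg.microtime_factor)
        clean = simulate_timeseries(emb, events, truth, hrfs, cfg, seed, noise_sd=0.0)
        ts_noise_sd = calibrate_noise_sd(clean.data, snr=config.snr)
        ts = simulate_timeseries(emb, events, truth, hrfs, cfg, seed, noise_sd=ts_noise_sd)
        selection = cv_select_hyperparams(ts, events, emb, hrfs,
                                          n_folds=config.n_sessions)
        fit = fit_modulation_weights(ts, events, emb, hrfs, selection)
        state.update(modulation=fit, hrfs=hrfs)
        table = pd.DataFrame(fit.weights, columns=list(emb.dim_labels))
        table["chosen_hrf"] = fit.chosen_hrf
        table["chosen_fraction"] = fit.chosen_fraction
        table["cv_r2"] = fit.cv_r2
        paths = oio.write_stat_maps(
            table, out / "modulation_fit.tsv",
            mask=truth.mask_volume(), coords=truth.voxel_coords,
            format=config.output_format,
        )
        finish_stage("modulate", t, paths)

    if "profiles" in config.stages:
        t = time.time()
        emb, truth, fit = state["emb"], state["truth"], state["modulation"]
        rois = {
            "sparse_blob": truth.voxel_class == "sparse",
            "dense_blob": truth.voxel_class == "dense",
            "background": truth.voxel_class == "noise",
        }
        rows, rank_frames = [], []
        for name, mask in rois.items():
            prof = regional_profile(fit.weights, mask, region=name)
            rows.append([name, *prof.values])
            if prof.values.any():
                ranked = representative_images(prof, emb, k=10)
                ranked.insert(0, "region", name)
                rank_frames.append(ranked)
        p1 = out / "regional_profiles.tsv"
        pd.DataFrame(rows, columns=["region", *emb.dim_labels]).to_csv(
            p1, sep="\t", index=False
        )
        p2 = out / "representative_images.tsv"
        pd.concat(rank_frames).to_csv(p2, sep="\t", index=False)
        finish_stage("profiles", t, [p1, p2])

    if "sparseness" in config.stages:
        t = time.time()
        truth, fit = state["truth"], state["modulation"]
        mask = truth.mask_volume()
        smoothed = smooth_volume(fit.weights, mask, config.fwhm_mm, config.voxel_mm,
                                 coords=truth.voxel_coords)
        s = hoyer_sparseness(rectify_weights(smoothed), axis=1)
        pool = noise_pool_mask(fit.cv_r2)
        z, p = sparseness_zmap(s, pool, min_pool=config.min_noise_pool)
        clusters, labels = sparse_clusters(z, mask, min_size=5,
                                           coords=truth.voxel_coords)
        paths = oio.write_stat_maps(
            {"s": s, "z": z, "p": p, "noise_pool": pool.astype(int)},
            out / "sparseness.tsv", mask=mask, coords=truth.voxel_coords,
            format=config.output_format,
        )
        p_cl = out / "sparseness_clusters.tsv"
        clusters.to_csv(p_cl, sep="\t", index=False)
        finish_stage("sparseness", t, paths + [p_cl])

    if "partition" in config.stages:
        t = time.time()
        seed = derive_seed(config.seed, 6)
        manifest["seeds"]["partition"] = seed
        emb, events, responses = state["emb"], state["events"], state["responses"]
        cats = generate_categories(emb, config.n_categories, seed)
        mapping = select_diagnostic_dimensions(emb, cats)
        index = emb.row_index()
        rows = [index[i] for i in events["image_id"]]
        dim_X = emb.values[rows][:, mapping.unique_dimensions]
        cat_X = cats.membership[rows].astype(float)
        part = partition_variance(
            dim_X, cat_X, responses.amplitudes,
            events["session_id"].to_numpy(),
            nc=state["ceiling"].nc if "ceiling" in state else None,
            nc_floor=config.nc_floor,
        )
        p1 = out / "diagnostic_dimensions.tsv"
        pd.DataFrame({
            "category": list(cats.category_names),
            "chosen_dimension": mapping.best_dimension,
            "auc": mapping.auc,
        }).to_csv(p1, sep="\t", index=False)
        table = {
            "unique_dim": part.unique_dim, "unique_cat": part.unique_cat,
            "combined": part.combined, "shared": part.shared,
        }
        if part.shared_nc is not None:
            table.update(unique_dim_nc=part.unique_dim_nc,
                         unique_cat_nc=part.unique_cat_nc,
                         combined_nc=part.combined_nc, shared_nc=part.shared_nc)
        paths = oio.write_stat_maps(
            table, out / "variance_partition.tsv",
            mask=state["truth"].mask_volume(), coords=state["truth"].voxel_coords,
            format=config.output_format,
        )
        finish_stage("partition", t, [p1] + paths)

    manifest["total_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
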