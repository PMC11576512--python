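"""Parametric-modulation model on simulated BOLD time series.

Builds onset + 66 mean-centred modulator regressors, selects each voxel's
HRF (from a 20-kernel library) and fractional-ridge regularization level
by between-session cross-validation, and fits final dimension weights.
"""

import numpy as np

from objdim import (SyntheticConfig, build_hrf_library, calibrate_noise_sd,
                    cv_select_hyperparams, fit_modulation_weights,
                    generate_embedding, generate_events, generate_ground_truth,
                    simulate_timeseries)
from objdim._utils import rowwise_pearson

cfg = SyntheticConfig(n_images=340, n_voxels=64, n_sessions=12,
                      trials_per_session=120, n_repeat_images=100, seed=3)
emb = generate_embedding(cfg.n_images, cfg.n_dims, cfg.seed)
events = generate_events(cfg)
truth = generate_ground_truth(cfg, emb)
hrfs = build_hrf_library(cfg.tr_seconds)

clean = simulate_timeseries(emb, events, truth, hrfs, cfg, seed=3, noise_sd=0.0)
sd = calibrate_noise_sd(clean.data, snr=1.0)
ts = simulate_timeseries(emb, events, truth, hrfs, cfg, seed=3, noise_sd=sd)

selection = cv_select_hyperparams(ts, events, emb, hrfs, n_folds=12)
fit = fit_modulation_weights(ts, events, emb, hrfs, selection)

sig = truth.voxel_class != "noise"
hit = np.mean(selection.hrf_index[sig] == truth.true_hrf_index[sig])
cc = rowwise_pearson(fit.weights[sig], truth.true_weights[sig])
print(f"scans: {ts.n_scans} over {cfg.n_sessions} sessions "
      f"(TR = {cfg.tr_seconds} s)")
print(f"HRF recovered exactly for {hit:.0%} of signal voxels")
print(f"median chosen ridge fraction (signal voxels): "
      f"{np.median(selection.fraction[sig]):.2f}")
print(f"weight correlation with ground truth: median {np.median(cc):.3f}")
print(f"cross-validated R^2: signal {np.median(selection.cv_r2[sig]):.3f}, "
      f"noise {np.median(selection.cv_r2[~sig]):.3f}")
print("-> a ridge fraction near 1 means little shrinkage was needed, and")
print("   noise voxels near R^2 = 0 form the later sparseness null pool.")
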