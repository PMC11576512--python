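"""Single-trial encoding model with permutation statistics.

Fits the 66 dimensions to trial response amplitudes by OLS, evaluates
leave-one-session-out predictions, and flags significant voxels by a
permutation null with FDR correction and noise-ceiling-corrected R^2.
"""

import numpy as np

from objdim import (SyntheticConfig, bh_fdr, calibrate_noise_sd,
                    estimate_noise_ceiling, generate_embedding, generate_events,
                    generate_ground_truth, loso_cv_predict, nc_correct,
                    permutation_pvalues, repeat_response_array,
                    simulate_single_trial)

cfg = SyntheticConfig(n_images=340, n_voxels=100, n_sessions=12,
                      trials_per_session=120, n_repeat_images=100, seed=2)
emb = generate_embedding(cfg.n_images, cfg.n_dims, cfg.seed)
events = generate_events(cfg)
truth = generate_ground_truth(cfg, emb)
clean = simulate_single_trial(emb, events, truth, seed=2, noise_sd=0.0)
sd = calibrate_noise_sd(clean.amplitudes, snr=1.0)
responses = simulate_single_trial(emb, events, truth, seed=2, noise_sd=sd)

cv = loso_cv_predict(emb, events, responses)
p = permutation_pvalues(cv, n_perm=1000, seed=2)
significant = bh_fdr(p, q=0.01)
nc = estimate_noise_ceiling(repeat_response_array(responses)).nc
corrected = nc_correct(cv.cv_r2, nc)

sig = truth.voxel_class != "noise"
print(f"held-out correlation: signal voxels {np.median(cv.cv_correlation[sig]):.3f}, "
      f"noise voxels {np.median(cv.cv_correlation[~sig]):.3f}")
print(f"FDR-significant voxels: {significant.sum()} of {cfg.n_voxels} "
      f"({(significant & sig).sum()} true signal, "
      f"{(significant & ~sig).sum()} false positives)")
print(f"median noise-ceiling-corrected R^2 of significant voxels: "
      f"{np.nanmedian(corrected[significant]):.3f}")
print("-> corrected R^2 near 1 means the model explains almost all the")
print("   explainable (non-noise) variance in those voxels.")
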