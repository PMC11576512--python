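"""Compare dimension-based and category-based encoding models.

Selects each category's most diagnostic dimension by AUC, then splits
cross-validated explained variance into portions unique to the dimension
model, unique to the category model, and shared.
"""

import numpy as np

from objdim import (SyntheticConfig, calibrate_noise_sd, generate_categories,
                    generate_embedding, generate_events, generate_ground_truth,
                    partition_variance, select_diagnostic_dimensions,
                    simulate_single_trial)

cfg = SyntheticConfig(n_images=340, n_voxels=80, n_sessions=12,
                      trials_per_session=120, n_repeat_images=100, seed=5)
emb = generate_embedding(cfg.n_images, cfg.n_dims, cfg.seed)
events = generate_events(cfg)
truth = generate_ground_truth(cfg, emb)
clean = simulate_single_trial(emb, events, truth, seed=5, noise_sd=0.0)
responses = simulate_single_trial(
    emb, events, truth, seed=5,
    noise_sd=calibrate_noise_sd(clean.amplitudes, snr=2.0))

cats = generate_categories(emb, 20, seed=5, flip_rate=0.05)
mapping = select_diagnostic_dimensions(emb, cats)
print(f"{len(cats.category_names)} categories map onto "
      f"{len(mapping.unique_dimensions)} distinct diagnostic dimensions "
      f"(median AUC {np.median(mapping.auc):.3f})")

idx = emb.row_index()
rows = [idx[i] for i in events["image_id"]]
dim_X = emb.values[rows][:, mapping.unique_dimensions]
cat_X = cats.membership[rows].astype(float)
part = partition_variance(dim_X, cat_X, responses.amplitudes,
                          events["session_id"].to_numpy())

sig = truth.voxel_class != "noise"
print(f"signal voxels, median cross-validated R^2:")
print(f"  unique to dimensions: {np.median(part.unique_dim[sig]):+.3f}")
print(f"  unique to categories: {np.median(part.unique_cat[sig]):+.3f}")
print(f"  shared:               {np.median(part.shared[sig]):+.3f}")
print(f"  combined:             {np.median(part.combined[sig]):+.3f}")
print("-> responses were generated from all 66 continuous dimensions; the")
print("   30-or-fewer diagnostic dimensions explain the most unique variance,")
print("   while the binary categories pick up part of the remainder.")
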