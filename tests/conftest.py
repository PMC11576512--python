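import numpy as np
import pytest

from objdim import (SyntheticConfig, build_hrf_library, generate_embedding,
                    generate_events, generate_ground_truth, simulate_single_trial)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(
        n_images=160, n_voxels=27, n_dims=66, n_sessions=4,
        trials_per_session=40, n_repeat_images=20, seed=7,
        frac_sparse_voxels=0.3, frac_dense_voxels=0.3, frac_noise_voxels=0.4,
    )


@pytest.fixture(scope="session")
def small_embedding(small_cfg):
    return generate_embedding(small_cfg.n_images, small_cfg.n_dims, small_cfg.seed)


@pytest.fixture(scope="session")
def small_events(small_cfg):
    return generate_events(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_embedding):
    return generate_ground_truth(small_cfg, small_embedding)


@pytest.fixture(scope="session")
def small_responses(small_embedding, small_events, small_truth):
    return simulate_single_trial(small_embedding, small_events, small_truth, seed=7)


@pytest.fixture(scope="session")
def hrfs():
    return build_hrf_library(1.5)
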