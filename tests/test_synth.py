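"""Generator contracts: determinism, sparsity structure, signal identities."""

import numpy as np
import pandas as pd
import pytest

from objdim import (SyntheticConfig, build_hrf_library, calibrate_noise_sd,
                    estimate_noise_ceiling, generate_categories,
                    generate_embedding, generate_events, generate_ground_truth,
                    repeat_response_array, simulate_single_trial,
                    simulate_timeseries)
from objdim.sparseness import hoyer_sparseness, rectify_weights


class TestEmbedding:
    def test_deterministic_and_nonnegative(self):
        a = generate_embedding(100, 66, seed=1)
        b = generate_embedding(100, 66, seed=1)
        assert np.array_equal(a.values, b.values)
        assert a.values.min() >= 0
        assert not np.any(np.all(a.values == 0, axis=1))

    def test_column_scales_non_increasing(self):
        emb = generate_embedding(300, 66, seed=2)
        stds = emb.values.std(axis=0)
        assert np.all(np.diff(stds) <= 1e-12)

    def test_zero_fraction_matches_truncation(self):
        emb = generate_embedding(2000, 66, seed=3, zero_fraction=0.6)
        frac0 = np.mean(emb.values == 0)
        assert abs(frac0 - 0.6) < 0.1

    def test_row_sparsity_at_least_half(self):
        emb = generate_embedding(500, 66, seed=4)
        assert np.mean((emb.values == 0).mean(axis=1)) >= 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_embedding(1, 66, seed=0)
        with pytest.raises(ValueError):
            generate_embedding(10, 0, seed=0)


class TestEvents:
    def test_repeats_once_per_session(self, small_cfg, small_events):
        rep = small_events[small_events["is_repeat"]]
        counts = rep.groupby("image_id").size()
        assert len(counts) == small_cfg.n_repeat_images
        assert (counts == small_cfg.n_sessions).all()
        per_sess = rep.groupby(["session_id", "image_id"]).size()
        assert (per_sess == 1).all()

    def test_onset_spacing_and_monotonicity(self, small_cfg, small_events):
        for _, g in small_events.groupby("session_id"):
            onsets = g["onset_seconds"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
            assert np.allclose(np.diff(onsets), small_cfg.trial_spacing_seconds)

    def test_non_repeats_unique_across_experiment(self, small_events):
        singles = small_events[~small_events["is_repeat"]]
        assert singles["image_id"].is_unique

    def test_deterministic(self, small_cfg):
        a = generate_events(small_cfg)
        b = generate_events(small_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            generate_events(SyntheticConfig(n_images=200, n_voxels=8,
                                            trials_per_session=10,
                                            n_repeat_images=20))


class TestGroundTruth:
    def test_class_counts_and_weight_structure(self, small_cfg, small_truth):
        counts = pd.Series(small_truth.voxel_class).value_counts()
        for frac, name in [(0.3, "sparse"), (0.3, "dense"), (0.4, "noise")]:
            assert abs(counts[name] - frac * small_cfg.n_voxels) <= 1
        nnz = np.count_nonzero(small_truth.true_weights, axis=1)
        assert nnz[small_truth.voxel_class == "sparse"].max() <= 2
        assert nnz[small_truth.voxel_class == "dense"].min() >= 22
        assert nnz[small_truth.voxel_class == "noise"].max() == 0

    def test_all_noise_proportion_gives_zero_weights(self, small_embedding):
        cfg = SyntheticConfig(n_images=160, n_voxels=10, frac_sparse_voxels=0,
                              frac_dense_voxels=0, frac_noise_voxels=1,
                              trials_per_session=120, n_repeat_images=100)
        truth = generate_ground_truth(cfg, small_embedding)
        assert np.all(truth.true_weights == 0)

    def test_sparse_rows_sparser_than_dense(self, small_truth):
        s = hoyer_sparseness(rectify_weights(small_truth.true_weights), axis=1)
        s_sparse = np.nanmean(s[small_truth.voxel_class == "sparse"])
        s_dense = np.nanmean(s[small_truth.voxel_class == "dense"])
        assert s_sparse > s_dense


class TestSingleTrial:
    def test_noiseless_reproduces_linear_model(self, small_embedding, small_events,
                                               small_truth):
        resp = simulate_single_trial(small_embedding, small_events, small_truth,
                                     seed=0, noise_sd=0.0)
        idx = small_embedding.row_index()
        X = small_embedding.values[[idx[i] for i in small_events["image_id"]]]
        expected = X @ small_truth.true_weights.T
        assert np.allclose(resp.amplitudes, expected, atol=1e-12)

    def test_repeat_images_identical_when_noiseless(self, small_embedding,
                                                    small_events, small_truth):
        resp = simulate_single_trial(small_embedding, small_events, small_truth,
                                     seed=0, noise_sd=0.0)
        arr = repeat_response_array(resp)
        assert np.allclose(arr, arr[0])

    def test_noise_variance_matches_configuration(self, small_embedding):
        cfg = SyntheticConfig(n_images=1060, n_voxels=5, n_sessions=12,
                              trials_per_session=180, n_repeat_images=100,
                              frac_sparse_voxels=0, frac_dense_voxels=0,
                              frac_noise_voxels=1, noise_sd=1.0, seed=3)
        emb = generate_embedding(cfg.n_images, 66, 3)
        truth = generate_ground_truth(cfg, emb)
        resp = simulate_single_trial(emb, generate_events(cfg), truth, seed=3)
        var = resp.amplitudes.var(axis=0)
        assert np.all(np.abs(var - 1.0) < 0.1)

    def test_unknown_image_raises(self, small_embedding, small_events, small_truth):
        bad = small_events.copy()
        bad.loc[0, "image_id"] = "img_99999"
        with pytest.raises(KeyError):
            simulate_single_trial(small_embedding, bad, small_truth, seed=0)

    def test_noise_ceiling_monotone_in_noise_level(self, small_embedding,
                                                   small_events, small_truth):
        """Lower noise must yield a higher empirical noise ceiling."""
        ncs = []
        for sd in (2.0, 1.0, 0.5):
            resp = simulate_single_trial(small_embedding, small_events,
                                         small_truth, seed=11, noise_sd=sd)
            nc = estimate_noise_ceiling(repeat_response_array(resp)).nc
            sig = small_truth.voxel_class != "noise"
            ncs.append(np.median(nc[sig]))
        assert ncs[0] < ncs[1] < ncs[2]


class TestTimeSeries:
    def test_zero_everything_gives_zero_series(self, small_embedding, hrfs):
        cfg = SyntheticConfig(n_images=160, n_voxels=4, n_sessions=2,
                              trials_per_session=30, n_repeat_images=10, seed=5,
                              frac_sparse_voxels=0, frac_dense_voxels=0,
                              frac_noise_voxels=1)
        truth = generate_ground_truth(cfg, small_embedding)
        ts = simulate_timeseries(small_embedding, generate_events(cfg), truth,
                                 hrfs, cfg, seed=5, noise_sd=0.0)
        # noise-class voxels carry no onset response either
        assert np.allclose(ts.data, 0.0)

    def test_onset_only_voxels_equal_scaled_onset_regressor(self, small_embedding, hrfs):
        from objdim.modulation import build_design_matrix
        cfg = SyntheticConfig(n_images=160, n_voxels=4, n_sessions=2,
                              trials_per_session=30, n_repeat_images=10, seed=5,
                              frac_sparse_voxels=0, frac_dense_voxels=0,
                              frac_noise_voxels=1, onset_amplitude=2.5)
        truth = generate_ground_truth(cfg, small_embedding)
        truth = type(truth)(truth.true_weights, truth.voxel_class,
                            truth.true_hrf_index, truth.noise_sd,
                            np.full(cfg.n_voxels, 2.5), truth.grid_shape,
                            truth.voxel_coords)
        events = generate_events(cfg)
        ts = simulate_timeseries(small_embedding, events, truth, hrfs, cfg,
                                 seed=5, noise_sd=0.0)
        for v in range(cfg.n_voxels):
            h = truth.true_hrf_index[v]
            scan_counts = {s: sl.stop - sl.start
                           for s, sl in ts.session_slices().items()}
            design = build_design_matrix(
                events, small_embedding, hrfs.kernels[h], tr=cfg.tr_seconds,
                scan_counts=scan_counts, include_session_intercepts=False)
            assert np.allclose(ts.data[:, v], 2.5 * design.X[:, 0], atol=1e-10)

    def test_single_event_impulse_response(self, hrfs):
        """One microtime-sample event at t=0 reproduces the sampled kernel."""
        from objdim.synth import DimensionEmbedding, GroundTruth
        emb = DimensionEmbedding(np.ones((2, 2)), ("a", "b"), ("d0", "d1"))
        events = pd.DataFrame({
            "trial_index": [0], "session_id": [0], "onset_seconds": [0.0],
            "image_id": ["a"], "is_repeat": [False],
        })
        cfg = SyntheticConfig(n_images=2, n_voxels=1, n_dims=2, n_sessions=1,
                              trials_per_session=1, n_repeat_images=1,
                              event_duration_seconds=0.15)
        truth = GroundTruth(np.zeros((1, 2)), np.array(["noise"]),
                            np.array([0]), np.zeros(1), np.ones(1),
                            (1, 1, 1), np.array([[0, 0, 0]]))
        ts = simulate_timeseries(emb, events, truth, hrfs, cfg, seed=0,
                                 noise_sd=0.0)
        kernel_at_scans = hrfs.kernels[0][:: hrfs.microtime_factor]
        n = min(ts.n_scans, kernel_at_scans.size)
        assert np.allclose(ts.data[:n, 0], kernel_at_scans[:n], atol=1e-10)

    def test_bad_hrf_index_raises(self, small_embedding, small_events, small_truth,
                                  hrfs):
        bad = type(small_truth)(small_truth.true_weights, small_truth.voxel_class,
                                np.full(small_truth.n_voxels, 99),
                                small_truth.noise_sd, small_truth.onset_amplitude,
                                small_truth.grid_shape, small_truth.voxel_coords)
        cfg = SyntheticConfig(n_images=160, n_voxels=27, n_sessions=4,
                              trials_per_session=40, n_repeat_images=20)
        with pytest.raises(IndexError):
            simulate_timeseries(small_embedding, small_events, bad, hrfs, cfg, 0)


class TestCategories:
    def test_generating_dimension_perfectly_diagnostic_without_flips(
            self, small_embedding):
        from objdim import dimension_auc
        cats = generate_categories(small_embedding, 5, seed=1, flip_rate=0.0)
        for c, d in enumerate(cats.generating_dimension):
            auc = dimension_auc(small_embedding.values[:, d], cats.membership[:, c])
            assert auc == 1.0

    def test_membership_binary_and_shared_dimension_allowed(self, small_embedding):
        dims = np.array([3, 3, 10])
        cats = generate_categories(small_embedding, 3, seed=2,
                                   generating_dims=dims)
        assert set(np.unique(cats.membership)) <= {0, 1}
        assert list(cats.generating_dimension) == [3, 3, 10]

    def test_calibrate_noise_sd_hits_target_ceiling(self, small_embedding,
                                                    small_events, small_truth):
        clean = simulate_single_trial(small_embedding, small_events, small_truth,
                                      seed=0, noise_sd=0.0)
        sd = calibrate_noise_sd(clean.amplitudes, noise_ceiling=0.5)
        sig = small_truth.voxel_class != "noise"
        achieved = clean.amplitudes.std(axis=0)[sig] ** 2 / (
            clean.amplitudes.std(axis=0)[sig] ** 2 + sd[sig] ** 2)
        assert np.allclose(achieved, 0.5, atol=1e-12)
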