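"""HRF library, design construction, fractional ridge and hyperparameter CV."""

import numpy as np
import pandas as pd
import pytest

from objdim import (DEFAULT_FRACTIONS, SyntheticConfig, build_design_matrix,
                    build_hrf_library, cv_select_hyperparams, fractional_ridge,
                    fit_modulation_weights, generate_events,
                    generate_ground_truth, simulate_timeseries)
from objdim.synth import DimensionEmbedding


class TestHRFLibrary:
    def test_size_and_peak_normalization(self, hrfs):
        assert len(hrfs) == 20
        assert np.allclose(hrfs.kernels.max(axis=1), 1.0)

    def test_peak_time_ordering(self, hrfs):
        """The library is ordered by realized time-to-peak: the argmax
        sample index is non-decreasing along the library, and the nominal
        peak parameter is non-decreasing with it."""
        argmax = hrfs.kernels.argmax(axis=1)
        assert np.all(np.diff(argmax) >= 0)
        assert np.all(np.diff(hrfs.params["time_to_peak"]) >= 0)

    def test_parameter_grid(self, hrfs):
        assert hrfs.params["time_to_peak"].nunique() == 10
        assert hrfs.params["undershoot_ratio"].nunique() == 2


@pytest.fixture(scope="module")
def tiny_embedding():
    rng = np.random.default_rng(0)
    vals = np.maximum(0.0, rng.exponential(1.0, size=(40, 6)) - 0.5)
    vals[np.all(vals == 0, axis=1), 0] = 1.0
    return DimensionEmbedding(vals, tuple(f"img_{i:05d}" for i in range(40)),
                              tuple(f"d{j}" for j in range(6)))


@pytest.fixture(scope="module")
def tiny_events():
    rows = []
    t = 0
    for s in range(2):
        for k in range(20):
            rows.append((t, s, 4.5 * k, f"img_{(s * 20 + k):05d}", False))
            t += 1
    return pd.DataFrame(rows, columns=["trial_index", "session_id",
                                       "onset_seconds", "image_id", "is_repeat"])


class TestDesignMatrix:
    def test_modulators_centred_and_constant_column_vanishes(
            self, tiny_events, hrfs):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 1.0, size=(40, 3))
        vals[:, 2] = 0.7  # constant dimension
        emb = DimensionEmbedding(vals, tuple(f"img_{i:05d}" for i in range(40)),
                                 ("a", "b", "c"))
        design = build_design_matrix(tiny_events, emb, hrfs.kernels[0], tr=1.5,
                                     scan_counts={0: 70, 1: 70})
        assert np.allclose(design.event_modulators.sum(axis=0), 0, atol=1e-10)
        col_c = design.X[:, design.column_names.index("c")]
        assert np.allclose(col_c, 0.0, atol=1e-12)

    def test_column_count(self, tiny_embedding, tiny_events, hrfs):
        design = build_design_matrix(tiny_events, tiny_embedding, hrfs.kernels[0],
                                     tr=1.5, scan_counts={0: 70, 1: 70})
        assert design.X.shape[1] == 1 + 6 + 2
        assert design.penalized.sum() == 7

    def test_impulse_event_reproduces_kernel(self, hrfs):
        emb = DimensionEmbedding(np.ones((1, 2)), ("img_00000",), ("a", "b"))
        events = pd.DataFrame({"trial_index": [0], "session_id": [0],
                               "onset_seconds": [0.0],
                               "image_id": ["img_00000"], "is_repeat": [False]})
        design = build_design_matrix(events, emb, hrfs.kernels[3], tr=1.5,
                                     scan_counts={0: 20}, event_duration=0.15,
                                     include_session_intercepts=False)
        expected = hrfs.kernels[3][:: hrfs.microtime_factor][:20]
        assert np.allclose(design.X[:, 0], expected, atol=1e-12)

    def test_event_outside_window_raises(self, tiny_embedding, tiny_events, hrfs):
        with pytest.raises(ValueError, match="outside"):
            build_design_matrix(tiny_events, tiny_embedding, hrfs.kernels[0],
                                tr=1.5, scan_counts={0: 10, 1: 10})


class TestFractionalRidge:
    def test_fraction_one_is_ols(self):
        rng = np.random.default_rng(0)
        X, Y = rng.normal(size=(100, 12)), rng.normal(size=(100, 4))
        coef = fractional_ridge(X, Y, np.array([1.0]))[0]
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(coef, ols, atol=1e-6)

    def test_orthonormal_closed_form(self):
        """For an orthonormal design the penalty is (1-f)/f and the solution
        is OLS / (1 + lambda)."""
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(60, 8)))
        y = rng.normal(size=(60, 2))
        fr = np.array([0.2, 0.5, 0.8])
        coefs = fractional_ridge(Q, y, fr)
        ols = Q.T @ y
        for i, f in enumerate(fr):
            lam = (1 - f) / f
            assert np.allclose(coefs[i], ols / (1 + lam), atol=1e-6)

    def test_achieved_fraction_tracks_request(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 30))
        Y = rng.normal(size=(150, 6))
        coefs = fractional_ridge(X, Y)
        ols_norm = np.linalg.norm(np.linalg.lstsq(X, Y, rcond=None)[0], axis=0)
        for i, f in enumerate(DEFAULT_FRACTIONS):
            ach = np.linalg.norm(coefs[i], axis=0) / ols_norm
            assert np.all(np.abs(ach - f) < 1e-3)

    def test_norm_strictly_increasing_in_fraction(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(80, 10)), rng.normal(size=80)
        coefs = fractional_ridge(X, y, np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.0]))
        norms = np.linalg.norm(coefs[:, :, 0], axis=1)
        assert np.all(np.diff(norms) > 0)

    def test_unpenalized_columns_exact_at_f1_and_excluded_from_norm(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=(120, 9)), np.ones(120)])
        y = X @ np.r_[rng.normal(size=9), 5.0] + 0.1 * rng.normal(size=120)
        coefs = fractional_ridge(X, y, np.array([0.5, 1.0]), unpenalized=[9])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(coefs[1, :, 0], ols, atol=1e-6)
        ach = np.linalg.norm(coefs[0, :9, 0]) / np.linalg.norm(ols[:9])
        assert abs(ach - 0.5) < 1e-3

    def test_zero_target_warns_and_returns_zero(self):
        X = np.random.default_rng(5).normal(size=(30, 4))
        with pytest.warns(UserWarning, match="zero"):
            coefs = fractional_ridge(X, np.zeros(30), np.array([0.5, 1.0]))
        assert np.allclose(coefs, 0.0)

    def test_invalid_fractions_rejected(self):
        X = np.eye(4)
        with pytest.raises(ValueError):
            fractional_ridge(X, np.ones(4), np.array([0.0, 0.5]))

    def test_default_grid_has_19_unique_values(self):
        assert len(DEFAULT_FRACTIONS) == 19
        assert DEFAULT_FRACTIONS.min() == pytest.approx(0.1)
        assert DEFAULT_FRACTIONS.max() == 1.0


@pytest.fixture(scope="module")
def modulation_sim(hrfs):
    """Small time-series study with known HRFs and weights, SNR 2."""
    from objdim import calibrate_noise_sd, generate_embedding
    cfg = SyntheticConfig(n_images=190, n_voxels=24, n_dims=12, n_sessions=4,
                          trials_per_session=55, n_repeat_images=10, seed=21,
                          frac_sparse_voxels=0.25, frac_dense_voxels=0.5,
                          frac_noise_voxels=0.25)
    emb = generate_embedding(cfg.n_images, cfg.n_dims, cfg.seed)
    events = generate_events(cfg)
    truth = generate_ground_truth(cfg, emb)
    clean = simulate_timeseries(emb, events, truth, hrfs, cfg, seed=21,
                                noise_sd=0.0)
    sd = calibrate_noise_sd(clean.data, snr=2.0)
    ts = simulate_timeseries(emb, events, truth, hrfs, cfg, seed=21, noise_sd=sd)
    return cfg, emb, events, truth, ts, clean


class TestHyperparameterCV:
    fractions = np.array([0.2, 0.5, 0.8, 0.95, 1.0])

    def test_hrf_recovered_and_null_voxels_near_zero(self, modulation_sim, hrfs):
        cfg, emb, events, truth, ts, _ = modulation_sim
        sel = cv_select_hyperparams(ts, events, emb, hrfs,
                                    fractions=self.fractions, n_folds=4)
        sig = truth.voxel_class != "noise"
        assert np.mean(sel.hrf_index[sig] == truth.true_hrf_index[sig]) >= 0.75
        assert np.all(np.abs(sel.cv_r2[~sig]) < 0.05)
        assert np.isin(sel.fraction, self.fractions).all()

    def test_noiseless_data_selects_no_shrinkage(self, modulation_sim, hrfs):
        cfg, emb, events, truth, _, clean = modulation_sim
        sel = cv_select_hyperparams(clean, events, emb, hrfs,
                                    fractions=self.fractions, n_folds=4)
        sig = truth.voxel_class != "noise"
        assert np.all(sel.fraction[sig] == 1.0)

    def test_fold_structure_validated(self, modulation_sim, hrfs):
        cfg, emb, events, truth, ts, _ = modulation_sim
        with pytest.raises(ValueError):
            cv_select_hyperparams(ts, events, emb, hrfs, n_folds=5)

    def test_noiseless_weight_recovery(self, modulation_sim, hrfs):
        from objdim._utils import rowwise_pearson
        cfg, emb, events, truth, _, clean = modulation_sim
        sel = cv_select_hyperparams(clean, events, emb, hrfs,
                                    fractions=np.array([1.0]), n_folds=4)
        fit = fit_modulation_weights(clean, events, emb, hrfs, sel)
        sig = truth.voxel_class != "noise"
        cc = rowwise_pearson(fit.weights[sig], truth.true_weights[sig])
        assert np.all(cc > 0.99)

    def test_sign_recovery_under_noise(self, modulation_sim, hrfs):
        cfg, emb, events, truth, ts, _ = modulation_sim
        sel = cv_select_hyperparams(ts, events, emb, hrfs,
                                    fractions=self.fractions, n_folds=4)
        fit = fit_modulation_weights(ts, events, emb, hrfs, sel)
        nz = truth.true_weights != 0
        agree = np.sign(fit.weights[nz]) == np.sign(truth.true_weights[nz])
        assert agree.mean() >= 0.95

    def test_all_zero_series_gives_zero_weights(self, modulation_sim, hrfs):
        from objdim.synth import TimeSeries
        cfg, emb, events, truth, ts, _ = modulation_sim
        zero = TimeSeries(np.zeros_like(ts.data), ts.session_ids, ts.tr_seconds)
        sel = cv_select_hyperparams(zero, events, emb, hrfs,
                                    fractions=np.array([0.5, 1.0]), n_folds=4)
        with pytest.warns(UserWarning):
            fit = fit_modulation_weights(zero, events, emb, hrfs, sel)
        assert np.allclose(fit.weights, 0.0)
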