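"""Split arithmetic, PLS compression, LM network training, metrics."""

import numpy as np
import pandas as pd
import pytest

from meatmsi.chemometrics import (DEFAULT_GRID, cv_percent, config_seed,
                                  evaluate, fit_pls, grid_search,
                                  normalize_and_center, normalize_histograms,
                                  pls_scores, split_data, summarize_targets,
                                  train_pls_ann)
from meatmsi.morphometry import FeatureCube
from meatmsi.nnet import ANNConfig, train_ann


def make_cube(values, feature_name="orientation"):
    values = np.asarray(values, dtype=float)
    n_bins = values.shape[1]
    edges = np.tile(np.linspace(0, 1, n_bins + 1), (values.shape[2], 1))
    return FeatureCube(values=values, feature_name=feature_name,
                       n_bins=n_bins, bin_edges=edges)


class TestSplit:
    def test_study_sizes(self):
        s = split_data(240, seed=0)
        assert (len(s.train), len(s.val), len(s.test)) == (168, 36, 36)

    def test_rounding_rule(self):
        s = split_data(10, seed=1)
        assert (len(s.train), len(s.val), len(s.test)) == (7, 2, 1)

    @pytest.mark.parametrize("n,seed", [(7, 0), (17, 5), (100, 9),
                                        (241, 3)])
    def test_partition_property(self, n, seed):
        s = split_data(n, seed)
        joined = np.sort(np.concatenate([s.train, s.val, s.test]))
        np.testing.assert_array_equal(joined, np.arange(n))

    def test_same_seed_same_partition(self):
        a, b = split_data(50, 7), split_data(50, 7)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_data(2, 0)


class TestNormalizeAndCenter:
    def test_equal_counts_uniform(self):
        cube = make_cube(np.full((2, 5, 3), 2.0))
        X = normalize_histograms(cube)
        np.testing.assert_allclose(X, 1 / 15)

    def test_identical_samples_center_to_zero(self):
        cube = make_cube(np.tile(np.arange(12.0).reshape(1, 4, 3), (3, 1, 1)))
        X, _ = normalize_and_center(cube)
        np.testing.assert_allclose(X, 0, atol=1e-15)

    def test_training_column_means_zero(self, rng):
        cube = make_cube(rng.integers(0, 9, (8, 6, 2)).astype(float))
        train = np.array([0, 2, 4, 6])
        X, _ = normalize_and_center(cube, train_idx=train)
        np.testing.assert_allclose(X[train].mean(axis=0), 0, atol=1e-12)

    def test_unfolding_is_band_major(self):
        values = np.zeros((2, 4, 3))
        values[0, 1, 2] = 5.0           # sample 0, bin 1, band 2
        with pytest.warns(UserWarning):
            X = normalize_histograms(make_cube(values))
        assert X[0, 2 * 4 + 1] == 1.0   # band 2 block, offset bin 1

    def test_empty_sample_warns_and_stays_zero(self):
        values = np.zeros((2, 3, 2))
        values[0, 0, 0] = 4
        with pytest.warns(UserWarning, match="empty"):
            X = normalize_histograms(make_cube(values))
        assert not X[1].any()


class TestPLS:
    def test_full_rank_explains_everything(self, rng):
        A = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 40))
        A -= A.mean(axis=0)
        y = rng.normal(size=30)
        model = fit_pls(A, y, 2)
        ev = model.explained_x_variance
        assert ev[-1] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(ev) >= -1e-12)

    def test_linear_target_reproduced(self, rng):
        X = rng.normal(size=(25, 8))
        X -= X.mean(axis=0)
        beta = rng.normal(size=8)
        y = X @ beta
        model = fit_pls(X, y, 8)
        S = pls_scores(model, X)
        A = np.c_[S, np.ones(len(S))]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r2, _ = evaluate(y, A @ coef)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_first_weight_is_dominant_eigenvector(self, rng):
        """First PLS1 weight equals the dominant eigenvector of X'yy'X."""
        X = rng.normal(size=(20, 50))
        X -= X.mean(axis=0)
        y = rng.normal(size=20)
        model = fit_pls(X, y, 3)
        M = np.outer(X.T @ y, X.T @ y)      # X' y y' X
        eigvals, eigvecs = np.linalg.eigh(M)
        v = eigvecs[:, -1]
        w = model.weights[:, 0]
        assert min(np.abs(w - v).max(), np.abs(w + v).max()) < 1e-8

    def test_excess_components_name_achievable_rank(self, rng):
        A = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 40))
        with pytest.raises(ValueError, match="rank 2"):
            fit_pls(A - A.mean(0), rng.normal(size=30), 5)


class TestTrainANN:
    def test_constant_target_learned_exactly(self, rng):
        S = rng.normal(size=(40, 10))
        y = np.full(40, 3.3)
        net, _ = train_ann(S[:30], y[:30], S[30:], y[30:],
                           ANNConfig(3, 3, seed=1))
        rmse = np.sqrt(np.mean((net.predict(S[:30]) - y[:30]) ** 2))
        assert rmse <= 1e-6

    def test_noiseless_linear_target(self, rng):
        """An OLS oracle attains R^2 = 1; the network must approach it."""
        S = rng.normal(size=(180, 10))
        y = S @ rng.normal(size=10) + 0.5
        net, _ = train_ann(S[:126], y[:126], S[126:153], y[126:153],
                           ANNConfig(6, 4, seed=0))
        r2, _ = evaluate(y[153:], net.predict(S[153:]))
        assert r2 >= 0.999

    def test_deterministic(self, rng):
        S = rng.normal(size=(60, 10))
        y = np.tanh(S[:, 0]) + 0.3 * S[:, 1]
        runs = [train_ann(S[:40], y[:40], S[40:], y[40:],
                          ANNConfig(4, 3, seed=9, max_epochs=50))
                for _ in range(2)]
        for attr in ("W1", "b1", "W2", "b2", "w3"):
            np.testing.assert_array_equal(getattr(runs[0][0], attr),
                                          getattr(runs[1][0], attr))
        assert runs[0][1] == runs[1][1]

    def test_training_loss_monotone(self, rng):
        """Accepted LM steps can only decrease the training SSE, so the
        final training error never exceeds the initial one."""
        S = rng.normal(size=(50, 10))
        y = S[:, 0] ** 2
        cfg = ANNConfig(3, 2, seed=4, max_epochs=30)
        net, _ = train_ann(S[:40], y[:40], S[40:], y[40:], cfg)
        fresh = type(net)(10, cfg)
        fresh.y_mean, fresh.y_scale = net.y_mean, net.y_scale
        sse0 = np.sum((fresh.predict(S[:40]) - y[:40]) ** 2)
        sse1 = np.sum((net.predict(S[:40]) - y[:40]) ** 2)
        assert sse1 <= sse0 + 1e-12

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ANNConfig(0, 3)
        with pytest.raises(ValueError):
            ANNConfig(3, 3, max_epochs=2000)


class TestEvaluate:
    def test_perfect_prediction(self):
        r2, rmse = evaluate(np.array([1., 2., 3.]), np.array([1., 2., 3.]))
        assert (r2, rmse) == (1.0, 0.0)

    def test_hand_computed_sums_of_squares(self):
        r2, rmse = evaluate(np.array([1., 2., 3.]), np.array([1., 2., 4.]))
        assert rmse == pytest.approx(np.sqrt(1 / 3), abs=1e-12)
        assert r2 == pytest.approx(0.5, abs=1e-12)

    def test_mean_predictor_scores_zero(self):
        y = np.array([2., 4., 9.])
        r2, _ = evaluate(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_truth_is_missing(self):
        r2, rmse = evaluate(np.array([2., 2., 2.]), np.array([1., 2., 3.]))
        assert np.isnan(r2)
        assert rmse > 0


class TestSummaries:
    @pytest.mark.parametrize("mean,sd,expected", [
        (5.59, 1.32, 23.6),    # total collagen
        (3.74, 0.83, 22.2),    # insoluble collagen
    ])
    def test_cv_from_printed_moments(self, mean, sd, expected):
        assert round(cv_percent(mean, sd), 1) == expected

    def test_zero_sd_zero_cv(self):
        assert cv_percent(5.0, 0.0) == 0.0

    def test_zero_mean_missing(self):
        assert np.isnan(cv_percent(0.0, 1.0))

    def test_summarize_targets(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        table = summarize_targets(df).table
        assert table.loc["a", "min"] == 1 and table.loc["a", "max"] == 3
        assert table.loc["a", "sd"] == pytest.approx(1.0)
        assert table.loc["a", "cv"] == pytest.approx(50.0)
        assert table.loc["b", "cv"] == 0.0


class TestGridSearch:
    @pytest.fixture
    def signal_data(self, rng):
        """y is encoded only in the orientation histograms."""
        n, bins, bands = 60, 20, 3
        y = rng.uniform(0, 1, n)
        signal = np.zeros((n, bins, bands))
        for i, yi in enumerate(y):
            k = min(int(yi * bins), bins - 1)
            signal[i, k, :] = 30
            signal[i, (k + 7) % bins, :] = 10
        noise = rng.integers(0, 40, (n, bins, bands)).astype(float)
        cubes = [make_cube(signal, "orientation"), make_cube(noise, "area")]
        return cubes, y

    def test_default_grid_enumerates_49(self):
        assert len(DEFAULT_GRID) == 49
        assert set(DEFAULT_GRID) == {(a, b) for a in range(2, 9)
                                     for b in range(2, 9)}

    def test_single_configuration_returned(self, signal_data):
        cubes, y = signal_data
        split = split_data(60, 3)
        rep = grid_search(cubes[:1], y, split, grid=((3, 2),), seed=1)
        assert (rep.n1l, rep.n2l) == (3, 2)

    def test_selects_feature_carrying_signal(self, signal_data):
        cubes, y = signal_data
        split = split_data(60, 3)
        rep = grid_search(cubes, y, split, grid=((4, 3), (2, 2)), seed=1,
                          strict=True)
        assert rep.feature_name == "orientation"

    def test_empty_grid_rejected(self, signal_data):
        cubes, y = signal_data
        with pytest.raises(ValueError, match="grid"):
            grid_search(cubes, y, split_data(60, 3), grid=())

    def test_report_fields_consistent(self, signal_data):
        cubes, y = signal_data
        split = split_data(60, 3)
        _, rep = train_pls_ann(cubes[0], y, split, 3, 2, seed=5)
        assert rep.r2c <= 1 and rep.r2v <= 1 and rep.r2p <= 1
        assert min(rep.rmsec, rep.rmsev, rep.rmsep) >= 0
        assert rep.n_bins == 20

    def test_config_seed_stable(self):
        assert config_seed(1, 0) == config_seed(1, 0)
        assert config_seed(1, 0) != config_seed(1, 1)
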