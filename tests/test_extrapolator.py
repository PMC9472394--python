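import numpy as np
import pytest

from seqlift import (ExpressionMatrix, ExtrapolatorConfig, apply_linear_baseline,
                     apply_ratio_baseline, extrapolate, fit_linear_baseline,
                     fit_ratio_baseline, load_extrapolator, save_extrapolator,
                     simulate_regression_world, train_extrapolator)


def make_matrix(values, prefix="g"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(values,
                            gene_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
                            sample_ids=[f"s{j}" for j in range(values.shape[1])])


@pytest.fixture(scope="module")
def linear_world():
    # targets are noiseless linear combinations of landmarks
    rng = np.random.default_rng(8)
    lm = rng.uniform(1, 8, size=(10, 2000))
    w = rng.uniform(0.1, 0.5, size=(30, 10))
    tg = w @ lm + 1.0
    values = np.vstack([lm, tg])
    genes = [f"L{i}" for i in range(10)] + [f"T{i}" for i in range(30)]
    m = ExpressionMatrix(values, genes, [f"s{j}" for j in range(2000)])
    return m, genes[:10]


@pytest.fixture(scope="module")
def trained(linear_world):
    m, lms = linear_world
    cfg = ExtrapolatorConfig(layer_units=[10, 32, 64, 30],
                             learning_rate=1e-3, seed=5, max_epochs=300)
    return train_extrapolator(m, lms, cfg)


class TestTrainExtrapolator:
    def test_noiseless_linear_map_recovered(self, linear_world, trained):
        """Held-out reconstruction error approaches zero when targets are
        exact linear functions of the landmarks."""
        m, lms = linear_world
        held = m.subset_samples(m.sample_ids[1800:])
        pred = extrapolate(trained, held.subset_genes(lms, space="landmark"))
        truth = held.subset_genes(trained.target_ids)
        rmse = np.sqrt(np.mean((pred.subset_genes(trained.target_ids).values
                                - truth.values) ** 2))
        assert rmse < 0.05

    def test_same_seed_identical_history(self, linear_world, trained):
        m, lms = linear_world
        cfg = ExtrapolatorConfig(layer_units=[10, 32, 64, 30],
                                 learning_rate=1e-3, seed=5, max_epochs=300)
        again = train_extrapolator(m, lms, cfg)
        assert trained.history.equals(again.history)

    def test_early_stopping_restores_best_epoch(self, trained):
        h = trained.history
        best = h.val_loss.min()
        assert h.attrs["best_epoch"] == int(h.val_loss.idxmin())
        # restored parameters reproduce the best validation loss exactly:
        # recompute is covered by determinism; here check the recorded tail
        n_worse = len(h) - 1 - int(h.val_loss.idxmin())
        assert n_worse <= 3  # patience bound
        assert best == h.val_loss.iloc[h.attrs["best_epoch"]]

    def test_missing_landmark_rejected(self, linear_world):
        m, _ = linear_world
        with pytest.raises(ValueError, match="missing"):
            train_extrapolator(m, ["NOPE"], ExtrapolatorConfig(max_epochs=1))

    def test_outputs_nonnegative_and_full_order(self, linear_world, trained):
        m, lms = linear_world
        held = m.subset_samples(m.sample_ids[:5])
        pred = extrapolate(trained, held.subset_genes(lms, space="landmark"))
        assert pred.gene_ids == m.gene_ids
        assert np.all(pred.values >= 0)
        again = extrapolate(trained, held.subset_genes(lms, space="landmark"))
        np.testing.assert_array_equal(pred.values, again.values)

    def test_save_load_round_trip(self, linear_world, trained, tmp_path):
        m, lms = linear_world
        save_extrapolator(trained, tmp_path / "model")
        back = load_extrapolator(tmp_path / "model")
        held = m.subset_samples(m.sample_ids[:7]).subset_genes(lms,
                                                               space="landmark")
        np.testing.assert_array_equal(extrapolate(trained, held).values,
                                      extrapolate(back, held).values)


class TestRatioBaseline:
    def test_doubling_recovered_exactly(self):
        x = make_matrix([[1, 2, 3], [2, 4, 6]])
        y = x.with_values(x.values * 2)
        b = fit_ratio_baseline(x, y)
        np.testing.assert_array_equal(b.scale_factors, [2.0, 2.0])
        np.testing.assert_array_equal(apply_ratio_baseline(b, x).values, y.values)

    def test_zero_mean_gene_gets_unit_factor(self):
        x = make_matrix([[0, 0], [1, 1]])
        y = make_matrix([[5, 5], [2, 2]])
        b = fit_ratio_baseline(x, y)
        assert b.scale_factors[0] == 1.0

    def test_mean_ratio_worked_example(self):
        x = make_matrix([[1, 1], [4, 4]])
        y = make_matrix([[3, 3], [2, 2]])
        b = fit_ratio_baseline(x, y)
        np.testing.assert_allclose(b.scale_factors, [3.0, 0.5])

    def test_empty_pool_rejected(self):
        x = ExpressionMatrix(np.zeros((1, 0)), ["g0"], [])
        with pytest.raises(ValueError, match="non-empty"):
            fit_ratio_baseline(x, x)


class TestLinearBaseline:
    def test_exact_recovery_of_noiseless_coefficients(self):
        rng = np.random.default_rng(2)
        lm = rng.uniform(0, 5, size=(2, 50))
        target = 2 * lm[0] + 3 * lm[1] + 1
        m = ExpressionMatrix(np.vstack([lm, target]), ["L1", "L2", "T"],
                             [f"s{j}" for j in range(50)])
        b = fit_linear_baseline(m, ["L1", "L2"])
        np.testing.assert_allclose(b.coefficients[0], [2.0, 3.0, 1.0],
                                   atol=1e-8)

    def test_constant_target_gets_intercept_only(self):
        rng = np.random.default_rng(3)
        lm = rng.uniform(0, 5, size=(2, 40))
        m = ExpressionMatrix(np.vstack([lm, np.full(40, 7.0)]),
                             ["L1", "L2", "T"], [f"s{j}" for j in range(40)])
        b = fit_linear_baseline(m, ["L1", "L2"])
        np.testing.assert_allclose(b.coefficients[0, :2], 0.0, atol=1e-10)
        assert abs(b.coefficients[0, 2] - 7.0) < 1e-10

    def test_noisy_estimates_within_three_standard_errors(self):
        rng = np.random.default_rng(4)
        n = 500
        lm = rng.uniform(0, 5, size=(2, n))
        noise = rng.normal(scale=0.1, size=n)
        target = 2 * lm[0] + 3 * lm[1] + 1 + noise
        m = ExpressionMatrix(np.vstack([lm, target]), ["L1", "L2", "T"],
                             [f"s{j}" for j in range(n)])
        b = fit_linear_baseline(m, ["L1", "L2"])
        design = np.hstack([lm.T, np.ones((n, 1))])
        cov = 0.1 ** 2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        np.testing.assert_array_less(np.abs(b.coefficients[0] - [2, 3, 1]),
                                     3 * se)

    def test_prediction_assembles_full_gene_order(self):
        rng = np.random.default_rng(5)
        lm = rng.uniform(0, 5, size=(2, 30))
        m = ExpressionMatrix(np.vstack([lm[0], lm[0] + lm[1], lm[1]]),
                             ["L1", "T", "L2"], [f"s{j}" for j in range(30)])
        b = fit_linear_baseline(m, ["L1", "L2"])
        pred = apply_linear_baseline(b, m.subset_genes(["L1", "L2"],
                                                       space="landmark"))
        assert pred.gene_ids == ["L1", "T", "L2"]
        np.testing.assert_allclose(pred.values, m.values, atol=1e-8)


class TestRegressionWorldContracts:
    def test_linear_world_is_fit_perfectly_by_ols_up_to_noise(self):
        full, lms = simulate_regression_world(n_landmark=10, n_target=20,
                                              n_samples=400, link="linear",
                                              noise_sd=0.0, seed=1)
        b = fit_linear_baseline(full, lms)
        pred = apply_linear_baseline(b, full.subset_genes(lms, space="landmark"))
        # clipping at zero makes a handful of entries nonlinear; the bulk is exact
        err = np.abs(pred.values - full.values)
        assert np.median(err) < 1e-8
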