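import numpy as np
import pytest
from scipy.special import expit, logit

from sleepscope import wesi
from sleepscope.types import EEGRecording, Hypnogram


def _separable_relatives(n, seed=0):
    """Wake windows alpha-dominant, sleep windows delta-dominant."""
    rng = np.random.default_rng(seed)
    wake = rng.dirichlet([5, 3, 9, 4], n // 2)
    sleep = rng.dirichlet([10, 4, 2, 2], n - n // 2)
    R = np.vstack([wake, sleep])
    L = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    return R, L


class TestFeatureConstruction:
    def test_predictor_count_is_14(self):
        std = wesi.Standardization(mean=np.zeros(4), sd=np.ones(4))
        X = wesi.build_feature_matrix(np.array([[0.4, 0.3, 0.2, 0.1]]), std)
        assert X.shape == (1, 14)

    def test_hand_computed_products_and_squares(self):
        std = wesi.Standardization(mean=np.zeros(4), sd=np.ones(4))
        rel = np.array([[0.4, 0.3, 0.2, 0.1]])
        z = logit(rel)[0]
        X = wesi.build_feature_matrix(rel, std)[0]
        assert np.allclose(X[:4], z)
        expected_products = [z[i] * z[j] for i, j in wesi.PRODUCT_PAIRS]
        assert np.allclose(X[4:10], expected_products)
        assert np.allclose(X[10:], z**2)

    def test_training_zscore_contract(self):
        rng = np.random.default_rng(1)
        rel = rng.dirichlet([4, 4, 4, 4], 500)
        std = wesi.Standardization.fit(wesi.logit_powers(rel))
        z = std.apply(wesi.logit_powers(rel))
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_degenerate_relatives_clipped(self):
        std = wesi.Standardization(mean=np.zeros(4), sd=np.ones(4))
        X = wesi.build_feature_matrix(np.array([[1.0, 0.0, 0.0, 0.0]]), std)
        assert np.all(np.isfinite(X))


class TestWindowPowers:
    def test_equal_band_noise_quarter_each(self):
        from scipy import signal as spsig

        rng = np.random.default_rng(2)
        fs = 200.0
        n = int(fs * 120)
        x = np.zeros(n)
        for lo, hi in ((0.5, 4), (4, 8), (8, 12), (12, 30)):
            sos = spsig.butter(6, [lo, hi], btype="bandpass", fs=fs, output="sos")
            c = spsig.sosfiltfilt(sos, rng.standard_normal(n))
            x += 20.0 * c / c.std()
        rec = EEGRecording(channels={"C3": x, "C4": x.copy()}, sample_rate=fs)
        starts, rel = wesi.window_band_powers_3s(rec)
        assert np.allclose(rel.sum(axis=1), 1.0)
        assert np.all(np.abs(rel.mean(axis=0) - 0.25) < 0.06)

    def test_ten_windows_per_epoch(self):
        rng = np.random.default_rng(3)
        fs = 200.0
        x = 30.0 * rng.standard_normal(int(fs * 60))  # two 30-s epochs
        rec = EEGRecording(channels={"C3": x, "C4": x.copy()}, sample_rate=fs)
        starts, rel = wesi.window_band_powers_3s(rec)
        assert len(starts) == 20


class TestTraining:
    def test_separable_auc(self):
        R, L = _separable_relatives(4000, seed=4)
        model = wesi.train(R, L, seed=0)
        ev = wesi.evaluate(model, R[model.test_indices], L[model.test_indices])
        assert ev["auc"] >= 0.95

    def test_parameter_count_is_15(self):
        R, L = _separable_relatives(400, seed=5)
        model = wesi.train(R, L, seed=0)
        assert model.n_parameters == 15

    def test_shuffled_labels_auc_half(self):
        rng = np.random.default_rng(6)
        R, L = _separable_relatives(10_000, seed=6)
        Ls = rng.permutation(L)
        model = wesi.train(R, Ls, seed=1)
        ev = wesi.evaluate(model, R[model.test_indices], Ls[model.test_indices])
        assert abs(ev["auc"] - 0.5) <= 0.05

    def test_huge_lambda_kills_coefficients(self):
        R, L = _separable_relatives(1000, seed=7)
        model = wesi.train(R, L, lam=100.0, seed=0)
        assert np.all(np.abs(model.coef) < 1e-6)

    def test_single_class_training_errors(self):
        R, _ = _separable_relatives(100, seed=8)
        with pytest.raises(ValueError, match="single class"):
            wesi.train(R, np.ones(100), seed=0)

    def test_deterministic_given_seed(self):
        R, L = _separable_relatives(1000, seed=9)
        m1 = wesi.train(R, L, seed=3)
        m2 = wesi.train(R, L, seed=3)
        assert m1.intercept == m2.intercept
        assert np.array_equal(m1.coef, m2.coef)

    def test_no_leakage_from_test_rows(self):
        R, L = _separable_relatives(1000, seed=10)
        m1 = wesi.train(R, L, seed=4)
        # corrupt every test row: fitted model must not change
        R2 = R.copy()
        R2[m1.test_indices] = 0.25
        m2 = wesi.train(R2, L, seed=4)
        assert m1.intercept == m2.intercept
        assert np.array_equal(m1.coef, m2.coef)
        assert np.array_equal(m1.standardization.mean, m2.standardization.mean)

    def test_subject_wise_split_separates_groups(self):
        R, L = _separable_relatives(1000, seed=11)
        groups = np.repeat(np.arange(50), 20)
        model = wesi.train(R, L, groups=groups, seed=5)
        tr = np.setdiff1d(np.arange(1000), model.test_indices)
        assert not set(groups[tr]) & set(groups[model.test_indices])


class TestScoring:
    def test_zero_coefficients_score_half(self):
        std = wesi.Standardization(mean=np.zeros(4), sd=np.ones(4))
        model = wesi.WESIModel(intercept=0.0, coef=np.zeros(14), standardization=std)
        s = wesi.score(model, np.array([[0.4, 0.3, 0.2, 0.1]]))
        assert s[0] == pytest.approx(0.5)

    def test_monotone_in_positive_coefficient(self):
        std = wesi.Standardization(mean=np.zeros(4), sd=np.ones(4))
        coef = np.zeros(14)
        coef[2] = 1.0  # alpha logit
        model = wesi.WESIModel(intercept=0.0, coef=coef, standardization=std)
        lo = wesi.score(model, np.array([[0.4, 0.3, 0.2, 0.1]]))
        hi = wesi.score(model, np.array([[0.3, 0.3, 0.3, 0.1]]))
        assert hi[0] > lo[0]

    def test_auc_matches_mann_whitney_oracle(self):
        from scipy.stats import mannwhitneyu

        R, L = _separable_relatives(600, seed=12)
        model = wesi.train(R, L, seed=0)
        s = wesi.score(model, R)
        u = mannwhitneyu(s[L == 1], s[L == 0]).statistic
        auc_oracle = u / ((L == 1).sum() * (L == 0).sum())
        assert wesi.evaluate(model, R, L)["auc"] == pytest.approx(auc_oracle)

    def test_one_class_test_set_errors(self):
        R, L = _separable_relatives(200, seed=13)
        model = wesi.train(R, L, seed=0)
        with pytest.raises(ValueError, match="one-class"):
            wesi.evaluate(model, R[:10], np.zeros(10))

    def test_serialization_round_trip(self):
        R, L = _separable_relatives(400, seed=14)
        model = wesi.train(R, L, seed=0)
        back = wesi.WESIModel.from_json(model.to_json())
        assert np.allclose(wesi.score(back, R), wesi.score(model, R))


class TestStageMeans:
    def test_constant_scores(self):
        hyp = Hypnogram(stages=np.array(["W"] * 2 + ["N1"] * 2 + ["N2"] * 2
                                        + ["N3"] * 2 + ["R"] * 2))
        starts = np.arange(0, 300, 3.0)
        scores = np.full(len(starts), 0.5)
        means = wesi.stage_means(scores, starts, hyp)
        assert all(v == pytest.approx(0.5) for v in means.values())

    def test_absent_stage_is_nan(self):
        hyp = Hypnogram(stages=np.array(["W"] * 4))
        starts = np.arange(0, 120, 3.0)
        means = wesi.stage_means(np.linspace(0, 1, len(starts)), starts, hyp)
        assert np.isnan(means["N3"])
        assert np.isfinite(means["W"])

    def test_bounded_by_min_max(self):
        rng = np.random.default_rng(15)
        hyp = Hypnogram(stages=np.array(["N2"] * 10))
        starts = np.arange(0, 300, 3.0)
        scores = rng.uniform(0.2, 0.9, len(starts))
        means = wesi.stage_means(scores, starts, hyp)
        assert scores.min() <= means["N2"] <= scores.max()


class TestBackTransform:
    def test_zero_variance_at_logit_zero(self):
        out = wesi.linear_scale_summary(0.0, 0.0)
        assert out["mean"] == pytest.approx(0.5)
        assert out["ci_low"] == pytest.approx(0.5)
        assert out["ci_high"] == pytest.approx(0.5)

    def test_ci_within_unit_interval(self):
        for m, se in [(-5, 2), (0, 1), (4, 3)]:
            out = wesi.linear_scale_summary(m, se)
            assert 0 < out["ci_low"] < out["ci_high"] < 1

    def test_matches_bootstrap_within_0p001(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(0.7, 0.9, 400)
        diff = wesi.validate_backtransform(vals, n_boot=10_000, seed=17)
        assert diff < 1e-3
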