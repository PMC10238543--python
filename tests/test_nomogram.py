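import numpy as np
import pandas as pd
import pytest

from pris.nomogram import (build_nomogram, calibration, compare_models,
                           decision_curve, ipcw_outcomes)
from pris.survival import cox_fit


@pytest.fixture(scope="module")
def fitted_cox():
    rng = np.random.default_rng(2)
    n = 300
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    eta = 0.8 * X["a"] + 0.3 * X["b"]
    t = 5.0 * (-np.log(rng.random(n)) / np.exp(eta)) ** (1 / 1.5)
    e = np.ones(n, int)
    return X, t, e, cox_fit(X, t, e)


class TestNomogram:
    def test_points_route_equals_cox_route(self, fitted_cox):
        X, t, e, fit = fitted_cox
        nomo = build_nomogram(fit, X, horizons=(1.0,))
        pred = nomo.predict_survival(X, 1.0)
        via_points = nomo.survival_from_points(nomo.total_points(X), 1.0)
        np.testing.assert_allclose(pred, via_points, atol=1e-12)

    def test_reference_patient_gets_zero_points(self, fitted_cox):
        X, t, e, fit = fitted_cox
        nomo = build_nomogram(fit, X, horizons=(1.0,))
        ref = pd.DataFrame({c: [nomo.reference[c]] for c in fit.terms})
        assert nomo.total_points(ref)[0] == pytest.approx(0.0, abs=1e-12)

    def test_points_decrease_with_predicted_survival(self, fitted_cox):
        X, t, e, fit = fitted_cox
        nomo = build_nomogram(fit, X, horizons=(1.0,))
        pts = nomo.total_points(X)
        pred = nomo.predict_survival(X, 1.0)
        order = np.argsort(pts)
        assert np.all(np.diff(pred[order]) <= 1e-12)

    def test_rankings_match_linear_predictor(self, fitted_cox):
        X, t, e, fit = fitted_cox
        nomo = build_nomogram(fit, X, horizons=(1.0,))
        pts = nomo.total_points(X)
        lp = nomo.linear_predictor(X)
        assert np.array_equal(np.argsort(pts), np.argsort(lp))

    def test_horizon_beyond_support_rejected(self, fitted_cox):
        X, t, e, fit = fitted_cox
        nomo = build_nomogram(fit, X, horizons=(1.0,))
        with pytest.raises(ValueError):
            nomo.predict_survival(X, t.max() * 10)

    def test_probabilities_in_unit_interval(self, fitted_cox):
        X, t, e, fit = fitted_cox
        nomo = build_nomogram(fit, X, horizons=(1.0,))
        for h in (0.5, 1.0, 2.0):
            p = nomo.predict_survival(X, h)
            assert ((p >= 0) & (p <= 1)).all()


class TestCalibration:
    def _well_specified(self, seed, n=400, shift=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        eta = 0.8 * x
        t = 5.0 * (-np.log(rng.random(n)) / np.exp(eta)) ** (1 / 1.5)
        # true model survival at horizon
        h = 2.0
        s_true = np.exp(-((h / 5.0) ** 1.5) * np.exp(eta))
        return np.clip(s_true + shift, 0.01, 0.99), t, np.ones(n, int), h

    def test_true_model_predictions_are_calibrated(self):
        ps = []
        for seed in range(60):
            pred, t, e, h = self._well_specified(seed)
            ps.append(calibration(pred, t, e, h)["p"])
        # HL p-values of a correctly specified model are not concentrated
        # near 0: median well above the rejection region
        assert np.median(ps) > 0.2
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_shifted_predictions_rejected(self):
        hits = 0
        for seed in range(40):
            pred, t, e, h = self._well_specified(seed, shift=0.2)
            hits += calibration(pred, t, e, h)["p"] < 0.05
        assert hits >= 36  # >= 90%

    def test_single_bin_mean_agreement(self):
        pred, t, e, h = self._well_specified(0)
        out = calibration(pred, t, e, h, bins=1)
        row = out["table"].iloc[0]
        assert row["predicted"] == pytest.approx(row["observed"], abs=0.05)


class TestDecisionCurve:
    def test_treat_all_matches_closed_form(self, rng):
        y = (rng.random(200) < 0.3).astype(float)
        risk = rng.random(200)
        ts = np.linspace(0.05, 0.95, 20)
        dc = decision_curve(risk, y, ts)
        rho = y.mean()
        expected = rho - (1 - rho) * ts / (1 - ts)
        np.testing.assert_allclose(dc["nb_all"], expected, atol=1e-12)
        np.testing.assert_allclose(dc["nb_none"], 0.0)

    def test_perfect_predictor_net_benefit_is_prevalence(self, rng):
        y = (rng.random(300) < 0.4).astype(float)
        dc = decision_curve(y, y, np.linspace(0.05, 0.95, 20))
        np.testing.assert_allclose(dc["nb_model"], y.mean(), atol=1e-12)

    def test_hand_computed_two_by_two(self):
        # 10 patients, threshold 0.25: 3 TP, 2 FP among risk >= 0.25
        risk = np.array([.9, .8, .3, .3, .2, .2, .1, .1, .05, .4])
        y = np.array([1, 1, 0, 1, 0, 1, 0, 0, 0, 0], float)
        dc = decision_curve(risk, y, [0.25])
        tp, fp, n = 3, 2, 10
        expected = tp / n - (fp / n) * 0.25 / 0.75
        assert dc["nb_model"].iloc[0] == pytest.approx(expected)

    def test_net_benefit_never_exceeds_prevalence(self, rng):
        y = (rng.random(500) < 0.25).astype(float)
        risk = np.clip(y * 0.6 + rng.random(500) * 0.4, 0, 1)
        dc = decision_curve(risk, y, np.linspace(0.01, 0.99, 50))
        assert (dc["nb_model"] <= y.mean() + 1e-12).all()

    def test_threshold_one_excluded(self, rng):
        dc = decision_curve(rng.random(50), (rng.random(50) < 0.5).astype(float),
                            [0.5, 1.0])
        assert len(dc) == 1

    def test_ipcw_weights_zero_for_early_censored(self, rng):
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        e[:5] = 1
        h = np.median(t)
        y, w = ipcw_outcomes(t, e, h)
        early_censored = (e == 0) & (t <= h)
        assert (w[early_censored] == 0).all()
        assert (w[t > h] > 0).all()


class TestCompareModels:
    def test_model_vs_itself(self, fitted_cox):
        X, t, e, fit = fitted_cox
        s = np.asarray(0.8 * X["a"] + 0.3 * X["b"])
        out = compare_models(s, s.copy(), t, e, n_boot=100, seed=0)
        assert out["difference"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_pure_noise_addition_does_not_help(self):
        diffs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 250
            x = rng.normal(size=n)
            t = rng.exponential(1 / np.exp(0.8 * x))
            noise_model = x + rng.normal(scale=0.01, size=n)
            out = compare_models(noise_model, x, t, np.ones(n, int),
                                 n_boot=40, seed=seed)
            diffs.append(out["difference"])
        assert abs(np.mean(diffs)) < 0.01

    def test_informative_extra_covariate_raises_c(self):
        wins = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 300
            a, b = rng.normal(size=n), rng.normal(size=n)
            t = rng.exponential(1 / np.exp(0.6 * a + 0.6 * b))
            out = compare_models(0.6 * a + 0.6 * b, 0.6 * a, t,
                                 np.ones(n, int), n_boot=40, seed=seed)
            wins += out["difference"] > 0
        assert wins >= 13
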