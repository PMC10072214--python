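"""Cox fitting, AIC, C-index, KM and log-rank against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from radsurv.phantom import HazardSpec, generate_survival
from radsurv.survival import (
    SurvivalData,
    aic,
    build_model_suite,
    c_index,
    c_index_ci,
    fit_cox,
    km_estimate,
    logrank_test,
)

from _oracles import c_index_oracle, cox_loglik_oracle, km_oracle, logrank_oracle


class TestCox:
    def test_tiny_fixture_matches_partial_likelihood_oracle(self):
        """6 patients, binary covariate, no ties: beta from direct
        maximization of the closed-form partial likelihood."""
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [1, 1, 0, 1, 1, 1]
        x = [1.0, 1.0, 0.0, 0.0, 1.0, 0.0]
        res = minimize_scalar(
            lambda b: -cox_loglik_oracle(b, time, event, x), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        data = SurvivalData(np.array(time), np.array(event), pd.DataFrame({"x": x}))
        fit = fit_cox(data)
        assert fit.coef["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-8)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.log_likelihood)
        assert fit.hr["x"] == pytest.approx(np.exp(fit.coef["x"]))

    def test_null_covariate_is_small_and_insignificant(self):
        rng = np.random.default_rng(0)
        ok = 0
        reps = 30
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(10, n) + 0.01
            data = SurvivalData(t, np.ones(n, dtype=int), pd.DataFrame({"x": x}))
            fit = fit_cox(data)
            ok += (abs(fit.coef["x"]) < 0.2) and (fit.p["x"] > 0.05)
        assert ok / reps >= 0.8

    def test_recovers_known_beta(self):
        hz = HazardSpec(beta=(0.8,), censoring_rate=0.2, seed=4)
        rng = np.random.default_rng(4)
        x = rng.normal(size=1000)
        te = [generate_survival([xi], hz, rng=rng) for xi in x]
        data = SurvivalData(
            np.array([t for t, _ in te]), np.array([e for _, e in te]), pd.DataFrame({"x": x})
        )
        fit = fit_cox(data)
        assert abs(fit.coef["x"] - 0.8) < 0.15

    def test_requires_events_and_covariates(self):
        data = SurvivalData(np.array([1.0, 2.0]), np.array([0, 0]),
                            pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="event"):
            fit_cox(data)


class TestAIC:
    def test_formula_arithmetic(self):
        assert aic(-5.0, 2) == 14.0
        assert aic(-5.0, 0) == 10.0

    def test_noise_covariate_raises_aic(self):
        """Adding a pure-noise covariate costs ~2 AIC on average."""
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(30):
            n = 150
            x = rng.normal(size=n)
            t = np.exp(-0.8 * x) * rng.exponential(15, n) + 0.01
            noise = rng.normal(size=n)
            d1 = SurvivalData(t, np.ones(n, int), pd.DataFrame({"x": x}))
            d2 = SurvivalData(t, np.ones(n, int), pd.DataFrame({"x": x, "u": noise}))
            deltas.append(fit_cox(d2).aic - fit_cox(d1).aic)
        assert 0 < np.mean(deltas) < 2.5

    def test_prognostic_covariate_lowers_aic(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        t = np.exp(-x) * rng.exponential(15, n) + 0.01
        u = rng.normal(size=n)
        base = SurvivalData(t, np.ones(n, int), pd.DataFrame({"u": u}))
        both = SurvivalData(t, np.ones(n, int), pd.DataFrame({"u": u, "x": x}))
        assert fit_cox(both).aic < fit_cox(base).aic


class TestCIndex:
    def _data(self, time, event):
        return SurvivalData(np.asarray(time, float), np.asarray(event, int))

    def test_perfect_ordering_is_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = self._data(t, [1, 1, 1, 1])
        assert c_index(-t, d, "strict") == 1.0
        assert c_index(-t, d, "half") == 1.0

    def test_constant_risk_tie_conventions(self):
        d = self._data([1.0, 2.0, 3.0], [1, 1, 1])
        r = np.zeros(3)
        assert c_index(r, d, "half") == 0.5
        assert c_index(r, d, "strict") == 0.0

    def test_fixture_matches_pair_enumeration(self, survival_fixture_8):
        time, event, risk = survival_fixture_8
        d = self._data(time, event)
        for mode in ("strict", "half"):
            ref = c_index_oracle(time, event, risk, mode)
            assert c_index(risk, d, mode) == pytest.approx(ref, abs=1e-12)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_ci

        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50) + 0.01
        e = (rng.uniform(size=50) < 0.7).astype(int)
        r = rng.normal(size=50)
        d = self._data(t, e)
        assert c_index(r, d, "half") == pytest.approx(ll_ci(t, -r, e), abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        d = self._data([5.0, 5.0], [1, 1])
        with pytest.raises(ValueError, match="comparable"):
            c_index(np.array([1.0, 2.0]), d)

    def test_bootstrap_ci_properties(self, survival_fixture_8):
        time, event, risk = survival_fixture_8
        d = self._data(time, event)
        point = c_index(risk, d)
        lo, hi = c_index_ci(risk, d, n_boot=400, seed=1)
        assert lo <= point <= hi
        perfect = -time
        _, hi2 = c_index_ci(perfect, d, n_boot=200, seed=1)
        assert hi2 == 1.0

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(7)

        def width(n):
            x = rng.normal(size=n)
            t = np.exp(-x) * rng.exponential(10, n) + 0.01
            d = self._data(t, np.ones(n, int))
            lo, hi = c_index_ci(x, d, n_boot=200, seed=3)
            return hi - lo

        assert width(500) < width(50)


class TestKM:
    def test_four_distinct_deaths(self):
        curve = km_estimate(SurvivalData(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, int)))
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_is_flat_one(self):
        curve = km_estimate(SurvivalData(np.array([1.0, 2.0, 3.0]), np.zeros(3, int)))
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_mixed_fixture_matches_hand_product_limit(self):
        time = np.array([2.0, 3.0, 3.0, 5.0, 8.0, 11.0])
        event = np.array([1, 1, 0, 1, 0, 1])
        curve = km_estimate(SurvivalData(time, event))
        ref = dict(km_oracle(time, event))
        for t, s in zip(curve.time, curve.survival):
            assert s == pytest.approx(ref[t], abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = np.round(rng.exponential(5, 40), 1) + 0.1
        curve = km_estimate(SurvivalData(t, np.ones(40, int)))
        for ti, si in zip(curve.time, curve.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        a = SurvivalData(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        chi2, p = logrank_test(a, a)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ten_patient_fixture_matches_hand_tabulation(self):
        ta = np.array([3.0, 5.0, 7.0, 9.0, 18.0])
        ea = np.array([1, 1, 0, 1, 1])
        tb = np.array([4.0, 6.0, 8.0, 12.0, 15.0])
        eb = np.array([0, 1, 1, 1, 0])
        ref = logrank_oracle(ta, ea, tb, eb)
        chi2, _ = logrank_test(SurvivalData(ta, ea), SurvivalData(tb, eb))
        assert chi2 == pytest.approx(ref, abs=1e-9)

    def test_no_events_raises(self):
        a = SurvivalData(np.array([1.0]), np.array([0]))
        with pytest.raises(ValueError, match="events"):
            logrank_test(a, a)


@pytest.fixture(scope="module")
def cohort_tables():
    """120 patients whose hazard is driven by RPC0 + DPC0."""
    rng = np.random.default_rng(10)
    n = 120
    idx = pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id")
    rpc = pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                       columns=[f"RPC{i}" for i in range(5)])
    dpc = pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                       columns=[f"DPC{i}" for i in range(5)])
    clin = pd.DataFrame(
        {
            "gender": rng.integers(0, 2, n),
            "age": rng.normal(60, 8, n),
            "stage_ivb": rng.integers(0, 2, n),
            "peripheral_invasion": rng.integers(0, 2, n),
        },
        index=idx,
    )
    risk = 0.9 * rpc["RPC0"] + 0.9 * dpc["DPC0"]
    t = np.exp(-risk) * rng.exponential(25, n) + 0.05
    cens = rng.exponential(40, n)
    time = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    return rpc, dpc, clin, SurvivalData(time.to_numpy(), event)


class TestModelSuite:
    def test_six_models_with_carry_forward(self, cohort_tables):
        rpc, dpc, clin, out = cohort_tables
        fits = build_model_suite(rpc, dpc, clin, out)
        assert set(fits) == {
            "clinical", "radiomic", "dosiomic",
            "radiomic_clinical", "dosiomic_clinical", "radiomic_dosiomic_clinical",
        }
        assert fits["clinical"].covariates == [
            "gender", "age", "stage_ivb", "peripheral_invasion"
        ]
        assert fits["radiomic"].covariates == [f"RPC{i}" for i in range(5)]
        # carried-forward PCs are exactly the significant ones
        combined = fits["radiomic_dosiomic_clinical"].covariates
        assert [c for c in combined if c.startswith("RPC")] == fits["radiomic"].significant
        assert [c for c in combined if c.startswith("DPC")] == fits["dosiomic"].significant
        assert "RPC0" in combined and "DPC0" in combined

    def test_combined_model_outperforms_components(self, cohort_tables):
        rpc, dpc, clin, out = cohort_tables
        fits = build_model_suite(rpc, dpc, clin, out)
        full = fits["radiomic_dosiomic_clinical"].c_index
        assert full >= fits["clinical"].c_index
        assert full >= fits["radiomic"].c_index - 0.01
        assert full >= fits["dosiomic"].c_index - 0.01

    def test_null_cohort_collapses_with_warning(self):
        rng = np.random.default_rng(11)
        n = 60
        idx = pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id")
        rpc = pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                           columns=[f"RPC{i}" for i in range(5)])
        dpc = pd.DataFrame(rng.normal(size=(n, 5)), index=idx,
                           columns=[f"DPC{i}" for i in range(5)])
        clin = pd.DataFrame(
            {"gender": rng.integers(0, 2, n), "age": rng.normal(60, 8, n),
             "stage_ivb": rng.integers(0, 2, n), "peripheral_invasion": rng.integers(0, 2, n)},
            index=idx,
        )
        out = SurvivalData(rng.exponential(20, n) + 0.05,
                           (rng.uniform(size=n) < 0.6).astype(int))
        fits = build_model_suite(rpc, dpc, clin, out)
        if not fits["radiomic"].significant and not fits["dosiomic"].significant:
            assert fits["radiomic_dosiomic_clinical"].covariates == fits["clinical"].covariates


class TestCalibration:
    def test_wald_ci_coverage(self):
        """95% Wald CIs cover the true beta at the nominal rate (60 cohorts)."""
        hz = HazardSpec(beta=(0.5,), censoring_rate=0.2, seed=0)
        rng = np.random.default_rng(0)
        cover = 0
        reps = 60
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            te = [generate_survival([xi], hz, rng=rng) for xi in x]
            data = SurvivalData(np.array([t for t, _ in te]),
                                np.array([e for _, e in te]), pd.DataFrame({"x": x}))
            fit = fit_cox(data)
            lo = fit.coef["x"] - 1.96 * fit.se["x"]
            hi = fit.coef["x"] + 1.96 * fit.se["x"]
            cover += lo <= 0.5 <= hi
        assert 0.87 <= cover / reps <= 1.0
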