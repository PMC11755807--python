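"""Survival machinery: product-limit hand checks, log-rank closed forms and
calibration, Cox oracles and recovery, IPSS-R coding, stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from piwiflow.survival import (
    FitError,
    cox_fit,
    cox_score_test,
    ipssr_ordinalize,
    km_curve,
    logrank,
    stepwise_cox,
)


def simulate_exponential(rng, n, log_hr, censor_max=40.0, base=0.05, x=None):
    if x is None:
        x = rng.integers(0, 2, n).astype(float)
    lam = base * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / lam)
    censor = rng.uniform(0, censor_max, n)
    return np.minimum(t_event, censor), (t_event <= censor).astype(int), x


class TestKaplanMeier:
    def test_three_events_hand_product_limit(self):
        km = km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.table["survival"], [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_curve([5, 8, 13], [0, 0, 0])
        assert (km.table["survival"] == 1.0).all()
        assert np.isnan(km.median)

    def test_six_subject_mixed_hand_computation(self):
        # events at 2 and 4; censored at 3, 5, 5, 6
        km = km_curve([2, 3, 4, 5, 5, 6], [1, 0, 1, 0, 0, 0])
        tab = km.table.set_index("time")["survival"]
        assert np.isclose(tab[2.0], 5 / 6)
        assert np.isclose(tab[3.0], 5 / 6)  # censoring leaves S unchanged
        assert np.isclose(tab[4.0], 5 / 6 * 3 / 4)
        assert np.isnan(km.median)  # S never drops to 0.5

    def test_curve_monotone_nonincreasing(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        km = km_curve(t, e)
        s = km.table["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert km.survival_at(0.0) == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.table.iterrows():
            assert np.isclose(row["survival"],
                              float(kmf.survival_function_at_times(row["time"]).iloc[0]))


class TestLogrank:
    def test_identical_strata_give_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = logrank(t, e, g)
        assert chi2 < 1e-12 and p > 1 - 1e-9

    def test_single_event_time_hypergeometric_closed_form(self):
        # one event at t=1 in stratum A; both strata fully at risk
        t = [1, 5, 5, 5]
        e = [1, 0, 0, 0]
        g = ["A", "A", "B", "B"]
        chi2, _ = logrank(t, e, g)
        # O-E = 1 - 2/4; Var = 1*(2/4)*(2/4)*(3/3) = 0.25 -> chi2 = 1.0
        assert np.isclose(chi2, 1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(500):
            t, e, x = simulate_exponential(rng, 60, log_hr=0.0)
            _, p = logrank(t, e, x)
            rejections += p < 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_symmetric_in_labels_and_time_scale(self, rng):
        t, e, x = simulate_exponential(rng, 40, log_hr=0.7)
        a = logrank(t, e, x)
        b = logrank(t, e, 1 - x)
        c = logrank(10 * t, e, x)
        assert np.allclose(a, b) and np.allclose(a, c)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t, e, x = simulate_exponential(rng, 70, log_hr=0.5)
        chi2, p = logrank(t, e, x)
        ref = logrank_test(t[x == 0], t[x == 1], e[x == 0], e[x == 1])
        assert np.isclose(chi2, ref.test_statistic, atol=1e-8)
        assert np.isclose(p, ref.p_value, atol=1e-10)


class TestCoxFit:
    @staticmethod
    def _partial_loglik(beta, t, e, x):
        """Independent Breslow partial likelihood (direct O(n^2) form)."""
        ll = 0.0
        for i in np.flatnonzero(e == 1):
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll

    def test_single_covariate_matches_grid_search(self, rng):
        t, e, x = simulate_exponential(rng, 80, log_hr=1.0)
        t += rng.uniform(0, 1e-9, size=t.size)  # ensure no ties
        model = cox_fit(t, e, pd.DataFrame({"x": x}))
        grid = np.arange(-4.0, 4.0, 1e-3)
        lls = [self._partial_loglik(b, t, e, x) for b in grid]
        coarse = grid[int(np.argmax(lls))]
        fine = np.arange(coarse - 2e-3, coarse + 2e-3, 1e-5)
        best = fine[int(np.argmax([self._partial_loglik(b, t, e, x) for b in fine]))]
        assert abs(model.coef[0] - best) < 1e-4

    def test_score_test_equals_logrank_without_ties(self, rng):
        t, e, x = simulate_exponential(rng, 100, log_hr=0.8)
        t += rng.uniform(0, 1e-9, size=t.size)
        stat, _ = cox_score_test(t, e, pd.DataFrame({"x": x}))
        chi2, _ = logrank(t, e, x)
        assert abs(stat - chi2) < 1e-6

    def test_true_hazard_ratio_three_recovered(self):
        rng = np.random.default_rng(7)
        t, e, x = simulate_exponential(rng, 200, log_hr=np.log(3.0))
        assert 0.2 <= 1 - e.mean() <= 0.45  # roughly 30% censoring
        model = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert 2.2 <= model.hr[0] <= 4.0
        lo, hi = model.ci
        assert lo[0] < model.hr[0] < hi[0]

    def test_null_covariate_usually_flat(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t, e, _ = simulate_exponential(rng, 200, log_hr=0.0)
            z = rng.normal(size=200)
            model = cox_fit(t, e, pd.DataFrame({"z": z}))
            hits += (abs(model.coef[0]) < 0.3) and (model.p[0] > 0.05)
        assert hits >= 45

    def test_constant_covariate_rejected(self, rng):
        t, e, x = simulate_exponential(rng, 30, log_hr=0.0)
        with pytest.raises(FitError, match="const"):
            cox_fit(t, e, pd.DataFrame({"const": np.ones(30)}))

    def test_matches_lifelines_two_covariates(self, rng):
        from lifelines import CoxPHFitter

        t, e, x = simulate_exponential(rng, 150, log_hr=0.7)
        z = rng.normal(size=150)
        t += rng.uniform(0, 1e-9, size=t.size)  # tie-free: Breslow == Efron
        model = cox_fit(t, e, pd.DataFrame({"x": x, "z": z}))
        cph = CoxPHFitter().fit(pd.DataFrame({"T": t, "E": e, "x": x, "z": z}), "T", "E")
        assert np.allclose(model.coef, cph.params_.to_numpy(), atol=1e-4)
        assert np.allclose(model.se, cph.standard_errors_.to_numpy(), atol=1e-4)


class TestIpssrOrdinalize:
    def test_boundary_cases_enumerated(self):
        clinical = pd.DataFrame(
            {
                "hemoglobin": [7.9, 8.0, 9.9, 10.0],
                "platelets": [49, 50, 99, 100],
                "neutrophils": [0.79, 0.8, 1.2, 2.0],
                "blasts": [2.0, 2.1, 5.0, 10.1],
                "cytogenetics": [0, 1, 3, 4],
            }
        )
        codes = ipssr_ordinalize(clinical)
        assert codes["hemoglobin"].tolist() == [2, 1, 1, 0]
        assert codes["platelets"].tolist() == [2, 1, 1, 0]
        assert codes["neutrophils"].tolist() == [1, 0, 0, 0]
        assert codes["blasts"].tolist() == [0, 1, 2, 3]
        assert codes["cytogenetics"].tolist() == [0, 1, 3, 4]

    def test_blast_ten_is_code_two(self):
        clinical = pd.DataFrame({"hemoglobin": [12], "platelets": [200],
                                 "neutrophils": [2], "blasts": [10.0], "cytogenetics": [2]})
        assert ipssr_ordinalize(clinical)["blasts"].iloc[0] == 2

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            ipssr_ordinalize(pd.DataFrame({"hemoglobin": [10]}))


class TestStepwise:
    def test_strong_predictor_retained_across_seeds(self):
        kept = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 300).astype(float)
            t, e, _ = simulate_exponential(rng, 300, log_hr=np.log(3.0), x=x)
            cand = pd.DataFrame(rng.normal(size=(300, 9)),
                                columns=[f"noise{i}" for i in range(9)])
            cand.insert(0, "signal", x)
            model = stepwise_cox(t, e, cand)
            kept += "signal" in model.names
        assert kept >= 45

    def test_pure_noise_usually_yields_empty_model(self):
        empty = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            t, e, _ = simulate_exponential(rng, 200, log_hr=0.0)
            cand = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
            model = stepwise_cox(t, e, cand)
            empty += len(model.names) == 0
        assert empty >= 40

    def test_duplicated_candidate_enters_once(self, rng):
        x = rng.integers(0, 2, 200).astype(float)
        t, e, _ = simulate_exponential(rng, 200, log_hr=np.log(3.0), x=x)
        cand = pd.DataFrame({"x": x, "x_copy": x, "noise": rng.normal(size=200)})
        model = stepwise_cox(t, e, cand)
        assert "x" in model.names
        assert "x_copy" not in model.names
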