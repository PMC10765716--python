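import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from fraildex.survival import (
    ConcordanceResult,
    NoEventsError,
    aalen_johansen,
    build_model_frame,
    fit_cause_specific_cox,
    harrells_c,
    kaplan_meier,
    lrt_interaction,
    ph_test,
)

from conftest import make_analysis_frame


def outcomes_frame(times, causes):
    return pd.DataFrame(
        {"person_id": [f"p{i}" for i in range(len(times))], "time": times, "cause": causes}
    )


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # deaths at 1 and 4, censorings at 2 and 5:
        # S(1) = 3/4; at t=4 two at risk -> S(4) = 3/4 * 1/2 = 3/8
        km = kaplan_meier(outcomes_frame([1, 2, 4, 5], ["cvd", "censored", "other", "censored"]))
        assert km(0.5) == 1.0
        assert km(1) == pytest.approx(3 / 4)
        assert km(3.9) == pytest.approx(3 / 4)
        assert km(4) == pytest.approx(3 / 8)

    def test_death_after_last_censoring_drops_to_zero(self):
        km = kaplan_meier(outcomes_frame([1, 2, 3], ["cvd", "censored", "cvd"]))
        assert km(1) == pytest.approx(2 / 3)
        assert km(3) == 0.0

    def test_all_censored_constant_one(self):
        with pytest.warns(UserWarning, match="no deaths"):
            km = kaplan_meier(outcomes_frame([1, 2, 3], ["censored"] * 3))
        assert km(10) == 1.0

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(3, size=400).round(1)  # rounded -> ties
        df = outcomes_frame(t, ["other"] * len(t))
        km = kaplan_meier(df)
        for q in [0.5, 1.0, 2.0, 5.0]:
            assert km(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_matches_lifelines(self, small_cohort):
        from lifelines import KaplanMeierFitter

        _, data = small_cohort
        km = kaplan_meier(data)
        kmf = KaplanMeierFitter().fit(data["time"], data["cause"] != "censored")
        grid = np.linspace(0.1, 7.9, 25)
        ours = km(grid)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestAalenJohansen:
    def test_hand_competing_risks(self):
        # (1, cvd), (2, cancer), (3, censored), (4, cvd):
        # CIF_cvd(1) = 1/4; CIF_cancer(2) = (3/4)(1/3) = 1/4;
        # S(2) = (3/4)(2/3) = 1/2; CIF_cvd(4) = 1/4 + (1/2)(1/1) = 3/4
        df = outcomes_frame([1, 2, 3, 4], ["cvd", "cancer", "censored", "cvd"])
        cif_cvd = aalen_johansen(df, "cvd")
        cif_cancer = aalen_johansen(df, "cancer")
        assert cif_cvd(1) == pytest.approx(1 / 4)
        assert cif_cvd(3.9) == pytest.approx(1 / 4)
        assert cif_cvd(4) == pytest.approx(3 / 4)
        assert cif_cancer(2) == pytest.approx(1 / 4)
        assert cif_cancer(10) == pytest.approx(1 / 4)

    def test_single_cause_reduces_to_cdf(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2, size=300).round(1)
        df = outcomes_frame(t, ["cancer"] * len(t))
        cif = aalen_johansen(df, "cancer")
        for q in [0.5, 1.0, 3.0]:
            assert cif(q) == pytest.approx((t <= q).mean(), abs=1e-12)
        assert aalen_johansen(df, "cvd")(10) == 0.0

    def test_accounting_identity_machine_precision(self, small_cohort):
        _, data = small_cohort
        km = kaplan_meier(data)
        cifs = [aalen_johansen(data, c) for c in ("cvd", "cancer", "other")]
        total = sum(c.values for c in cifs)
        np.testing.assert_allclose(1.0 - km.values, total, atol=1e-12)
        for c in cifs:
            np.testing.assert_array_equal(c.times, km.times)
            assert (np.diff(c.values) >= -1e-15).all()
            assert c.initial == 0.0

    def test_grouped_curves_and_empty_group_warning(self, small_cohort):
        _, data = small_cohort
        curves = aalen_johansen(data, "cvd", groups=data["category"])
        assert set(curves) == {"robust", "pre_frail", "frail"}
        groups = pd.Series(["only"] * len(data))
        groups.iloc[0] = None
        assert "only" in aalen_johansen(data, "cvd", groups=groups)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(8)
        n = 200
        t = rng.exponential(4, size=n)  # continuous -> tie-free
        event = rng.integers(0, 3, size=n)  # 0 censored, 1 cvd, 2 cancer
        causes = np.array(["censored", "cvd", "cancer"])[event]
        df = outcomes_frame(t, causes)
        ours = aalen_johansen(df, "cvd")
        ajf = AalenJohansenFitter(calculate_variance=False).fit(
            pd.Series(t), pd.Series(event), event_of_interest=1
        )
        grid = ajf.cumulative_density_.index.to_numpy()
        theirs = ajf.cumulative_density_.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(ours(grid), theirs, atol=1e-8)


def brute_force_c(risk, time, event):
    """O(n^2) double-loop concordance oracle."""
    conc = comp = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            short, long_ = (i, j) if time[i] < time[j] else (j, i)
            if not event[short]:
                continue
            comp += 1
            if risk[short] > risk[long_]:
                conc += 1
            elif risk[short] == risk[long_]:
                conc += 0.5
    return conc / comp, int(comp)


class TestHarrellsC:
    def test_perfect_risk_ordering(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 100)
        res = harrells_c(-t, t, np.ones(100, bool))
        assert res.c == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        n = 5000
        t = rng.exponential(1, n)
        res = harrells_c(rng.normal(size=n), t, np.ones(n, bool))
        assert res.c == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("n", [200, 500])
    def test_equals_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        t = rng.exponential(2, n).round(1)  # ties in time
        e = rng.random(n) < 0.6
        r = rng.integers(0, 8, n).astype(float)  # ties in score
        res = harrells_c(r, t, e)
        c_oracle, pairs = brute_force_c(r, t, e)
        assert res.c == pytest.approx(c_oracle, abs=1e-12)
        assert res.n_comparable_pairs == pairs

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(4)
        n = 300
        t = rng.exponential(2, n)
        e = rng.random(n) < 0.7
        r = rng.normal(size=n)
        res = harrells_c(r, t, e)
        assert res.c == pytest.approx(concordance_index(t, -r, e), abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(NoEventsError):
            harrells_c([1.0, 2.0], [1.0, 2.0], [False, False])

    def test_ci_is_ordered_and_bounded(self):
        rng = np.random.default_rng(7)
        n = 400
        t = rng.exponential(2, n)
        e = rng.random(n) < 0.5
        res = harrells_c(rng.normal(size=n) - 0.3 * t, t, e)
        assert 0.0 <= res.ci_low <= res.c <= res.ci_high <= 1.0
        assert res.se > 0


def cox_frame(time, event, x):
    """Minimal analysis frame with x smuggled in as FI (x = FI/0.1)."""
    return pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(len(time))],
            "time": time,
            "cause": np.where(event, "other", "censored"),
            "fi": np.asarray(x, float) * 0.1,
            "sex": "male",
            "education": "low",
            "living_alone": "no",
            "age": 70.0,
            "category": "robust",
        }
    )


class TestCauseSpecificCox:
    def test_hand_fit_matches_partial_likelihood_oracle(self):
        # 6 persons, one binary covariate, no ties
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 0, 1], bool)
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])

        def neg_log_pl(beta):
            ll = 0.0
            for i in range(6):
                if not event[i]:
                    continue
                risk = time >= time[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        oracle = optimize.minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded").x
        fit = fit_cause_specific_cox(
            cox_frame(time, event, x), "other", adjusters=(), compute_concordance=False
        )
        assert fit.coefficients.loc["fi_per_0.1", "coef"] == pytest.approx(
            oracle, abs=1e-4
        )
        assert fit.n_events == 4

    def test_zero_events_raises(self, small_cohort):
        _, data = small_cohort
        censored_only = data[data["cause"] == "censored"]
        with pytest.raises(NoEventsError):
            fit_cause_specific_cox(censored_only, "cvd")

    def test_competing_causes_are_censored(self, small_cohort):
        _, data = small_cohort
        fits = {
            c: fit_cause_specific_cox(data, c, compute_concordance=False)
            for c in ("cvd", "cancer", "other")
        }
        total_deaths = int((data["cause"] != "censored").sum())
        assert sum(f.n_events for f in fits.values()) == total_deaths
        assert all(f.n == len(data[data.fi.notna()]) for f in fits.values())

    def test_category_parameterization(self, small_cohort):
        _, data = small_cohort
        fit = fit_cause_specific_cox(
            data, "all_cause", fi_param="categories", compute_concordance=False
        )
        assert {"pre_frail", "frail"} <= set(fit.coefficients.index)
        assert fit.hr("frail") > fit.hr("pre_frail") > 0

    def test_cause_relabeling_symmetry(self, small_cohort):
        _, data = small_cohort
        swapped = data.copy()
        swapped["cause"] = data["cause"].map(
            {"cvd": "cancer", "cancer": "cvd", "other": "other", "censored": "censored"}
        )
        a = fit_cause_specific_cox(data, "cvd", compute_concordance=False)
        b = fit_cause_specific_cox(swapped, "cancer", compute_concordance=False)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)

    def test_concordance_attached_and_sane(self, small_cohort):
        _, data = small_cohort
        fit = fit_cause_specific_cox(data, "all_cause")
        assert isinstance(fit.concordance, ConcordanceResult)
        assert 0.5 < fit.concordance.c < 1.0

    def test_invalid_target_cause(self, small_cohort):
        _, data = small_cohort
        with pytest.raises(ValueError, match="target_cause"):
            fit_cause_specific_cox(data, "respiratory")


class TestPHTest:
    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 50
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.5 * x))
            event = t < 2.5
            t = np.minimum(t, 2.5)
            fit = fit_cause_specific_cox(
                cox_frame(t, event, x), "other", adjusters=(), compute_concordance=False
            )
            if ph_test(fit)["global"] < 0.05:
                rejections += 1
        assert rejections <= 8  # ~5% nominal; Binomial(50, .05) upper tail

    def test_detects_effect_reversal(self):
        # hazard effect +1 before t=1, -1 after: a strong PH violation
        rng = np.random.default_rng(23)
        n = 5000
        x = rng.normal(size=n)
        u = rng.exponential(size=n)
        early = u < np.exp(x) * 1.0
        t = np.where(early, u * np.exp(-x), 1.0 + (u - np.exp(x)) * np.exp(x))
        event = t < 4.0
        t = np.minimum(t, 4.0)
        fit = fit_cause_specific_cox(
            cox_frame(t, event, x), "other", adjusters=(), compute_concordance=False
        )
        assert ph_test(fit)["fi_per_0.1"] < 0.05

    def test_requires_more_events_than_covariates(self):
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 0], bool)
        fit = fit_cause_specific_cox(
            cox_frame(time, event, np.array([0.5, -0.5, 0.1])),
            "other",
            adjusters=(),
            compute_concordance=False,
        )
        with pytest.raises(ValueError, match="events"):
            ph_test(fit)

    def test_supported_on_default_cohort(self, small_cohort):
        _, data = small_cohort
        fit = fit_cause_specific_cox(
            data, "all_cause", adjust_age=True, compute_concordance=False
        )
        pvals = ph_test(fit)
        assert set(pvals) > {"global", "fi_per_0.1"}
        assert all(0.0 <= p <= 1.0 for p in pvals.values())


class TestLRTInteraction:
    def test_null_pvalues_uniform(self):
        from fraildex.simulate import GeneratorConfig, generate_cohort

        pvals = []
        for seed in range(50):
            cohort = generate_cohort(GeneratorConfig(n=1500, seed=3000 + seed))
            data = make_analysis_frame(cohort)
            res = lrt_interaction(data, "sex", adjusters=("sex",))
            pvals.append(res.p)
        assert res.df == 1
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_injected_interaction(self):
        rng = np.random.default_rng(11)
        n = 10_000
        fi01 = rng.uniform(0, 4, n)  # FI/0.1 in [0, 4]
        fem = rng.random(n) < 0.5
        lam = 0.03 * np.exp(np.log(1.2) * fi01 + np.log(1.5) * fi01 * fem)
        t = rng.exponential(1 / lam)
        event = t < 8.0
        t = np.minimum(t, 8.0)
        data = cox_frame(t, event, fi01)
        data["sex"] = np.where(fem, "female", "male")
        res = lrt_interaction(data, "sex", adjusters=("sex",))
        assert res.p < 0.05
        assert res.chi2 > 0 and res.df == 1

    def test_education_interaction_has_two_df(self, small_cohort):
        _, data = small_cohort
        res = lrt_interaction(data, "education")
        assert res.df == 2
        assert 0.0 <= res.p <= 1.0
        assert res.ll_full >= res.ll_reduced - 1e-8
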