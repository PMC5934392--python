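"""Kaplan-Meier, log-rank, Cox PH and the treatment-interaction analysis."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from gcsubtype import EP, MP, SimulationConfig, SubtypeLabels, ValidationError
from gcsubtype.simulate import simulate_clinical
from gcsubtype.survival import (
    ConvergenceError,
    cox_fit,
    cox_loglik,
    cox_score_test,
    encode_covariates,
    fit_cox_arrays,
    interaction_test,
    km_by_stage,
    km_estimate,
    logrank_test,
    subset_for_adjuvant_analysis,
)


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        value, beyond = km.survival_at(3.5)
        assert value == 1.0
        v2, beyond2 = km.survival_at(100.0)
        assert v2 == 1.0 and beyond2

    def test_product_limit_hand_computation(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival_at(1.0)[0] == pytest.approx(2 / 3)
        assert km.survival_at(2.5)[0] == pytest.approx(1 / 3)
        assert km.survival_at(3.0)[0] == pytest.approx(0.0)

    def test_doubling_times_rescales_x_axis_only(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        a = km_estimate(t, e)
        b = km_estimate(2 * t, e)
        for q in (1.0, 3.0, 7.0):
            assert a.survival_at(q)[0] == pytest.approx(b.survival_at(2 * q)[0])

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1, 2], [1, 1])

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3, 200)
        km = km_estimate(t, np.ones(200, dtype=int))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km.survival_at(q)[0] == pytest.approx((t > q).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_null(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2, 40)
        e = rng.integers(0, 2, 40)
        res = logrank_test(np.r_[t, t], np.r_[e, e], [0] * 40 + [1] * 40)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_zero_events_flagged(self):
        res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert res.zero_events and res.p == 1.0

    def test_matches_breslow_cox_score_test(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2, 120)                 # continuous: no ties
        e = rng.integers(0, 2, 120)
        e[:5] = 1
        g = rng.integers(0, 2, 120)
        res = logrank_test(t, e, g)
        score = cox_score_test(g.reshape(-1, 1).astype(float), t, e, ties="breslow")
        assert res.chi2 == pytest.approx(score, rel=1e-10)


class TestCoxFit:
    def _sim(self, rng, n=250, beta=(0.8, -0.4)):
        x1 = rng.binomial(1, 0.5, n).astype(float)
        x2 = rng.normal(0, 1, n)
        haz = 0.1 * np.exp(beta[0] * x1 + beta[1] * x2)
        T = rng.exponential(1 / haz)
        C = rng.exponential(12, n)
        return np.column_stack([x1, x2]), np.minimum(T, C), (T <= C).astype(int)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines(self, ties):
        rng = np.random.default_rng(4)
        X, t, e = self._sim(rng)
        if ties == "efron":
            t = np.round(t, 0) + 0.5          # force ties; lifelines uses Efron
        fit = fit_cox_arrays(X, t, e, names=["x1", "x2"], ties=ties)
        df = pd.DataFrame({"t": t, "e": e, "x1": X[:, 0], "x2": X[:, 1]})
        ll = CoxPHFitter().fit(df, "t", "e")
        if ties == "efron":
            assert np.allclose(fit.coef.values, ll.params_.values, atol=1e-5)
            assert np.allclose(fit.se.values, ll.standard_errors_.values, atol=1e-5)
        else:
            # untied data: Breslow and Efron coincide
            assert np.allclose(fit.coef.values, ll.params_.values, atol=1e-5)
        assert fit.lrt_stat >= 0.0

    def test_brute_force_small_instance(self):
        """n=6, binary covariate: grid maximization of the written-out
        partial likelihood agrees to 1e-6."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])

        def pl(beta):
            order = np.argsort(t)
            ll = 0.0
            for i in order:
                if e[i] == 0:
                    continue
                risk = [j for j in range(6) if t[j] >= t[i]]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-5, 5, 2001)
        brute = grid[np.argmax([pl(b) for b in grid])]
        fit = fit_cox_arrays(x.reshape(-1, 1), t, e, names=["x"])
        assert fit.coef["x"] == pytest.approx(brute, abs=5e-3)
        assert cox_loglik([fit.coef["x"]], x, t, e) == pytest.approx(
            pl(fit.coef["x"]), abs=1e-10
        )
        assert fit.coef["x"] == pytest.approx(
            _golden_max(pl, brute - 0.1, brute + 0.1), abs=1e-6
        )

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(5)
        X, t, e = self._sim(rng, n=150)
        a = fit_cox_arrays(X, t, e)
        b = fit_cox_arrays(X, t**2, e)
        assert np.allclose(a.coef.values, b.coef.values, atol=1e-8)

    def test_parameter_recovery_hr2(self):
        rng = np.random.default_rng(6)
        X, t, e = self._sim(rng, n=600, beta=(np.log(2.0), 0.0))
        fit = fit_cox_arrays(X[:, :1], t, e, names=["grp"])
        assert fit.hazard_ratios["grp"] == pytest.approx(2.0, rel=0.25)
        assert fit.ci_lower["grp"] < 2.0 < fit.ci_upper["grp"]

    def test_too_few_events_and_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="events"):
            fit_cox_arrays(np.ones((4, 1)) * [[0], [1], [0], [1]],
                           [1, 2, 3, 4], [1, 0, 0, 0])
        with pytest.raises(ValidationError, match="constant"):
            fit_cox_arrays(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 1, 1])

    def test_complete_separation_flagged(self):
        # all covariate=1 subjects censored late: likelihood is monotone
        t = np.r_[np.arange(1, 11), np.full(10, 50.0)]
        e = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        x = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_cox_arrays(x.reshape(-1, 1), t, e)
        assert any("monotone" in w for w in fit.warnings_)

    def test_stage_encodings(self):
        df = pd.DataFrame({"stage": ["I", "II", "III", "IV"],
                           "sex": ["M", "F", "M", "F"]})
        num = encode_covariates(df, ["stage", "sex"])
        assert list(num["stage"]) == [1.0, 2.0, 3.0, 4.0]
        assert list(num["sex_m"]) == [1.0, 0.0, 1.0, 0.0]
        cat = encode_covariates(df, ["stage"], stage_coding="categorical")
        assert list(cat.columns) == ["stage_II", "stage_III", "stage_IV"]


def _golden_max(f, lo, hi, tol=1e-9):
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b = d
        else:
            a = c
        c, d = b - gr * (b - a), a + gr * (b - a)
    return (a + b) / 2


class TestAdjuvantSubset:
    def test_rules(self):
        df = pd.DataFrame({
            "stage": ["I", "II", "IV", "IV", "III"],
            "distant_metastasis": [0, 0, 1, 0, 0],
        })
        out = subset_for_adjuvant_analysis(df)
        assert list(out.index) == [1, 3, 4]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "stage": rng.choice(["I", "II", "III", "IV"], 500),
            "distant_metastasis": rng.integers(0, 2, 500),
        })
        out = subset_for_adjuvant_analysis(df)
        expected = [i for i in df.index
                    if df.loc[i, "stage"] in ("II", "III", "IV")
                    and df.loc[i, "distant_metastasis"] == 0]
        assert list(out.index) == expected


class TestInteraction:
    def test_detects_ep_only_chemo_benefit_with_power(self):
        """At hr_chemo_ep=0.45 vs 1.0 and n=400, the EP benefit shows with
        CI excluding 1 and the interaction reaches p<0.05 in most replicates."""
        hits_ci, hits_p = 0, 0
        reps = 10
        for r in range(reps):
            config = SimulationConfig(hr_chemo_ep=0.45, hr_chemo_mp=1.0, seed=19)
            clinical, labels = simulate_clinical(config, 400, stream=r)
            res = interaction_test(clinical, labels)
            assert res.hr_chemo_ep < 1.0
            hits_ci += res.ci_chemo_ep[1] < 1.0
            hits_p += res.interaction_p < 0.05
        assert hits_ci > reps / 2
        assert hits_p >= 0.7 * reps

    def test_relabeling_subtypes_negates_interaction_coefficient(self):
        config = SimulationConfig(hr_chemo_ep=0.5, hr_chemo_mp=1.2, seed=23)
        clinical, labels = simulate_clinical(config, 300)
        res = interaction_test(clinical, labels)
        swapped = SubtypeLabels(labels.labels.map({MP: EP, EP: MP}))
        res2 = interaction_test(clinical, swapped)
        assert res2.interaction_coef == pytest.approx(-res.interaction_coef, abs=1e-5)
        assert res2.interaction_p == pytest.approx(res.interaction_p, abs=1e-6)

    def test_empty_stratum_named_in_error(self):
        config = SimulationConfig(seed=29)
        clinical, labels = simulate_clinical(config, 100)
        broken = clinical.copy()
        mp_ids = labels.samples(MP)
        broken.loc[broken["sample_id"].isin(mp_ids), "chemo"] = 1
        with pytest.raises(ValidationError, match="subtype=MP, chemo=0"):
            interaction_test(broken, labels)


class TestKMByStage:
    def test_stage_independent_hazard_ratio_shows_in_every_stratum(self):
        config = SimulationConfig(hr_mp=2.5, hr_chemo_ep=1.0, hr_chemo_mp=1.0,
                                  seed=37)
        clinical, labels = simulate_clinical(config, 800)
        table = km_by_stage(clinical, labels)
        assert (table["p"] < 0.05).sum() >= 3          # majority of strata
        assert (table["note"] == "").all()

    def test_single_subtype_stratum_skipped_with_note(self):
        config = SimulationConfig(seed=41)
        clinical, labels = simulate_clinical(config, 120)
        forced = labels.labels.copy()
        stage1 = clinical.loc[clinical["stage"] == "I", "sample_id"]
        forced.loc[stage1] = EP
        table = km_by_stage(clinical, SubtypeLabels(forced))
        assert "skipped" in table.loc["I", "note"]
        assert np.isnan(table.loc["I", "p"])
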