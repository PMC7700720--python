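import numpy as np
import pandas as pd
import pytest

from lncssn.survival import (
    HIGH,
    LOW,
    RiskModel,
    assign_risk_groups,
    build_risk_model,
    dichotomize_by_median,
    fit_multivariate_cox,
    independence_analysis,
    kaplan_meier,
    logrank_test,
    risk_score,
    split_cohort,
    time_dependent_roc,
    truncate_follow_up,
    univariate_cox_screen,
)
from lncssn.synthetic import SimulationConfig, simulate_cohort
from lncssn.preprocess import filter_low_expression, normalize_counts


def _clinical(ids, os_days, event):
    n = len(ids)
    return pd.DataFrame(
        {
            "os_days": os_days,
            "event": event,
            "age": [60] * n,
            "sex": ["male"] * n,
            "weight": [70.0] * n,
            "grade": [2] * n,
            "stage": [1] * n,
            "group": ["tumor"] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def _exponential_cohort(seed, n, beta, censor_scale=2000.0):
    """Exponential survival with log-hazard beta'x on standard-normal covariates."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    x = rng.standard_normal((n, len(beta)))
    hazard = 1e-3 * np.exp(x @ beta)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(censor_scale, size=n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    cov = pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))],
                       index=[f"P{i}" for i in range(n)])
    return cov, pd.Series(times, index=cov.index), pd.Series(events, index=cov.index)


class TestCohortHandling:
    def test_split_307_gives_154_and_153(self):
        clin = _clinical([f"P{i}" for i in range(307)], [100] * 307, [1] * 307)
        train, test = split_cohort(clin, seed=0)
        assert len(train) == 154 and len(test) == 153
        assert set(train) | set(test) == set(clin.index)
        assert set(train) & set(test) == set()

    def test_split_is_seeded_and_even_for_n4(self):
        clin = _clinical(["a", "b", "c", "d"], [1, 2, 3, 4], [1, 1, 1, 1])
        assert split_cohort(clin, 3) == split_cohort(clin, 3)
        train, test = split_cohort(clin, 3)
        assert len(train) == 2 and len(test) == 2
        with pytest.raises(ValueError, match="at least 4"):
            split_cohort(clin.iloc[:3], 0)

    def test_median_dichotomization(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = dichotomize_by_median(values)
        assert list(groups) == [LOW, LOW, HIGH, HIGH]
        n = 307
        odd = pd.Series(np.arange(n, dtype=float), index=[f"P{i}" for i in range(n)])
        labels = dichotomize_by_median(odd)
        assert (labels == HIGH).sum() == 154 and (labels == LOW).sum() == 153
        with pytest.raises(ValueError, match="degenerate"):
            dichotomize_by_median(pd.Series([2.0, 2.0, 2.0]))

    def test_follow_up_truncation(self):
        clin = _clinical(["a", "b"], [3000, 1000], [1, 1])
        out = truncate_follow_up(clin, 1825)
        assert out.loc["a", "os_days"] == 1825 and out.loc["a", "event"] == 0
        assert out.loc["b", "os_days"] == 1000 and out.loc["b", "event"] == 1


def _binary_partial_loglik(beta, x, times, events):
    """Breslow partial log-likelihood for a single covariate, no ties assumed."""
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            at_risk = x[i:]
            ll += beta * x[i] - np.log(np.exp(beta * at_risk).sum())
    return ll


class TestCoxFitting:
    def test_single_covariate_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        n = 40
        x = rng.integers(0, 2, size=n).astype(float)
        # continuous times: no ties, so Breslow == Efron
        times = rng.exponential(1.0 / (1e-2 * np.exp(0.8 * x)))
        events = np.ones(n, dtype=int)
        cov = pd.DataFrame({"x": x}, index=[f"P{i}" for i in range(n)])
        model = fit_multivariate_cox(
            cov, pd.Series(times, index=cov.index), pd.Series(events, index=cov.index)
        )
        grid = np.arange(-3, 3, 1e-4)
        lls = [_binary_partial_loglik(b, x, times, events) for b in grid]
        assert model.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
        assert model.hr[0] == pytest.approx(np.exp(model.beta[0]))

    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            fit_multivariate_cox(
                cov,
                pd.Series([1, 2, 3, 4.0], index=cov.index),
                pd.Series([1, 1, 1, 1], index=cov.index),
            )

    def test_more_covariates_than_events_rejected(self):
        cov = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 0.5], "y": [1.0, 0.0, 2.0, 1.5]}, index=list("abcd")
        )
        with pytest.raises(ValueError, match="events"):
            fit_multivariate_cox(
                cov,
                pd.Series([1, 2, 3, 4.0], index=cov.index),
                pd.Series([0, 0, 0, 1], index=cov.index),
            )

    def test_parameter_recovery_single_seed(self):
        cov, times, events = _exponential_cohort(1, 500, beta=(0.5, -0.3))
        model = fit_multivariate_cox(cov, times, events)
        se = (np.log(model.ci95[:, 1]) - np.log(model.ci95[:, 0])) / (2 * 1.96)
        assert np.all(np.abs(model.beta - np.array([0.5, -0.3])) < 3 * se)


class TestUnivariateScreen:
    def _screen_input(self, seed, n, effect):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(1, n)),
            index=["LNC0"],
            columns=[f"P{i}" for i in range(n)],
        )
        high = (expr.loc["LNC0"] >= expr.loc["LNC0"].median()).to_numpy()
        hazard = 1e-3 * np.exp(effect * high.astype(float))
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(2500.0, size=n)
        clin = _clinical(
            expr.columns,
            np.minimum(t_event, t_cens),
            (t_event <= t_cens).astype(int),
        )
        return expr, clin

    def test_alpha_zero_selects_nothing(self):
        expr, clin = self._screen_input(0, 100, effect=1.0)
        selected, models = univariate_cox_screen(expr, clin, ["LNC0"], alpha=0.0)
        assert selected == [] and "LNC0" in models

    def test_protective_effect_detected(self):
        hits = 0
        for seed in range(10):
            expr, clin = self._screen_input(seed, 200, effect=np.log(0.4))
            selected, _ = univariate_cox_screen(expr, clin, ["LNC0"])
            hits += "LNC0" in selected
        assert hits >= 9

    def test_empty_candidate_list_rejected(self):
        expr, clin = self._screen_input(0, 50, effect=0.0)
        with pytest.raises(ValueError, match="no candidate"):
            univariate_cox_screen(expr, clin, [])


class TestRiskScore:
    def test_printed_coefficients_sum(self):
        model = RiskModel(
            lnc_ids=["a", "b", "c"], coefficients=[0.5324, 0.7105, 0.3738], cutoff=0.0
        )
        expr = pd.DataFrame(
            np.ones((3, 1)), index=["a", "b", "c"], columns=["patient"]
        )
        assert risk_score(model, expr)["patient"] == pytest.approx(1.6167)

    def test_zero_expression_gives_zero_score_and_linearity(self):
        model = RiskModel(lnc_ids=["a", "b"], coefficients=[0.5, -0.25], cutoff=0.0)
        expr = pd.DataFrame(
            [[0.0, 2.0, 4.0], [0.0, 1.0, 2.0]], index=["a", "b"], columns=list("xyz")
        )
        scores = risk_score(model, expr)
        assert scores["x"] == 0.0
        assert scores["z"] == pytest.approx(2 * scores["y"])

    def test_doubling_one_gene_adds_its_coefficient(self):
        model = RiskModel(lnc_ids=["a", "b"], coefficients=[0.4, 0.1], cutoff=0.0)
        base = pd.DataFrame([[1.0], [1.0]], index=["a", "b"], columns=["p"])
        doubled = base.copy()
        doubled.loc["a"] = 2.0
        delta = risk_score(model, doubled)["p"] - risk_score(model, base)["p"]
        assert delta == pytest.approx(0.4)

    def test_missing_lncRNA_rejected(self):
        model = RiskModel(lnc_ids=["a", "z"], coefficients=[0.4, 0.1], cutoff=0.0)
        expr = pd.DataFrame([[1.0]], index=["a"], columns=["p"])
        with pytest.raises(ValueError, match="missing"):
            risk_score(model, expr)

    def test_group_assignment_rules(self):
        scores = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        groups = assign_risk_groups(scores, 0.5)
        assert list(groups) == [LOW, HIGH, HIGH]
        shifted = assign_risk_groups(scores + 10.0, 10.5)
        assert list(shifted) == list(groups)
        assert (assign_risk_groups(scores, 1.0) == LOW).all()

    def test_training_median_splits_even(self):
        rng = np.random.default_rng(2)
        cov, times, events = _exponential_cohort(3, 154, beta=(0.6,))
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(2, 154)),
            index=["g1", "g2"],
            columns=cov.index,
        )
        clin = _clinical(cov.index, times, events)
        model = build_risk_model(expr, clin, ["g1", "g2"])
        groups = assign_risk_groups(risk_score(model, expr), model.cutoff)
        assert (groups == HIGH).sum() == 77 and (groups == LOW).sum() == 77


class TestKaplanMeierAndLogrank:
    def test_product_limit_hand_example(self):
        t = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        e = pd.Series([1, 1, 1, 1], index=t.index)
        g = pd.Series(["all"] * 4, index=t.index)
        curves = kaplan_meier(t, e, g)
        sf, median = curves["all"]
        assert sf.loc[2.0, "survival"] == pytest.approx(0.5)
        assert median == 2.0
        # no censoring: KM equals the empirical survival function
        assert sf.loc[3.0, "survival"] == pytest.approx(0.25)

    def test_all_censored_median_not_reached(self):
        t = pd.Series([5.0, 6.0, 7.0], index=list("abc"))
        e = pd.Series([0, 0, 0], index=t.index)
        curves = kaplan_meier(t, e, pd.Series(["g"] * 3, index=t.index))
        sf, median = curves["g"]
        assert (sf["survival"] == 1.0).all()
        assert np.isinf(median)

    def test_survival_curve_monotone_from_one(self):
        rng = np.random.default_rng(0)
        t = pd.Series(rng.exponential(100, 50))
        e = pd.Series(rng.integers(0, 2, 50))
        sf, _ = kaplan_meier(t, e, pd.Series(["g"] * 50))["g"]
        s = sf["survival"].to_numpy()
        assert s[0] == 1.0 and (np.diff(s) <= 1e-12).all()

    def test_identical_groups_score_zero(self):
        t = pd.Series([3.0, 5, 8, 3, 5, 8], index=list("abcdef"))
        e = pd.Series([1, 0, 1, 1, 0, 1], index=t.index)
        g = pd.Series(["A", "A", "A", "B", "B", "B"], index=t.index)
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        # groups: A dies at 1, 3; B dies at 2; censored: A at 4, B at 5, 6
        t = pd.Series([1.0, 3.0, 4.0, 2.0, 5.0, 6.0], index=list("abcdef"))
        e = pd.Series([1, 1, 0, 1, 0, 0], index=t.index)
        g = pd.Series(["A", "A", "A", "B", "B", "B"], index=t.index)
        # observed-minus-expected for group A per event time:
        # t=1: O=1, E=3/6, V=0.25; t=2: O=0, E=2/5, V=0.24; t=3: O=1, E=2/4, V=0.25
        # U = 2 - 1.4 = 0.6, Var = 0.74 -> chi2 = 0.6^2 / 0.74
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.6**2 / 0.74, rel=1e-10)

    def test_requires_exactly_two_groups(self):
        t = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        e = pd.Series([1, 1, 1], index=t.index)
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(t, e, pd.Series(["A", "B", "C"], index=t.index))

    def test_logrank_agrees_with_cox_wald_on_large_sample(self):
        cov, times, events = _exponential_cohort(7, 1000, beta=(0.2,))
        binary = (cov["x0"] > 0).astype(float)
        model = fit_multivariate_cox(
            binary.to_frame("grp"), times, events
        )
        wald_chi2 = (model.beta[0] / (
            (np.log(model.ci95[0, 1]) - np.log(model.ci95[0, 0])) / (2 * 1.96)
        )) ** 2
        groups = pd.Series(np.where(binary > 0, "hi", "lo"), index=cov.index)
        stat, _ = logrank_test(times, events, groups)
        assert stat == pytest.approx(wald_chi2, rel=0.05)


class TestTimeDependentRoc:
    def test_perfect_marker(self):
        t = pd.Series([100.0, 200, 300, 2000, 2100, 2200], index=list("abcdef"))
        e = pd.Series([1, 1, 1, 0, 0, 0], index=t.index)
        scores = pd.Series([6.0, 5, 4, 1, 2, 3], index=t.index)
        roc = time_dependent_roc(scores, t, e, horizon=1825)
        assert roc.auc == 1.0

    def test_constant_marker_is_chance(self):
        t = pd.Series([100.0, 200, 2000, 2100], index=list("abcd"))
        e = pd.Series([1, 1, 0, 0], index=t.index)
        scores = pd.Series([1.0, 1, 1, 1], index=t.index)
        roc = time_dependent_roc(scores, t, e, horizon=1825)
        assert roc.auc == 0.5

    def test_uncensored_toy_equals_pair_counting(self):
        rng = np.random.default_rng(0)
        t = pd.Series(rng.uniform(10, 3000, 30))
        e = pd.Series(np.ones(30, dtype=int))
        scores = pd.Series(rng.normal(size=30) + (t < 1825) * 1.0)
        roc = time_dependent_roc(scores, t, e, horizon=1825)
        cases = scores[t <= 1825]
        controls = scores[t > 1825]
        pairs = sum(
            1.0 if c > n else 0.5 if c == n else 0.0
            for c in cases
            for n in controls
        )
        assert roc.auc == pytest.approx(pairs / (len(cases) * len(controls)))

    def test_matches_independent_ipcw_estimator(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        cov, times, events = _exponential_cohort(11, 300, beta=(0.8,))
        scores = pd.Series(cov["x0"].to_numpy(), index=cov.index)
        horizon = float(np.quantile(times, 0.6))
        roc = time_dependent_roc(scores, times, events, horizon=horizon)
        y = np.array(
            list(zip(events.astype(bool), times)),
            dtype=[("event", bool), ("time", float)],
        )
        auc, _ = sksurv_metrics.cumulative_dynamic_auc(
            y, y, scores.to_numpy(), [horizon]
        )
        assert roc.auc == pytest.approx(float(auc[0]), abs=0.02)

    def test_needs_cases_and_controls(self):
        t = pd.Series([100.0, 200.0], index=list("ab"))
        e = pd.Series([1, 1], index=t.index)
        s = pd.Series([1.0, 2.0], index=t.index)
        with pytest.raises(ValueError, match="case and one control"):
            time_dependent_roc(s, t, e, horizon=50)  # no cases by day 50
        with pytest.raises(ValueError, match="follow-up range"):
            time_dependent_roc(s, t, e, horizon=250)


class TestIndependenceAnalysis:
    def _cohort_with_risk(self, seed=0, n=160):
        rng = np.random.default_rng(seed)
        risk = rng.standard_normal(n)
        hazard = 1e-3 * np.exp(0.9 * (risk > 0))
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(2500.0, size=n)
        clin = _clinical(
            [f"P{i}" for i in range(n)],
            np.minimum(t_event, t_cens),
            (t_event <= t_cens).astype(int),
        )
        clin["age"] = rng.integers(30, 85, n)
        clin["sex"] = rng.choice(["male", "female"], n)
        clin["weight"] = rng.normal(75, 12, n)
        clin["grade"] = rng.choice([1, 2, 3, 4], n)
        clin["stage"] = rng.choice([1, 2, 3, 4], n)
        groups = pd.Series(
            np.where(risk > 0, HIGH, LOW), index=clin.index, name="risk_group"
        )
        return clin, groups

    def test_report_shape_and_definitional_hr(self):
        clin, groups = self._cohort_with_risk()
        report = independence_analysis(clin, groups)
        assert len(report) == 6
        np.testing.assert_allclose(
            report["multi_hr"], np.exp(report["multi_beta"]), rtol=1e-10
        )

    def test_risk_term_significant_nuisance_not(self):
        """Only the risk group drives hazard; nuisance covariates are null."""
        risk_hits, nuisance_ok = 0, 0
        for seed in range(5):
            clin, groups = self._cohort_with_risk(seed=seed)
            report = independence_analysis(clin, groups)
            risk_hits += report.loc["risk_score_high_vs_low", "multi_p"] < 0.05
            nuisance_ok += report.loc["weight", "multi_p"] > 0.05
        assert risk_hits >= 4 and nuisance_ok >= 4
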