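import numpy as np
import pytest

import ruletrait as rt
from ruletrait.errors import ConfigError, EmptyGroupError, UndefinedTestError
from ruletrait.rules import Condition, Rule, RuleSet
from ruletrait.validation import SurvivalData


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        d = SurvivalData([1.0, 2.0, 3.0], [0, 0, 0], [1, 1, 1])
        curve = rt.km_estimate(d, 1)
        assert curve.event_times.size == 0

    def test_hand_product_limit_no_censoring(self):
        d = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1], [1, 1, 1])
        curve = rt.km_estimate(d, 1)
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        np.testing.assert_allclose(curve.event_times, [1.0, 2.0, 3.0])

    def test_hand_product_limit_with_censoring(self):
        # subjects: event at 1, censored at 2, event at 3
        # S(1) = 2/3; at t=3 risk set is {third}: S(3) = 2/3 * 0 = 0
        d = SurvivalData([1.0, 2.0, 3.0], [1, 0, 1], [1, 1, 1])
        curve = rt.km_estimate(d, 1)
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0], atol=1e-12)

    def test_matches_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 60)
        d = SurvivalData(t, np.ones(60, int), np.ones(60, int))
        curve = rt.km_estimate(d, 1)
        ts = np.sort(t)
        ecdf = np.searchsorted(ts, curve.event_times, side="right") / 60
        np.testing.assert_allclose(curve.survival, 1 - ecdf, atol=1e-12)

    def test_bands_contain_estimate(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, 80)
        e = (rng.random(80) < 0.7).astype(int)
        d = SurvivalData(t, e, np.ones(80, int))
        c = rt.km_estimate(d, 1)
        assert (c.ci_lower <= c.survival + 1e-12).all()
        assert (c.ci_upper >= c.survival - 1e-12).all()
        assert (c.ci_upper <= 1.0).all()
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_empty_group_rejected(self):
        d = SurvivalData([1.0], [1], [0])
        with pytest.raises(EmptyGroupError):
            rt.km_estimate(d, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        d = SurvivalData(np.tile(t, 2), np.tile(e, 2), np.repeat([0, 1], 4))
        stat, p = rt.logrank_test(d)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        d = SurvivalData(
            rng.exponential(1, 50), (rng.random(50) < 0.8).astype(int),
            (rng.random(50) < 0.5).astype(int),
        )
        s1, p1 = rt.logrank_test(d)
        d2 = SurvivalData(d.time, d.event, 1 - d.group)
        s2, p2 = rt.logrank_test(d2)
        assert s1 == pytest.approx(s2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_perfect_early_late_separation_tiny_p(self):
        t = np.concatenate([np.linspace(0.1, 1, 50), np.linspace(5, 6, 50)])
        d = SurvivalData(t, np.ones(100, int), np.repeat([1, 0], 50))
        _, p = rt.logrank_test(d)
        assert p < 1e-6

    def test_no_events_undefined(self):
        d = SurvivalData([1.0, 2.0], [0, 0], [0, 1])
        with pytest.raises(UndefinedTestError):
            rt.logrank_test(d)


class TestAUC:
    def test_perfect_scores(self):
        assert rt.auc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_all_ties_half(self):
        assert rt.auc([0.3, 0.3, 0.3], [0, 1, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert rt.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_reversal_complement_without_ties(self):
        rng = np.random.default_rng(3)
        s = rng.random(30)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        assert rt.auc(s, y) + rt.auc(-s, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            rt.auc([0.1, 0.2], [1, 1])


class TestValidateRules:
    def test_support_one_rule_untestable(self, planted_marker_cohort):
        t = planted_marker_cohort.markers
        rules = RuleSet([Rule((Condition("m0", lower=-1e12),))])
        out = rt.validate_rules(t, rules)
        assert not out[0].testable

    def test_planted_rule_separates_km_curves(self, planted_marker_cohort):
        t = planted_marker_cohort.markers
        rules = RuleSet([Rule((Condition("m0", lower=0.5), Condition("m1", upper=0.3)))])
        out = rt.validate_rules(t, rules)
        v = out[0]
        assert v.testable and v.p_value < 0.01
        # risk-increasing rule: endorsed group has worse survival at the end
        assert v.km_endorsed.survival[-1] < v.km_not_endorsed.survival[-1]

    def test_consistent_with_direct_logrank(self, planted_marker_cohort):
        t = planted_marker_cohort.markers
        rule = Rule((Condition("m2", upper=-0.4), Condition("m3", lower=-0.2)))
        out = rt.validate_rules(t, RuleSet([rule]))
        g = rt.binarize([rule], t).values[:, 0]
        stat, p = rt.logrank_test(SurvivalData(t.time, t.event, g))
        assert out[0].statistic == pytest.approx(stat)
        assert out[0].p_value == pytest.approx(p)


class TestCV:
    def test_same_seed_identical_report(self, planted_marker_cohort):
        t = planted_marker_cohort.markers
        kw = dict(
            n_repeats=2,
            induce_kwargs={"n_trees": 25},
            mcmc_kwargs={"n_samples": 300, "n_burn": 100},
        )
        r1 = rt.cv_80_20(t, seed=5, **kw)
        r2 = rt.cv_80_20(t, seed=5, **kw)
        assert r1.results.equals(r2.results)

    def test_single_class_outcome_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"x": np.arange(30.0), "outcome": np.ones(30, int)})
        with pytest.raises(ConfigError):
            rt.cv_80_20(rt.MarkerTable(df, ["x"]), n_repeats=1, seed=0)

    def test_comparator_methods_recorded(self, planted_marker_cohort):
        from sklearn.tree import DecisionTreeClassifier

        t = planted_marker_cohort.markers
        rep = rt.cv_80_20(
            t,
            n_repeats=2,
            seed=6,
            induce_kwargs={"n_trees": 25},
            mcmc_kwargs={"n_samples": 300, "n_burn": 100},
            comparators={"tree": DecisionTreeClassifier(max_depth=3, random_state=0)},
        )
        assert set(rep.results.method) == {"latent-trait", "tree"}
        assert ((rep.results.auc >= 0) & (rep.results.auc <= 1)).all()
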