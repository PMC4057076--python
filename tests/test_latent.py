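import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import ruletrait as rt
from ruletrait.errors import ConfigError, DegenerateItemError, SchemaError
from ruletrait.latent import (
    ItemParams,
    LatentTraitModel,
    OutcomeLink,
    model_from_json,
    model_to_json,
)


class TestCurves:
    @pytest.mark.parametrize("a,b", [(0.5, -1.0), (2.0, 0.0), (3.0, 1.7), (-1.3, 0.4)])
    def test_icc_half_at_difficulty(self, a, b):
        assert rt.icc(b, a, b) == 0.5

    def test_icc_closed_form_value(self):
        assert rt.icc(1.0, 2.0, 0.0) == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)

    def test_icc_point_symmetry(self):
        th = np.linspace(-4, 4, 33)
        a, b = 1.7, 0.6
        np.testing.assert_allclose(rt.icc(th, a, b) + rt.icc(2 * b - th, a, b), 1.0, atol=1e-12)

    def test_icc_monotone_with_sign_of_a(self):
        th = np.linspace(-4, 4, 100)
        assert (np.diff(rt.icc(th, 2.0, 0.3)) > 0).all()
        assert (np.diff(rt.icc(th, -2.0, 0.3)) < 0).all()

    def test_iic_peak_value(self):
        a, b = 2.2, -0.7
        assert rt.iic(b, a, b) == pytest.approx(a**2 / 4, abs=1e-12)

    def test_iic_zero_discrimination(self):
        th = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(rt.iic(th, 0.0, 1.0), 0.0, atol=1e-15)

    def test_iic_symmetric_about_difficulty(self):
        a, b, d = 1.4, 0.9, 0.63
        assert rt.iic(b + d, a, b) == pytest.approx(rt.iic(b - d, a, b), abs=1e-12)

    def test_iic_maximized_at_difficulty(self):
        th = np.linspace(-5, 5, 1001)
        vals = rt.iic(th, 1.8, 0.25)
        assert abs(th[np.argmax(vals)] - 0.25) < 0.02


class TestLogPosterior:
    def test_single_subject_all_zero_params(self):
        X = np.array([[1]])
        y = np.array([1])
        lp = rt.log_posterior(
            np.zeros(1), np.zeros(1), np.zeros(1), 0.0, 0.0, endorsements=X, outcome=y
        )
        prior_const = (
            norm.logpdf(0.0, scale=1.0)
            + 2 * norm.logpdf(0.0, scale=2.0)
            + 2 * norm.logpdf(0.0, scale=10.0)
        )
        assert lp == pytest.approx(2 * np.log(0.5) + prior_const, abs=1e-12)

    def test_duplicating_subjects_doubles_likelihood(self):
        rng = np.random.default_rng(0)
        n, J = 6, 3
        X = (rng.random((n, J)) < 0.5).astype(int)
        y = (rng.random(n) < 0.5).astype(int)
        th = rng.standard_normal(n)
        a, b = rng.standard_normal(J), rng.standard_normal(J)

        def parts(Xm, ym, thm):
            full = rt.log_posterior(thm, a, b, 0.3, 0.7, endorsements=Xm, outcome=ym)
            prior = (
                norm.logpdf(thm).sum()
                + norm.logpdf(a, scale=2).sum()
                + norm.logpdf(b, scale=2).sum()
                + 2 * norm.logpdf(0.0, scale=10.0)
                + norm.logpdf(0.3, scale=10.0)
                + norm.logpdf(0.7, scale=10.0)
                - 2 * norm.logpdf(0.0, scale=10.0)
            )
            return full - prior

        single = parts(X, y, th)
        double = parts(np.vstack([X, X]), np.concatenate([y, y]), np.concatenate([th, th]))
        assert double == pytest.approx(2 * single, abs=1e-9)

    def test_matches_bruteforce_summation(self):
        # independent oracle: term-by-term scalar re-summation
        rng = np.random.default_rng(1)
        n, J = 5, 3
        X = (rng.random((n, J)) < 0.5).astype(int)
        y = (rng.random(n) < 0.5).astype(int)
        th = rng.standard_normal(n)
        a, b = rng.standard_normal(J), rng.standard_normal(J)
        b0, b1 = 0.4, 1.1

        total = 0.0
        for i in range(n):
            for j in range(J):
                p = 1 / (1 + np.exp(-a[j] * (th[i] - b[j])))
                total += np.log(p if X[i, j] else 1 - p)
            q = 1 / (1 + np.exp(-(b0 + b1 * th[i])))
            total += np.log(q if y[i] else 1 - q)
            total += norm.logpdf(th[i])
        for j in range(J):
            total += norm.logpdf(a[j], scale=2) + norm.logpdf(b[j], scale=2)
        total += norm.logpdf(b0, scale=10) + norm.logpdf(b1, scale=10)

        lp = rt.log_posterior(th, a, b, b0, b1, endorsements=X, outcome=y)
        assert lp == pytest.approx(total, abs=1e-10)

    def test_greedy_coordinate_ascent_increases_density(self):
        rng = np.random.default_rng(2)
        n, J = 8, 2
        X = (rng.random((n, J)) < 0.5).astype(int)
        y = (rng.random(n) < 0.5).astype(int)
        params = {
            "theta": np.zeros(n), "a": np.ones(J), "b": np.zeros(J),
            "beta0": 0.0, "beta1": 0.5,
        }

        def lp(p):
            return rt.log_posterior(
                p["theta"], p["a"], p["b"], p["beta0"], p["beta1"],
                endorsements=X, outcome=y,
            )

        cur = lp(params)
        eps = 0.05
        for _ in range(3):
            for key in params:
                for idx in np.ndindex(np.shape(params[key]) or (1,)):
                    for sign in (+1, -1):
                        trial = {k: np.array(v, dtype=float, copy=True) for k, v in params.items()}
                        if np.shape(params[key]):
                            trial[key][idx] += sign * eps
                        else:
                            trial[key] = trial[key] + sign * eps
                        val = lp(trial)
                        if val > cur:
                            params, cur = trial, val
            assert lp(params) >= cur - 1e-12
        assert cur > lp({"theta": np.zeros(n), "a": np.ones(J), "b": np.zeros(J),
                         "beta0": 0.0, "beta1": 0.5}) - 1e-12


class TestMCMC:
    def test_degenerate_items_rejected_with_index(self, small_latent_cohort):
        em, y, _ = small_latent_cohort
        X = em.values.copy()
        X[:, 3] = 1
        with pytest.raises(DegenerateItemError) as exc:
            rt.fit_mcmc(X, y, n_samples=50, n_burn=10, seed=0)
        assert 3 in exc.value.indices

    def test_same_seed_identical_chains(self, small_latent_cohort):
        em, y, _ = small_latent_cohort
        s1 = rt.fit_mcmc(em, y, n_samples=300, n_burn=100, seed=4)
        s2 = rt.fit_mcmc(em, y, n_samples=300, n_burn=100, seed=4)
        np.testing.assert_array_equal(s1.a, s2.a)
        np.testing.assert_array_equal(s1.beta1, s2.beta1)
        np.testing.assert_array_equal(s1.theta, s2.theta)

    def test_beta1_nonnegative_in_every_draw(self, small_latent_cohort):
        em, y, _ = small_latent_cohort
        s = rt.fit_mcmc(em, y, n_samples=400, n_burn=100, seed=5)
        assert (s.beta1 >= 0).all()

    def test_too_few_items_rejected(self):
        X = np.tile([[0], [1]], (15, 1))
        with pytest.raises(ConfigError):
            rt.fit_mcmc(X, np.tile([0, 1], 15), n_samples=20, n_burn=5, seed=0)

    def test_point_estimates_match_bruteforce_mean(self, small_latent_cohort):
        em, y, _ = small_latent_cohort
        s = rt.fit_mcmc(em, y, n_samples=250, n_burn=50, seed=6)
        m = rt.point_estimates(s)
        # independent oracle: scalar accumulation over retained draws
        acc = np.zeros(s.a.shape[1])
        for r in range(s.a.shape[0]):
            acc += s.a[r]
        np.testing.assert_allclose(m.items.a, acc / s.a.shape[0], atol=1e-12)
        assert s.a.shape[0] == s.n_total - s.n_burn

    def test_draws_csv_export(self, small_latent_cohort, tmp_path):
        import pandas as pd

        em, y, _ = small_latent_cohort
        s = rt.fit_mcmc(em, y, n_samples=120, n_burn=40, seed=8)
        p = tmp_path / "draws.csv"
        s.to_csv(p)
        df = pd.read_csv(p, index_col="draw")
        assert len(df) == s.n_retained
        np.testing.assert_allclose(df["beta1"].to_numpy(), s.beta1, atol=1e-6)

    def test_two_stage_mode_runs(self, small_latent_cohort):
        em, y, _ = small_latent_cohort
        s = rt.fit_mcmc(em, n_samples=300, n_burn=100, seed=7, joint=False)
        m = rt.point_estimates(s)
        assert np.isfinite(m.items.a).all()
        # items-only identification: mean discrimination nonnegative
        assert m.items.a.mean() >= 0


class TestInference:
    def _model(self, a, b, beta0=0.0, beta1=2.0):
        return LatentTraitModel(ItemParams(np.asarray(a, float), np.asarray(b, float)),
                                OutcomeLink(beta0, beta1))

    def test_no_endorsements_pulls_theta_negative(self):
        m = self._model([1.5, 2.0, 1.0], [0.0, -0.5, 0.5])
        mean, sd = rt.infer_theta(m, np.zeros((1, 3)))
        assert mean[0] < 0
        assert 0 < sd[0] < 1

    def test_zero_information_returns_prior(self):
        m = self._model([0.0, 0.0], [0.0, 1.0])
        mean, sd = rt.infer_theta(m, np.array([[1, 0]]))
        assert mean[0] == 0.0 and sd[0] == 1.0

    def test_theta_monotone_in_positive_endorsements(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            J = 6
            a = rng.uniform(0.5, 2.5, J)
            b = rng.uniform(-1.5, 1.5, J)
            m = self._model(a, b)
            x = (rng.random(J) < 0.5).astype(float)
            j = int(rng.integers(J))
            x0, x1 = x.copy(), x.copy()
            x0[j], x1[j] = 0.0, 1.0
            m0, _ = rt.infer_theta(m, x0[None, :])
            m1, _ = rt.infer_theta(m, x1[None, :])
            assert m1[0] >= m0[0]

    def test_column_mismatch_rejected(self):
        m = self._model([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(SchemaError):
            rt.infer_theta(m, np.zeros((2, 3)))

    def test_flat_link_gives_constant_risk(self):
        m = self._model([1.5, -1.0], [0.2, -0.3], beta0=0.7, beta1=0.0)
        X = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
        risk = rt.predict_risk(m, X)
        np.testing.assert_allclose(risk, expit(0.7), atol=1e-12)

    def test_risk_monotone_in_inferred_severity(self):
        rng = np.random.default_rng(4)
        J = 5
        a = rng.uniform(0.5, 2.0, J) * rng.choice([-1, 1], J)
        m = self._model(a, rng.uniform(-1, 1, J))
        X = (rng.random((40, J)) < 0.5).astype(float)
        theta_hat, _ = rt.infer_theta(m, X)
        risk = rt.predict_risk(m, X)
        order = np.argsort(theta_hat)
        assert (np.diff(risk[order]) >= -1e-9).all()

    def test_plugin_mode_close_to_marginal(self):
        m = self._model([2.0, 1.5, 1.0], [0.0, 0.5, -0.5], beta0=-0.2, beta1=1.0)
        X = np.array([[1, 1, 0], [0, 0, 1]], dtype=float)
        pm = rt.predict_risk(m, X, marginalize=True)
        pp = rt.predict_risk(m, X, marginalize=False)
        assert np.all((pm > 0) & (pm < 1))
        assert np.allclose(pm, pp, atol=0.1)

    def test_model_json_roundtrip(self, tmp_path):
        m = self._model([1.0, -2.0], [0.3, -0.4], beta0=0.1, beta1=1.7)
        p = tmp_path / "model.json"
        model_to_json(m, p)
        back = model_from_json(p)
        np.testing.assert_allclose(back.items.a, m.items.a)
        np.testing.assert_allclose(back.items.b, m.items.b)
        assert back.link.beta1 == pytest.approx(1.7)
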