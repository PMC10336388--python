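"""Savage-Dickey Bayes factors, HDIs, marginal effects and GLMM fitting."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import shoalspect as ss
from shoalspect.errors import DataError
from shoalspect.glmm import (
    BayesianGLMM,
    SavageDickeyBF,
    build_design,
    gp_covariance,
    marginal_contrast,
    savage_dickey_bf,
)
from shoalspect.simulate import generate_behavior_table


def quiet_fit(model, data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(data)


class TestHdi:
    def test_uniform_draws_width_is_nominal(self):
        """Order statistics: the 89% HDI of U(0,1) draws has width ~0.89."""
        rng = np.random.default_rng(0)
        lo, hi = ss.hdi(rng.uniform(size=100_000), 0.89)
        assert hi - lo == pytest.approx(0.89, abs=0.01)

    def test_narrowest_window_beats_central_interval(self):
        rng = np.random.default_rng(1)
        draws = rng.gamma(2.0, 1.0, size=50_000)  # skewed
        lo, hi = ss.hdi(draws, 0.89)
        qlo, qhi = np.quantile(draws, [0.055, 0.945])
        assert hi - lo <= qhi - qlo
        assert np.mean((draws >= lo) & (draws <= hi)) >= 0.89 - 1e-3

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ss.hdi(np.array([1.0, 2.0]))


class TestSavageDickey:
    def test_posterior_equal_to_prior_gives_unit_bf(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0, 1, size=50_000)
        bf = savage_dickey_bf(norm.pdf(0, 0, 1), draws)
        assert bf.bayes_factor == pytest.approx(1.0, rel=0.05)

    def test_shifted_posterior_matches_closed_form(self):
        """Prior N(0,1), posterior N(1.5, 0.5^2): the ratio of normal
        densities at 0 is the analytic answer (~45)."""
        rng = np.random.default_rng(3)
        draws = rng.normal(1.5, 0.5, size=200_000)
        bf = savage_dickey_bf(norm.pdf(0, 0, 1), draws)
        want = norm.pdf(0, 0, 1) / norm.pdf(0, 1.5, 0.5)
        assert bf.direction == "for"
        assert bf.bayes_factor == pytest.approx(want, rel=0.15)

    def test_posterior_far_from_null_hits_ceiling(self):
        """Posterior N(3, 0.5^2): no draws near 0, the KDE density
        underflows and the ratio is reported as > ceiling with a flag."""
        rng = np.random.default_rng(3)
        draws = rng.normal(3.0, 0.5, size=200_000)
        bf = savage_dickey_bf(norm.pdf(0, 0, 1), draws)
        assert bf.capped and bf.direction == "for"
        assert bf.bayes_factor >= 1e6

    def test_conjugate_normal_normal_analytic_oracle(self):
        """Savage-Dickey at 10k draws vs the exact marginal-likelihood BF
        in the conjugate normal-normal model (within 5%)."""
        rng = np.random.default_rng(2)
        tau, sigma, n = 1.0, 2.0, 25
        mu_true = 0.6
        y = rng.normal(mu_true, sigma, size=n)
        post_var = 1.0 / (1 / tau**2 + n / sigma**2)
        post_mean = post_var * y.sum() / sigma**2
        draws = rng.normal(post_mean, np.sqrt(post_var), size=10_000)
        bf = savage_dickey_bf(norm.pdf(0, 0, tau), draws)
        # analytic BF10 = m1(y)/m0(y) via marginal likelihoods
        from scipy.stats import multivariate_normal

        cov1 = sigma**2 * np.eye(n) + tau**2 * np.ones((n, n))
        m1 = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov1)
        m0 = np.sum(norm.logpdf(y, 0, sigma))
        want = np.exp(m1 - m0)
        got = bf.bayes_factor if bf.direction == "for" else 1 / bf.bayes_factor
        assert got == pytest.approx(want, rel=0.05)

    def test_vanishing_posterior_density_reports_ceiling(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(50.0, 0.1, size=10_000)
        bf = savage_dickey_bf(norm.pdf(0, 0, 1), draws)
        assert bf.capped and bf.direction == "for"

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            savage_dickey_bf(0.4, np.zeros(100))


class TestClassifyBf:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (1.0, "weak"),
            (2.9, "weak"),
            (3.0, "moderate"),
            (9.5, "moderate"),
            (10.0, "strong"),
            (29.9, "strong"),
            (30.0, "very strong"),
            (68.0, "very strong"),
            (100.0, "very strong"),
            (100.1, "extreme"),
        ],
    )
    def test_band_edges(self, bf, label):
        assert ss.classify_bf(bf) == label

    def test_sub_unit_bf_rejected(self):
        with pytest.raises(ValueError):
            ss.classify_bf(0.5)

    def test_strength_property_on_result(self):
        assert SavageDickeyBF(9.5, "for").strength == "moderate"


class TestMarginalContrast:
    def test_identical_levels_give_zero_effect(self):
        rng = np.random.default_rng(6)
        eta = rng.normal(1.0, 0.3, size=20_000)
        (lo, hi), eff = marginal_contrast(eta, eta, "log")
        assert eff == 0.0 and lo == 0.0 and hi == 0.0

    def test_poisson_log_link_closed_form(self):
        eta_a = np.full(5000, np.log(2.0))
        eta_b = np.full(5000, np.log(8.0))
        (_, _), eff = marginal_contrast(eta_a, eta_b, "log")
        assert eff == pytest.approx(6.0)

    def test_link_monotonicity_preserved(self):
        rng = np.random.default_rng(7)
        eta_a = rng.normal(0.0, 0.5, 10_000)
        eta_b = eta_a + 0.7  # predictor ordering is uniform across draws
        for link in ("log", "logit"):
            (lo, hi), eff = marginal_contrast(eta_a, eta_b, link)
            assert eff > 0 and lo > 0


class TestBuildDesign:
    def test_treatment_coding_and_centering(self):
        data = pd.DataFrame(
            {
                "group_size": [5, 10, 20],
                "temperature_c": [23.0, 24.0, 25.0],
                "mean_length_mm": [28.0, 30.0, 32.0],
            }
        )
        X, names = build_design(data)
        assert names == [
            "intercept",
            "g_intermediate",
            "g_large",
            "temperature_c",
            "mean_length_mm",
        ]
        assert X[:, 1].tolist() == [0.0, 1.0, 0.0]
        assert X[:, 2].tolist() == [0.0, 0.0, 1.0]
        assert X[:, 3].mean() == pytest.approx(0.0)

    def test_unknown_group_size_rejected(self):
        data = pd.DataFrame(
            {"group_size": [7], "temperature_c": [24.0], "mean_length_mm": [30.0]}
        )
        with pytest.raises(DataError):
            build_design(data)


class TestBayesianGLMM:
    def test_poisson_effect_recovery(self):
        """A strong known group effect lands inside the 89% HDI and earns
        evidence 'for'."""
        coefs = {
            "intercept": 1.0,
            "g_intermediate": 0.0,
            "g_large": 1.2,
            "temperature_c": 0.0,
            "mean_length_mm": 0.0,
            "sigma_trial": 0.2,
        }
        data, _ = generate_behavior_table(coefs, family="poisson", seed=8)
        data = data.rename(columns={"y": "n_inspections"})
        m = quiet_fit(
            BayesianGLMM("n_inspections", family="poisson", random_state=0), data
        )
        draws = m.draws_["g_large"]
        lo, hi = ss.hdi(draws)
        assert lo <= 1.2 <= hi
        c = m.contrast("small", "large")
        assert c.bf_direction == "for"
        assert c.hdi89[0] <= c.marginal_effect <= c.hdi89[1]
        assert c.marginal_effect > 0

    def test_single_trial_rejected(self):
        data = pd.DataFrame(
            {
                "trial_id": ["T01"] * 5,
                "group_size": [5] * 5,
                "temperature_c": [24.0] * 5,
                "mean_length_mm": [30.0] * 5,
                "y": [1, 2, 0, 1, 3],
            }
        )
        with pytest.raises(DataError, match="2 trials"):
            BayesianGLMM("y", family="poisson").fit(data)

    def test_family_input_validation(self):
        coefs = {"intercept": 0.0, "sigma_trial": 0.1}
        data, _ = generate_behavior_table(coefs, family="poisson", seed=9)
        data["y"] = data["y"] + 0.5
        with pytest.raises(DataError, match="integer"):
            BayesianGLMM("y", family="poisson").fit(data)
        data["y"] = -1.0
        with pytest.raises(DataError, match="positive"):
            BayesianGLMM("y", family="gamma").fit(data)

    def test_beta_boundary_values_squeezed_not_fatal(self):
        coefs = {"intercept": 0.0, "sigma_trial": 0.1, "kappa": 5.0}
        data, _ = generate_behavior_table(coefs, family="beta", seed=10)
        data.loc[data.index[:3], "y"] = 0.0
        data.loc[data.index[3:5], "y"] = 1.0
        m = quiet_fit(
            BayesianGLMM("y", family="beta", n_steps=400, n_burn=150, random_state=0),
            data,
        )
        assert np.isfinite(m.draws_["intercept"]).all()

    def test_contrast_table_lists_all_three_ordered_pairs(self):
        coefs = {"intercept": 0.5, "sigma_trial": 0.2}
        data, _ = generate_behavior_table(coefs, family="poisson", seed=11)
        data = data.rename(columns={"y": "n_inspections"})
        m = quiet_fit(
            BayesianGLMM(
                "n_inspections", family="poisson", n_steps=500, n_burn=200,
                random_state=0,
            ),
            data,
        )
        t = m.contrast_table()
        assert t["contrast"].tolist() == [
            "small -> intermediate",
            "small -> large",
            "intermediate -> large",
        ]
        assert (t["bayes_factor"] > 0).all()
        assert (t["hdi89_lo"] <= t["marginal_effect"]).all()
        assert (t["marginal_effect"] <= t["hdi89_hi"]).all()


class TestGpTerm:
    @staticmethod
    def _cohesion_data(seed, n_trials=6, f=None, kappa=25.0):
        rng = np.random.default_rng(seed)
        gs = ([5, 10, 20] * 5)[:n_trials]
        rows = []
        for j in range(n_trials):
            u = rng.normal(0, 0.2)
            temp = 24 + rng.normal(0, 0.3)
            for minute in range(1, 15):
                eta = -0.8 + u + (0.0 if f is None else f[minute - 1])
                mu = 1 / (1 + np.exp(-eta))
                rows.append(
                    dict(
                        trial_id=f"T{j:02d}",
                        group_size=gs[j],
                        temperature_c=temp,
                        mean_length_mm=30.0,
                        phase="before" if minute <= 7 else "during",
                        minute_index=minute,
                        y=rng.beta(mu * kappa, (1 - mu) * kappa),
                    )
                )
        return pd.DataFrame(rows)

    def test_covariance_limits(self):
        t = np.arange(1, 15, dtype=float)
        k_flat = gp_covariance(t, 1.0, 1e6)
        assert np.allclose(k_flat, k_flat[0, 0] * np.ones((14, 14)), atol=1e-6)
        k_zero = gp_covariance(t, 0.0, 3.0)
        assert np.allclose(k_zero, 1e-9 * np.eye(14))

    def test_vanishing_amplitude_matches_plain_model(self):
        """With the GP amplitude pinned to ~0 the time-series model's
        predictions equal the non-GP model's."""
        data = self._cohesion_data(12)
        kw = dict(
            family="beta", prior_set="beta_refuge", phase_interaction=True,
            n_steps=500, n_burn=200, random_state=0,
        )
        plain = quiet_fit(BayesianGLMM("y", **kw), data)
        gp = quiet_fit(
            BayesianGLMM("y", gp_time=True, gp_amplitude=1e-8, gp_lengthscale=3.0, **kw),
            data,
        )
        pred_plain = plain.predict(data)
        pred_gp = gp.predict(data)
        assert np.allclose(pred_plain, pred_gp, atol=0.02)

    def test_infinite_lengthscale_gives_constant_smooth(self):
        data = self._cohesion_data(13)
        gp = quiet_fit(
            BayesianGLMM(
                "y", family="beta", prior_set="beta_refuge", phase_interaction=True,
                gp_time=True, gp_amplitude=0.5, gp_lengthscale=1e5,
                n_steps=500, n_burn=200, random_state=0,
            ),
            data,
        )
        f = gp.gp_function_draws()
        # every draw of the smooth is flat across minutes
        assert np.max(f.max(axis=1) - f.min(axis=1)) < 1e-3

    def test_gp_beats_plain_model_on_autocorrelated_minutes(self):
        """AR(1) structure over minutes: the GP model's predictive density
        for the held-out final minute beats the plain GLMM on average."""
        from scipy.special import gammaln, logsumexp

        def predictive_logdens(model, test):
            Xm, _ = build_design(test, model.continuous, model.phase_interaction)
            beta = np.column_stack([model.draws_[n] for n in model.coef_names_])
            eta = beta @ Xm.T
            if model.gp_time:
                fdraws = model.gp_function_draws()
                eta = eta + fdraws[:, test["minute_index"].to_numpy(int) - 1]
            mu = 1 / (1 + np.exp(-eta))
            mu = np.clip(mu, 1e-9, 1 - 1e-9)
            kap = model.draws_["kappa"][:, None]
            y = test["y"].to_numpy()
            ll = (
                gammaln(kap)
                - gammaln(mu * kap)
                - gammaln((1 - mu) * kap)
                + (mu * kap - 1) * np.log(y)
                + ((1 - mu) * kap - 1) * np.log1p(-y)
            ).sum(axis=1)
            return logsumexp(ll) - np.log(len(ll))

        diffs = []
        for sim in range(6):
            rng = np.random.default_rng(100 + sim)
            ar = np.zeros(14)
            for t in range(1, 14):
                ar[t] = 0.85 * ar[t - 1] + rng.normal(0, 0.45)
            data = self._cohesion_data(200 + sim, f=ar)
            train = data[data["minute_index"] <= 13]
            test = data[data["minute_index"] == 14]
            kw = dict(
                family="beta", prior_set="beta_refuge", phase_interaction=True,
                n_steps=500, n_burn=200, random_state=sim,
            )
            plain = quiet_fit(BayesianGLMM("y", **kw), train)
            gp = quiet_fit(BayesianGLMM("y", gp_time=True, **kw), train)
            diffs.append(predictive_logdens(gp, test) - predictive_logdens(plain, test))
        assert np.mean(diffs) > 0


class TestInspectorsGLM:
    @staticmethod
    def _groups(counts_by_size):
        rows = []
        meta_rows = []
        trial = 0
        for size, counts in counts_by_size.items():
            trial += 1
            tid = f"T{trial:02d}"
            meta_rows.append(
                dict(trial_id=tid, group_size=size, temperature_c=24.0,
                     mean_length_mm=30.0)
            )
            for i, c in enumerate(counts):
                rows.append(
                    dict(trial_id=tid, start_frame=i * 100, end_frame=i * 100 + 50,
                         inspector_ids=tuple(range(c)), n_inspectors=c)
                )
        return pd.DataFrame(rows), pd.DataFrame(meta_rows)

    def test_constant_counts_give_log_mean(self):
        groups, meta = self._groups({5: [2] * 30, 10: [3] * 30, 20: [5] * 30})
        table = ss.fit_inspectors_glm(groups, meta)
        est = table.set_index("group_size_label")["estimate_log"]
        assert est["small"] == pytest.approx(np.log(2), abs=1e-6)
        assert est["intermediate"] == pytest.approx(np.log(3), abs=1e-6)
        assert est["large"] == pytest.approx(np.log(5), abs=1e-6)

    def test_simulated_means_within_two_se(self):
        rng = np.random.default_rng(14)
        means = {5: 2.5, 10: 3.7, 20: 5.5}
        counts = {
            size: np.maximum(rng.poisson(mu, 200), 1).tolist()
            for size, mu in means.items()
        }
        groups, meta = self._groups(counts)
        table = ss.fit_inspectors_glm(groups, meta).set_index("group_size_label")
        for size, label in ((5, "small"), (10, "intermediate"), (20, "large")):
            truth = np.log(np.mean(counts[size]))
            row = table.loc[label]
            assert abs(row["estimate_log"] - truth) <= 2 * row["se"] + 1e-9

    def test_missing_level_is_singular(self):
        groups, meta = self._groups({5: [2] * 10, 10: [3] * 10})
        with pytest.raises(DataError, match="singular"):
            ss.fit_inspectors_glm(groups, meta)
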