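"""Likelihoods, initial-condition model, and the joint density composition."""

import numpy as np
import pytest
from scipy.special import gammaln

import deerpop as dp
from deerpop.data_model import ModelParams, _initial_logpdf
from deerpop.inference import _loglik_terms


def _multinomial_logpmf_oracle(y, n, pi):
    """Direct factorial-formula evaluation, independent of scipy.stats."""
    y = np.asarray(y, float)
    return float(gammaln(n + 1) - gammaln(y + 1).sum() + (y * np.log(pi)).sum())


def _normal_logpdf_oracle(x, mu, sd):
    return float(-0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2)


def _dirichlet_logpdf_oracle(x, alpha):
    x, alpha = np.asarray(x, float), np.asarray(alpha, float)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(x)).sum()
    )


class TestClassificationProportions:
    def test_simple_shares(self):
        pi = dp.classification_proportions(np.array([1.0, 1.0, 2.0]))
        np.testing.assert_allclose(pi, [0.25, 0.25, 0.5])

    def test_degenerate_stage(self):
        np.testing.assert_allclose(
            dp.classification_proportions(np.array([0.0, 5.0, 0.0])), [0, 1, 0]
        )

    def test_treated_females_pooled(self):
        """Sterile does are indistinguishable in the field: pooled with fertile."""
        pi = dp.classification_proportions(np.array([10.0, 20.0, 20.0, 50.0]))
        assert pi[1] == pytest.approx(0.4)
        assert pi.sum() == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            dp.classification_proportions(np.zeros(3))


class TestClassificationLoglik:
    def test_empty_observation(self):
        assert dp.classification_loglik(np.zeros(3), 0, np.array([0.2, 0.3, 0.5])) == 0.0

    def test_single_count(self):
        ll = dp.classification_loglik(np.array([1, 0, 0]), 1, np.array([0.25, 0.25, 0.5]))
        assert ll == pytest.approx(np.log(0.25))

    def test_matches_formula_oracle(self):
        y, pi = np.array([3, 4, 5]), np.array([0.25, 0.33, 0.42])
        assert dp.classification_loglik(y, 12, pi) == pytest.approx(
            _multinomial_logpmf_oracle(y, 12, pi), abs=1e-10
        )

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dp.classification_loglik(np.array([1, 1, 1]), 5, np.array([0.3, 0.3, 0.4]))

    def test_impossible_class(self):
        ll = dp.classification_loglik(np.array([1, 0, 0]), 1, np.array([0.0, 0.5, 0.5]))
        assert ll == -np.inf


class TestDensityLoglik:
    def test_at_the_mode(self):
        n = dp.StageVector(n1=10, n2=20, n3=10)
        ll = dp.density_loglik(4.0, 0.5, n, 10.0)
        assert ll == pytest.approx(np.log(1 / (0.5 * np.sqrt(2 * np.pi))))

    def test_one_se_deviation_costs_half(self):
        n = dp.StageVector(n1=10, n2=20, n3=10)
        assert dp.density_loglik(4.0, 0.5, n, 10.0) - dp.density_loglik(
            4.5, 0.5, n, 10.0
        ) == pytest.approx(0.5)

    def test_missing_contributes_zero(self):
        assert dp.density_loglik(np.nan, 0.5, dp.StageVector(n1=1, n2=1, n3=1), 1.0) == 0.0

    def test_matches_normal_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.uniform(1, 100, 3)
            area, se = rng.uniform(2, 50), rng.uniform(0.1, 5)
            y = rng.uniform(0, 60)
            assert dp.density_loglik(y, se, n, area) == pytest.approx(
                _normal_logpdf_oracle(y, n.sum() / area, se), abs=1e-10
            )


class TestInitialStateDraw:
    def test_uninformative_counts_give_uniform_dirichlet(self):
        rng = np.random.default_rng(0)
        draws = np.array(
            [dp.initial_state_draw(np.zeros(3), 10.0, 1.0, 5.0, rng).gamma1 for _ in range(4000)]
        )
        # Dirichlet(1,1,1) mean = 1/3 each
        np.testing.assert_allclose(draws.mean(axis=0), [1 / 3] * 3, atol=0.02)

    def test_dirichlet_mean_formula(self):
        rng = np.random.default_rng(1)
        y = np.array([10.0, 20.0, 10.0])
        draws = np.array(
            [dp.initial_state_draw(y, 10.0, 1.0, 5.0, rng).gamma1 for _ in range(4000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), (y + 1) / (y + 1).sum(), atol=0.02)

    def test_degenerate_se_recovers_density(self):
        rng = np.random.default_rng(2)
        init = dp.initial_state_draw(np.array([5.0, 5, 5]), 12.0, 1e-9, 4.0, rng)
        assert init.d1 == pytest.approx(12.0, abs=1e-6)
        np.testing.assert_allclose(init.n1, 12.0 * init.gamma1 * 4.0)

    def test_missing_year_one_data_raises(self):
        with pytest.raises(ValueError):
            dp.initial_state_draw(np.zeros(3), np.nan, 1.0, 5.0, np.random.default_rng(0))


def _toy_params_and_data(rng, P=2, T=4):
    design = dp.SyntheticDesign(
        n_parks=P, n_years=T, areas=(10.0, 5.0, 8.0)[:P],
    )
    data, truth = dp.generate_dataset(design, rng)
    vit = truth.vitals
    gamma1 = data.counts[:, 0] + 1.0
    gamma1 /= gamma1.sum(axis=1, keepdims=True)
    params = ModelParams(
        s=np.tile([vit.s1, vit.s2, vit.s3], (P, 1)),
        a=np.array([4.0, 6.0, 3.0]), b=np.array([2.0, 3.0, 4.0]),
        m=vit.m, r_f=vit.r_f, K_f=vit.K_f, sigma_p2=vit.sigma_p2,
        d1=data.density[:, 0].copy(), gamma1=gamma1,
    )
    logN = np.log(np.maximum(truth.states, 1e-6))
    return params, logN, data


class TestJointLogDensity:
    def test_finite_at_truth(self):
        params, logN, data = _toy_params_and_data(np.random.default_rng(21))
        assert np.isfinite(dp.joint_log_density(params, logN, data))

    def test_composition_matches_component_oracle(self):
        """Joint = prior + initial terms + process transitions + data terms."""
        cfg = dp.PriorConfig()
        for seed in range(20):
            params, logN, data = _toy_params_and_data(np.random.default_rng(100 + seed))
            total = dp.joint_log_density(params, logN, data, cfg)
            logN_eff = logN.copy()
            logN_eff[:, 0, :] = np.log(params.initial_states(data.areas))
            proc, dat = _loglik_terms(params, logN_eff, data, "ricker_exp")
            expected = (
                dp.log_prior(params, cfg)
                + _initial_logpdf(params, data)
                + proc.sum()
                + dat.sum()
            )
            assert total == pytest.approx(expected, rel=1e-12)

    def test_removing_one_observation_changes_by_its_loglik(self):
        params, logN, data = _toy_params_and_data(np.random.default_rng(55))
        base = dp.joint_log_density(params, logN, data)
        i, t = 1, 2
        data2 = dp.SurveyDataset(
            park_ids=data.park_ids, areas=data.areas, years=data.years,
            density=data.density.copy(), density_se=data.density_se.copy(),
            counts=data.counts.copy(),
        )
        data2.density[i, t] = np.nan
        data2.density_se[i, t] = np.nan
        dropped = dp.joint_log_density(params, logN, data2)
        logN_eff = logN.copy()
        logN_eff[:, 0, :] = np.log(params.initial_states(data.areas))
        n_it = np.exp(logN_eff[i, t])
        ll = dp.density_loglik(data.density[i, t], data.density_se[i, t], n_it, data.areas[i])
        assert base - dropped == pytest.approx(ll, abs=1e-9)

    def test_initial_prior_uses_dirichlet_and_truncnorm_oracles(self):
        params, logN, data = _toy_params_and_data(np.random.default_rng(77))
        from scipy import stats

        expected = 0.0
        for i in range(data.n_parks):
            alpha = data.counts[i, 0] + 1.0
            expected += _dirichlet_logpdf_oracle(params.gamma1[i], alpha)
            y, se = data.density[i, 0], data.density_se[i, 0]
            trunc = 1.0 - stats.norm.cdf(0.0, loc=y, scale=se)
            expected += _normal_logpdf_oracle(params.d1[i], y, se) - np.log(trunc)
        assert _initial_logpdf(params, data) == pytest.approx(expected, abs=1e-9)
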