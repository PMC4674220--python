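"""Forecasting under treatments and the decision metrics."""

import numpy as np
import pytest

import deerpop as dp
from conftest import make_degenerate_draws as _degenerate_draws


class TestForecast:
    def test_deterministic_limit_equals_repeated_projection(self, median_vitals):
        vit = median_vitals.with_(sigma_p2=0.5)
        draws = _degenerate_draws(vit, n=1)
        ens = dp.forecast(draws, 3, process_noise=False, rng=np.random.default_rng(0))
        f_form = draws.fecundity_form
        n = np.exp(draws.values["logN"][0, 0, :, -1, :])  # (P, 3)
        areas = draws.areas
        for y in range(3):
            out = np.empty_like(n)
            for i in range(len(areas)):
                D = n[i].sum() / areas[i]
                f = dp.fecundity(vit.r_f, vit.K_f, D, form=f_form)
                A = dp.build_projection_matrix(vit, f)
                out[i] = dp.project(A, n[i])
            n = out
            got = ens.states[0, y][:, [0, 1, 3]]
            np.testing.assert_allclose(got, n, rtol=1e-10)
            assert np.all(ens.states[0, y][:, 2] == 0.0)

    def test_regional_density_definition(self, median_vitals):
        draws = _degenerate_draws(median_vitals.with_(sigma_p2=0.5), n=3)
        ens = dp.forecast(draws, 2, rng=np.random.default_rng(1))
        expected = ens.states.sum(axis=(2, 3)) / draws.areas.sum()
        np.testing.assert_allclose(ens.regional_density(), expected)

    def test_heavy_cull_lowers_year1_density(self, small_draws):
        rng = lambda: np.random.default_rng(99)
        base = dp.forecast(small_draws, 1, rng=rng(), max_draws=400)
        cull = dp.forecast(
            small_draws, 1, dp.TreatmentSpec(type="cull", proportion=0.9),
            rng=rng(), max_draws=400,
        )
        assert np.median(cull.regional_density()[:, 0]) < np.median(
            base.regional_density()[:, 0]
        )

    def test_year1_density_monotone_in_cull_proportion(self, small_draws):
        meds = []
        for p in [0.0, 0.2, 0.4, 0.6, 0.9]:
            ens = dp.forecast(
                small_draws, 1, dp.TreatmentSpec(type="cull", proportion=p),
                rng=np.random.default_rng(5), max_draws=400,
            )
            meds.append(np.median(ens.regional_density()[:, 0]))
        assert all(b <= a + 1e-12 for a, b in zip(meds, meds[1:]))

    def test_invalid_horizon(self, small_draws):
        with pytest.raises(ValueError):
            dp.forecast(small_draws, 0)


class TestObjectiveProbabilities:
    def _ens_with_densities(self, dens):
        """Forecast ensemble stub whose regional densities equal ``dens``."""
        dens = np.asarray(dens, float)
        n = dens.shape[0]
        states = np.zeros((n, 1, 1, 4))
        states[:, 0, 0, 1] = dens  # area 1 => density equals abundance
        return dp.ForecastEnsemble(
            states=states, treated=np.zeros((n, 1, 1)), areas=np.array([1.0]),
            schedule=[dp.TreatmentSpec(type="none")],
        )

    def test_all_within(self):
        ens = self._ens_with_densities([10.0, 10.0, 10.0])
        assert dp.objective_probabilities(ens, dp.ManagementObjective(5, 15)) == (0, 1, 0)

    def test_thirds(self):
        ens = self._ens_with_densities([4.0, 10.0, 20.0])
        p = dp.objective_probabilities(ens, dp.ManagementObjective(5, 15))
        assert p == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_boundary_counts_as_within(self):
        ens = self._ens_with_densities([5.0, 15.0])
        assert dp.objective_probabilities(ens, dp.ManagementObjective(5, 15))[1] == 1.0

    def test_matches_counting_oracle_and_sums_to_one(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            dens = rng.uniform(0, 30, rng.integers(3, 50))
            ens = self._ens_with_densities(dens)
            lo, hi = sorted(rng.uniform(0, 30, 2))
            obj = dp.ManagementObjective(lo, hi)
            p_below, p_in, p_above = dp.objective_probabilities(ens, obj)
            n = len(dens)
            assert p_below == pytest.approx(np.sum(dens < lo) / n)
            assert p_above == pytest.approx(np.sum(dens > hi) / n)
            assert p_below + p_in + p_above == pytest.approx(1.0, abs=1e-12)


class TestNetEffect:
    def test_ten_times_more_likely(self):
        assert dp.net_effect(0.5, 0.05) == pytest.approx(10.0)

    def test_equal_probabilities(self):
        assert dp.net_effect(0.3, 0.3) == 1.0

    def test_zero_action_probability(self):
        assert dp.net_effect(0.0, 0.2) == 0.0

    def test_zero_baseline_warns_infinite(self):
        with pytest.warns(UserWarning):
            assert dp.net_effect(0.1, 0.0) == np.inf


class TestEffortAndCost:
    def test_no_treatment_no_effort(self, small_draws):
        ens = dp.forecast(small_draws, 3, rng=np.random.default_rng(0), max_draws=50)
        assert dp.treatment_effort(ens)["median_total"] == 0.0

    def test_single_draw_hand_sum(self, median_vitals):
        """Two-year sterilization effort equals the hand-computed p * n2 sums."""
        vit = median_vitals.with_(sigma_p2=0.5)
        draws = _degenerate_draws(vit, n=1)
        tr = dp.TreatmentSpec(type="sterilize", proportion=0.3)
        ens = dp.forecast(draws, 2, tr, process_noise=False, rng=np.random.default_rng(0))
        n2 = np.exp(draws.values["logN"][0, 0, :, -1, 1])
        year1 = 0.3 * n2
        post = np.stack([
            np.exp(draws.values["logN"][0, 0, :, -1, 0]),
            0.7 * n2, 0.3 * n2,
            np.exp(draws.values["logN"][0, 0, :, -1, 2]),
        ], axis=1)
        f_form = draws.fecundity_form
        nxt = np.empty_like(post)
        for i, area in enumerate(draws.areas):
            D = post[i].sum() / area
            f = dp.fecundity(vit.r_f, vit.K_f, D, form=f_form)
            A = dp.build_treated_matrix(vit, f, tr)
            nxt[i] = A @ post[i]
        year2 = 0.3 * nxt[:, 1]
        expected = year1.sum() + year2.sum()
        assert dp.treatment_effort(ens)["median_total"] == pytest.approx(expected, rel=1e-9)

    def test_cull_and_sterilize_effort_similar(self, small_draws):
        """Culling and sterilization handle similar numbers of does at equal p.

        Culling empties the doe pool but the density release boosts
        fecundity and recruits new fertile does; sterilization keeps
        density high but only newly fertile does are handled.  The two
        effects nearly cancel, so the efforts track each other closely.
        """
        p = 0.4
        cull = dp.forecast(
            small_draws, 5, dp.TreatmentSpec(type="cull", proportion=p),
            rng=np.random.default_rng(3), max_draws=300,
        )
        ster = dp.forecast(
            small_draws, 5, dp.TreatmentSpec(type="sterilize", proportion=p),
            rng=np.random.default_rng(3), max_draws=300,
        )
        e_cull = dp.treatment_effort(cull)["median_total"]
        e_ster = dp.treatment_effort(ster)["median_total"]
        assert abs(e_cull - e_ster) / e_ster < 0.25
        # and both are far below annual contraception, which re-treats reverting does
        contra = dp.forecast(
            small_draws, 5, dp.TreatmentSpec(type="contracept1", proportion=p),
            rng=np.random.default_rng(3), max_draws=300,
        )
        assert e_cull < dp.treatment_effort(contra)["median_total"]
        assert e_ster < dp.treatment_effort(contra)["median_total"]

    def test_combined_strategy_cheaper_than_fertility_alone(self, small_draws):
        """Cull hard once, then maintain: fewer animals handled than contraception alone."""
        p = 0.4
        horizon = 5
        schedule = [dp.TreatmentSpec(type="cull", proportion=0.9)] + [
            dp.TreatmentSpec(type="contracept1", proportion=p)
        ] * (horizon - 1)
        combined = dp.forecast(
            small_draws, horizon, schedule, rng=np.random.default_rng(4), max_draws=300
        )
        alone = dp.forecast(
            small_draws, horizon, dp.TreatmentSpec(type="contracept1", proportion=p),
            rng=np.random.default_rng(4), max_draws=300,
        )
        assert (
            dp.treatment_effort(combined)["median_total"]
            < dp.treatment_effort(alone)["median_total"]
        )

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"contracept1": 12_900}, 9_675_000.0),
            ({"cull": 3_510}, 1_298_700.0),
            ({"contracept1": 680}, 510_000.0),
            ({}, 0.0),
        ],
    )
    def test_program_cost_worked_examples(self, counts, expected):
        assert dp.program_cost(counts) == expected

    def test_program_cost_rejects_negative(self):
        with pytest.raises(ValueError):
            dp.program_cost({"cull": -1})


class TestDecisionSummary:
    def test_probabilities_sum_to_one(self, small_draws):
        ds = dp.decision_summary(
            small_draws, dp.TreatmentSpec(type="cull", proportion=0.4),
            dp.ManagementObjective(5, 15), horizon_years=3,
            rng=np.random.default_rng(0), max_draws=200,
        )
        assert ds.p_below + ds.p_in + ds.p_above == pytest.approx(1.0, abs=1e-12)
        assert ds.program_cost == pytest.approx(ds.median_total_treated * 370.0, rel=0.2)
        assert len(ds.p_in_by_year) == 3
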