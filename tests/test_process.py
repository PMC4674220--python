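"""Projection matrices, density-dependent fecundity, treatment events, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import deerpop as dp
from deerpop.process import POSITIVITY_FLOOR


class TestFecundity:
    @pytest.mark.parametrize(
        "D, expected",
        [(27.12, 1.0), (0.0, np.exp(0.86)), (54.24, np.exp(-0.86))],
    )
    def test_reference_values(self, D, expected):
        assert dp.fecundity(0.86, 27.12, D) == pytest.approx(expected, rel=1e-12)

    def test_scaled_form_max_is_rf(self):
        assert dp.fecundity(0.86, 27.12, 0.0, form="scaled") == pytest.approx(0.86)

    @given(
        r=st.floats(0.1, 3.0), K=st.floats(5.0, 80.0),
        d1=st.floats(0.0, 100.0), d2=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive_and_decreasing_in_density(self, r, K, d1, d2):
        lo, hi = sorted((d1, d2))
        f_lo, f_hi = dp.fecundity(r, K, lo), dp.fecundity(r, K, hi)
        assert f_lo > 0 and f_hi > 0
        if hi > lo:
            assert f_hi < f_lo

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            dp.fecundity(-0.1, 27.0, 1.0)
        with pytest.raises(ValueError):
            dp.fecundity(0.86, 0.0, 1.0)


class TestProjectionMatrix:
    def test_unit_survival_structure(self):
        vit = dp.VitalRates(s1=1 - 1e-12, s2=1 - 1e-12, s3=1 - 1e-12, m=0.5, r_f=1, K_f=1)
        A = dp.build_projection_matrix(vit, 0.0)
        np.testing.assert_allclose(A, [[0, 0, 0], [0.5, 1, 0], [0.5, 0, 1]], atol=1e-9)

    def test_median_vitals_entries(self, median_vitals):
        A = dp.build_projection_matrix(median_vitals, 0.86)
        assert A[0, 1] == pytest.approx(0.68 * 0.86)
        assert A[1, 0] == pytest.approx(0.76 * 0.53)
        assert A[2, 0] == pytest.approx(0.76 * 0.47)
        assert np.all(A >= 0)

    def test_zero_fecundity_growth_is_max_survival(self, median_vitals):
        A = dp.build_projection_matrix(median_vitals, 0.0)
        lam = dp.dominant_eigenvalue(A)
        assert lam == pytest.approx(max(median_vitals.s2, median_vitals.s3), abs=1e-10)


class TestTreatedMatrix:
    def test_sterilize_column_is_absorbing(self, median_vitals):
        A = dp.build_treated_matrix(
            median_vitals, 0.86, dp.TreatmentSpec(type="sterilize", proportion=0.4)
        )
        np.testing.assert_allclose(A[:, 2], [0, 0, 0.68, 0])

    def test_contracept3_mean_duration_three_years(self, median_vitals):
        tr = dp.TreatmentSpec(type="contracept3", proportion=0.4)
        # geometric reversion with annual rate 1/3 => mean time to reversion 3
        assert tr.reversion_rate == pytest.approx(1 / 3)
        assert 1.0 / tr.reversion_rate == pytest.approx(3.0)
        A = dp.build_treated_matrix(median_vitals, 0.86, tr)
        assert A[1, 2] == pytest.approx(0.68 / 3)
        assert A[2, 2] == pytest.approx(0.68 * 2 / 3)

    def test_untreated_limit_matches_three_stage(self, median_vitals):
        """With nobody treated, the 4-stage system reproduces 3-stage dynamics."""
        tr = dp.TreatmentSpec(type="contracept1", proportion=0.0)
        A4 = dp.build_treated_matrix(median_vitals, 0.86, tr)
        A3 = dp.build_projection_matrix(median_vitals, 0.86)
        n = dp.StageVector(n1=40, n2=60, n3=30)
        out4 = dp.project(A4, n.as_array(treated=True))
        out3 = dp.project(A3, n.as_array())
        np.testing.assert_allclose(out4[[0, 1, 3]], out3, rtol=1e-12)
        assert out4[2] == 0.0

    def test_unknown_type_rejected(self, median_vitals):
        with pytest.raises(ValueError):
            dp.TreatmentSpec(type="vaccinate", proportion=0.2)


class TestTreatmentEvent:
    def test_full_cull_empties_female_stages(self):
        n = dp.StageVector(n1=10, n2=100, n2s=5, n3=20)
        out, k = dp.apply_treatment_event(n, dp.TreatmentSpec(type="cull", proportion=1.0))
        assert out.n2 == 0 and out.n2s == 0
        assert k == pytest.approx(105)
        assert (out.n1, out.n3) == (10, 20)

    def test_sterilize_conserves_females(self):
        n = dp.StageVector(n1=0, n2=100, n2s=10, n3=0)
        out, k = dp.apply_treatment_event(
            n, dp.TreatmentSpec(type="sterilize", proportion=0.4)
        )
        assert out.n2 == pytest.approx(60)
        assert out.n2s == pytest.approx(50)
        assert k == pytest.approx(40)
        assert out.females == pytest.approx(n.females)

    @pytest.mark.parametrize("ttype", ["cull", "sterilize", "contracept1", "contracept3"])
    def test_zero_proportion_is_identity(self, ttype):
        n = dp.StageVector(n1=10, n2=20, n2s=3, n3=5)
        out, k = dp.apply_treatment_event(n, dp.TreatmentSpec(type=ttype, proportion=0.0))
        assert k == 0.0
        assert (out.n1, out.n2, out.n2s, out.n3) == (10, 20, 3, 5)

    @given(p=st.floats(0.0, 1.0), n2=st.floats(0.0, 500.0), n2s=st.floats(0.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_cull_scales_females_sterilize_conserves(self, p, n2, n2s):
        n = dp.StageVector(n1=7, n2=n2, n2s=n2s, n3=9)
        culled, _ = dp.apply_treatment_event(n, dp.TreatmentSpec(type="cull", proportion=p))
        assert culled.females == pytest.approx((1 - p) * n.females, abs=1e-9)
        ster, _ = dp.apply_treatment_event(n, dp.TreatmentSpec(type="sterilize", proportion=p))
        assert ster.females == pytest.approx(n.females, abs=1e-9)


class TestProject:
    def test_identity(self):
        n = dp.StageVector(n1=1, n2=2, n3=3)
        out = dp.project(np.eye(3), n)
        assert (out.n1, out.n2, out.n3) == (1, 2, 3)

    def test_median_matrix_hand_product(self, median_vitals):
        A = dp.build_projection_matrix(median_vitals, 0.86)
        out = dp.project(A, np.array([100.0, 100.0, 100.0]))
        np.testing.assert_allclose(out, [58.48, 108.28, 80.72], rtol=1e-12)

    def test_linearity(self, median_vitals):
        A = dp.build_projection_matrix(median_vitals, 0.5)
        n = np.array([10.0, 20.0, 30.0])
        np.testing.assert_allclose(dp.project(A, 3.0 * n), 3.0 * dp.project(A, n))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dp.project(np.eye(4), np.ones(3))

    def test_long_run_growth_equals_dominant_eigenvalue(self, median_vitals):
        """Power iteration of the projection matches eigenanalysis to 1e-6."""
        A = dp.build_projection_matrix(median_vitals, 0.86)
        n = np.array([100.0, 100.0, 100.0])
        for _ in range(200):
            n = dp.project(A, n)
            n /= n.sum()
        ratio = dp.project(A, n).sum() / n.sum()
        assert ratio == pytest.approx(dp.dominant_eigenvalue(A), abs=1e-6)


class TestProcessNoise:
    def test_zero_variance_is_exact(self):
        n = dp.StageVector(n1=5, n2=6, n3=7)
        out = dp.add_process_noise(n, 0.0, np.random.default_rng(0))
        assert (out.n1, out.n2, out.n2s, out.n3) == (5, 6, 0, 7)

    def test_median_and_log_moments(self):
        rng = np.random.default_rng(12)
        n_det = np.array([50.0, 80.0, 30.0])
        sigma2 = 0.3
        draws = np.array([dp.add_process_noise(n_det, sigma2, rng) for _ in range(20000)])
        np.testing.assert_allclose(np.median(draws, axis=0), n_det, rtol=0.03)
        logs = np.log(draws)
        np.testing.assert_allclose(logs.mean(axis=0), np.log(n_det), atol=0.02)
        np.testing.assert_allclose(logs.var(axis=0), sigma2, rtol=0.05)

    def test_positivity_floor_prevents_log_zero(self):
        out = dp.add_process_noise(np.array([0.0, 1.0]), 0.1, np.random.default_rng(0))
        assert np.all(out > 0)
        assert out[0] < 10 * POSITIVITY_FLOOR
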