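"""Superposition predictions: troughs, peaks, steady states, regimen AUC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pqakin import (
    BiexponentialParams,
    DoseRegimen,
    FirstOrderPTMParams,
    auc_closed_form,
    concentration_at,
    doses_to_steady_state,
    post_dose_concentration,
    pqa_level_post_dose,
    pqa_level_pre_dose,
    pqa_post_dose_concentration,
    pqa_pre_dose_concentration,
    pre_dose_concentration,
    predict_regimen,
    simplified_regimen_auc,
    steady_state_concentration,
    steady_state_pqa_level,
    superposed_concentration_at,
)

pk_strategy = st.builds(BiexponentialParams,
                        A=st.floats(1.0, 500.0), B=st.floats(1.0, 500.0),
                        alpha=st.floats(0.05, 2.0), beta=st.floats(0.05, 2.0))
ptm_strategy = st.builds(FirstOrderPTMParams,
                         p0=st.floats(0.0, 0.5), k=st.floats(0.0, 0.1))
tau_strategy = st.floats(3.0, 30.0)


class TestSuperposedConcentration:
    def test_single_dose_reduces_to_plain_curve(self, multi_pk):
        reg = DoseRegimen(tau=14.0, n_doses=1)
        for t in (0.0, 3.0, 20.0, 56.0):
            assert superposed_concentration_at(multi_pk, reg, t) == pytest.approx(
                concentration_at(multi_pk, t))

    def test_jump_at_dose_instant_equals_bolus(self, multi_pk):
        reg = DoseRegimen(tau=14.0, n_doses=5)
        eps = 1e-9
        below = superposed_concentration_at(multi_pk, reg, 14.0 - eps)
        above = superposed_concentration_at(multi_pk, reg, 14.0)
        assert above - below == pytest.approx(multi_pk.c0, abs=1e-5)

    def test_trough_before_second_dose(self, multi_pk):
        assert pre_dose_concentration(multi_pk, 14.0, 2) == pytest.approx(32.46, abs=0.01)


class TestTroughPeak:
    def test_first_peak_is_the_bolus(self, multi_pk):
        assert post_dose_concentration(multi_pk, 14.0, 1) == pytest.approx(multi_pk.c0)
        assert pre_dose_concentration(multi_pk, 14.0, 1) == 0.0

    @given(m=st.integers(1, 20))
    def test_peak_minus_trough_is_bolus(self, multi_pk, m):
        diff = post_dose_concentration(multi_pk, 14.0, m) - pre_dose_concentration(
            multi_pk, 14.0, m)
        assert diff == pytest.approx(multi_pk.c0)

    def test_fifth_dose_trough_by_direct_sum(self, multi_pk):
        expected = sum(concentration_at(multi_pk, 14.0 * i) for i in range(1, 5))
        got = pre_dose_concentration(multi_pk, 14.0, 5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(66.60, abs=0.01)

    def test_invalid_dose_number_rejected(self, multi_pk):
        with pytest.raises(ValueError):
            pre_dose_concentration(multi_pk, 14.0, 0)

    @given(pk=pk_strategy, tau=tau_strategy)
    def test_sequences_increase_toward_steady_state(self, pk, tau):
        pre_ss = steady_state_concentration(pk, tau, "pre")
        post_ss = steady_state_concentration(pk, tau, "post")
        pres = [pre_dose_concentration(pk, tau, m) for m in range(2, 12)]
        posts = [post_dose_concentration(pk, tau, m) for m in range(1, 12)]
        # non-decreasing (strict up to float rounding of the re-summed terms)
        assert all(b >= a * (1 - 1e-12) for a, b in zip(pres, pres[1:]))
        assert all(b >= a * (1 - 1e-12) for a, b in zip(posts, posts[1:]))
        assert all(p <= pre_ss * (1 + 1e-12) for p in pres)
        assert all(p <= post_ss * (1 + 1e-12) for p in posts)


class TestSteadyStateConcentration:
    def test_closed_form_matches_long_series(self, multi_pk):
        i = np.arange(1, 5000)
        series = float(np.sum(concentration_at(multi_pk, 14.0 * i)))
        assert steady_state_concentration(multi_pk, 14.0, "pre") == pytest.approx(
            series, rel=1e-12)

    def test_reference_values(self, multi_pk):
        assert steady_state_concentration(multi_pk, 14.0, "pre") == pytest.approx(73.92, abs=0.01)
        assert steady_state_concentration(multi_pk, 14.0, "post") == pytest.approx(
            73.92 + multi_pk.c0, abs=0.01)

    def test_long_interval_means_no_accumulation(self, multi_pk):
        assert steady_state_concentration(multi_pk, 1e4, "pre") == pytest.approx(0.0, abs=1e-10)
        assert steady_state_concentration(multi_pk, 1e4, "post") == pytest.approx(multi_pk.c0)


class TestVariantTroughPeak:
    def test_first_peak_carries_initial_level(self, multi_pk, asn2):
        assert pqa_post_dose_concentration(multi_pk, asn2, 14.0, 1) == pytest.approx(
            asn2.p0 * multi_pk.c0)
        assert pqa_level_post_dose(multi_pk, asn2, 14.0, 1) == pytest.approx(asn2.p0)

    def test_zero_rate_keeps_level_at_p0(self, multi_pk):
        ptm = FirstOrderPTMParams(p0=0.05, k=0.0)
        for m in range(1, 8):
            assert pqa_level_post_dose(multi_pk, ptm, 14.0, m) == pytest.approx(0.05)
            if m >= 2:
                assert pqa_level_pre_dose(multi_pk, ptm, 14.0, m) == pytest.approx(0.05)

    def test_fifth_dose_values_by_direct_sum(self, multi_pk, asn2):
        expected = sum(
            concentration_at(multi_pk, 14.0 * i)
            * (1 - (1 - asn2.p0) * np.exp(-asn2.k * 14.0 * i))
            for i in range(1, 5))
        assert pqa_pre_dose_concentration(multi_pk, asn2, 14.0, 5) == pytest.approx(
            expected, rel=1e-12)
        assert pqa_pre_dose_concentration(multi_pk, asn2, 14.0, 5) == pytest.approx(9.14, abs=0.01)
        assert 100 * pqa_level_pre_dose(multi_pk, asn2, 14.0, 5) == pytest.approx(13.7, abs=0.05)
        assert 100 * pqa_level_post_dose(multi_pk, asn2, 14.0, 5) == pytest.approx(6.7, abs=0.05)

    @given(pk=pk_strategy, ptm=ptm_strategy, tau=tau_strategy, m=st.integers(2, 12))
    def test_trough_level_at_least_peak_level(self, pk, ptm, tau, m):
        # fresh unmodified drug dilutes the aged, more-modified pool
        pre = pqa_level_pre_dose(pk, ptm, tau, m)
        post = pqa_level_post_dose(pk, ptm, tau, m)
        assert pre >= post - 1e-12

    @given(pk=pk_strategy, ptm=ptm_strategy, tau=tau_strategy)
    def test_doubling_dose_leaves_levels_unchanged(self, pk, ptm, tau):
        doubled = BiexponentialParams(2 * pk.A, 2 * pk.B, pk.alpha, pk.beta)
        assert pre_dose_concentration(doubled, tau, 4) == pytest.approx(
            2 * pre_dose_concentration(pk, tau, 4), rel=1e-12)
        assert pqa_level_pre_dose(doubled, ptm, tau, 4) == pytest.approx(
            pqa_level_pre_dose(pk, ptm, tau, 4), rel=1e-12)


class TestSteadyStateLevel:
    def test_reference_value_and_series_agreement(self, multi_pk, asn2):
        cf = steady_state_pqa_level(multi_pk, asn2, 14.0, "pre")
        series = steady_state_pqa_level(multi_pk, asn2, 14.0, "pre", method="series",
                                        n_terms=100_000)
        assert cf == pytest.approx(0.1613, abs=5e-4)
        assert cf == pytest.approx(series, rel=1e-10)

    def test_zero_rate_collapses_to_p0(self, multi_pk):
        ptm = FirstOrderPTMParams(p0=0.08, k=0.0)
        for phase in ("pre", "post"):
            assert steady_state_pqa_level(multi_pk, ptm, 14.0, phase) == pytest.approx(0.08)

    def test_saturated_site_stays_at_one(self, multi_pk):
        ptm = FirstOrderPTMParams(p0=1.0, k=0.01)
        for phase in ("pre", "post"):
            assert steady_state_pqa_level(multi_pk, ptm, 14.0, phase) == pytest.approx(1.0)

    def test_unconverged_series_raises(self, multi_pk, asn2):
        with pytest.raises(RuntimeError):
            steady_state_pqa_level(multi_pk, asn2, 0.05, method="series", n_terms=10)

    @given(pk=pk_strategy, ptm=ptm_strategy, tau=tau_strategy)
    def test_level_sequences_monotone_and_bounded(self, pk, ptm, tau):
        pre_ss = steady_state_pqa_level(pk, ptm, tau, "pre")
        post_ss = steady_state_pqa_level(pk, ptm, tau, "post")
        pres = [pqa_level_pre_dose(pk, ptm, tau, m) for m in range(2, 10)]
        posts = [pqa_level_post_dose(pk, ptm, tau, m) for m in range(1, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(pres, pres[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(posts, posts[1:]))
        assert all(p <= pre_ss + 1e-9 for p in pres)
        assert all(p <= post_ss + 1e-9 for p in posts)


class TestDosesToSteadyState:
    def test_full_tolerance_is_one_dose(self, multi_pk):
        assert doses_to_steady_state(multi_pk, None, 14.0, tolerance=1.0) == 1

    def test_reference_convergence_count(self, multi_pk):
        m = doses_to_steady_state(multi_pk, None, 14.0, tolerance=0.015)
        assert 8 <= m <= 11  # around the tenth dose

    def test_tighter_tolerance_never_fewer_doses(self, multi_pk, asn2):
        counts = [doses_to_steady_state(multi_pk, asn2, 14.0, tol)
                  for tol in (0.1, 0.03, 0.01, 0.003)]
        assert counts == sorted(counts)


class TestRegimenTableAndAUC:
    def test_prediction_table_shape_and_identities(self, multi_pk, asn2):
        df = predict_regimen(multi_pk, asn2, DoseRegimen(tau=14.0, n_doses=5))
        assert len(df) == 5
        np.testing.assert_allclose(df["post_conc"] - df["pre_conc"], multi_pk.c0)
        assert np.isnan(df.loc[0, "pre_level_pct"])
        assert df.loc[0, "post_level_pct"] == pytest.approx(100 * asn2.p0)

    def test_single_interval_equals_single_dose_auc(self, multi_pk):
        reg = DoseRegimen(tau=14.0, n_doses=1)
        s = simplified_regimen_auc(multi_pk, None, reg, 14.0)
        assert s.total_auc == pytest.approx(auc_closed_form(multi_pk, 0, 14))

    def test_zero_rate_variant_scales_total(self, multi_pk):
        ptm = FirstOrderPTMParams(p0=0.05, k=0.0)
        s = simplified_regimen_auc(multi_pk, ptm, DoseRegimen(14.0, 5), 56.0)
        assert s.pqa_auc == pytest.approx(0.05 * s.total_auc, rel=1e-10)

    def test_four_interval_reference_value(self, multi_pk):
        s = simplified_regimen_auc(multi_pk, None, DoseRegimen(14.0, 5), 56.0)
        assert s.total_auc == pytest.approx(4644.3, abs=0.5)

    def test_sub_interval_window_falls_back_to_single_dose(self, multi_pk):
        s = simplified_regimen_auc(multi_pk, None, DoseRegimen(14.0, 5), 7.0)
        assert s.total_auc == pytest.approx(auc_closed_form(multi_pk, 0, 7))

    def test_refined_interval_converges_to_exact_superposition(self, multi_pk):
        # with many short intervals the post->pre trapezoids approach the
        # exact integral of the superposed curve over the same window
        window = 56.0
        exact_grid = np.linspace(0, window, 20001)
        reg_fine = DoseRegimen(tau=window / 56, n_doses=56)
        vals = [superposed_concentration_at(multi_pk, reg_fine, t) for t in exact_grid]
        exact = np.trapezoid(vals, exact_grid)
        approx = simplified_regimen_auc(multi_pk, None, reg_fine, window).total_auc
        assert approx == pytest.approx(exact, rel=0.02)
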