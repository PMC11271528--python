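"""LQ survival model, mean inactivation dose and RBE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnctmk import (
    PhaseMixture,
    PhaseParams,
    RadiationQuality,
    SurvivalCurve,
    alpha_effective,
    mean_inactivation_dose,
    mid_lq_closed_form,
    rbe,
    rbe_table,
    survival_asynchronous,
    survival_phase,
)
from .conftest import G1S_PARAMS, SG2M_PARAMS, XRAY_Z1D


class TestAlphaEffective:
    def test_zero_quality_returns_alpha0(self):
        q0 = RadiationQuality(y_star=0.0)
        assert alpha_effective(G1S_PARAMS, q0) == G1S_PARAMS.alpha0

    def test_hand_multiplication(self, xray_quality):
        # α★ = 0.319 + 0.698·0.055, multiplied out by hand
        assert alpha_effective(G1S_PARAMS, xray_quality) == pytest.approx(
            0.319 + 0.698 * 0.055, rel=1e-12
        )

    def test_zero_beta_ignores_quality(self):
        p = PhaseParams(alpha0=0.3, beta=0.0)
        for ystar in (0.0, 50.0, 400.0):
            assert alpha_effective(p, RadiationQuality(y_star=ystar)) == 0.3


class TestSurvivalPhase:
    def test_no_dose_no_kill(self, xray_quality):
        assert survival_phase(G1S_PARAMS, xray_quality, 0.0) == 1.0

    def test_pure_exponential(self):
        p = PhaseParams(alpha0=1.0, beta=0.0)
        q0 = RadiationQuality(y_star=0.0)
        assert survival_phase(p, q0, 1.0) == pytest.approx(math.exp(-1.0), rel=1e-15)

    def test_term_by_term_oracle_at_2gy(self, xray_quality):
        # independent term-wise evaluation with plain-Python arithmetic
        d = 2.0
        alpha = 0.319 + 0.698 * 0.055
        expected = math.exp(-(alpha * d + 0.055 * d * d))
        assert survival_phase(G1S_PARAMS, xray_quality, d) == pytest.approx(
            expected, rel=1e-14
        )

    def test_negative_dose_rejected(self, xray_quality):
        with pytest.raises(ValueError):
            survival_phase(G1S_PARAMS, xray_quality, -0.5)

    @settings(derandomize=True, max_examples=60)
    @given(
        alpha0=st.floats(0.0, 2.0),
        beta=st.floats(0.0, 0.5),
        ystar=st.floats(0.0, 500.0),
        dose=st.floats(0.0, 20.0),
    )
    def test_three_algebraic_forms_coincide(self, alpha0, beta, ystar, dose):
        """The three printed forms of the phase survival law agree exactly."""
        from bnctmk.microdosimetry import KEV_UM_TO_GY

        p = PhaseParams(alpha0=alpha0, beta=beta)
        q = RadiationQuality(y_star=ystar)
        r_d, rho = q.geometry.r_d, q.geometry.rho
        # form 1: y*-explicit; form 2: z1D*-explicit; form 3: α★-collapsed
        z1d = KEV_UM_TO_GY * ystar / (rho * math.pi * r_d**2)
        form1 = (alpha0 + z1d * beta) * dose + beta * dose**2
        form2 = (alpha0 + q.z1d_star * beta) * dose + beta * dose**2
        form3 = alpha_effective(p, q) * dose + beta * dose**2
        from bnctmk import neg_log_survival_phase

        model = neg_log_survival_phase(p, q, dose)
        assert form1 == pytest.approx(form2, rel=1e-12, abs=1e-300)
        assert form2 == pytest.approx(form3, rel=1e-12, abs=1e-300)
        assert model == pytest.approx(form3, rel=1e-12, abs=1e-300)


class TestAsynchronousMixture:
    def test_single_phase_mixture_degenerates(self, phase_params, xray_quality):
        mix = PhaseMixture(fractions={"G1/S": 1.0})
        for d in (0.0, 1.0, 4.0):
            assert survival_asynchronous(
                phase_params, mix, xray_quality, d
            ) == pytest.approx(survival_phase(G1S_PARAMS, xray_quality, d), rel=1e-15)

    def test_equal_params_collapse(self, xray_quality, async_mixture):
        same = {"G1/S": G1S_PARAMS, "S/G2/M": PhaseParams(0.319, 0.055, "S/G2/M")}
        for d in (1.0, 3.0):
            assert survival_asynchronous(
                same, async_mixture, xray_quality, d
            ) == pytest.approx(survival_phase(G1S_PARAMS, xray_quality, d), rel=1e-12)

    def test_hand_weighted_sum_at_2gy(self, phase_params, async_mixture, xray_quality):
        d = 2.0
        s1 = math.exp(-((0.319 + 0.698 * 0.055) * d + 0.055 * d * d))
        s2 = math.exp(-((0.083 + 0.698 * 0.067) * d + 0.067 * d * d))
        expected = 0.549 * s1 + 0.451 * s2
        assert survival_asynchronous(
            phase_params, async_mixture, xray_quality, d
        ) == pytest.approx(expected, rel=1e-14)

    def test_bounded_by_phase_curves_and_monotone(
        self, phase_params, async_mixture, xray_quality
    ):
        doses = np.linspace(0.0, 12.0, 49)
        s_async = survival_asynchronous(phase_params, async_mixture, xray_quality, doses)
        s1 = survival_phase(G1S_PARAMS, xray_quality, doses)
        s2 = survival_phase(SG2M_PARAMS, xray_quality, doses)
        assert s_async[0] == pytest.approx(1.0, abs=1e-15)
        assert np.all(np.diff(s_async) < 0)
        assert np.all(s_async <= np.maximum(s1, s2) + 1e-15)
        assert np.all(s_async >= np.minimum(s1, s2) - 1e-15)

    def test_missing_phase_params_rejected(self, async_mixture, xray_quality):
        with pytest.raises(KeyError):
            survival_asynchronous({"G1/S": G1S_PARAMS}, async_mixture, xray_quality, 1.0)


class TestMeanInactivationDose:
    def test_pure_exponential_analytic(self):
        assert mean_inactivation_dose(lambda d: math.exp(-d)) == pytest.approx(
            1.0, rel=1e-10
        )

    def test_pure_gaussian_analytic(self):
        assert mean_inactivation_dose(lambda d: math.exp(-d * d)) == pytest.approx(
            math.sqrt(math.pi) / 2.0, rel=1e-10
        )

    def test_closed_form_vs_quadrature_on_fixture_curve(self, xray_quality):
        alpha = alpha_effective(G1S_PARAMS, xray_quality)
        closed = mid_lq_closed_form(alpha, G1S_PARAMS.beta)
        quad = mean_inactivation_dose(
            lambda d: survival_phase(G1S_PARAMS, xray_quality, d)
        )
        assert quad == pytest.approx(closed, rel=1e-8)

    def test_non_decaying_curve_rejected(self):
        with pytest.raises(ValueError):
            mean_inactivation_dose(lambda d: 1.0)

    def test_strictly_decreasing_in_alpha_and_beta(self):
        alphas = np.linspace(0.05, 1.5, 8)
        betas = np.linspace(0.005, 0.2, 8)
        for b in betas:
            mids = [mid_lq_closed_form(a, b) for a in alphas]
            assert np.all(np.diff(mids) < 0)
        for a in alphas:
            mids = [mid_lq_closed_form(a, b) for b in betas]
            assert np.all(np.diff(mids) < 0)


class TestRbe:
    def test_identity_and_scaling(self):
        assert rbe(2.0, 2.0) == 1.0
        assert rbe(2.0, 1.0) == 2.0

    def test_invalid_doses_rejected(self):
        with pytest.raises(ValueError):
            rbe(2.0, 0.0)
        with pytest.raises(ValueError):
            rbe(-1.0, 1.0)

    def test_harder_spectrum_gives_rbe_above_one(self, phase_params):
        ref = RadiationQuality.from_z1d(XRAY_Z1D, label="ref")
        hard = RadiationQuality(y_star=80.0, label="hard")
        for p in phase_params.values():
            d_ref = mid_lq_closed_form(alpha_effective(p, ref), p.beta)
            d_hard = mid_lq_closed_form(alpha_effective(p, hard), p.beta)
            assert rbe(d_ref, d_hard) > 1.0

    def test_rbe_increases_with_z1d(self, phase_params):
        ref = RadiationQuality.from_z1d(XRAY_Z1D)
        rbes = []
        for ystar in (5.0, 20.0, 80.0, 160.0):
            q = RadiationQuality(y_star=ystar)
            p = G1S_PARAMS
            rbes.append(
                rbe(
                    mid_lq_closed_form(alpha_effective(p, ref), p.beta),
                    mid_lq_closed_form(alpha_effective(p, q), p.beta),
                )
            )
        assert np.all(np.diff(rbes) > 0)


class TestRbeTable:
    def test_reference_row_is_unity(self, phase_params, async_mixture, xray_quality):
        table = rbe_table(phase_params, async_mixture, [xray_quality], xray_quality)
        assert set(table["phase"]) == {"G1/S", "S/G2/M", "asynchronous"}
        np.testing.assert_allclose(table["rbe"], 1.0, rtol=0, atol=0)

    def test_monotone_in_quality_and_mixture_bound(
        self, phase_params, async_mixture, xray_quality
    ):
        q1 = RadiationQuality(y_star=20.0, label="soft")
        q2 = RadiationQuality(y_star=120.0, label="hard")
        table = rbe_table(phase_params, async_mixture, [q1, q2], xray_quality)
        for phase in ("G1/S", "S/G2/M", "asynchronous"):
            sub = table[table["phase"] == phase].set_index("quality_label")
            assert sub.loc["soft", "rbe"] < sub.loc["hard", "rbe"]
        # asynchronous D̄ lies between the two phase D̄s per quality
        for label in ("soft", "hard"):
            sub = table[table["quality_label"] == label].set_index("phase")
            lo = min(sub.loc["G1/S", "dbar_Gy"], sub.loc["S/G2/M", "dbar_Gy"])
            hi = max(sub.loc["G1/S", "dbar_Gy"], sub.loc["S/G2/M", "dbar_Gy"])
            assert lo <= sub.loc["asynchronous", "dbar_Gy"] <= hi

    def test_empty_quality_list_rejected(self, phase_params, async_mixture, xray_quality):
        with pytest.raises(ValueError):
            rbe_table(phase_params, async_mixture, [], xray_quality)


class TestSurvivalCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([0.0, 1.0]), np.array([1.0, 1.5]))
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([1.0, 0.5]), np.array([0.9, 0.8]))
        curve = SurvivalCurve(np.array([0.0, 2.0]), np.array([1.0, 0.5]))
        assert list(curve.to_frame().columns) == ["dose_Gy", "surviving_fraction"]
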