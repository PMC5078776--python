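"""FvCB forward model, conductance algebra, and the A/Ci estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafgas.fvcb import (
    AciCurve,
    FitConfig,
    FvcbParams,
    fit_aci,
    fixed_point_assimilation,
    forward_fvcb,
    gs_h2o_to_co2,
    total_conductance,
)


class TestForwardModel:
    def test_compensation_point_zero_respiration(self, constants):
        """With rd = 0 net assimilation vanishes exactly at gamma_star."""
        params = FvcbParams(vcmax=100, jmax=150, rd=0.0, gm=math.inf)
        pred = forward_fvcb(params, constants, constants.gamma_star)
        assert pred.a == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("ci", [80.0, 300.0, 1200.0])
    def test_infinite_gm_equals_rectangular_form(self, constants, ci):
        """As gm -> inf each branch reduces to p (ci - G*)/(ci + q) - rd."""
        params = FvcbParams(vcmax=100, jmax=150, rd=1.5, gm=math.inf)
        gs, km = constants.gamma_star, constants.km_effective
        a_rub = 100 * (ci - gs) / (ci + km) - 1.5
        a_rubp = (150 / 4) * (ci - gs) / (ci + 2 * gs) - 1.5
        assert forward_fvcb(params, constants, ci).a == pytest.approx(
            min(a_rub, a_rubp), abs=1e-9
        )

    def test_matches_damped_fixed_point_oracle(self, constants, truth_params):
        """Quadratic root equals iterating cc = ci - A(cc)/gm to convergence."""
        a_quad = forward_fvcb(truth_params, constants, 300.0).a
        a_fp = fixed_point_assimilation(truth_params, constants, 300.0,
                                        tol=1e-10)
        assert a_quad == pytest.approx(a_fp, abs=1e-8)

    def test_fixed_point_agreement_over_grid(self, constants):
        """Quadratic and fixed-point solutions agree over a (ci, gm) grid."""
        worst = 0.0
        for gm in (0.05, 0.1, 0.3, 1.0, 5.0):
            params = FvcbParams(vcmax=100, jmax=150, rd=1.5, gm=gm)
            for ci in np.linspace(50, 2000, 40):
                a_quad = forward_fvcb(params, constants, float(ci)).a
                a_fp = fixed_point_assimilation(params, constants, float(ci))
                worst = max(worst, abs(a_quad - a_fp))
        assert worst < 1e-7

    def test_monotone_in_ci_above_compensation(self, constants, truth_params):
        ci = np.linspace(constants.gamma_star, 2000, 200)
        a = forward_fvcb(truth_params, constants, ci).a
        assert np.all(np.diff(a) >= -1e-10)

    def test_decreasing_in_rd(self, constants):
        base = dict(vcmax=100, jmax=150, gm=0.3)
        a_lo = forward_fvcb(FvcbParams(rd=0.5, **base), constants, 400.0).a
        a_hi = forward_fvcb(FvcbParams(rd=2.5, **base), constants, 400.0).a
        assert a_hi < a_lo

    def test_limitation_labels(self, constants, truth_params):
        pred = forward_fvcb(truth_params, constants,
                            np.array([100.0, 1800.0]))
        assert list(pred.limitation) == ["rubisco", "rubp"]

    def test_implied_cc_positive(self, constants, truth_params):
        ci = np.linspace(50, 2000, 50)
        a = forward_fvcb(truth_params, constants, ci).a
        cc = ci - a / truth_params.gm
        assert np.all(cc > 0)

    def test_rejects_nonpositive_ci(self, constants, truth_params):
        with pytest.raises(ValueError):
            forward_fvcb(truth_params, constants, 0.0)

    @given(
        vcmax=st.floats(1, 400), jmax=st.floats(1, 600),
        rd=st.floats(0, 5), gm=st.floats(0.01, 10),
        ci=st.floats(1.0, 2000.0),
    )
    @settings(derandomize=True, max_examples=150)
    def test_physical_root_always_exists(self, constants, vcmax, jmax, rd,
                                         gm, ci):
        """The smaller quadratic root keeps cc in (0, ci + rd/gm] for any
        admissible parameter combination (no spurious domain errors)."""
        params = FvcbParams(vcmax=vcmax, jmax=jmax, rd=rd, gm=gm)
        a = forward_fvcb(params, constants, ci).a
        assert np.isfinite(a)
        assert ci - a / gm > 0


class TestConductanceAlgebra:
    @pytest.mark.parametrize(
        "gs_h2o, expected",
        [(1600.0, 1.0), (0.0, 0.0), (511.2, 0.3195)],
    )
    def test_h2o_to_co2_conversion(self, gs_h2o, expected):
        assert gs_h2o_to_co2(gs_h2o) == pytest.approx(expected, abs=1e-12)

    def test_negative_gs_rejected(self):
        with pytest.raises(ValueError):
            gs_h2o_to_co2(-1.0)

    @pytest.mark.parametrize(
        "gs, gm, expected",
        [(0.3, 0.3, 0.15), (0.4, math.inf, 0.4), (0.4, 0.3, 0.4 * 0.3 / 0.7)],
    )
    def test_total_conductance_values(self, gs, gm, expected):
        assert total_conductance(gs, gm) == pytest.approx(expected, rel=1e-12)

    def test_total_conductance_both_zero_rejected(self):
        with pytest.raises(ValueError):
            total_conductance(0.0, 0.0)

    @given(gs=st.floats(1e-6, 10), gm=st.floats(1e-6, 10))
    @settings(derandomize=True, max_examples=100)
    def test_harmonic_bounds_and_symmetry(self, gs, gm):
        """Series conductance lies in [min/2, min] and is symmetric."""
        tot = total_conductance(gs, gm)
        assert min(gs, gm) / 2 - 1e-15 <= tot <= min(gs, gm) + 1e-15
        assert tot == pytest.approx(total_conductance(gm, gs), rel=1e-12)


class TestFitAci:
    def test_noiseless_recovery_exact(self, forward_curve, constants,
                                      truth_params):
        """Self-consistency: refitting noiseless forward data returns the
        generating parameters to optimizer precision."""
        fit = fit_aci(forward_curve, constants)
        assert fit.converged
        for name in ("vcmax", "jmax", "rd", "gm"):
            got = getattr(fit.params, name)
            want = getattr(truth_params, name)
            assert got == pytest.approx(want, rel=1e-3), name
        assert fit.rss < 1e-12

    def test_infinite_gm_data_hits_upper_bound(self, constants, protocol_ci):
        """Data generated by the rectangular (gm = inf) model drives the
        fitted gm to its upper bound with matching RSS."""
        rect = FvcbParams(vcmax=100, jmax=150, rd=1.5, gm=math.inf)
        a = forward_fvcb(rect, constants, protocol_ci).a
        curve = AciCurve(ci=protocol_ci, a=a, ca=protocol_ci)
        fit = fit_aci(curve, constants)
        assert fit.gm_effectively_infinite
        # the rectangular model's own residuals on this data are zero
        assert fit.rss < 1e-6

    def test_rectangular_recovery_of_vcmax_jmax(self, constants, protocol_ci):
        rect = FvcbParams(vcmax=120, jmax=180, rd=1.0, gm=math.inf)
        a = forward_fvcb(rect, constants, protocol_ci).a
        fit = fit_aci(AciCurve(ci=protocol_ci, a=a, ca=protocol_ci), constants)
        assert fit.params.vcmax == pytest.approx(120, rel=5e-3)
        assert fit.params.jmax == pytest.approx(180, rel=5e-3)

    def test_too_few_points_rejected(self, constants):
        curve = AciCurve(ci=[100.0, 300.0, 800.0], a=[5.0, 15.0, 25.0])
        with pytest.raises(ValueError, match="too few points"):
            fit_aci(curve, constants)

    def test_fix_rd_config(self, forward_curve, constants):
        fit = fit_aci(forward_curve, constants, FitConfig(fix_rd=1.5))
        assert fit.params.rd == 1.5
        assert fit.params.vcmax == pytest.approx(100, rel=1e-3)

    def test_pn_max_at_protocol_top(self, forward_curve, constants):
        """P_N max equals the fitted model at the 2000-ppm end of the sweep."""
        fit = fit_aci(forward_curve, constants)
        a_top = forward_curve.a[np.argmax(forward_curve.ca)]
        assert fit.pn_max >= a_top - 1e-6

    def test_noisy_fit_reports_uncertainty(self, forward_curve, constants):
        rng = np.random.default_rng(7)
        noisy = AciCurve(ci=forward_curve.ci,
                         a=forward_curve.a + rng.normal(0, 0.5, 16),
                         ca=forward_curve.ca)
        fit = fit_aci(noisy, constants)
        assert set(fit.param_se) == {"vcmax", "jmax", "rd", "gm"}
        assert all(se > 0 for se in fit.param_se.values())

    def test_gm_shrinkage_prior_pulls_gm(self, forward_curve, constants):
        """A tight log-gm prior dominates when the likelihood is flat."""
        cfg = FitConfig(gm_log_prior=(np.log(0.3), 0.01), prior_noise_sd=5.0)
        fit = fit_aci(forward_curve, constants, cfg,
                      initial=FvcbParams(100, 150, 1.5, 1.0))
        assert fit.params.gm == pytest.approx(0.3, rel=0.1)


class TestTypes:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            FvcbParams(vcmax=-1, jmax=150)
        with pytest.raises(ValueError):
            FvcbParams(vcmax=100, jmax=150, rd=-0.1)
        with pytest.raises(ValueError):
            FvcbParams(vcmax=100, jmax=150, gm=0.0)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            AciCurve(ci=[100, 200], a=[1.0])
        with pytest.raises(ValueError):
            AciCurve(ci=[-5.0, 200.0], a=[1.0, 2.0])

    def test_constants_km_effective(self, constants):
        want = constants.kc * (1 + constants.o2 / constants.ko)
        assert constants.km_effective == pytest.approx(want)
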