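"""Structural model: covariate construction, steady-state kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cyclopk import (
    CovariateEffect,
    DosingRegimen,
    FixedEffects,
    RandomEffectsSpec,
    conc_ss,
    cv_to_variance,
    individual_clearance,
    individual_volume,
    variance_to_cv,
)


class TestIndividualParameters:
    @pytest.mark.parametrize(
        "wt,hgb,eta,kappa,expected",
        [
            (40.0, 120.0, 0.0, 0.0, 15.0),  # reference patient
            (40.0, 73.0, 0.0, 0.0, 15.0 * 1.13113),  # low haemoglobin
            (80.0, 120.0, 0.0, 0.0, 15.0 * 2**0.89),  # allometric doubling
        ],
    )
    def test_clearance_values(self, final_fixed, wt, hgb, eta, kappa, expected):
        assert individual_clearance(final_fixed, wt, hgb, eta, kappa) == pytest.approx(
            expected, rel=1e-4
        )

    @pytest.mark.parametrize(
        "wt,eta,expected",
        [(40.0, 0.0, 71.1), (20.0, 0.0, 35.55), (40.0, np.log(2.0), 142.2)],
    )
    def test_volume_values(self, final_fixed, wt, eta, expected):
        assert individual_volume(final_fixed, wt, eta) == pytest.approx(expected, rel=1e-9)

    def test_reference_point_is_exact(self, final_fixed):
        fe = final_fixed
        assert individual_clearance(fe, fe.wt_ref, fe.hgb_ref, 0.0, 0.0) == fe.theta_cl
        assert individual_volume(fe, fe.wt_ref, 0.0) == fe.theta_v

    def test_monotone_in_hgb_and_wt(self, final_fixed):
        hgb = np.linspace(73, 164, 50)
        cl = individual_clearance(final_fixed, 40.0, hgb)
        assert np.all(np.diff(cl) < 0)  # theta_hgb < 0
        wt = np.linspace(10, 100, 50)
        cl = individual_clearance(final_fixed, wt, 120.0)
        assert np.all(np.diff(cl) > 0)  # theta_all > 0

    def test_hgb_factor_must_stay_positive(self):
        with pytest.raises(ValueError, match="HGB"):
            FixedEffects(theta_hgb=-0.03)  # factor < 0 at HGB 164

    def test_clearance_rejects_bad_inputs(self, final_fixed):
        with pytest.raises(ValueError):
            individual_clearance(final_fixed, -1.0, 120.0)
        with pytest.raises(ValueError, match="HGB"):
            individual_clearance(final_fixed, 40.0, 600.0)


class TestSteadyStateConcentration:
    def test_zero_dose_gives_zero(self):
        reg = DosingRegimen(0.0, 12.0)
        t = np.linspace(0, 11.99, 25)
        assert np.allclose(conc_ss(reg, t, 15.0, 71.1, 1.15), 0.0)

    def test_matches_superposition_oracle(self, superposition_oracle):
        reg = DosingRegimen(107.5, 12.0)
        for t in (0.0, 1.0, 2.0, 6.0, 11.5):
            ours = conc_ss(reg, t, 15.0, 71.1, 1.15)
            ref = superposition_oracle(107.5, 12.0, t, 15.0, 71.1, 1.15, n_doses=300)
            assert ours == pytest.approx(ref, rel=1e-3)

    def test_auc_identity(self):
        # steady-state AUC over one interval is 1000*D/CL, independent of Ka, V
        for cl, v, ka, dose in [(15.0, 71.1, 1.15, 107.5), (5.0, 30.0, 0.7, 50.0)]:
            reg = DosingRegimen(dose, 12.0)
            auc, _ = quad(lambda t: conc_ss(reg, t, cl, v, ka), 0.0, 12.0, limit=200)
            assert auc == pytest.approx(1000.0 * dose / cl, rel=1e-6)

    def test_periodicity_trough(self):
        # value at t -> tau- equals the pre-dose value at t=0
        reg = DosingRegimen(100.0, 12.0)
        almost_tau = np.nextafter(12.0, 0.0)
        assert conc_ss(reg, almost_tau, 16.0, 76.5, 1.15) == pytest.approx(
            conc_ss(reg, 0.0, 16.0, 76.5, 1.15), rel=1e-6
        )

    def test_degenerate_ka_equals_k_limit(self):
        # the limiting expression continues the profile smoothly
        reg = DosingRegimen(100.0, 12.0)
        cl, v = 15.0, 71.1
        k = cl / v
        near = conc_ss(reg, 3.0, cl, v, k * (1.0 + 1e-6))
        limit = conc_ss(reg, 3.0, cl, v, k)
        assert limit == pytest.approx(near, rel=1e-4)

    def test_time_domain_enforced(self):
        reg = DosingRegimen(100.0, 12.0)
        with pytest.raises(ValueError):
            conc_ss(reg, 12.0, 15.0, 71.1, 1.15)
        with pytest.raises(ValueError):
            conc_ss(reg, -0.1, 15.0, 71.1, 1.15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        t=st.floats(0.0, 11.99),
        cl=st.floats(2.0, 60.0),
        v=st.floats(10.0, 300.0),
        ka=st.floats(0.3, 4.0),
        dose=st.floats(5.0, 600.0),
    )
    def test_concentration_positive(self, t, cl, v, ka, dose):
        reg = DosingRegimen(dose, 12.0)
        assert conc_ss(reg, t, cl, v, ka) > 0.0


class TestVariabilityConventions:
    @pytest.mark.parametrize(
        "cv,var", [(34.91, 0.121871), (0.0, 0.0), (100.0, 1.0)]
    )
    def test_cv_to_variance(self, cv, var):
        assert cv_to_variance(cv) == pytest.approx(var, abs=1e-6)
        assert variance_to_cv(cv_to_variance(cv)) == pytest.approx(cv, abs=1e-9)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            cv_to_variance(-1.0)

    def test_iiv_matrix_psd_enforced(self):
        with pytest.raises(ValueError):
            RandomEffectsSpec(omega2_cl=0.01, omega2_v=0.01, omega_clv=0.05)

    def test_final_model_correlation_is_high(self, final_random):
        # covariance 0.136 with the reported CVs implies r ~ 0.905
        assert final_random.corr_clv == pytest.approx(0.905, abs=0.005)


class TestCovariateEffectForms:
    def test_forms(self):
        lin = CovariateEffect("HGB", "CL", "linear", 120.0, theta=-0.00279)
        assert lin.multiplier(120.0) == pytest.approx(1.0)
        assert lin.multiplier(73.0) == pytest.approx(1.13113, rel=1e-5)
        pw = CovariateEffect("WT", "CL", "power", 40.0, theta=0.75)
        assert pw.multiplier(80.0) == pytest.approx(2**0.75)
        cat = CovariateEffect("GEND", "CL", "categorical", theta=0.2)
        assert cat.multiplier(1.0) == pytest.approx(1.2)
        assert cat.multiplier(0.0) == pytest.approx(1.0)

    def test_invalid_form_rejected(self):
        with pytest.raises(ValueError):
            CovariateEffect("HGB", "CL", "exponential", 120.0)
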