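"""Closed-form standard-linear-solid mathematics and the analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viscomap import (DomainError, MaterialSpec, SLSParameters,
                      analytic_confined_response, analytic_uniaxial_response,
                      creep_strain, dimensionless_relaxation, material_from_fit,
                      relaxation_modulus, sls_from_material)

material_strategy = st.builds(
    MaterialSpec,
    E=st.floats(1e3, 1e6),
    nu=st.floats(0.1, 0.49),
    g=st.floats(0.05, 0.95),
    tau_R=st.floats(0.1, 100.0),
)


class TestConversions:
    def test_study_material_maps_to_worked_maxwell_parameters(self, study_material):
        p = sls_from_material(study_material)
        assert p.E1 == pytest.approx(10e3)
        assert p.E2 == pytest.approx(40e3)
        assert p.eta == pytest.approx(200e3)
        assert p.tau_C == pytest.approx(25.0)
        # symbolic re-substitution recovers the inputs
        assert p.g == pytest.approx(0.8)
        assert p.tau_R == pytest.approx(5.0)

    def test_back_conversion_of_worked_parameters(self):
        p = SLSParameters(E1=10e3, E2=40e3, eta=200e3)
        E, g, tau_R = material_from_fit(p)
        assert (E, g, tau_R) == pytest.approx((10e3, 0.8, 5.0))

    def test_equal_springs_give_half_weight(self):
        for X in (1.0, 10e3, 3.7e5):
            E, g, tau_R = material_from_fit(SLSParameters(E1=X, E2=X, eta=X * 1.0))
            assert g == pytest.approx(0.5)
            assert tau_R == pytest.approx(1.0)

    def test_eta_from_creep_time_constant_definition(self):
        # eta = tau_C * E1 E2 / (E1 + E2) with tau_C = 25 s
        eta = 25.0 * 10e3 * 40e3 / 50e3
        p = SLSParameters(E1=10e3, E2=40e3, eta=eta)
        assert p.tau_R == pytest.approx(5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(m=material_strategy)
    def test_round_trip_is_identity(self, m):
        E, g, tau_R = material_from_fit(sls_from_material(m))
        assert E == pytest.approx(m.E, rel=1e-12)
        assert g == pytest.approx(m.g, rel=1e-12)
        assert tau_R == pytest.approx(m.tau_R, rel=1e-12)

    def test_degenerate_elastic_limit_rejected(self):
        with pytest.raises(DomainError, match="g"):
            MaterialSpec(E=10e3, nu=0.495, g=0.0, tau_R=5.0)
        with pytest.raises(DomainError, match="E2"):
            SLSParameters(E1=10e3, E2=0.0, eta=1.0)

    @pytest.mark.parametrize("bad", [
        dict(E=-1.0, nu=0.3, g=0.5, tau_R=1.0),
        dict(E=1e3, nu=0.55, g=0.5, tau_R=1.0),
        dict(E=1e3, nu=0.3, g=1.2, tau_R=1.0),
        dict(E=1e3, nu=0.3, g=0.5, tau_R=0.0),
    ])
    def test_invalid_material_rejected(self, bad):
        with pytest.raises(DomainError):
            MaterialSpec(**bad)

    def test_derived_moduli_ordering(self, study_material):
        m = study_material
        assert m.bulk_modulus == pytest.approx(10e3 / (3 * 0.01))
        assert m.shear_modulus_instant > m.shear_modulus_longterm > 0


class TestCreepAndRelaxation:
    def test_creep_strain_worked_values(self, study_sls):
        # instantaneous: sigma0 / (E1 + E2); long-term: sigma0 / E1
        assert creep_strain(study_sls, 1000.0, 0.0) == pytest.approx(0.02)
        assert creep_strain(study_sls, 1000.0, 1e9) == pytest.approx(0.1)
        expected = 0.1 * (1.0 - 0.8 * np.exp(-1.0))
        assert creep_strain(study_sls, 1000.0, 25.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.070570, abs=5e-7)

    def test_creep_strain_matches_hereditary_integral(self, study_sls):
        """Cross-check Boltzmann superposition: eps(t) = sigma0 * D(t) for a
        step load equals the convolution of D-dot with the stress history."""
        # numerical hereditary integral on a fine grid: eps(t) =
        # sigma0*D(0) + sigma0 * int_0^t D'(s) ds, with D from the fitted form
        t = np.linspace(0.0, 100.0, 200001)
        D = creep_strain(study_sls, 1.0, t)  # compliance for unit stress
        dDdt = np.gradient(D, t)
        eps_num = D[0] + np.cumsum((dDdt[1:] + dDdt[:-1]) / 2 * np.diff(t))
        eps_closed = creep_strain(study_sls, 1.0, t[1:])
        assert np.allclose(eps_num, eps_closed, rtol=1e-6)

    def test_creep_strain_vectorizes_and_rejects_negative_time(self, study_sls):
        t = np.array([0.0, 1.0, 10.0])
        out = creep_strain(study_sls, 1000.0, t)
        assert out.shape == t.shape
        with pytest.raises(DomainError):
            creep_strain(study_sls, 1000.0, -1.0)
        with pytest.raises(DomainError):
            creep_strain(study_sls, -5.0, t)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(m=material_strategy)
    def test_creep_is_increasing_towards_plateau(self, m):
        p = sls_from_material(m)
        t = np.linspace(0.0, 20 * p.tau_C, 500)
        eps = creep_strain(p, 1000.0, t)
        assert np.all(np.diff(eps) > 0)
        assert np.all(eps < 1000.0 / p.E1)

    def test_dimensionless_relaxation_worked_values(self):
        assert dimensionless_relaxation(0.8, 5.0, 0.0) == pytest.approx(1.0)
        assert dimensionless_relaxation(0.8, 5.0, 1e9) == pytest.approx(0.2)
        expected = 1.0 - 0.8 * (1.0 - np.exp(-1.0))
        assert dimensionless_relaxation(0.8, 5.0, 5.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.494304, abs=5e-7)

    def test_dimensionless_relaxation_monotone_and_bounded(self):
        t = np.linspace(0.0, 100.0, 1000)
        gR = dimensionless_relaxation(0.8, 5.0, t)
        assert np.all(np.diff(gR) < 0)
        assert gR[0] == 1.0 and np.all(gR > 0.2 - 1e-12)
        with pytest.raises(DomainError):
            dimensionless_relaxation(1.5, 5.0, t)

    @pytest.mark.parametrize("seed", range(5))
    def test_laplace_interconversion_identity(self, seed):
        """Relaxation modulus and creep compliance satisfy
        s*Ehat(s) * s*Dhat(s) = 1 (the hereditary-integral duality)."""
        rng = np.random.default_rng(seed)
        p = SLSParameters(E1=10 ** rng.uniform(3, 5),
                          E2=10 ** rng.uniform(3, 5),
                          eta=10 ** rng.uniform(3, 6))
        s = np.logspace(-3, 3, 61)
        E_hat = p.E1 / s + p.E2 / (s + 1.0 / p.tau_R)
        delta = 1.0 / p.E1 - 1.0 / (p.E1 + p.E2)
        D_hat = 1.0 / (p.E1 * s) - delta / (s + 1.0 / p.tau_C)
        assert np.allclose(s * E_hat * s * D_hat, 1.0, rtol=1e-10)

    def test_relaxation_modulus_endpoints(self, study_sls):
        assert relaxation_modulus(study_sls, 0.0) == pytest.approx(50e3)
        assert relaxation_modulus(study_sls, 1e9) == pytest.approx(10e3)


class TestAnalyticOracles:
    def test_uniaxial_longterm_modulus_is_exactly_E(self, study_material, hold_times):
        c = analytic_uniaxial_response(study_material, 1000.0, np.array([0.0, 1.0, 2.0, 1e12]))
        assert 1000.0 / c.eps_zz[-1] == pytest.approx(10e3, rel=1e-12)

    def test_uniaxial_instantaneous_modulus_and_apparent_g(self, study_material):
        c = analytic_uniaxial_response(study_material, 1000.0, np.array([0.0, 1.0, 2.0, 1e12]))
        E_inst = 1000.0 / c.eps_zz[0]
        K, G0 = study_material.bulk_modulus, study_material.shear_modulus_instant
        assert E_inst == pytest.approx(9 * K * G0 / (3 * K + G0), rel=1e-12)
        assert E_inst == pytest.approx(49.34e3, rel=1e-3)
        apparent_g = 1.0 - (1000.0 / c.eps_zz[-1]) / E_inst
        assert apparent_g == pytest.approx(0.7973, abs=5e-4)
        assert abs(apparent_g - 0.8) / 0.8 < 0.10

    def test_uniaxial_retardation_time(self, study_material, hold_times):
        """The uniaxial creep exponential has time constant tauR*G0/G_inf = 25 s."""
        c = analytic_uniaxial_response(study_material, 1000.0, hold_times)
        # distance to the exact plateau sigma0/E is a pure exponential;
        # log-linearise it to read off the time constant
        resid = 1000.0 / 10e3 - c.eps_zz
        slope = np.polyfit(hold_times, np.log(resid), 1)[0]
        assert -1.0 / slope == pytest.approx(25.0, rel=1e-9)

    def test_confined_longterm_modulus_is_pwave_modulus(self, study_material):
        c = analytic_confined_response(study_material, 1000.0, np.array([0.0, 1.0, 2.0, 1e12]))
        m = study_material
        M_inf = m.bulk_modulus + 4 * m.shear_modulus_longterm / 3
        assert 1000.0 / c.eps_zz[-1] == pytest.approx(M_inf, rel=1e-12)
        assert M_inf == pytest.approx(337.79e3, rel=1e-3)
        # E recovered from a confined curve is ~34x the true 10 kPa (>> 10% error)
        assert abs(M_inf - 10e3) / 10e3 > 0.10

    def test_confined_apparent_g_is_small(self, study_material):
        c = analytic_confined_response(study_material, 1000.0, np.array([0.0, 1.0, 2.0, 1e12]))
        m = study_material
        M0 = m.bulk_modulus + 4 * m.shear_modulus_instant / 3
        apparent_g = 1.0 - (1000.0 / c.eps_zz[-1]) / (1000.0 / c.eps_zz[0])
        assert M0 == pytest.approx(355.63e3, rel=1e-3)
        assert apparent_g == pytest.approx(0.0502, abs=5e-4)
        assert abs(apparent_g - 0.8) / 0.8 > 0.10
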