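"""Unit tests for the DEB state, fluxes, thermal corrections and conversions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermodeb import (
    DEBError,
    DEBParameters,
    OrganismState,
    Stage,
    adult_instar_duration,
    allocation_fraction,
    assimilation_flux,
    maintenance_flux,
    maintenance_thermal_correction,
    mass_at_maturity,
    mobilization_flux,
    neonate_state,
    scaled_functional_response,
    state_derivatives,
    uptake_thermal_correction,
)

from _oracles import oracle_fluxes


class TestFunctionalResponse:
    @pytest.mark.parametrize("X, ks, expected", [
        (0.3, 0.3, 0.5),       # half-saturation by definition
        (0.0, 0.3, 0.0),
        (0.9, 0.3, 0.75),      # X = 3 ks
    ])
    def test_examples(self, X, ks, expected):
        assert scaled_functional_response(X, ks) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DEBError):
            scaled_functional_response(-0.1, 0.3)
        with pytest.raises(DEBError):
            scaled_functional_response(1.0, 0.0)

    @given(st.floats(0, 1e3), st.floats(1e-3, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing(self, X, ks):
        f = scaled_functional_response(X, ks)
        assert 0 <= f < 1
        assert scaled_functional_response(X + 1.0, ks) > f


class TestElementaryFluxes:
    def test_assimilation(self, params):
        assert assimilation_flux(params, 1e-3, 0.0, 1.0) == 0.0
        assert assimilation_flux(params, 1.0, 1.0, 1.0) == pytest.approx(params.p_AM)
        p313 = replace(params, p_AM=313.0)
        assert assimilation_flux(p313, 1e-3, 0.5, 1.0) == pytest.approx(1.565)

    def test_maintenance(self, params):
        p = replace(params, p_M=500.0)
        assert maintenance_flux(p, 1e-3, 1.0) == pytest.approx(0.5)
        assert maintenance_flux(p, 1e-3, 2.0) == pytest.approx(1.0)  # linear in qM

    def test_mobilization(self, params):
        assert mobilization_flux(params, 0.0, 1e-3, 0.65, 0.5, 1.0) == 0.0
        # hand evaluation: E=10, v*qM=0.1, E_G=4000, V=1e-3, p_S=0.5, k=0.65
        p = replace(params, v_dot=0.1, E_G=4000.0)
        got = mobilization_flux(p, 10.0, 1e-3, 0.65, 0.5, 1.0)
        assert got == pytest.approx(10.0 * (4.0 + 0.5) / (4.0 + 6.5), rel=1e-12)
        # E -> infinity limit: (qM v E_G V^(2/3) + p_S)/kappa
        big = mobilization_flux(p, 1e12, 1e-3, 0.65, 0.5, 1.0)
        assert big == pytest.approx((4.0 + 0.5) / 0.65, rel=1e-3)


class TestThermalCorrections:
    def test_arrhenius_reference_and_examples(self, params):
        assert maintenance_thermal_correction(params, params.T_star) == pytest.approx(1.0)
        # frozen from direct arithmetic with Ea = 0.65 eV
        assert maintenance_thermal_correction(params, 301.15) == pytest.approx(1.9808, abs=1e-3)
        assert maintenance_thermal_correction(params, 285.15) == pytest.approx(0.4858, abs=1e-3)

    def test_arrhenius_monotone(self, params):
        T = np.linspace(270, 320, 200)
        q = [maintenance_thermal_correction(params, t) for t in T]
        assert np.all(np.diff(q) > 0)

    def test_half_deactivation_at_T_d(self, params):
        qA = uptake_thermal_correction(params, params.T_d)
        qM = maintenance_thermal_correction(params, params.T_d)
        assert qA / qM == pytest.approx(0.5, rel=1e-12)

    def test_not_renormalised_at_reference(self, params):
        # deactivation is already active at 20 degC
        assert uptake_thermal_correction(params, params.T_star) == pytest.approx(0.903, abs=1e-3)

    def test_unimodal_decreasing_above_T_d(self, params):
        T = np.linspace(params.T_d, params.T_d + 15, 100)
        qA = [uptake_thermal_correction(params, t) for t in T]
        assert np.all(np.diff(qA) < 0)

    def test_deactivation_ratio_identity(self, params):
        for T in (280.0, 290.0, 300.0, 310.0):
            ratio = uptake_thermal_correction(params, T) / maintenance_thermal_correction(params, T)
            kB = params.k_B
            expected = 1.0 / (1.0 + math.exp(params.E_d * (1 / (kB * params.T_d) - 1 / (kB * T))))
            assert ratio == pytest.approx(expected, rel=1e-12)


class TestAllocationFraction:
    def test_asymptotes_and_midpoint(self, params):
        assert allocation_fraction(params, params.T_hat - 1000) == pytest.approx(0.7, abs=1e-9)
        assert allocation_fraction(params, params.T_hat + 1000) == pytest.approx(0.6, abs=1e-9)
        assert allocation_fraction(params, params.T_hat) == pytest.approx(0.65)

    def test_degenerate_sigmoid_is_constant(self, params):
        p = replace(params, lambda_=0.0)
        for T in (-10.0, 5.0, 22.0, 40.0):
            assert allocation_fraction(p, T) == pytest.approx(0.65)

    def test_non_increasing_in_temperature(self, params):
        T = np.linspace(-5, 40, 200)
        k = [allocation_fraction(params, t) for t in T]
        assert np.all(np.diff(k) <= 0)
        assert all(params.kappa_min <= x <= params.kappa_max for x in k)


class TestAdultInstar:
    @pytest.mark.parametrize("convention", ["rate_scaled", "as_printed"])
    def test_reference_duration(self, params, convention):
        p = replace(params, delta_convention=convention)
        assert adult_instar_duration(p, p.T_star) == pytest.approx(2.0, rel=1e-12)

    def test_rate_scaled_shrinks_with_warming(self, params):
        p = replace(params, delta_convention="rate_scaled")
        assert adult_instar_duration(p, 301.15) == pytest.approx(2.0 / 1.9808, abs=2e-3)

    def test_always_positive(self, params):
        for T in (270.0, 290.0, 310.0):
            for conv in ("rate_scaled", "as_printed"):
                assert adult_instar_duration(replace(params, delta_convention=conv), T) > 0


class TestStateDerivatives:
    def test_zero_reserve_signs(self, params):
        s = OrganismState(E=0.0, V=1e-3, R=0.1)
        dE, dV, dR = state_derivatives(params, s, 20.0, 3.0)
        assert dE >= 0          # assimilation only
        assert dV < 0           # maintenance shrinks structure
        assert dR <= 0          # only the drain acts

    def test_failed_state_rejected(self, params):
        s = OrganismState(E=1.0, V=1e-3, R=0.1)
        s.stage = Stage.FAILED
        with pytest.raises(DEBError):
            state_derivatives(params, s, 20.0, 3.0)

    @given(
        E=st.floats(0.0, 50.0),
        V=st.floats(1e-6, 5e-3),
        R=st.floats(0.0, 5.0),
        T=st.floats(2.0, 35.0),
        X=st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_energy_closure(self, E, V, R, T, X):
        """p_A - dE/dt - E_G dV/dt - p_S - (1-kappa) p_C = 0 identically."""
        params = DEBParameters()
        s = OrganismState(E=E, V=V, R=R)
        dE, dV, dR = state_derivatives(params, s, T, X)
        T_K = T + 273.15
        qM = maintenance_thermal_correction(params, T_K)
        qA = uptake_thermal_correction(params, T_K)
        kappa = allocation_fraction(params, T)
        f = scaled_functional_response(X, params.ks)
        p_A = assimilation_flux(params, V, f, qA)
        p_S = maintenance_flux(params, V, qM)
        p_C = mobilization_flux(params, E, V, kappa, p_S, qM)
        residual = p_A - dE - params.E_G * dV - p_S - (1 - kappa) * p_C
        scale = max(abs(p_A), abs(p_C), abs(p_S), 1e-30)
        assert abs(residual) / scale < 1e-10

    def test_dual_implementation_oracle(self, params):
        """100 random draws agree with a symbol-by-symbol re-evaluation."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            E = float(rng.uniform(0, 30))
            V = float(rng.uniform(1e-6, 5e-3))
            R = float(rng.uniform(0, 3))
            T = float(rng.uniform(4, 34))
            X = float(rng.uniform(0, 4))
            p = replace(
                params,
                p_AM=float(rng.uniform(50, 400)),
                p_M=float(rng.uniform(*params.p_M_bounds)),
                k_j=float(rng.uniform(*params.k_j_bounds)),
                v_dot=float(rng.uniform(0.02, 0.3)),
                E_G=float(rng.uniform(800, 5000)),
            )
            got = state_derivatives(p, OrganismState(E=E, V=V, R=R), T, X)
            want = oracle_fluxes(p, E, V, R, T, X)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-12, abs=1e-15)


class TestMassConversion:
    def test_examples(self, params):
        s = OrganismState(E=0.0, V=1e-3, R=2.0, stage=Stage.MATURE_AWAITING_CLUTCH)
        assert mass_at_maturity(params, s, 0.0) == pytest.approx(params.d_m * 1e-3)
        s2 = OrganismState(E=5.0, V=1e-3, R=2.0, stage=Stage.MATURE_AWAITING_CLUTCH)
        assert mass_at_maturity(params, s2, 2.5) == pytest.approx(190 + 200 + 100)

    def test_monotone_in_components(self, params):
        base = mass_at_maturity(params, OrganismState(E=1.0, V=1e-3, R=0.0), 1.0)
        assert mass_at_maturity(params, OrganismState(E=2.0, V=1e-3, R=0.0), 1.0) > base
        assert mass_at_maturity(params, OrganismState(E=1.0, V=2e-3, R=0.0), 1.0) > base
        assert mass_at_maturity(params, OrganismState(E=1.0, V=1e-3, R=0.0), 2.0) > base

    def test_negative_clutch_rejected(self, params):
        with pytest.raises(DEBError):
            mass_at_maturity(params, OrganismState(E=1.0, V=1e-3, R=0.0), -0.1)


class TestParametersAndState:
    def test_invariant_validation(self):
        with pytest.raises(DEBError):
            DEBParameters(kappa_min=0.8, kappa_max=0.7)
        with pytest.raises(DEBError):
            DEBParameters(p_M=2000.0)           # outside admissible interval
        with pytest.raises(DEBError):
            DEBParameters(E_G=-1.0)
        DEBParameters(p_M=2000.0, p_M_bounds=(300.0, 2500.0))  # bounds overridable

    def test_config_roundtrip_and_unknown_keys(self, tmp_path):
        cfg = tmp_path / "pars.toml"
        cfg.write_text('p_AM = 150.0\nv = 0.1\n"lambda" = 1.5\n')
        p = DEBParameters.from_file(cfg)
        assert (p.p_AM, p.v_dot, p.lambda_) == (150.0, 0.1, 1.5)
        with pytest.raises(DEBError, match="unknown"):
            DEBParameters.from_dict({"p_AMM": 1.0})

    def test_yaml_config(self, tmp_path):
        cfg = tmp_path / "pars.yaml"
        cfg.write_text("ks: 0.5\nm0: 6.0\n")
        p = DEBParameters.from_file(cfg)
        assert (p.ks, p.m0) == (0.5, 6.0)

    def test_state_validation_and_stage_order(self):
        with pytest.raises(DEBError):
            OrganismState(E=-1.0, V=1e-3, R=0.0)
        s = OrganismState(E=1.0, V=1e-3, R=0.0)
        s.advance_stage(Stage.MATURE_AWAITING_CLUTCH)
        with pytest.raises(DEBError):
            s.advance_stage(Stage.JUVENILE)

    def test_neonate_mass_balance(self, params):
        s = neonate_state(params)
        mass = params.d_m * s.V + s.E / params.d_e
        assert mass == pytest.approx(params.m0, rel=1e-12)
        assert s.R == 0.0
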