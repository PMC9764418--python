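"""Case-1 washing (frozen solid phase): displacement, dilution, dispersion."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats
from scipy.special import erfc, erfcx

import cakewash as cw
from cakewash.filtration import constant_pressure_filtration, make_initial_wash_cake
from cakewash.materials import BinarySolubilityCurve, MaterialSystem
from cakewash.washing import (
    axial_dispersion_coefficient,
    mass_balance_audit,
    wash_cstr_cascade,
    wash_dilution,
    wash_dispersion_pde,
    wash_displacement,
    wash_ratio,
    wr_from_time,
)


def layered_cake(fx, n_layers):
    filt = constant_pressure_filtration(fx.suspension, fx.conditions, fx.system)
    cake = make_initial_wash_cake(filt, n_layers)
    cake._hydraulics = {
        "pressure_drop": fx.conditions.pressure_drop,
        "media_resistance": fx.conditions.media_resistance,
    }
    return cake


class TestWashRatio:
    def test_definition_and_degenerate_cake(self):
        assert wash_ratio(2.0e-6, 1.0e-6) == 2.0
        assert wash_ratio(0.0, 1.0e-6) == 0.0
        with pytest.raises(ValueError):
            wash_ratio(1e-6, 0.0)

    def test_time_form(self):
        # W_r = u_s t / (eps L): one void volume passes when u_s t = eps L
        assert wr_from_time(10.0, 1e-4, 0.01, 0.44) == pytest.approx(
            1e-4 * 10 / (0.44 * 0.01)
        )

    def test_axial_dispersion_modes(self):
        assert axial_dispersion_coefficient(0.0, 50e-6, 1e-9, "fixed_D") == 1e-9
        assert axial_dispersion_coefficient(1e-3, 50e-6, 1e-9, "correlation") == (
            pytest.approx(1e-9 + 0.5 * 1e-3 * 50e-6)
        )
        us = np.array([1e-5, 1e-4, 1e-3])
        vals = [axial_dispersion_coefficient(u, 50e-6, 1e-9, "correlation") for u in us]
        assert vals == sorted(vals)


class TestDisplacement:
    def test_piecewise_filtrate_composition(self, pcm_heptane_fx):
        cake = layered_cake(pcm_heptane_fx, 1)
        curve = wash_displacement(cake, pcm_heptane_fx.protocol, pcm_heptane_fx.system)
        before = curve.wash_ratio < 1.0
        np.testing.assert_allclose(
            curve.filtrate_mass_fractions["solute"][before], 0.12, rtol=1e-12
        )
        after = curve.wash_ratio >= 1.0
        np.testing.assert_allclose(curve.filtrate_mass_fractions["solute"][after], 0.0)
        np.testing.assert_allclose(
            curve.filtrate_mass_fractions["crystallization_solvent"][after], 0.0
        )
        assert np.all(np.diff(curve.c_over_c0) <= 0)

    def test_zero_solubility_dissolve_degenerates_to_plain_displacement(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        zero_curve = BinarySolubilityCurve([0.0, 1.0], [0.136364, 0.0])
        system0 = MaterialSystem(
            fx.system.solute, fx.system.crystallization_solvent,
            fx.system.wash_solvent, zero_curve,
        )
        plain = wash_displacement(cake, fx.protocol, fx.system, dissolve=False)
        degen = wash_displacement(cake, fx.protocol, system0, dissolve=True)
        np.testing.assert_allclose(
            degen.cumulative_solid_mass_change, plain.cumulative_solid_mass_change
        )
        np.testing.assert_allclose(degen.c_over_c0, plain.c_over_c0)

    def test_model1_audit_solid_untouched(self, pcm_heptane_fx):
        cake = layered_cake(pcm_heptane_fx, 1)
        curve = wash_displacement(cake, pcm_heptane_fx.protocol, pcm_heptane_fx.system)
        assert float(np.sum(curve.final_cake.solid_mass)) == float(
            np.sum(cake.solid_mass)
        )
        audit = mass_balance_audit(curve, cake)
        assert audit["max_relative_residual"] < 1e-10


class TestDilution:
    def test_exponential_washout_closed_form(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        curve = wash_dilution(cake, fx.protocol, fx.system)
        np.testing.assert_allclose(
            curve.c_over_c0, np.exp(-curve.wash_ratio), rtol=0, atol=1e-8
        )
        assert curve.c_over_c0[-1] == pytest.approx(math.exp(-2.0), abs=1e-8)
        assert math.exp(-2.0) > 0.01  # two cake volumes do not finish the wash
        assert np.all(np.diff(curve.c_over_c0) <= 0)

    def test_initial_filtrate_is_mother_liquor(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        curve = wash_dilution(cake, fx.protocol, fx.system)
        assert curve.filtrate_mass_fractions["solute"][0] == pytest.approx(0.12, rel=1e-9)
        assert curve.filtrate_mass_fractions["crystallization_solvent"][0] == (
            pytest.approx(0.88, rel=1e-9)
        )

    def test_audit_closure(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        curve = wash_dilution(cake, fx.protocol, fx.system)
        assert mass_balance_audit(curve, cake)["max_relative_residual"] < 1e-10


class TestCascade:
    def test_single_tank_degenerates_to_dilution(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        dil = wash_dilution(cake, fx.protocol, fx.system)
        cas = wash_cstr_cascade(cake, fx.protocol, fx.system)
        np.testing.assert_allclose(cas.c_over_c0, dil.c_over_c0, rtol=0, atol=1e-10)

    def test_ten_tanks_match_the_erlang_closed_form(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 10)
        curve = wash_cstr_cascade(cake, fx.protocol, fx.system)
        # equal tanks in series: outlet c/c0 is the Erlang(N, N) survival
        expected = stats.gamma.sf(curve.wash_ratio, a=10, scale=1 / 10)
        np.testing.assert_allclose(curve.c_over_c0, expected, rtol=0, atol=1e-8)

    def test_three_stage_wash_curve_morphology(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 10)
        c = wash_cstr_cascade(cake, fx.protocol, fx.system)

        def at(w):
            return float(np.interp(w, c.wash_ratio, c.c_over_c0))

        assert at(0.3) > 0.99  # constant-rate stage
        assert 0.1 < at(1.0) < 0.9  # intermediate fall
        assert at(2.0) < 0.05  # long tail
        assert np.all(np.diff(c.c_over_c0) <= 1e-12)

    def test_convergence_to_the_displacement_step(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        sups = []
        for n in (5, 20, 80):
            cake = layered_cake(fx, n)
            c = wash_cstr_cascade(cake, fx.protocol, fx.system)
            step = np.where(c.wash_ratio < 1.0, 1.0, 0.0)
            # the transition sharpens like 1/sqrt(N); exclude a fixed window
            # around the discontinuity and watch the tails collapse
            away = np.abs(c.wash_ratio - 1.0) > 0.25
            sups.append(float(np.max(np.abs(c.c_over_c0 - step)[away])))
        assert sups[0] > sups[1] > sups[2]
        assert sups[-1] < 0.05


class TestDispersionPDE:
    @staticmethod
    def flux_inlet_washout(zeta, tau, Pe):
        """Semi-infinite advection-dispersion washout, flux (third-type) inlet."""
        a = (zeta - tau) * np.sqrt(Pe / (4 * tau))
        b = (zeta + tau) * np.sqrt(Pe / (4 * tau))
        inj = (
            0.5 * erfc(a)
            + np.sqrt(Pe * tau / np.pi) * np.exp(-a * a)
            - 0.5 * (1 + Pe * zeta + Pe * tau) * np.exp(Pe * zeta - b * b) * erfcx(b)
        )
        return 1.0 - inj

    def _moderate_peclet_protocol(self, fx, cake, Pe=100.0, n_nodes=400, wr=0.5):
        A = fx.conditions.filter_area
        Qw = 1e-7
        u_s = Qw / A
        v = u_s / float(np.mean(cake.porosity))
        D = v * cake.height / Pe
        return replace(
            fx.protocol,
            flow_mode="constant_flow",
            wash_flow_rate=Qw,
            molecular_diffusivity=D,
            n_nodes=n_nodes,
            wash_ratio_max=wr,
        )

    def test_matches_the_flux_inlet_closed_form(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        proto = self._moderate_peclet_protocol(fx, cake)
        curve = wash_dispersion_pde(cake, proto, fx.system)
        assert not curve.metadata["upwind"]
        n = proto.n_nodes
        zc = (np.arange(n) + 0.5) / n
        field = curve.metadata["holdup_field"]
        ana = self.flux_inlet_washout(zc, proto.wash_ratio_max, curve.metadata["peclet"])
        assert float(np.max(np.abs(field - ana))) < 1e-3

    def test_mass_balance_every_output_step(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        curve = wash_dispersion_pde(cake, fx.protocol, fx.system)
        # solute in filtrate never exceeds the initial inventory and the
        # final closure holds to solver tolerance
        init_solute = cake.liquids[0].mass_solute
        out = curve.cumulative_filtrate_mass["solute"]
        assert np.all(out <= init_solute * (1 + 1e-8))
        assert np.all(np.diff(out) >= -1e-15)
        audit = mass_balance_audit(curve, cake)
        assert audit["max_relative_residual"] < 1e-8

    def test_small_dispersion_recovers_the_displacement_step(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        curve = wash_dispersion_pde(cake, fx.protocol, fx.system)  # D = 1e-9, huge Pe

        def at(w):
            return float(np.interp(w, curve.wash_ratio, curve.c_over_c0))

        assert at(0.7) > 0.9
        assert at(1.3) < 0.1
        drops = np.diff(curve.c_over_c0)
        w_mid = curve.wash_ratio[np.argmin(drops)]
        assert abs(w_mid - 1.0) < 0.1

    def test_high_cell_peclet_triggers_upwinding(self, pcm_heptane_fx):
        fx = pcm_heptane_fx
        cake = layered_cake(fx, 1)
        curve = wash_dispersion_pde(cake, fx.protocol, fx.system)
        assert curve.metadata["cell_peclet"] > 2.0
        assert curve.metadata["upwind"]
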