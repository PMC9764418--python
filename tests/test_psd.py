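"""PSD discretization, statistics and mass-conserving dissolution/growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from cakewash.materials import DegenerateInputError
from cakewash.psd import (
    DissolutionKinetics,
    InfeasibleDissolutionError,
    ParticleSizeDistribution,
    advance_growth_dissolution,
    fit_lognormal_psd,
    lognormal_psd_from_d50,
    number_moments,
    quantile,
    sauter_mean,
    shift_to_exchange,
    specific_surface_area,
    uniform_dissolve,
)

UM = 1e-6


def random_psd(seed=0, n=12):
    rng = np.random.default_rng(seed)
    edges = np.sort(rng.uniform(1, 300, n + 1)) * UM
    mass = rng.uniform(0.0, 1.0, n)
    return ParticleSizeDistribution(edges, mass)


class TestLognormalFit:
    def test_number_weighted_moments_realized_within_two_percent(self):
        psd = fit_lognormal_psd(77 * UM, 174 * UM, n_bins=150)
        mean, std = number_moments(psd)
        assert mean == pytest.approx(77 * UM, rel=0.02)
        assert std == pytest.approx(174 * UM, rel=0.02)

    def test_mass_weighted_mean_matches_dense_quadrature(self):
        mean, std = 77 * UM, 174 * UM
        psd = fit_lognormal_psd(mean, std, n_bins=500)
        s2 = math.log1p((std / mean) ** 2)
        s, mu = math.sqrt(s2), math.log(mean) - s2 / 2
        # mass-weighted mean diameter of the continuous number lognormal,
        # by quadrature in log-diameter (heavy upper tail)
        def kernel(x, power):
            return math.exp(power * x) * math.exp(-0.5 * ((x - mu) / s) ** 2)

        lo, hi = mu - 40 * s, mu + 40 * s
        peaks = [mu + 3 * s2, mu + 4 * s2]  # where the d^3 / d^4 integrands peak
        num = integrate.quad(kernel, lo, hi, args=(4,), limit=400, points=peaks)[0]
        den = integrate.quad(kernel, lo, hi, args=(3,), limit=400, points=peaks)[0]
        realized = float(np.sum(psd.bin_mass * psd.midpoints) / psd.total_mass)
        assert realized == pytest.approx(num / den, rel=1e-3)

    def test_vanishing_spread_concentrates_mass_at_the_mean(self):
        mean = 77 * UM
        psd = fit_lognormal_psd(mean, mean * 1e-6, n_bins=200, span=(10 * UM, 1000 * UM))
        i = np.searchsorted(psd.bin_edges, mean) - 1
        assert psd.bin_mass[i] / psd.total_mass > 0.999

    def test_too_narrow_span_raises(self):
        from cakewash.psd import DiscretizationError

        with pytest.raises(DiscretizationError):
            fit_lognormal_psd(77 * UM, 174 * UM, n_bins=80, span=(0.1 * UM, 1000 * UM))

    def test_d50_parameterization_reproduces_the_median_exactly(self):
        psd = lognormal_psd_from_d50(77 * UM, 174 * UM, n_bins=150, total_mass=5.895e-3)
        assert quantile(psd, 0.5) == pytest.approx(77 * UM, rel=1e-3)
        assert psd.total_mass == pytest.approx(5.895e-3, rel=1e-12)


class TestQuantile:
    def test_single_bin_quantiles_stay_inside_the_bin(self):
        psd = ParticleSizeDistribution([10 * UM, 20 * UM], [1.0])
        for p in (0.1, 0.5, 0.9):
            assert 10 * UM < quantile(psd, p) < 20 * UM

    def test_symmetric_two_bin_median_is_the_shared_edge(self):
        psd = ParticleSizeDistribution([10 * UM, 20 * UM, 30 * UM], [0.5, 0.5])
        assert quantile(psd, 0.5) == pytest.approx(20 * UM, rel=1e-14)

    def test_against_refined_grid_scan(self):
        psd = random_psd(3)
        # 10x refined grid with mass uniform within each coarse bin
        fine_edges = np.concatenate(
            [
                np.linspace(a, b, 11)[:-1]
                for a, b in zip(psd.bin_edges[:-1], psd.bin_edges[1:])
            ]
            + [psd.bin_edges[-1:]]
        )
        fine_mass = np.repeat(psd.bin_mass / 10.0, 10)
        cum = np.cumsum(fine_mass) / fine_mass.sum()
        for p in (0.1, 0.25, 0.5, 0.75, 0.9):
            k = np.searchsorted(cum, p)
            width = fine_edges[k + 1] - fine_edges[k]
            assert abs(quantile(psd, p) - fine_edges[k + 1]) <= width + 1e-18

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_monotone_in_p_and_ordered_percentiles(self, seed):
        psd = random_psd(seed)
        d10, d50, d90 = (quantile(psd, p) for p in (0.1, 0.5, 0.9))
        assert d10 <= d50 <= d90

    def test_empty_psd_is_degenerate(self):
        psd = ParticleSizeDistribution([1 * UM, 2 * UM], [0.0])
        with pytest.raises(DegenerateInputError):
            quantile(psd, 0.5)


class TestSauterAndSurface:
    def test_monodisperse_identity_and_sphericity_scaling(self):
        d = 50 * UM
        psd = ParticleSizeDistribution([d - 1e-12, d + 1e-12], [1.0])
        assert sauter_mean(psd, 1.0) == pytest.approx(d, rel=1e-9)
        assert sauter_mean(psd, 0.5) == pytest.approx(d / 2, rel=1e-9)

    def test_bimodal_against_hand_harmonic_mean(self):
        psd = ParticleSizeDistribution([9 * UM, 11 * UM, 99 * UM, 101 * UM], [0.3, 0.0, 0.7])
        hand = (0.3 + 0.7) / (0.3 / (10 * UM) + 0.7 / (100 * UM))
        assert sauter_mean(psd, 1.0) == pytest.approx(hand, rel=1e-12)

    def test_specific_surface_of_monodisperse_spheres(self):
        d, rho = 50 * UM, 1293.0
        psd = ParticleSizeDistribution([d - 1e-12, d + 1e-12], [1.0])
        assert specific_surface_area(psd, rho, 1.0) == pytest.approx(6 / (rho * d), rel=1e-9)
        halved = ParticleSizeDistribution([d / 2 - 1e-12, d / 2 + 1e-12], [1.0])
        assert specific_surface_area(halved, rho, 1.0) == pytest.approx(
            2 * specific_surface_area(psd, rho, 1.0), rel=1e-9
        )

    def test_specific_surface_against_hand_summation(self):
        psd = random_psd(7)
        rho, phi = 1293.0, 0.4127
        hand = sum(
            6 * m / (rho * d * phi) for m, d in zip(psd.bin_mass, psd.midpoints)
        ) / psd.total_mass
        assert specific_surface_area(psd, rho, phi) == pytest.approx(hand, rel=1e-12)


class TestUniformDissolve:
    def test_zero_dissolution_preserves_the_fixture_median(self, pcm_water_fx):
        psd = pcm_water_fx.suspension.psd
        out = uniform_dissolve(psd, 0.0)
        assert quantile(out, 0.5) == pytest.approx(77 * UM, rel=1e-3)
        assert out.total_mass == pytest.approx(psd.total_mass, rel=1e-14)

    def test_seven_eighths_dissolution_halves_all_diameters(self):
        psd = random_psd(1)
        out = uniform_dissolve(psd, psd.total_mass * 7 / 8)
        np.testing.assert_allclose(out.bin_edges, psd.bin_edges / 2, rtol=1e-12)

    @given(st.integers(0, 500), st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_exact_mass_balance_and_shape_preservation(self, seed, frac):
        psd = random_psd(seed)
        dm = frac * psd.total_mass * 0.999
        out = uniform_dissolve(psd, dm)
        assert out.total_mass + dm == pytest.approx(psd.total_mass, rel=1e-12)
        np.testing.assert_allclose(
            out.bin_mass / out.total_mass, psd.bin_mass / psd.total_mass, rtol=1e-10
        )

    def test_overdraw_raises(self):
        psd = random_psd(2)
        with pytest.raises(InfeasibleDissolutionError):
            uniform_dissolve(psd, psd.total_mass * 1.01)


class TestGrowthDissolution:
    KIN = DissolutionKinetics(rate_constant=1e-6, exponent=1.0)

    def test_zero_supersaturation_is_identity(self):
        psd = random_psd(4)
        out, dm = advance_growth_dissolution(psd, self.KIN, 0.0, 10.0)
        assert dm == 0.0
        np.testing.assert_allclose(out.bin_mass, psd.bin_mass)

    @given(st.integers(0, 300), st.floats(-0.5, 0.5), st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_mass_conservation_and_sign(self, seed, sigma, dt):
        psd = random_psd(seed)
        out, dm = advance_growth_dissolution(psd, self.KIN, sigma, dt)
        assert out.total_mass + dm == pytest.approx(psd.total_mass, rel=1e-10, abs=1e-22)
        slack = 1e-12 * psd.total_mass  # round-off of the quartic integrals
        if sigma < 0:
            assert out.total_mass <= psd.total_mass + slack
        elif sigma > 0:
            assert out.total_mass >= psd.total_mass - slack

    def test_sustained_dissolution_empties_fines_first_and_raises_d50(self):
        psd = lognormal_psd_from_d50(77 * UM, 174 * UM, n_bins=100)
        d50_0 = quantile(psd, 0.5)
        first_occupied_0 = np.argmax(psd.bin_mass > 1e-9 * psd.total_mass)
        kin = DissolutionKinetics(rate_constant=1e-7, exponent=1.0)
        out = psd
        for _ in range(20):
            out, _ = advance_growth_dissolution(out, kin, -0.5, 10.0)
        first_occupied = np.argmax(out.bin_mass > 1e-9 * out.total_mass)
        assert first_occupied > first_occupied_0
        assert quantile(out, 0.5) > d50_0

    def test_shrinking_sphere_analytic_mass(self):
        # uniform number density on a bin [a, b] shifted by dL has exact mass
        # ratio ((b+dL)^4 - (a+dL)^4) / (b^4 - a^4); a narrow bin converges to
        # the shrinking-sphere law (d + dL)^3 / d^3.
        d = 60 * UM
        kin = DissolutionKinetics(rate_constant=1.0, exponent=1.0)
        for h, tol in ((0.05, 2e-3), (0.005, 2e-5), (0.0005, 1e-6)):
            a, b = d * (1 - h), d * (1 + h)
            psd = ParticleSizeDistribution([a, b], [1.0])
            dL = -10 * UM
            out, dm = advance_growth_dissolution(psd, kin, -1.0, 10 * UM)  # G*dt = -10 um
            exact_bin = ((b + dL) ** 4 - (a + dL) ** 4) / (b**4 - a**4)
            assert out.total_mass == pytest.approx(exact_bin, rel=1e-10)
            sphere = ((d + dL) / d) ** 3
            assert out.total_mass == pytest.approx(sphere, rel=tol)

    def test_flash_exchange_hits_the_requested_mass(self):
        psd = random_psd(9)
        for delta in (0.3 * psd.total_mass, -0.4 * psd.total_mass):
            out, actual = shift_to_exchange(psd, delta)
            assert actual == pytest.approx(delta, rel=1e-9)
            assert out.total_mass == pytest.approx(psd.total_mass - delta, rel=1e-9)
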