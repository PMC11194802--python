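"""Thermochemistry: normal modes, isotope substitution, Eyring rates, KIEs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grekin import (
    CONSTANTS,
    GeneratorConfig,
    HarmonicSystem,
    barrier_from_energies,
    eyring_rate,
    gen_toy_hessian,
    hessian_frequencies,
    isotope_substitute,
    kie_from_barriers,
    thermal_energy,
)
from grekin.constants import AMU_KG, BOHR_M, HARTREE_J
from grekin.thermo import read_hessian_file, write_hessian_file


def diatomic(m1, m2, k=0.35):
    """Two atoms joined by one spring of constant k (hartree/bohr^2) along x."""
    return gen_toy_hessian(
        GeneratorConfig(seed=0), n_atoms=2,
        spring_constants=np.array([k]), masses=np.array([m1, m2]),
    )


def analytic_wavenumber(k_au, mu_amu):
    """Closed-form diatomic wavenumber, cm^-1 (the independent oracle)."""
    k_si = k_au * HARTREE_J / BOHR_M**2
    mu_si = mu_amu * AMU_KG
    return math.sqrt(k_si / mu_si) / (2.0 * math.pi * CONSTANTS.c)


class TestHessianFrequencies:
    @pytest.mark.parametrize("m1,m2,k", [(1.0, 1.0, 0.3), (1.00783, 31.972, 0.4),
                                         (12.0, 16.0, 0.9)])
    def test_diatomic_matches_reduced_mass_formula(self, m1, m2, k):
        nus = hessian_frequencies(diatomic(m1, m2, k))
        mu = m1 * m2 / (m1 + m2)
        expected = analytic_wavenumber(k, mu)
        assert nus[-1] == pytest.approx(expected, rel=1e-8)
        # remaining 5 modes are rigid (zero curvature)
        assert np.allclose(nus[:-1], 0.0, atol=1e-6 * expected)

    def test_zero_hessian_all_zero(self):
        sys0 = HarmonicSystem(masses=np.array([1.0, 2.0]), hessian=np.zeros((6, 6)))
        assert np.allclose(hessian_frequencies(sys0), 0.0)

    def test_quadrupled_masses_halve_frequencies(self):
        base = diatomic(3.0, 7.0)
        heavy = HarmonicSystem(masses=base.masses * 4.0, hessian=base.hessian)
        nu0 = hessian_frequencies(base)[-1]
        nu4 = hessian_frequencies(heavy)[-1]
        assert nu4 == pytest.approx(nu0 / 2.0, rel=1e-10)

    def test_projection_removes_rigid_modes(self):
        system = diatomic(1.0, 16.0)
        nus = hessian_frequencies(system, project_tr=True)
        # translations and the two rotations of a linear system go to zero;
        # the stretch survives
        assert np.sum(np.abs(nus) > 1.0) == 1

    def test_negative_curvature_reported_negative(self):
        base = diatomic(1.0, 1.0, k=0.3)
        ts = HarmonicSystem(masses=base.masses, hessian=-base.hessian)
        assert hessian_frequencies(ts)[0] < 0

    @pytest.mark.parametrize("bad", [np.zeros((5, 5)), np.arange(36.0).reshape(6, 6)])
    def test_invalid_hessian_rejected(self, bad):
        with pytest.raises(ValueError):
            HarmonicSystem(masses=np.array([1.0, 2.0]), hessian=bad)


class TestIsotopeSubstitution:
    def test_no_substitution_identical(self):
        system = diatomic(1.00783, 31.972)
        same = isotope_substitute(system, [], 2.0)
        assert np.allclose(hessian_frequencies(system), hessian_frequencies(same))

    def test_h_to_d_stretch_ratio(self):
        # X-H oscillator with X = sulfur: ratio follows the reduced masses
        system = diatomic(1.00783, 31.972)
        sub = isotope_substitute(system, [0], 2.01410)
        nu_h = hessian_frequencies(system)[-1]
        nu_d = hessian_frequencies(sub)[-1]
        mu_h = 1.00783 * 31.972 / (1.00783 + 31.972)
        mu_d = 2.01410 * 31.972 / (2.01410 + 31.972)
        assert nu_h / nu_d == pytest.approx(math.sqrt(mu_d / mu_h), rel=1e-10)
        assert nu_h / nu_d == pytest.approx(1.39, abs=0.01)

    def test_zpe_difference_gives_normal_kie(self):
        # H/D substitution lowers the ZPE of the reactant stretch more than
        # any TS mode it feeds, so the barrier rises and KIE > 1
        system = diatomic(1.00783, 31.972)
        sub = isotope_substitute(system, [0], 2.01410)
        nu_h = hessian_frequencies(system)[-1:]
        nu_d = hessian_frequencies(sub)[-1:]
        dzpe = thermal_energy(nu_h, scale=1.0).zpe - thermal_energy(nu_d, scale=1.0).zpe
        kie = math.exp(dzpe * 1000.0 / (CONSTANTS.R * 303.0))
        assert kie > 3.0  # a C/S-H stretch ZPE loss gives a large primary KIE

    def test_bad_index(self):
        with pytest.raises(IndexError):
            isotope_substitute(diatomic(1.0, 2.0), [5], 2.0)


class TestThermalEnergy:
    def test_single_mode_zpe_closed_form(self):
        corr = thermal_energy([1000.0], T=303.0, scale=1.0)
        expected = CONSTANTS.NA * CONSTANTS.h * CONSTANTS.c * 1000.0 / 2.0 / 1000.0
        assert corr.zpe == pytest.approx(expected, rel=1e-12)
        assert corr.zpe == pytest.approx(5.981, abs=5e-4)

    def test_low_frequency_equipartition_limit(self):
        corr = thermal_energy([1e-6], T=303.0, scale=1.0)
        assert corr.e_vib == pytest.approx(CONSTANTS.R * 303.0 / 1000.0, rel=1e-6)

    def test_high_frequency_frozen(self):
        corr = thermal_energy([3000.0], T=303.0, scale=1.0)
        assert corr.e_vib < 1e-3

    def test_scaling_modes(self):
        both = thermal_energy([800.0, 1600.0], T=303.0, scale=0.9806)
        zpe_only = thermal_energy([800.0, 1600.0], T=303.0, scale=0.9806,
                                  scale_evib=False)
        unscaled = thermal_energy([800.0, 1600.0], T=303.0, scale=1.0)
        assert both.zpe == pytest.approx(0.9806 * unscaled.zpe)
        assert both.e_vib == pytest.approx(0.9806 * unscaled.e_vib)
        assert zpe_only.e_vib == pytest.approx(unscaled.e_vib)
        assert both.total == pytest.approx(both.zpe + both.e_vib)

    def test_e_vib_bounded_and_monotone_in_T(self):
        nus = [50.0, 400.0, 1500.0]
        temps = [100.0, 200.0, 303.0, 600.0]
        prev = -1.0
        for T in temps:
            corr = thermal_energy(nus, T=T, scale=1.0)
            assert corr.e_vib <= len(nus) * CONSTANTS.R * T / 1000.0 + 1e-12
            assert corr.e_vib > prev
            prev = corr.e_vib

    def test_negative_wavenumber_rejected(self):
        with pytest.raises(ValueError):
            thermal_energy([-100.0])


class TestEyring:
    def test_zero_barrier_prefactor(self):
        assert eyring_rate(0.0, 303.0) == pytest.approx(6.31e12, rel=1e-3)

    @pytest.mark.parametrize("barrier,expected", [(40.4, 6.8e5), (64.8, 42.0)])
    def test_published_elementary_rates(self, barrier, expected):
        assert eyring_rate(barrier, 303.0) == pytest.approx(expected, rel=0.05)

    def test_monotone_in_barrier_and_temperature(self):
        barriers = np.linspace(-10.0, 120.0, 25)
        rates = [eyring_rate(b, 303.0) for b in barriers]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        for b in (20.0, 60.0, 100.0):
            assert eyring_rate(b, 606.0) > eyring_rate(b, 303.0)

    def test_kappa_scales_linearly(self):
        assert eyring_rate(50.0, kappa=0.5) == pytest.approx(
            0.5 * eyring_rate(50.0, kappa=1.0)
        )


class TestKie:
    @pytest.mark.parametrize("ref,iso,expected,tol", [
        (40.4, 43.2, 3.01, 0.03),
        (72.2, 77.4, 7.87, 0.03),
    ])
    def test_published_ikies(self, ref, iso, expected, tol):
        assert kie_from_barriers(ref, iso) == pytest.approx(expected, rel=tol)

    def test_identity(self):
        assert kie_from_barriers(55.5, 55.5) == 1.0

    @given(
        a=st.floats(min_value=-50.0, max_value=150.0),
        b=st.floats(min_value=-50.0, max_value=150.0),
    )
    def test_reciprocal_property(self, a, b):
        assert kie_from_barriers(a, b) * kie_from_barriers(b, a) == pytest.approx(
            1.0, rel=1e-12
        )


class TestBarrierFromEnergies:
    def test_equal_corrections_cancel(self):
        corr = thermal_energy([1000.0], scale=1.0)
        assert barrier_from_energies(140.4, 100.0, corr, corr) == pytest.approx(40.4)

    def test_synthetic_frequency_sets(self):
        corr_min = thermal_energy([500.0, 1500.0], T=303.0, scale=1.0)
        corr_ts = thermal_energy([450.0], T=303.0, scale=1.0)
        barrier = barrier_from_energies(50.0, 0.0, corr_ts, corr_min)
        # hand-computed sum on the same closed forms
        expected = 50.0 + (corr_ts.zpe + corr_ts.e_vib) - (corr_min.zpe + corr_min.e_vib)
        assert barrier == pytest.approx(expected, rel=1e-12)


class TestHessianFile:
    def test_round_trip(self, tmp_path):
        system = diatomic(1.00783, 31.972)
        path = tmp_path / "hessian.txt"
        write_hessian_file(system, path)
        back = read_hessian_file(path)
        assert np.allclose(back.masses, system.masses)
        assert np.allclose(back.hessian, system.hessian)
        assert np.allclose(
            hessian_frequencies(back), hessian_frequencies(system)
        )

    def test_malformed_file(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("2\nH 1.0 0 0 0\n")
        with pytest.raises(ValueError):
            read_hessian_file(path)
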