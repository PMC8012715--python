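"""Binding-ladder equilibria, Lamm solver physics, signal synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aucplex as ap
from aucplex.synthetic import (BindingLadderModel,
                               equilibrium_ladder, ladder_occupancy,
                               sector_mass, simulate_lamm, synthesize_mwl,
                               synthesize_fluorescence_titration)


def brute_force_ladder(K1, K2, K3, ptot, dtot, n_grid=200_000):
    """Independent oracle: refined grid search over the free-dimer concentration."""
    b1, b2, b3 = K1, K1 * K2, K1 * K2 * K3

    def residual(p):
        d = dtot / (1.0 + b1 * p + b2 * p ** 2 + b3 * p ** 3)
        return p + d * (b1 * p + 2 * b2 * p ** 2 + 3 * b3 * p ** 3) - ptot

    lo, hi = 0.0, ptot
    for _ in range(4):  # successive grid refinement
        p = np.linspace(lo, hi, n_grid)
        i = int(np.argmin(np.abs(residual(p))))
        lo, hi = p[max(i - 1, 0)], p[min(i + 1, n_grid - 1)]
    p_best = p[i]
    d = dtot / (1.0 + b1 * p_best + b2 * p_best ** 2 + b3 * p_best ** 3)
    return {"free_dimer": p_best, "free_duplex": d,
            "complex1": b1 * p_best * d, "complex2": b2 * p_best ** 2 * d,
            "complex3": b3 * p_best ** 3 * d}


class TestEquilibriumLadder:
    def test_no_ligand_all_dna_free(self):
        out = equilibrium_ladder(BindingLadderModel(1e7, 1e7, 1e7, 0.0, 1e-6))
        assert out["free_duplex"] == 1e-6
        assert out["complex1"] == out["complex2"] == out["complex3"] == 0.0

    def test_saturating_single_site_limit(self):
        out = equilibrium_ladder(
            BindingLadderModel(1e15, 0.0, 0.0, 1e-4, 1e-7))
        assert out["complex1"] == pytest.approx(1e-7, rel=1e-6)
        assert out["free_duplex"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_grid_oracle(self):
        K = 1e8
        out = equilibrium_ladder(BindingLadderModel(K, K, K, 1e-6, 0.5e-6))
        ref = brute_force_ladder(K, K, K, 1e-6, 0.5e-6)
        for key in out:
            assert out[key] == pytest.approx(ref[key], rel=1e-4, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0, 1e9), st.floats(0, 1e9), st.floats(0, 1e9),
           st.one_of(st.just(0.0), st.floats(1e-12, 1e-5)),
           st.floats(1e-10, 1e-5))
    def test_mass_balance_exact(self, K1, K2, K3, ptot, dtot):
        out = equilibrium_ladder(BindingLadderModel(K1, K2, K3, ptot, dtot))
        p_tot = (out["free_dimer"] + out["complex1"] + 2 * out["complex2"]
                 + 3 * out["complex3"])
        d_tot = (out["free_duplex"] + out["complex1"] + out["complex2"]
                 + out["complex3"])
        assert p_tot == pytest.approx(ptot, rel=1e-9, abs=1e-15)
        assert d_tot == pytest.approx(dtot, rel=1e-9)

    def test_bound_dna_monotone_in_total_protein(self):
        totals = np.geomspace(1e-9, 1e-5, 25)
        thetas = [ladder_occupancy(equilibrium_ladder(
            BindingLadderModel(1e7, 4e7, 1.6e8, p, 8e-8))) for p in totals]
        assert np.all(np.diff(thetas) >= -1e-12)


class TestLammSolver:
    def test_sector_mass_conserved(self, species_table, geometry, conditions,
                                   scan_times):
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004)
        f = simulate_lamm([(species_table["dimer"], 1.0)], geometry, setup,
                          conditions)
        masses = [sector_mass(f.radii, prof) for prof in f.fields["dimer"]]
        assert np.all(np.abs(np.array(masses) / masses[0] - 1.0) < 1e-3)

    def test_zero_speed_pure_diffusion(self, species_table, geometry, conditions):
        setup = ap.InstrumentSetup(rotor_speed=0.0,
                                   scan_times=(1000.0, 5000.0, 20000.0),
                                   radial_step=0.004)
        f = simulate_lamm([(species_table["dimer"], 1.0)], geometry, setup,
                          conditions)
        prof = f.fields["dimer"]
        m0 = sector_mass(f.radii, prof[0])
        assert sector_mass(f.radii, prof[-1]) == pytest.approx(m0, rel=1e-6)
        # uniform initial condition stays uniform under pure diffusion
        assert np.ptp(prof[-1]) < 1e-9

    def test_low_diffusion_boundary_tracks_analytic_trajectory(
            self, geometry, conditions):
        """Faxen limit: boundary midpoint at r_m exp(s w^2 t) to 0.5%."""
        sp = ap.HydroSpecies("lowD", 5.9e6, 0.7295, 3.7, D=1e-8)
        setup = ap.InstrumentSetup(scan_times=(3600.0,), radial_step=0.002)
        f = simulate_lamm([(sp, 1.0)], geometry, setup, conditions)
        prof = f.fields["lowD"][0]
        plateau = np.median(prof[(f.radii > 6.4) & (f.radii < 6.8)])
        idx = int(np.argmax(prof > 0.5 * plateau))
        r_mid = float(np.interp(0.5 * plateau,
                                [prof[idx - 1], prof[idx]],
                                [f.radii[idx - 1], f.radii[idx]]))
        r_pred = geometry.meniscus_radius * np.exp(
            3.7e-13 * setup.omega ** 2 * 3600.0)
        assert abs(r_mid - r_pred) / r_pred < 5e-3

    def test_fields_non_negative(self, species_table, geometry, conditions,
                                 scan_times):
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004)
        f = simulate_lamm([(species_table["complex3"], 1.0)], geometry, setup,
                          conditions)
        assert np.all(f.fields["complex3"] >= 0.0)

    def test_coarse_grid_rejected_with_suggestion(self, species_table, geometry,
                                                  conditions):
        setup = ap.InstrumentSetup(scan_times=(600.0,), radial_step=0.2)
        with pytest.raises(ValueError, match="radial_step"):
            simulate_lamm([(species_table["dimer"], 1.0)], geometry, setup,
                          conditions)

    def test_unstable_time_step_rejected(self, species_table, geometry,
                                         conditions):
        setup = ap.InstrumentSetup(scan_times=(6000.0,), radial_step=0.004)
        with pytest.raises(ValueError, match="dt"):
            simulate_lamm([(species_table["dimer"], 1.0)], geometry, setup,
                          conditions, dt=5000.0)


class TestSynthesizeMwl:
    def test_zero_noise_single_species_exact_composition(
            self, species_table, geometry, conditions, scan_times,
            wavelengths, basis_profiles):
        prot, dna = basis_profiles
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004,
                                   wavelength_grid=wavelengths, noise_sigma=0.0)
        f = simulate_lamm([(species_table["dna"], 1e-6)], geometry, setup,
                          conditions)
        data = synthesize_mwl(f, prot, dna)
        ell = geometry.pathlength
        for k in (0, 20, 40):
            eps = dna.epsilon[k]
            np.testing.assert_allclose(data.absorbance[k] / (ell * eps),
                                       f.fields["dna"], rtol=1e-12)

    def test_seeded_generation_bit_identical(self, species_table, geometry,
                                             conditions, scan_times,
                                             wavelengths, basis_profiles):
        prot, dna = basis_profiles
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004,
                                   wavelength_grid=wavelengths,
                                   noise_sigma=0.01, seed=77)
        f = simulate_lamm([(species_table["dna"], 1e-6)], geometry, setup,
                          conditions)
        a = synthesize_mwl(f, prot, dna).absorbance
        b = synthesize_mwl(f, prot, dna).absorbance
        assert np.array_equal(a, b)

    def test_wavelength_grid_mismatch_rejected(self, species_table, geometry,
                                               conditions, scan_times,
                                               basis_profiles):
        prot, dna = basis_profiles
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004,
                                   wavelength_grid=(250.0, 260.0, 270.0))
        f = simulate_lamm([(species_table["dna"], 1e-6)], geometry, setup,
                          conditions)
        with pytest.raises(ValueError, match="wavelength grid"):
            synthesize_mwl(f, prot, dna)


class TestFluorescenceTitration:
    def test_zero_protein_single_boundary_at_free_dna(
            self, species_table, geometry, conditions, scan_times):
        lad = BindingLadderModel(1e7, 4e7, 1.6e8, 0.0, 8e-8)
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004)
        scans, truths = synthesize_fluorescence_titration(
            [lad], species_table, geometry, setup, conditions)
        assert truths[0]["free_duplex"] == 8e-8
        # signal is exactly the free-duplex unit field times loading
        unit = simulate_lamm([(species_table["dna"], 8e-8 * 1e9)], geometry,
                             setup, conditions)
        np.testing.assert_allclose(scans[0].signal, unit.fields["dna"],
                                   rtol=1e-10)

    def test_saturating_protein_single_boundary_at_complex3(
            self, species_table, geometry, conditions, scan_times):
        lad = BindingLadderModel(1e9, 1e9, 1e12, 1e-4, 8e-8)
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004)
        scans, truths = synthesize_fluorescence_titration(
            [lad], species_table, geometry, setup, conditions)
        assert truths[0]["complex3"] == pytest.approx(8e-8, rel=1e-3)
        unit = simulate_lamm([(species_table["complex3"], 8e-8 * 1e9)],
                             geometry, setup, conditions)
        np.testing.assert_allclose(scans[0].signal, unit.fields["complex3"],
                                   rtol=2e-3, atol=1e-3)

    def test_protein_only_species_carry_no_signal(
            self, species_table, geometry, conditions, scan_times):
        # all DNA-free: huge protein, zero DNA -> zero signal everywhere
        lad = BindingLadderModel(1e7, 4e7, 1.6e8, 1e-5, 0.0)
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004)
        scans, _ = synthesize_fluorescence_titration(
            [lad], species_table, geometry, setup, conditions)
        assert np.all(scans[0].signal == 0.0)

    def test_seeded_titration_reproducible(self, species_table, geometry,
                                           conditions, scan_times):
        lads = [BindingLadderModel(1e7, 4e7, 1.6e8, c, 8e-8)
                for c in (1e-8, 1e-7)]
        setup = ap.InstrumentSetup(scan_times=scan_times, radial_step=0.004,
                                   noise_sigma=1.0, seed=5)
        a, _ = synthesize_fluorescence_titration(lads, species_table, geometry,
                                                 setup, conditions)
        b, _ = synthesize_fluorescence_titration(lads, species_table, geometry,
                                                 setup, conditions)
        for x, y in zip(a, b):
            assert np.array_equal(x.signal, y.signal)
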