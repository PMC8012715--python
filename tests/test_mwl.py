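"""Spectral deconvolution, co-migration distributions, stoichiometry."""

import numpy as np
import pytest

import aucplex as ap
from aucplex.mwl import (OPERATOR_WINDOWS, component_distributions, recompose,
                         spectral_decompose, stoichiometry_from_peaks,
                         complex_mass_from_sv)
from aucplex.spectra import ExtinctionProfile
from aucplex.synthetic import simulate_lamm, synthesize_mwl


def make_mwl(species_loadings, geometry, conditions, times, wavelengths,
             profiles, noise=0.0, seed=0, radial_step=0.004):
    prot, dna = profiles
    setup = ap.InstrumentSetup(scan_times=times, radial_step=radial_step,
                               wavelength_grid=wavelengths, noise_sigma=noise,
                               seed=seed)
    fields = simulate_lamm(species_loadings, geometry, setup, conditions)
    return fields, synthesize_mwl(fields, prot, dna)


class TestSpectralDecompose:
    def test_zero_noise_two_component_exact(self, species_table, geometry,
                                            conditions, scan_times,
                                            wavelengths, basis_profiles):
        fields, data = make_mwl(
            [(species_table["dna"], 4e-7), (species_table["dimer"], 8e-7)],
            geometry, conditions, scan_times, wavelengths, basis_profiles)
        comps = {c.component_label: c
                 for c in spectral_decompose(data, list(basis_profiles))}
        truth_p = 2.0 * fields.fields["dimer"]   # monomer units
        truth_d = fields.fields["dna"]
        assert np.max(np.abs(comps["protein"].conc - truth_p)) < 1e-10 * truth_p.max()
        assert np.max(np.abs(comps["dna"].conc - truth_d)) < 1e-10 * truth_d.max()

    def test_protein_only_data_gives_zero_dna(self, species_table, geometry,
                                              conditions, scan_times,
                                              wavelengths, basis_profiles):
        _, data = make_mwl([(species_table["dimer"], 1e-6)], geometry,
                           conditions, scan_times, wavelengths, basis_profiles)
        comps = {c.component_label: c
                 for c in spectral_decompose(data, list(basis_profiles))}
        assert comps["dna"].conc.max() < 1e-12

    def test_profile_order_invariance(self, species_table, geometry, conditions,
                                      scan_times, wavelengths, basis_profiles):
        _, data = make_mwl(
            [(species_table["complex2"], 3e-7)], geometry, conditions,
            scan_times, wavelengths, basis_profiles)
        prot, dna = basis_profiles
        a = {c.component_label: c.conc for c in spectral_decompose(data, [prot, dna])}
        b = {c.component_label: c.conc for c in spectral_decompose(data, [dna, prot])}
        for label in a:
            np.testing.assert_allclose(a[label], b[label], rtol=1e-10)

    def test_collinear_profiles_rejected(self, species_table, geometry,
                                         conditions, scan_times, wavelengths,
                                         basis_profiles):
        prot, _ = basis_profiles
        near_copy = ExtinctionProfile(prot.wavelengths, prot.epsilon * 2.0, "copy")
        _, data = make_mwl([(species_table["dimer"], 1e-6)], geometry,
                           conditions, scan_times, wavelengths, basis_profiles)
        with pytest.raises(ValueError, match="separability"):
            spectral_decompose(data, [prot, near_copy])

    def test_off_grid_profiles_rejected(self, species_table, geometry,
                                        conditions, scan_times, wavelengths,
                                        basis_profiles):
        prot, dna = basis_profiles
        other = ExtinctionProfile(np.arange(400.0, 500.0, 2.0),
                                  np.ones(50), "offgrid")
        _, data = make_mwl([(species_table["dimer"], 1e-6)], geometry,
                           conditions, scan_times, wavelengths, basis_profiles)
        with pytest.raises(ValueError, match="grid"):
            spectral_decompose(data, [prot, other])

    def test_recomposition_reproduces_input(self, species_table, geometry,
                                            conditions, scan_times,
                                            wavelengths, basis_profiles):
        _, data = make_mwl(
            [(species_table["complex3"], 3e-7)], geometry, conditions,
            scan_times, wavelengths, basis_profiles, noise=0.003, seed=2)
        comps = spectral_decompose(data, list(basis_profiles))
        rebuilt = recompose(comps, list(basis_profiles), data.pathlength)
        rms = np.sqrt(np.mean((rebuilt - data.absorbance) ** 2))
        assert rms < 1.5 * 0.003  # within the injected noise floor

    def test_recovery_degrades_as_profiles_collapse(
            self, species_table, geometry, conditions, scan_times, wavelengths):
        """Conditioning sweep: smaller vector angle -> larger recovery error."""
        wl = np.asarray(wavelengths)
        base = np.exp(-0.5 * ((wl - 260.0) / 18.0) ** 2)
        errors = []
        for shift in (40.0, 20.0, 8.0):  # decreasing spectral separation
            other = np.exp(-0.5 * ((wl - 260.0 - shift) / 18.0) ** 2)
            prot = ExtinctionProfile(wl, 1.4e4 * other, "protein")
            dna = ExtinctionProfile(wl, 5.6e5 * base, "dna")
            fields, data = make_mwl(
                [(species_table["complex1"], 5e-7)], geometry, conditions,
                scan_times, wl, (prot, dna), noise=0.005, seed=4)
            comps = {c.component_label: c
                     for c in spectral_decompose(data, [prot, dna],
                                                 min_angle_deg=1.0)}
            truth = fields.fields["complex1"]
            errors.append(np.sqrt(np.mean((comps["dna"].conc - truth) ** 2))
                          / truth.max())
        assert errors[0] < errors[1] < errors[2]


class TestComponentDistributions:
    def test_complex_components_comigrate(self, species_table, geometry,
                                          conditions, scan_times, wavelengths,
                                          basis_profiles, s_grid):
        _, data = make_mwl([(species_table["complex3"], 4e-7)], geometry,
                           conditions, scan_times, wavelengths, basis_profiles)
        comps = spectral_decompose(data, list(basis_profiles))
        dists = component_distributions(
            comps, vbar_by_component={"protein": 0.7295, "dna": 0.55},
            s_grid=s_grid, conditions=conditions)
        assert dists["protein"].peak_s() == pytest.approx(
            dists["dna"].peak_s(), rel=0.05)

    def test_free_protein_only_gives_empty_dna_distribution(
            self, species_table, geometry, conditions, scan_times,
            wavelengths, basis_profiles, s_grid):
        _, data = make_mwl([(species_table["dimer"], 1e-6)], geometry,
                           conditions, scan_times, wavelengths, basis_profiles)
        comps = spectral_decompose(data, list(basis_profiles))
        dists = component_distributions(
            comps, vbar_by_component={"protein": 0.7295, "dna": 0.55},
            s_grid=s_grid, conditions=conditions)
        assert dists["dna"].total() < 1e-3 * dists["protein"].total()

    def test_protein_conservation_at_snr50(self, species_table, geometry,
                                           conditions, scan_times, wavelengths,
                                           basis_profiles, s_grid):
        loading = 4e-7
        _, data = make_mwl([(species_table["complex3"], loading)], geometry,
                           conditions, scan_times, wavelengths, basis_profiles,
                           noise=0.01, seed=6)
        comps = spectral_decompose(data, list(basis_profiles))
        dists = component_distributions(
            comps, vbar_by_component={"protein": 0.7295, "dna": 0.55},
            s_grid=s_grid, conditions=conditions)
        assert dists["protein"].total() == pytest.approx(6 * loading, rel=0.03)


class TestStoichiometry:
    def make_dists(self, ratio, s_peak=8.31):
        g = np.linspace(1.0, 12.0, 111)
        peak = np.exp(-0.5 * ((g - s_peak) / 0.2) ** 2)
        dna = ap.SedimentationDistribution(g, peak, "molar", "dna")
        prot = ap.SedimentationDistribution(g, ratio * peak, "molar", "protein")
        return prot, dna

    def test_zero_protein_gives_zero_ratio(self):
        prot, dna = self.make_dists(0.0)
        res = stoichiometry_from_peaks(prot, dna, (7.5, 9.25), 29_500.0,
                                       21_500.0, 0.7295, 0.55)
        assert res.molar_ratio == 0.0
        assert res.inferred_dimers_per_duplex == 0

    def test_three_dimer_complex_mass(self):
        prot, dna = self.make_dists(6.0)
        res = stoichiometry_from_peaks(prot, dna, (7.5, 9.25), 29_500.0,
                                       21_500.0, 0.7295, 0.55)
        assert res.inferred_dimers_per_duplex == 3
        assert res.complex_mass_calc == pytest.approx(3 * 59_000 + 21_500)
        assert res.vbar_avg == pytest.approx(0.7101, abs=5e-5)

    def test_empty_dna_window_rejected(self):
        prot, dna = self.make_dists(2.0, s_peak=3.0)
        with pytest.raises(ValueError, match="ratio undefined"):
            stoichiometry_from_peaks(prot, dna, (7.5, 9.25), 29_500.0,
                                     21_500.0, 0.7295, 0.55)

    @pytest.mark.parametrize("name,n_dimers", [("complex1", 1),
                                               ("complex2", 2),
                                               ("complex3", 3)])
    def test_closed_loop_ratio_recovery(self, name, n_dimers, species_table,
                                        geometry, conditions, scan_times,
                                        wavelengths, basis_profiles, s_grid):
        """MWL round trip: pure complex fixtures give 2/4/6 monomers per duplex."""
        _, data = make_mwl([(species_table[name], 5e-7)], geometry, conditions,
                           scan_times, wavelengths, basis_profiles,
                           noise=0.01, seed=13)
        comps = spectral_decompose(data, list(basis_profiles))
        dists = component_distributions(
            comps, vbar_by_component={"protein": 0.7295, "dna": 0.55},
            s_grid=s_grid, conditions=conditions)
        res = stoichiometry_from_peaks(dists["protein"], dists["dna"],
                                       OPERATOR_WINDOWS[name], 29_500.0,
                                       21_500.0, 0.7295, 0.55)
        assert res.molar_ratio == pytest.approx(2 * n_dimers, rel=0.10)
        assert res.inferred_dimers_per_duplex == n_dimers


class TestComplexMassFromSv:
    def test_generator_complex3_self_consistency(self, conditions):
        from aucplex.hydro import svedberg_diffusion
        D = svedberg_diffusion(8.31, 198_500.0, 0.7101, conditions)
        mass, flag = complex_mass_from_sv(8.31, D, 0.7101, conditions,
                                          calculated_mass=198_500.0)
        assert mass == pytest.approx(198_500.0, rel=0.01)
        assert not flag

    def test_protein_only_vbar_biases_high_and_flags(self, conditions):
        from aucplex.hydro import svedberg_diffusion
        D = svedberg_diffusion(8.31, 198_500.0, 0.7101, conditions)
        mass, flag = complex_mass_from_sv(8.31, D, 0.7295, conditions,
                                          calculated_mass=198_500.0,
                                          disagreement_tol=0.05)
        assert mass > 198_500.0
        assert flag

    def test_mass_inverse_in_diffusion(self, conditions):
        m1, _ = complex_mass_from_sv(8.31, 3e-7, 0.7101, conditions)
        m2, _ = complex_mass_from_sv(8.31, 6e-7, 0.7101, conditions)
        assert m1 == pytest.approx(2.0 * m2, rel=1e-12)
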