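"""End-to-end pipeline: simulate -> deconvolute -> stoichiometry -> isotherm -> fits.

The pipeline reproduces the full analysis chain on synthetic data: a
multiwavelength run of an equilibrated protein/DNA binding ladder is
deconvoluted into molar protein and DNA sedimentation distributions and
integrated into stoichiometries; a fluorescence-detected titration of
labeled DNA is inverted into a binding isotherm and fitted with the Hill
and non-cooperative models.  Everything is driven by one YAML-style config
with a single mandatory seed; reruns with the same config are deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import (BindingIsotherm, bootstrap_ci, compare_models,
                      isotherm_from_titration)
from .hydro import SolutionConditions
from .io import (packaged_operator_duplex, packaged_protein_sequence,
                 write_isotherm_csv, write_mwl, write_profile_csv,
                 write_scan_csv)
from .mwl import (OPERATOR_WINDOWS, component_distributions,
                  spectral_decompose, stoichiometry_from_peaks)
from .spectra import (dna_duplex_extinction_260, dna_duplex_mass,
                      protein_extinction_280)
from .sv import cs_inversion, default_s_grid
from .synthetic import (BindingLadderModel, CellGeometry, InstrumentSetup,
                        default_species_table, equilibrium_ladder,
                        simulate_lamm, synthesize_fluorescence_titration,
                        synthesize_mwl, synthetic_basis_profiles)

logger = logging.getLogger("aucplex")

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]


_ALLOWED_KEYS = {
    "seed", "rotor_speed_rpm", "scan_times_s", "radial_step_cm",
    "meniscus_cm", "bottom_cm", "pathlength_cm",
    "density_g_ml", "viscosity_mpas", "temperature_K",
    "noise_sigma", "wavelength_min_nm", "wavelength_max_nm", "wavelength_step_nm",
    "K1_per_M", "K2_per_M", "K3_per_M",
    "mwl_protein_dimer_uM", "mwl_dna_duplex_uM",
    "titration_max_nM", "titration_points", "titration_dna_nM",
    "titration_noise_sigma", "s_grid_min", "s_grid_max", "s_grid_points",
    "bootstrap_reps", "plots",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected, seed mandatory)."""

    seed: int
    rotor_speed_rpm: float = 50_000.0
    scan_times_s: list = dc_field(default_factory=lambda: list(np.arange(600.0, 6600.0, 600.0)))
    radial_step_cm: float = 0.004
    meniscus_cm: float = 5.9
    bottom_cm: float = 7.2
    pathlength_cm: float = 1.2
    density_g_ml: float = 0.99823
    viscosity_mpas: float = 1.002
    temperature_K: float = 293.15
    noise_sigma: float = 0.005
    wavelength_min_nm: float = 220.0
    wavelength_max_nm: float = 300.0
    wavelength_step_nm: float = 2.0
    # cooperative stepwise ladder constants (1/M)
    K1_per_M: float = 1.0e7
    K2_per_M: float = 4.0e7
    K3_per_M: float = 1.6e8
    mwl_protein_dimer_uM: float = 3.0
    mwl_dna_duplex_uM: float = 0.5
    titration_max_nM: float = 794.0
    titration_points: int = 11
    titration_dna_nM: float = 80.0
    titration_noise_sigma: float = 0.5
    s_grid_min: float = 0.5
    s_grid_max: float = 15.0
    s_grid_points: int = 100
    bootstrap_reps: int = 200
    plots: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages are enabled)")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def geometry(self) -> CellGeometry:
        return CellGeometry(self.meniscus_cm, self.bottom_cm, self.pathlength_cm)

    def conditions(self) -> SolutionConditions:
        return SolutionConditions(self.density_g_ml, self.viscosity_mpas,
                                  self.temperature_K)

    def wavelengths(self) -> tuple:
        return tuple(np.arange(self.wavelength_min_nm,
                               self.wavelength_max_nm + 0.5 * self.wavelength_step_nm,
                               self.wavelength_step_nm))

    def s_grid(self):
        return default_s_grid(self.s_grid_min, self.s_grid_max, self.s_grid_points)


def default_config(seed: int = 1, **overrides) -> PipelineConfig:
    return PipelineConfig.from_dict({"seed": seed, **overrides})


def _stage(report, name):
    logger.info("stage %s ...", name)
    report["stages"].append({"name": name, "t_start": time.time()})
    return name


def _stage_done(report):
    entry = report["stages"][-1]
    entry["elapsed_s"] = round(time.time() - entry.pop("t_start"), 3)
    logger.info("stage %s done in %.1f s", entry["name"], entry["elapsed_s"])


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic analysis chain; returns the report dict.

    Writes distribution/isotherm CSVs, the simulated MWL dataset, and
    ``report.json`` into ``out_dir``.  Deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry, conditions = config.geometry(), config.conditions()
    species = default_species_table(conditions)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                               for k, v in vars(config).items()},
                    "stages": []}
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_mwl = int(seeds[0].generate_state(1)[0] % (2**31))
    seed_titr = int(seeds[1].generate_state(1)[0] % (2**31))
    seed_boot = int(seeds[2].generate_state(1)[0] % (2**31))

    # --- spectra -----------------------------------------------------------
    _stage(report, "spectra")
    protein_seq = packaged_protein_sequence()
    top, bottom = packaged_operator_duplex()
    eps280 = protein_extinction_280(protein_seq)
    eps260 = dna_duplex_extinction_260(top, bottom)
    duplex_mass = dna_duplex_mass(top, bottom)
    wavelengths = config.wavelengths()
    prot_profile, dna_profile = synthetic_basis_profiles(wavelengths, eps280, eps260)
    # per-monomer basis for stoichiometry in monomer units
    write_profile_csv(prot_profile, out / "profile_protein.csv")
    write_profile_csv(dna_profile, out / "profile_dna.csv")
    from .spectra import vector_angle
    report["spectra"] = {"eps280_protein": eps280, "eps260_duplex": eps260,
                         "duplex_mass_Da": duplex_mass,
                         "vector_angle_deg": vector_angle(prot_profile, dna_profile)}
    _stage_done(report)

    # --- multiwavelength run ----------------------------------------------
    _stage(report, "mwl_simulation")
    ladder = BindingLadderModel(config.K1_per_M, config.K2_per_M, config.K3_per_M,
                                config.mwl_protein_dimer_uM * 1e-6,
                                config.mwl_dna_duplex_uM * 1e-6)
    conc = equilibrium_ladder(ladder)
    loadings = [(species["dna"], conc["free_duplex"]),
                (species["dimer"], conc["free_dimer"]),
                (species["complex1"], conc["complex1"]),
                (species["complex2"], conc["complex2"]),
                (species["complex3"], conc["complex3"])]
    setup_mwl = InstrumentSetup(rotor_speed=config.rotor_speed_rpm,
                                scan_times=tuple(config.scan_times_s),
                                radial_step=config.radial_step_cm,
                                wavelength_grid=wavelengths,
                                noise_sigma=config.noise_sigma, seed=seed_mwl)
    fields = simulate_lamm(loadings, geometry, setup_mwl, conditions)
    mwl_data = synthesize_mwl(fields, prot_profile, dna_profile)
    write_mwl(mwl_data, out / "mwl")
    report["mwl_simulation"] = {"equilibrium_M": conc, "seed": seed_mwl}
    _stage_done(report)

    # --- deconvolution and stoichiometry -----------------------------------
    _stage(report, "deconvolution")
    components = spectral_decompose(mwl_data, [prot_profile, dna_profile])
    dists = component_distributions(
        components,
        vbar_by_component={"protein": 0.7295, "dna": 0.55},
        s_grid=config.s_grid(), conditions=conditions)
    for label, dist in dists.items():
        np.savetxt(out / f"distribution_{label}.csv",
                   np.column_stack([dist.s_grid, dist.amplitude]),
                   delimiter=",", header="s_S,amplitude", comments="")
    stoich = {}
    for name, window in OPERATOR_WINDOWS.items():
        try:
            res = stoichiometry_from_peaks(
                dists["protein"], dists["dna"], window,
                monomer_mass=species["dimer"].molar_mass / 2.0,
                duplex_mass=species["dna"].molar_mass,
                vbar_protein=0.7295, vbar_dna=0.55)
        except ValueError:
            continue
        stoich[name] = {"s_range_S": list(window),
                        "molar_ratio_monomers_per_duplex": res.molar_ratio,
                        "inferred_dimers": res.inferred_dimers_per_duplex,
                        "vbar_avg_ml_g": res.vbar_avg,
                        "complex_mass_calc_Da": res.complex_mass_calc}
    report["stoichiometry"] = stoich
    _stage_done(report)

    # --- fluorescence titration and binding analysis ------------------------
    _stage(report, "titration")
    concs_nM = config.titration_max_nM / (2.0 ** np.arange(config.titration_points))
    ladders = [BindingLadderModel(config.K1_per_M, config.K2_per_M, config.K3_per_M,
                                  c * 1e-9, config.titration_dna_nM * 1e-9)
               for c in concs_nM]
    setup_fl = InstrumentSetup(rotor_speed=config.rotor_speed_rpm,
                               scan_times=tuple(config.scan_times_s),
                               radial_step=config.radial_step_cm,
                               noise_sigma=config.titration_noise_sigma,
                               seed=seed_titr)
    scans, truths = synthesize_fluorescence_titration(
        ladders, species, geometry, setup_fl, conditions)
    for scanset, c in zip(scans, concs_nM):
        write_scan_csv(scanset, out / f"titration_{c:09.3f}nM.csv")
    dist_by_conc = {}
    for scanset, c in zip(scans, concs_nM):
        # labeled-DNA species (duplex and its complexes) are elongated: f/f0 ~ 1.6
        dist_by_conc[c * 1e-9] = cs_inversion(
            scanset, s_grid=config.s_grid(), vbar=0.6, frictional_ratio=1.6,
            conditions=conditions)
    iso = isotherm_from_titration(dist_by_conc)
    write_isotherm_csv(iso, out / "isotherm.csv")
    _stage_done(report)

    _stage(report, "binding_fits")
    comparison = compare_models(iso)
    hill = comparison.fits["hill"]
    boot = bootstrap_ci(hill, iso, n_reps=max(100, config.bootstrap_reps),
                        seed=seed_boot)
    report["binding"] = {
        "K_D_M": hill.K_D, "hill_n": hill.n,
        "K_D_sd_M": boot.sd_K, "hill_n_sd": boot.sd_n,
        "aic": comparison.aic,
        "akaike_weights_percent": comparison.weights_percent,
        "best_model": comparison.best_model,
        "bootstrap_seed": seed_boot,
        "truth_occupancy": [
            {"total_dimer_M": lad.total_protein_dimer,
             "theta": (t["complex1"] + t["complex2"] + t["complex3"])
                      / lad.total_dna_duplex}
            for lad, t in zip(ladders, truths)],
    }
    _stage_done(report)

    if config.plots:
        _make_plots(out, dists, iso, hill)

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("report written to %s", report_path)
    return report


def _make_plots(out: Path, dists, iso: BindingIsotherm, hill) -> None:
    """Optional diagnostic plots (never load-bearing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for label, dist in dists.items():
        ax.plot(dist.s_grid, dist.amplitude, label=label)
    ax.set_xlabel("s (S)")
    ax.set_ylabel("molar amplitude / S")
    ax.legend()
    fig.savefig(out / "distributions.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.semilogx(iso.concentrations, iso.theta, "ko", label="isotherm")
    grid = np.geomspace(iso.concentrations[0], iso.concentrations[-1], 200)
    ax.semilogx(grid, hill.predict(grid), "b-",
                label=f"Hill fit (K_D={hill.K_D*1e9:.1f} nM, n={hill.n:.2f})")
    ax.set_xlabel("total dimer (M)")
    ax.set_ylabel("fraction bound")
    ax.legend()
    fig.savefig(out / "isotherm.png", dpi=120)
    plt.close(fig)
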