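"""Shared fixtures: solution conditions, cell, scan schedules and profiles.

Session scope is used for everything deterministic so that the Lamm-kernel
cache is shared across tests (identical scan schedules reuse kernels).
"""

import numpy as np
import pytest

import aucplex as ap
from aucplex.synthetic import default_species_table, synthetic_basis_profiles


@pytest.fixture(scope="session")
def conditions():
    return ap.SolutionConditions()


@pytest.fixture(scope="session")
def geometry():
    return ap.CellGeometry()


@pytest.fixture(scope="session")
def species_table(conditions):
    return default_species_table(conditions)


@pytest.fixture(scope="session")
def scan_times():
    """10 scans over 600-6000 s at 50,000 rpm (fast species still in column)."""
    return tuple(np.arange(600.0, 6001.0, 600.0))


@pytest.fixture(scope="session")
def titration_times():
    """Longer schedule (18 scans to 10,800 s) for resolving slow free DNA."""
    return tuple(np.arange(600.0, 10801.0, 600.0))


@pytest.fixture(scope="session")
def s_grid():
    return ap.default_s_grid(0.5, 15.0, 80)


@pytest.fixture(scope="session")
def wavelengths():
    return tuple(np.arange(220.0, 301.0, 2.0))


@pytest.fixture(scope="session")
def basis_profiles(wavelengths):
    """Protein (per monomer) and DNA (per duplex) extinction basis spectra."""
    from aucplex.io import packaged_operator_duplex, packaged_protein_sequence
    from aucplex.spectra import dna_duplex_extinction_260, protein_extinction_280
    eps280 = protein_extinction_280(packaged_protein_sequence())
    eps260 = dna_duplex_extinction_260(*packaged_operator_duplex())
    return synthetic_basis_profiles(wavelengths, eps280, eps260)


def scan_metadata(geometry, conditions, rpm=50_000.0):
    return {"rpm": rpm, "meniscus_cm": geometry.meniscus_radius,
            "bottom_cm": geometry.bottom_radius,
            "pathlength_cm": geometry.pathlength,
            "temperature_K": conditions.temperature}


@pytest.fixture(scope="session")
def closure_species(conditions):
    """Two species whose D follows the c(s) closure (f/f0 = 1.25, vbar 0.7295).

    Round-trip inversions of these species are exact up to discretization:
    the kernel dictionary contains their transport model.
    """
    from aucplex.hydro import mass_from_s_ff0, svedberg_diffusion
    out = []
    for name, s in (("slow", 3.0), ("fast", 3.7)):
        M = mass_from_s_ff0(s, 1.25, 0.7295, conditions)
        D = svedberg_diffusion(s, M, 0.7295, conditions)
        out.append(ap.HydroSpecies(name, M, 0.7295, s, D))
    return out
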