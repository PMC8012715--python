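"""Synthetic sedimentation-velocity data generation.

Generates physically consistent single- and multiwavelength
sedimentation-velocity datasets from a mass-action protein/DNA binding
ladder: a repressor dimer P binds a DNA duplex O in up to three stepwise
equilibria (O + P <-> OP, OP + P <-> OP2, OP2 + P <-> OP3).  The ladder is
equilibrated once at t = 0 and the resulting species sediment independently
(non-interconverting approximation); each species field obeys the Lamm
equation in sector geometry, solved by a conservative Crank-Nicolson finite
volume scheme with Scharfetter-Gummel (exponentially fitted) advection, so
total material is conserved to solver roundoff and steep low-diffusion
boundaries remain positive.

Signals are composed from the species fields: multiwavelength absorbance via
per-species extinction spectra built from the protein/DNA basis profiles,
and fluorescence-detected titrations in which only duplex-containing species
carry signal (a 5'-label on the DNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .hydro import (HydroSpecies, SolutionConditions, SVEDBERG,
                    weight_average_vbar)
from .spectra import ExtinctionProfile

__all__ = [
    "CellGeometry", "InstrumentSetup", "BindingLadderModel",
    "SpeciesFields", "MWLDataset", "SVScanSet",
    "equilibrium_ladder", "ladder_occupancy", "simulate_lamm",
    "synthesize_mwl", "synthesize_fluorescence_titration",
    "default_species_table", "NANR_DIMER_S", "DNA_DUPLEX_S",
]

# Fixture hydrodynamic parameters for the repressor/operator system
# (s in S, M in Da, vbar in mL/g).  Complex s-values for complexes 1 and 2
# are the midpoints of the 4.0-5.0 and 6-7.25 S integration windows.
DNA_DUPLEX_S = 3.0
NANR_DIMER_S = 3.70
PROTEIN_VBAR = 0.7295
DNA_VBAR = 0.55
NANR_DIMER_MASS = 59_000.0
DNA_DUPLEX_MASS = 21_500.0


# ---------------------------------------------------------------------------
# Instrument and cell description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Standard double-sector cell: solution column and optical pathlength."""

    meniscus_radius: float = 5.9    # cm
    bottom_radius: float = 7.2      # cm
    pathlength: float = 1.2         # cm
    sector_angle: float = 0.0436    # rad (2.5 degree sector)

    def __post_init__(self):
        if not (0 < self.meniscus_radius < self.bottom_radius):
            raise ValueError("need 0 < meniscus_radius < bottom_radius")
        if self.pathlength <= 0 or self.sector_angle <= 0:
            raise ValueError("pathlength and sector_angle must be positive")


@dataclass(frozen=True)
class InstrumentSetup:
    """Rotor speed, scan schedule, radial/wavelength sampling and noise.

    ``noise_sigma`` is i.i.d. Gaussian noise per datum in signal units;
    ``ti_noise`` (function of radius) and ``ri_noise`` (function of scan)
    are optional systematic offset vectors.  ``seed`` drives every random
    draw made from this setup.
    """

    rotor_speed: float = 50_000.0            # rpm
    scan_times: tuple = (0.0,)               # s, strictly increasing
    radial_step: float = 0.0026              # cm (~500 points over 1.3 cm)
    wavelength_grid: tuple | None = None     # nm, strictly increasing
    noise_sigma: float = 0.0                 # signal units
    ti_noise: tuple | None = None            # per-radius offset
    ri_noise: tuple | None = None            # per-scan offset
    seed: int = 0

    def __post_init__(self):
        if self.rotor_speed < 0:
            raise ValueError("rotor_speed must be >= 0")
        times = np.asarray(self.scan_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
            raise ValueError("scan_times must be non-empty, non-negative, strictly increasing")
        if self.radial_step <= 0:
            raise ValueError("radial_step must be positive")
        if self.wavelength_grid is not None:
            wl = np.asarray(self.wavelength_grid, dtype=float)
            if wl.size == 0 or np.any(np.diff(wl) <= 0):
                raise ValueError("wavelength_grid must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "scan_times", tuple(float(t) for t in times))

    @property
    def omega(self) -> float:
        """Angular velocity, rad/s."""
        return self.rotor_speed * 2.0 * np.pi / 60.0


def default_species_table(conditions: SolutionConditions = SolutionConditions()
                          ) -> dict[str, HydroSpecies]:
    """Fixture species ladder: free DNA, free dimer, and the 1:1/2:1/3:1 complexes.

    Complex vbar is the weight average of its protein and DNA parts; D comes
    from the Svedberg relation at the given conditions.
    """
    def complex_species(name, n_dimers, s):
        m_pro = n_dimers * NANR_DIMER_MASS
        mass = m_pro + DNA_DUPLEX_MASS
        vbar = weight_average_vbar(m_pro, PROTEIN_VBAR, DNA_DUPLEX_MASS, DNA_VBAR)
        return HydroSpecies(name, mass, vbar, s, composition=(2 * n_dimers, 1))

    table = {
        "dna": HydroSpecies("dna", DNA_DUPLEX_MASS, DNA_VBAR, DNA_DUPLEX_S,
                            composition=(0, 1)),
        "dimer": HydroSpecies("dimer", NANR_DIMER_MASS, PROTEIN_VBAR, NANR_DIMER_S,
                              composition=(2, 0)),
        "complex1": complex_species("complex1", 1, 4.5),
        "complex2": complex_species("complex2", 2, 6.6),
        "complex3": complex_species("complex3", 3, 8.31),
    }
    return {k: v.with_consistent_D(conditions) for k, v in table.items()}


# ---------------------------------------------------------------------------
# Mass-action binding ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingLadderModel:
    """Stepwise dimer-binding ladder O + nP with association constants K1..K3 (1/M)."""

    K1: float
    K2: float
    K3: float
    total_protein_dimer: float  # M
    total_dna_duplex: float     # M

    def __post_init__(self):
        if min(self.K1, self.K2, self.K3) < 0:
            raise ValueError("association constants must be >= 0")
        if self.total_protein_dimer < 0 or self.total_dna_duplex < 0:
            raise ValueError("total concentrations must be >= 0")


def equilibrium_ladder(model: BindingLadderModel) -> dict[str, float]:
    """Equilibrium species concentrations (M) of the binding ladder.

    Solves the mass balances by root-finding on the free-dimer concentration
    p (the bound-protein function is monotone in p):

        d(p) = Dtot / (1 + K1 p + K1 K2 p^2 + K1 K2 K3 p^3)
        p + d(p) (K1 p + 2 K1 K2 p^2 + 3 K1 K2 K3 p^3) = Ptot

    Returns keys free_dimer, free_duplex, complex1, complex2, complex3.
    """
    K1, K2, K3 = model.K1, model.K2, model.K3
    ptot, dtot = model.total_protein_dimer, model.total_dna_duplex
    b1, b2, b3 = K1, K1 * K2, K1 * K2 * K3  # cumulative association constants

    def free_duplex(p):
        return dtot / (1.0 + b1 * p + b2 * p * p + b3 * p ** 3)

    def balance(p):
        d = free_duplex(p)
        return p + d * (b1 * p + 2.0 * b2 * p * p + 3.0 * b3 * p ** 3) - ptot

    if ptot == 0.0:
        p = 0.0
    else:
        try:
            p = brentq(balance, 0.0, ptot, xtol=1e-30, rtol=1e-15, maxiter=200)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"equilibrium ladder failed to converge for K=({K1:g},{K2:g},{K3:g}) "
                f"1/M, totals P={ptot:g} M, O={dtot:g} M") from exc
    d = free_duplex(p)
    out = {
        "free_dimer": p,
        "free_duplex": d,
        "complex1": b1 * p * d,
        "complex2": b2 * p * p * d,
        "complex3": b3 * p ** 3 * d,
    }
    # exact mass-balance audit
    p_tot = out["free_dimer"] + out["complex1"] + 2 * out["complex2"] + 3 * out["complex3"]
    d_tot = out["free_duplex"] + out["complex1"] + out["complex2"] + out["complex3"]
    scale_p = max(ptot, 1e-300)
    scale_d = max(dtot, 1e-300)
    if abs(p_tot - ptot) > 1e-9 * scale_p or abs(d_tot - dtot) > 1e-9 * scale_d:
        raise RuntimeError("equilibrium ladder violates mass balance beyond 1e-9 relative")
    return out


def ladder_occupancy(species_conc: Mapping[str, float]) -> float:
    """Fraction of duplex bound by at least one dimer."""
    bound = (species_conc["complex1"] + species_conc["complex2"]
             + species_conc["complex3"])
    total = bound + species_conc["free_duplex"]
    if total == 0:
        raise ValueError("no duplex present; occupancy undefined")
    return bound / total


# ---------------------------------------------------------------------------
# Lamm-equation solver
# ---------------------------------------------------------------------------

def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), numerically safe (B(0)=1, B(inf)=0)."""
    x = np.clip(x, -500.0, 500.0)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = x[nz] / np.expm1(x[nz])
    return out


def _lamm_operator(radii_faces, radii_centers, dr, s_cgs, D, omega2):
    """Tridiagonal transport operator dc/dt = L c for one species.

    Finite-volume, sector geometry (cell measure r dr), Scharfetter-Gummel
    face fluxes, zero flux through meniscus and bottom.
    Returns (lower, diag, upper) of L.
    """
    n = radii_centers.size
    v = s_cgs * omega2 * radii_faces[1:-1]  # interior face velocities, cm/s
    if D > 0:
        pe = v * dr / D
        a_left = (D / dr) * _bernoulli(-pe)   # multiplies left cell
        a_right = (D / dr) * _bernoulli(pe)   # multiplies right cell
    else:
        a_left = np.maximum(v, 0.0)
        a_right = np.maximum(-v, 0.0)
    rf = radii_faces[1:-1]
    # flux through interior face j (between cells j and j+1), times r_face
    # Phi_j = rf_j * (a_left_j * c_j - a_right_j * c_{j+1})
    lower = np.zeros(n)   # L[i, i-1]
    diag = np.zeros(n)
    upper = np.zeros(n)   # L[i, i+1]
    w = radii_centers * dr
    # outflow/inflow bookkeeping per cell
    diag[:-1] -= rf * a_left / w[:-1]
    upper[:-1] += rf * a_right / w[:-1]
    diag[1:] -= rf * a_right / w[1:]
    lower[1:] += rf * a_left / w[1:]
    return lower, diag, upper


@dataclass
class SpeciesFields:
    """Per-species molar concentration fields c_k(r, t) from one simulation."""

    radii: np.ndarray                      # cm, cell centers
    times: np.ndarray                      # s
    species: list[HydroSpecies]
    loadings: np.ndarray                   # M, per species
    fields: dict[str, np.ndarray]          # name -> (n_t, n_r), M
    geometry: CellGeometry
    setup: InstrumentSetup
    conditions: SolutionConditions

    def total_signal(self, weights: Mapping[str, float]) -> np.ndarray:
        """Weighted sum of species fields (n_t, n_r)."""
        out = np.zeros((self.times.size, self.radii.size))
        for name, wgt in weights.items():
            if wgt != 0.0:
                out += wgt * self.fields[name]
        return out


def simulate_lamm(species: Sequence[tuple[HydroSpecies, float]],
                  geometry: CellGeometry = CellGeometry(),
                  setup: InstrumentSetup = InstrumentSetup(),
                  conditions: SolutionConditions = SolutionConditions(),
                  courant: float = 0.5,
                  dt: float | None = None) -> SpeciesFields:
    """Sediment each (species, loading) pair independently in sector geometry.

    Crank-Nicolson in time with uniform sub-steps per scan interval chosen so
    the advective Courant number stays below ``courant``; Scharfetter-Gummel
    faces keep the scheme positive at arbitrarily large cell Peclet number.
    The sector-weighted integral of each species field is conserved to solver
    roundoff (reflective ends).
    """
    m, b = geometry.meniscus_radius, geometry.bottom_radius
    n_r = int(round((b - m) / setup.radial_step))
    if n_r < 20:
        raise ValueError(
            f"radial_step {setup.radial_step} cm gives only {n_r} cells over the "
            f"{b - m:.3f} cm column; use radial_step <= {(b - m) / 20:.4f}")
    dr = (b - m) / n_r
    faces = m + dr * np.arange(n_r + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    times = np.asarray(setup.scan_times, dtype=float)
    omega2 = setup.omega ** 2

    fields: dict[str, np.ndarray] = {}
    specs, loadings = [], []
    for spec, loading in species:
        if loading < 0:
            raise ValueError(f"{spec.name}: negative loading concentration")
        spec = spec.with_consistent_D(conditions) if spec.D is None else spec
        if spec.s <= 0 and (spec.D is None or spec.D <= 0):
            raise ValueError(f"{spec.name}: needs s > 0 or D > 0")
        specs.append(spec)
        loadings.append(loading)
        D = spec.D if spec.D is not None else 0.0
        s_cgs = spec.s * SVEDBERG
        v_max = abs(s_cgs) * omega2 * b
        dt_courant = courant * dr / v_max if v_max > 0 else np.inf
        if dt is not None:
            if v_max > 0 and dt > 4.0 * dr / v_max:
                raise ValueError(
                    f"{spec.name}: time step {dt:g} s is unstable for this grid; "
                    f"use dt <= {4.0 * dr / v_max:.1f} s or a coarser radial_step")
            dt_courant = min(dt_courant, dt)

        lower, diag, upper = _lamm_operator(faces, centers, dr, s_cgs, D, omega2)
        c = np.full(n_r, 1.0)  # unit loading; PDE is linear, scale at the end
        out = np.empty((times.size, n_r))
        t_now = 0.0
        i_rec = 0
        if times[0] == 0.0:
            out[0] = c
            i_rec = 1
        for t_target in times[i_rec:]:
            interval = t_target - t_now
            n_sub = max(1, int(np.ceil(interval / min(dt_courant, interval))))
            h = interval / n_sub
            # theta = 1/2 (Crank-Nicolson) banded matrices for this step size
            ab_lhs = np.zeros((3, n_r))
            ab_lhs[0, 1:] = -0.5 * h * upper[:-1]
            ab_lhs[1] = 1.0 - 0.5 * h * diag
            ab_lhs[2, :-1] = -0.5 * h * lower[1:]
            for _ in range(n_sub):
                rhs = c + 0.5 * h * (diag * c)
                rhs[:-1] += 0.5 * h * upper[:-1] * c[1:]
                rhs[1:] += 0.5 * h * lower[1:] * c[:-1]
                c = solve_banded((1, 1), ab_lhs, rhs)
            t_now = t_target
            out[i_rec] = c
            i_rec += 1
        np.clip(out, 0.0, None, out=out)
        fields[spec.name] = out * loading

    return SpeciesFields(centers, times, specs, np.asarray(loadings, float),
                         fields, geometry, setup, conditions)


def sector_mass(radii: np.ndarray, profile: np.ndarray) -> float:
    """Sector-weighted amount, integral of c r dr (per unit sector angle/path)."""
    return float(np.sum(profile * radii) * (radii[1] - radii[0]))


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

@dataclass
class MWLDataset:
    """Multiwavelength absorbance A(lambda, t, r) plus acquisition metadata."""

    wavelengths: np.ndarray           # nm
    times: np.ndarray                 # s
    radii: np.ndarray                 # cm
    absorbance: np.ndarray            # (n_wl, n_t, n_r)
    pathlength: float
    metadata: dict = field(default_factory=dict)


@dataclass
class SVScanSet:
    """Radial signal scans over time at a single detection channel."""

    radii: np.ndarray
    times: np.ndarray
    signal: np.ndarray                # (n_t, n_r)
    metadata: dict = field(default_factory=dict)


def species_extinction(spec: HydroSpecies, protein_profile: ExtinctionProfile,
                       dna_profile: ExtinctionProfile) -> np.ndarray:
    """Species spectrum from composition: n_monomers*eps_protein + n_duplex*eps_dna.

    The protein basis profile is per monomer.
    """
    n_pro, n_dna = spec.composition
    return n_pro * protein_profile.epsilon + n_dna * dna_profile.epsilon


def synthesize_mwl(fields: SpeciesFields, protein_profile: ExtinctionProfile,
                   dna_profile: ExtinctionProfile) -> MWLDataset:
    """Compose multiwavelength absorbance data from species fields.

    A(lambda, t, r) = pathlength * sum_k eps_k(lambda) c_k(t, r), plus
    i.i.d. Gaussian noise of ``setup.noise_sigma`` and the optional ti/ri
    systematic offsets; seeded by ``setup.seed`` (bit-reproducible).
    """
    setup = fields.setup
    if setup.wavelength_grid is None:
        raise ValueError("setup.wavelength_grid is required for multiwavelength synthesis")
    wl = np.asarray(setup.wavelength_grid, dtype=float)
    for prof in (protein_profile, dna_profile):
        if prof.wavelengths.shape != wl.shape or not np.allclose(prof.wavelengths, wl):
            raise ValueError(
                f"profile '{prof.component_label}' wavelength grid does not match setup grid")
    n_t, n_r = fields.times.size, fields.radii.size
    A = np.zeros((wl.size, n_t, n_r))
    for spec in fields.species:
        eps = species_extinction(spec, protein_profile, dna_profile)
        A += eps[:, None, None] * fields.fields[spec.name][None, :, :]
    A *= fields.geometry.pathlength
    rng = np.random.default_rng(setup.seed)
    if setup.noise_sigma > 0:
        A = A + rng.normal(0.0, setup.noise_sigma, size=A.shape)
    if setup.ti_noise is not None:
        ti = np.asarray(setup.ti_noise, dtype=float)
        if ti.size != n_r:
            raise ValueError(f"ti_noise length {ti.size} != {n_r} radii")
        A = A + ti[None, None, :]
    if setup.ri_noise is not None:
        ri = np.asarray(setup.ri_noise, dtype=float)
        if ri.size != n_t:
            raise ValueError(f"ri_noise length {ri.size} != {n_t} scans")
        A = A + ri[None, :, None]
    meta = {"rpm": setup.rotor_speed, "meniscus_cm": fields.geometry.meniscus_radius,
            "bottom_cm": fields.geometry.bottom_radius,
            "pathlength_cm": fields.geometry.pathlength,
            "temperature_K": fields.conditions.temperature, "seed": setup.seed}
    return MWLDataset(wl, fields.times, fields.radii, A,
                      fields.geometry.pathlength, meta)


def synthetic_basis_profiles(wavelengths: Sequence[float],
                             eps280_protein: float,
                             eps260_dna: float) -> tuple[ExtinctionProfile, ExtinctionProfile]:
    """Smooth synthetic protein and DNA extinction basis spectra.

    Emulates the qualitative shapes over 220-300 nm — an aromatic band near
    278 nm on a strong far-UV rise for protein, the 260 nm base-stacking band
    for DNA — pinned to the given molar coefficients at 280 and 260 nm.
    Gaussian band mixtures, not measured spectra; adequate for exercising
    spectral deconvolution, whose conditioning depends only on the vector
    angle between the two shapes.
    """
    wl = np.asarray(wavelengths, dtype=float)

    def bands(centers_widths_amps):
        return sum(a * np.exp(-0.5 * ((wl - c) / w) ** 2)
                   for c, w, a in centers_widths_amps)

    # pin each shape at its reference wavelength (nearest grid point)
    prot = bands([(278.0, 12.0, 1.0), (222.0, 14.0, 8.0)])
    prot = prot * (eps280_protein / prot[np.argmin(np.abs(wl - 280.0))])
    dna = bands([(258.0, 16.0, 1.0), (205.0, 12.0, 1.6)])
    dna = dna * (eps260_dna / dna[np.argmin(np.abs(wl - 260.0))])
    return (ExtinctionProfile(wl, prot, "protein"),
            ExtinctionProfile(wl, dna, "dna"))


def synthesize_fluorescence_titration(
        ladders: Sequence[BindingLadderModel],
        species_table: Mapping[str, HydroSpecies] | None = None,
        geometry: CellGeometry = CellGeometry(),
        setup: InstrumentSetup = InstrumentSetup(),
        conditions: SolutionConditions = SolutionConditions(),
        signal_per_molar: float = 1e9,
) -> tuple[list[SVScanSet], list[dict[str, float]]]:
    """Simulate a fluorescence-detected titration of labeled duplex.

    Only duplex-containing species carry signal (the label sits on the DNA);
    each contributes ``signal_per_molar`` per molar of duplex.  Each titration
    point gets an independent noise stream spawned from ``setup.seed``.

    Returns the scan sets and the underlying equilibrium species
    concentrations per point (the generator truth).
    """
    if species_table is None:
        species_table = default_species_table(conditions)
    dna_species = {name: sp for name, sp in species_table.items()
                   if sp.composition[1] > 0}
    if not dna_species:
        raise ValueError("species table contains no duplex-bearing species")
    # unit-loading fields per species, reused across titration points (linear PDE)
    unit = simulate_lamm([(sp, 1.0) for sp in dna_species.values()],
                         geometry, setup, conditions)
    # species-table names vs equilibrium-ladder keys
    conc_key = {"dna": "free_duplex", "dimer": "free_dimer"}
    child_seeds = np.random.SeedSequence(setup.seed).spawn(len(ladders))
    scans, truths = [], []
    for ladder, seed_seq in zip(ladders, child_seeds):
        conc = equilibrium_ladder(ladder)
        signal = unit.total_signal(
            {name: conc[conc_key.get(name, name)] * signal_per_molar
             for name in dna_species})
        rng = np.random.default_rng(seed_seq)
        if setup.noise_sigma > 0:
            signal = signal + rng.normal(0.0, setup.noise_sigma, size=signal.shape)
        meta = {"rpm": setup.rotor_speed, "meniscus_cm": geometry.meniscus_radius,
                "bottom_cm": geometry.bottom_radius,
                "pathlength_cm": geometry.pathlength,
                "temperature_K": conditions.temperature,
                "total_protein_dimer_M": ladder.total_protein_dimer,
                "total_dna_duplex_M": ladder.total_dna_duplex,
                "signal_per_molar": signal_per_molar}
        scans.append(SVScanSet(unit.radii.copy(), unit.times.copy(), signal, meta))
        truths.append(conc)
    return scans, truths
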