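"""Svedberg-relation conversions among s, D, M, vbar and f/f0.

All internal arithmetic is CGS: s in seconds (1 S = 1e-13 s), D in cm^2/s,
molar mass in g/mol, density in g/mL, viscosity converted from the mPa.s of
the user-facing API to poise.  Sedimentation coefficients are handled at
experimental conditions throughout (the analyses this package supports report
apparent values); ``standardize_s`` is the hook for an s20,w correction and
defaults to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS_CGS", "BOLTZMANN_CGS", "AVOGADRO", "SVEDBERG",
    "SolutionConditions", "HydroSpecies", "CompositeVbar",
    "weight_average_vbar", "svedberg_mass", "svedberg_diffusion",
    "diffusion_from_mass", "mass_from_s_ff0", "frictional_ratio_from_sD",
    "standardize_s",
]

# Unit conversions and physical constants, centralized (CGS).
R_GAS_CGS = 8.314462618e7      # erg mol^-1 K^-1
BOLTZMANN_CGS = 1.380649e-16   # erg K^-1
AVOGADRO = 6.02214076e23       # mol^-1
SVEDBERG = 1e-13               # s per Svedberg unit
MPAS_TO_POISE = 0.01           # 1 mPa.s (= 1 cP) = 0.01 poise


@dataclass(frozen=True)
class SolutionConditions:
    """Buffer density (g/mL), viscosity (mPa.s) and temperature (K).

    These are configuration inputs (measured or estimated externally, e.g.
    with SEDNTERP-style calculators); defaults are water-like at 20 C.
    """

    density: float = 0.99823
    viscosity: float = 1.002
    temperature: float = 293.15

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0 or self.temperature <= 0:
            raise ValueError("density, viscosity and temperature must be positive")
        if not (273.0 <= self.temperature <= 320.0):
            raise ValueError(f"temperature {self.temperature} K outside 273-320 K")

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity * MPAS_TO_POISE


def weight_average_vbar(M1: float, vbar1: float, M2: float, vbar2: float) -> float:
    """Mass-weighted partial specific volume of a two-part complex (mL/g).

    vbar = (M1 vbar1 + M2 vbar2) / (M1 + M2); used for protein-DNA
    hetero-complexes where the two parts have very different vbar.
    """
    if M1 <= 0 or M2 < 0:
        raise ValueError("masses must be positive (M2 may be zero)")
    if M2 == 0:
        return float(vbar1)
    return float((M1 * vbar1 + M2 * vbar2) / (M1 + M2))


def _buoyancy(vbar: float, conditions: SolutionConditions) -> float:
    b = 1.0 - vbar * conditions.density
    if abs(b) < 1e-12:
        raise ValueError("neutral buoyancy: 1 - vbar*rho = 0, mass undefined")
    return b


def svedberg_mass(s: float, D: float, vbar: float,
                  conditions: SolutionConditions = SolutionConditions()) -> float:
    """Molar mass (Da) from the Svedberg equation M = s R T / (D (1 - vbar rho)).

    ``s`` in Svedberg units, ``D`` in cm^2/s.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    b = _buoyancy(vbar, conditions)
    return s * SVEDBERG * R_GAS_CGS * conditions.temperature / (D * b)


def svedberg_diffusion(s: float, M: float, vbar: float,
                       conditions: SolutionConditions = SolutionConditions()) -> float:
    """D (cm^2/s) consistent with (s, M, vbar) via the Svedberg equation."""
    if M <= 0:
        raise ValueError("molar mass must be positive")
    b = _buoyancy(vbar, conditions)
    return s * SVEDBERG * R_GAS_CGS * conditions.temperature / (M * b)


def _anhydrous_radius(M: float, vbar: float) -> float:
    """Radius (cm) of the anhydrous sphere of molar mass M and volume M*vbar/NA."""
    return (3.0 * M * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)


def diffusion_from_mass(M: float, vbar: float, frictional_ratio: float,
                        conditions: SolutionConditions = SolutionConditions()) -> float:
    """D (cm^2/s) by Stokes-Einstein with the anhydrous sphere scaled by f/f0."""
    if M <= 0 or vbar <= 0:
        raise ValueError("mass and vbar must be positive")
    if frictional_ratio < 1.0:
        raise ValueError(f"frictional ratio {frictional_ratio} < 1 is unphysical")
    r0 = _anhydrous_radius(M, vbar)
    f = 6.0 * np.pi * conditions.viscosity_poise * r0 * frictional_ratio
    return BOLTZMANN_CGS * conditions.temperature / f


def mass_from_s_ff0(s: float, frictional_ratio: float, vbar: float,
                    conditions: SolutionConditions = SolutionConditions()) -> float:
    """Molar mass (Da) implied by (s, f/f0, vbar) — the c(s) closure.

    From s = M (1 - vbar rho) / (NA f) with f = 6 pi eta (f/f0) r0(M):
    M^(2/3) = s NA 6 pi eta (f/f0) (3 vbar / 4 pi NA)^(1/3) / (1 - vbar rho).
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if frictional_ratio < 1.0:
        raise ValueError(f"frictional ratio {frictional_ratio} < 1 is unphysical")
    b = _buoyancy(vbar, conditions)
    if b <= 0:
        raise ValueError("floating species (1 - vbar*rho <= 0) not supported here")
    coef = (s * SVEDBERG * AVOGADRO * 6.0 * np.pi * conditions.viscosity_poise
            * frictional_ratio * (3.0 * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0) / b)
    return coef ** 1.5


def frictional_ratio_from_sD(s: float, D: float, vbar: float,
                             conditions: SolutionConditions = SolutionConditions()) -> float:
    """f/f0 implied by an (s, D) pair at the given vbar."""
    M = svedberg_mass(s, D, vbar, conditions)
    f = BOLTZMANN_CGS * conditions.temperature / D
    f0 = 6.0 * np.pi * conditions.viscosity_poise * _anhydrous_radius(M, vbar)
    return f / f0


def standardize_s(s: float, conditions: SolutionConditions | None = None) -> float:
    """Hook for standardizing s to reference conditions; identity by default."""
    return s


@dataclass(frozen=True)
class HydroSpecies:
    """One sedimenting species.

    Parameters
    ----------
    name : label used in reports.
    molar_mass : Da.
    vbar : partial specific volume, mL/g.
    s : sedimentation coefficient, Svedberg units, at experimental conditions.
    D : diffusion coefficient, cm^2/s; derived from the Svedberg relation at
        construction (``with_consistent_D``) when not given.
    frictional_ratio : optional f/f0 (>= 1).
    composition : (n_protein_monomers, n_dna_duplexes).
    """

    name: str
    molar_mass: float
    vbar: float
    s: float
    D: float | None = None
    frictional_ratio: float | None = None
    composition: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.molar_mass <= 0 or self.vbar <= 0:
            raise ValueError(f"{self.name}: molar mass and vbar must be positive")
        if self.frictional_ratio is not None and self.frictional_ratio < 1.0:
            raise ValueError(f"{self.name}: frictional ratio < 1")
        npro, ndna = self.composition
        if npro < 0 or ndna < 0 or npro != int(npro) or ndna != int(ndna):
            raise ValueError(f"{self.name}: composition must be non-negative integers")

    def with_consistent_D(self, conditions: SolutionConditions = SolutionConditions()
                          ) -> "HydroSpecies":
        """Return a copy whose D satisfies the Svedberg relation.

        When D is already set, it is checked for consistency (1e-6 relative).
        """
        D = svedberg_diffusion(self.s, self.molar_mass, self.vbar, conditions)
        if self.D is not None:
            if abs(self.D - D) > 1e-6 * D:
                raise ValueError(
                    f"{self.name}: (s, D, M) inconsistent with the Svedberg relation: "
                    f"given D={self.D:.4e}, implied D={D:.4e}")
            return self
        return HydroSpecies(self.name, self.molar_mass, self.vbar, self.s, D,
                            self.frictional_ratio, self.composition)


@dataclass(frozen=True)
class CompositeVbar:
    """Weight-averaged vbar of a protein/DNA complex, with its inputs."""

    M1: float
    vbar1: float
    M2: float
    vbar2: float
    vbar_avg: float = field(init=False)

    def __post_init__(self):
        v = weight_average_vbar(self.M1, self.vbar1, self.M2, self.vbar2)
        lo, hi = sorted((self.vbar1, self.vbar2))
        assert lo - 1e-12 <= v <= hi + 1e-12
        object.__setattr__(self, "vbar_avg", v)
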