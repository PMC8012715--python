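"""Molar extinction profiles for protein and DNA spectral components.

This module provides the spectral side of a multiwavelength sedimentation
analysis: composition-based extinction coefficients (protein at 280 nm,
nucleic-acid duplexes at 260 nm by the nearest-neighbor method), duplex
molar masses, fitting of intrinsic extinction profiles from dilution-series
spectra, and the vector-angle separability diagnostic used to decide whether
two spectral components can be deconvoluted from mixed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtinctionProfile",
    "DilutionSeries",
    "protein_extinction_280",
    "protein_monomer_mass",
    "dna_strand_extinction_260",
    "dna_duplex_extinction_260",
    "dna_strand_mass",
    "dna_duplex_mass",
    "duplex_hypochromicity",
    "fit_extinction_profile",
    "vector_angle",
    "reverse_complement",
]

# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

#: Trp/Tyr/cystine increments (M^-1 cm^-1) of the standard composition rule
#: for protein eps280 (Gill & von Hippel / Pace; the rule behind ProtParam).
EPS280_TRP = 5500.0
EPS280_TYR = 1490.0
EPS280_CYSTINE = 125.0

#: Nearest-neighbor single-strand eps260 parameters (M^-1 cm^-1), the classic
#: Cantor-Warshaw-Tinoco dinucleotide/mononucleotide set that underlies the
#: common vendor oligo calculators (Cantor, Warshaw & Tinoco, Biopolymers 9,
#: 1059 (1970), as tabulated by Tataurov, You & Owczarzy, Biophys. Chem. 133,
#: 66 (2008)).  Vendor tables differ from each other by a few percent.
NN_EPS260 = {
    "AA": 27400.0, "AC": 21200.0, "AG": 25000.0, "AT": 22800.0,
    "CA": 21200.0, "CC": 14600.0, "CG": 18000.0, "CT": 15200.0,
    "GA": 25200.0, "GC": 17600.0, "GG": 21600.0, "GT": 20000.0,
    "TA": 23400.0, "TC": 16200.0, "TG": 19000.0, "TT": 16800.0,
}
MONO_EPS260 = {"A": 15400.0, "C": 7400.0, "G": 11500.0, "T": 8700.0}

#: Average masses (Da) of internal deoxynucleotide residues (nucleoside
#: monophosphate minus water); a 5'-OH strand is the residue sum minus 61.96
#: (HPO3 replaced by H at the 5' end).
DNA_RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
_5PRIME_OH_CORRECTION = 61.96

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: 20 standard amino acids (validation set for protein sequences).
_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtinctionProfile:
    """Molar extinction vs wavelength for one spectral component.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing.
    epsilon : array, M^-1 cm^-1, non-negative, same length.
    component_label : non-empty name ("protein", "dna", ...).
    """

    wavelengths: np.ndarray
    epsilon: np.ndarray
    component_label: str

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ep = np.asarray(self.epsilon, dtype=float)
        if wl.ndim != 1 or ep.shape != wl.shape:
            raise ValueError("wavelengths and epsilon must be 1-D and equal length")
        if wl.size < 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be non-empty and strictly increasing")
        if np.any(ep < 0):
            raise ValueError("extinction coefficients must be non-negative")
        if not self.component_label:
            raise ValueError("component_label must be non-empty")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", ep)

    def at(self, wavelength: float) -> float:
        """Extinction at a grid wavelength (exact match required)."""
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength))[0]
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength} nm not on profile grid")
        return float(self.epsilon[idx[0]])

    def scaled(self, factor: float) -> "ExtinctionProfile":
        return ExtinctionProfile(self.wavelengths, self.epsilon * factor,
                                 self.component_label)


@dataclass(frozen=True)
class DilutionSeries:
    """Absorbance spectra of a dilution ladder of one component.

    ``spectra[i, j]`` is the absorbance at ``wavelengths[i]`` for dilution
    ``j`` at concentration ``concentrations[j]`` (arbitrary relative units
    are fine; the fitted profile is rescaled through a reference point).
    A zero-concentration blank row is permitted and acts as an intercept.
    """

    wavelengths: np.ndarray
    concentrations: np.ndarray
    spectra: np.ndarray
    pathlength: float = 1.2

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        spec = np.asarray(self.spectra, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(conc).size < 2:
            raise ValueError("dilution series needs at least 2 distinct concentrations")
        if spec.shape != (wl.size, conc.size):
            raise ValueError(
                f"spectra shape {spec.shape} inconsistent with "
                f"{wl.size} wavelengths x {conc.size} dilutions")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "spectra", spec)


# ---------------------------------------------------------------------------
# Composition-based extinction coefficients and masses
# ---------------------------------------------------------------------------

def protein_extinction_280(sequence: str, cystine_mode: str = "reduced") -> float:
    """Protein molar extinction at 280 nm from Trp/Tyr (and cystine) counts.

    eps280 = 5500*nTrp + 1490*nTyr (+ 125 per cystine pair when
    ``cystine_mode="oxidized"``), i.e. the composition rule used by ProtParam.
    """
    if cystine_mode not in ("reduced", "oxidized"):
        raise ValueError(f"cystine_mode must be 'reduced' or 'oxidized', got {cystine_mode!r}")
    seq = sequence.upper()
    for pos, res in enumerate(seq):
        if res not in _AMINO_ACIDS:
            raise ValueError(f"unknown residue code {res!r} at position {pos}")
    eps = EPS280_TRP * seq.count("W") + EPS280_TYR * seq.count("Y")
    if cystine_mode == "oxidized":
        eps += EPS280_CYSTINE * (seq.count("C") // 2)
    return eps


def protein_monomer_mass(sequence: str) -> float:
    """Average molecular mass (Da) of a protein chain."""
    from Bio.SeqUtils import molecular_weight
    seq = sequence.upper()
    for pos, res in enumerate(seq):
        if res not in _AMINO_ACIDS:
            raise ValueError(f"unknown residue code {res!r} at position {pos}")
    return float(molecular_weight(seq, seq_type="protein"))


def _check_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    for pos, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"{name}: base {base!r} at position {pos} is not one of A/C/G/T "
                             "(ambiguity codes are not supported)")
    return seq


def reverse_complement(seq: str) -> str:
    return _check_dna(seq, "sequence").translate(_DNA_COMPLEMENT)[::-1]


def dna_strand_extinction_260(seq: str) -> float:
    """Single-strand eps260 by the nearest-neighbor method.

    Sum of dinucleotide nearest-neighbor extinctions minus the extinctions of
    the internal mononucleotides (counted twice by the dinucleotide sum).
    """
    seq = _check_dna(seq, "strand")
    if len(seq) == 0:
        return 0.0
    if len(seq) == 1:
        return MONO_EPS260[seq]
    nn = sum(NN_EPS260[seq[i:i + 2]] for i in range(len(seq) - 1))
    mono = sum(MONO_EPS260[b] for b in seq[1:-1])
    return nn - mono


def duplex_hypochromicity(top: str) -> float:
    """Fractional eps260 loss upon duplex formation, h = 0.287 fAT + 0.059 fGC."""
    top = _check_dna(top, "top strand")
    f_at = (top.count("A") + top.count("T")) / len(top)
    return 0.287 * f_at + 0.059 * (1.0 - f_at)


def _check_duplex(top: str, bottom: str) -> tuple[str, str]:
    top = _check_dna(top, "top strand")
    bottom = _check_dna(bottom, "bottom strand")
    if bottom != reverse_complement(top):
        raise ValueError("strands are not reverse-complementary")
    return top, bottom


def dna_duplex_extinction_260(top: str, bottom: str) -> float:
    """Duplex eps260: hypochromicity-corrected sum of the two strand values.

    eps_ds = (1 - h) * (eps_ss,top + eps_ss,bottom) with h from the
    base-composition formula ``duplex_hypochromicity``.
    """
    top, bottom = _check_duplex(top, bottom)
    h = duplex_hypochromicity(top)
    return (1.0 - h) * (dna_strand_extinction_260(top) + dna_strand_extinction_260(bottom))


def dna_strand_mass(seq: str) -> float:
    """Average mass (Da) of a 5'-OH, 3'-OH DNA strand (no terminal phosphate)."""
    seq = _check_dna(seq, "strand")
    if len(seq) == 0:
        return 0.0
    return sum(DNA_RESIDUE_MASS[b] for b in seq) - _5PRIME_OH_CORRECTION


def dna_duplex_mass(top: str, bottom: str) -> float:
    """Average mass (Da) of an unlabeled duplex (both strands 5'-OH)."""
    if len(top) == 0 and len(bottom) == 0:
        return 0.0
    top, bottom = _check_duplex(top, bottom)
    return dna_strand_mass(top) + dna_strand_mass(bottom)


# ---------------------------------------------------------------------------
# Dilution-series profile fitting
# ---------------------------------------------------------------------------

def fit_extinction_profile(series: DilutionSeries, reference_wavelength: float,
                           reference_epsilon: float,
                           component_label: str = "component") -> ExtinctionProfile:
    """Fit an intrinsic extinction profile from dilution-series spectra.

    At each wavelength the absorbance is regressed linearly (slope +
    intercept) against concentration x pathlength; the slope vector is then
    rescaled so that the profile passes through ``reference_epsilon`` at
    ``reference_wavelength``.  A zero-concentration blank row only feeds the
    intercept and leaves the profile unchanged.  Negative fitted slopes are
    clamped to zero with a warning.
    """
    x = series.concentrations * series.pathlength
    # design matrix [x, 1]; one shared least-squares solve for all wavelengths
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, series.spectra.T, rcond=None)
    slopes = coef[0]
    if np.any(slopes < 0):
        warnings.warn("negative fitted extinction slopes clamped to zero")
        slopes = np.clip(slopes, 0.0, None)
    ref = ExtinctionProfile(series.wavelengths, slopes, component_label)
    at_ref = ref.at(reference_wavelength)
    if at_ref <= 0:
        raise ValueError("fitted profile vanishes at the reference wavelength; cannot rescale")
    return ref.scaled(reference_epsilon / at_ref)


# ---------------------------------------------------------------------------
# Spectral separability
# ---------------------------------------------------------------------------

def vector_angle(p1: ExtinctionProfile, p2: ExtinctionProfile) -> float:
    """Angle (degrees, in [0, 90]) between two extinction profiles.

    arccos of the normalized inner product over the common wavelength grid.
    0 deg means linear dependence (inseparable components); 90 deg means
    orthogonal spectra (perfectly separable).
    """
    if p1.wavelengths.shape != p2.wavelengths.shape or \
            not np.allclose(p1.wavelengths, p2.wavelengths):
        raise ValueError("profiles must share the same wavelength grid")
    n1 = np.linalg.norm(p1.epsilon)
    n2 = np.linalg.norm(p2.epsilon)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm extinction profile has no direction")
    cosang = float(np.dot(p1.epsilon, p2.epsilon) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
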