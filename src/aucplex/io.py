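"""Readers and writers for the package's plain-text formats.

Scan sets are long-format CSV (time_s, radius_cm, signal) with a
``# key: value`` metadata header; multiwavelength runs are a directory of
per-wavelength scan CSVs plus a YAML manifest; extinction profiles,
dilution series and isotherms are small CSV tables; sequences are FASTA.
All round trips are lossless to full float precision (values are written
with repr-level precision).
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .binding import BindingIsotherm
from .spectra import ExtinctionProfile
from .synthetic import MWLDataset, SVScanSet

__all__ = [
    "write_scan_csv", "read_scan_csv", "write_mwl", "read_mwl",
    "write_profile_csv", "read_profile_csv", "read_dilution_series_csv",
    "write_isotherm_csv", "read_isotherm_csv", "read_fasta",
    "packaged_protein_sequence", "packaged_operator_duplex", "file_sha256",
]

_FLOAT_FMT = "%.17g"


def _write_metadata_header(fh, metadata: dict) -> None:
    for key, value in metadata.items():
        fh.write(f"# {key}: {value}\n")


def _read_metadata_header(path: Path) -> tuple[dict, int]:
    """Parse leading '# key: value' lines; returns (metadata, n_header_lines)."""
    metadata = {}
    n = 0
    with open(path, "r", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
            key, _, value = body.partition(":")
            value = value.strip()
            try:
                metadata[key.strip()] = float(value)
            except ValueError:
                metadata[key.strip()] = value
            n += 1
    return metadata, n


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} "
                         f"(line {1 + _count_header_lines(path)})")


def _count_header_lines(path) -> int:
    try:
        return _read_metadata_header(Path(path))[1]
    except Exception:
        return 0


# ---------------------------------------------------------------------------
# Scan sets
# ---------------------------------------------------------------------------

def write_scan_csv(scans: SVScanSet, path) -> None:
    path = Path(path)
    times = np.repeat(scans.times, scans.radii.size)
    radii = np.tile(scans.radii, scans.times.size)
    with open(path, "w") as fh:
        _write_metadata_header(fh, scans.metadata)
        fh.write("time_s,radius_cm,signal\n")
        np.savetxt(fh, np.column_stack([times, radii, scans.signal.ravel()]),
                   delimiter=",", fmt=_FLOAT_FMT)


def read_scan_csv(path) -> SVScanSet:
    path = Path(path)
    metadata, n_header = _read_metadata_header(path)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    _require_columns(df, {"time_s", "radius_cm", "signal"}, path)
    times = np.unique(df["time_s"].to_numpy())
    radii = np.unique(df["radius_cm"].to_numpy())
    if df.shape[0] != times.size * radii.size:
        raise ValueError(f"{path}: scan table is not a complete (time x radius) grid")
    pivot = df.pivot(index="time_s", columns="radius_cm", values="signal")
    return SVScanSet(radii, times, pivot.to_numpy(), metadata)


# ---------------------------------------------------------------------------
# Multiwavelength datasets (directory + YAML manifest)
# ---------------------------------------------------------------------------

def write_mwl(data: MWLDataset, directory) -> Path:
    """Write per-wavelength scan CSVs plus a manifest.yaml; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, wl in enumerate(data.wavelengths):
        fname = f"scans_{wl:07.2f}nm.csv"
        meta = dict(data.metadata)
        meta["wavelength_nm"] = float(wl)
        meta["pathlength_cm"] = data.pathlength
        write_scan_csv(SVScanSet(data.radii, data.times, data.absorbance[i], meta),
                       directory / fname)
        entries.append({"wavelength_nm": float(wl), "file": fname})
    manifest = {"pathlength_cm": data.pathlength,
                "metadata": {k: (float(v) if isinstance(v, (int, float, np.floating))
                                 else v) for k, v in data.metadata.items()},
                "datasets": entries}
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_mwl(manifest_path) -> MWLDataset:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("datasets", "pathlength_cm"):
        if key not in manifest:
            raise ValueError(f"{manifest_path}: manifest lacks '{key}'")
    wavelengths, cubes = [], []
    radii = times = None
    for entry in sorted(manifest["datasets"], key=lambda e: e["wavelength_nm"]):
        scans = read_scan_csv(manifest_path.parent / entry["file"])
        if radii is None:
            radii, times = scans.radii, scans.times
        elif not (np.allclose(radii, scans.radii) and np.allclose(times, scans.times)):
            raise ValueError(f"{entry['file']}: grid differs from other wavelengths")
        wavelengths.append(entry["wavelength_nm"])
        cubes.append(scans.signal)
    return MWLDataset(np.asarray(wavelengths, float), times, radii,
                      np.stack(cubes), float(manifest["pathlength_cm"]),
                      dict(manifest.get("metadata", {})))


# ---------------------------------------------------------------------------
# Profiles, dilution series, isotherms
# ---------------------------------------------------------------------------

def write_profile_csv(profile: ExtinctionProfile, path) -> None:
    with open(path, "w") as fh:
        _write_metadata_header(fh, {"component": profile.component_label})
        fh.write("wavelength_nm,epsilon\n")
        np.savetxt(fh, np.column_stack([profile.wavelengths, profile.epsilon]),
                   delimiter=",", fmt=_FLOAT_FMT)


def read_profile_csv(path) -> ExtinctionProfile:
    path = Path(path)
    metadata, n_header = _read_metadata_header(path)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    _require_columns(df, {"wavelength_nm", "epsilon"}, path)
    return ExtinctionProfile(df["wavelength_nm"].to_numpy(),
                             df["epsilon"].to_numpy(),
                             str(metadata.get("component", path.stem)))


def read_dilution_series_csv(path, pathlength: float = 1.2):
    """Dilution-series spectra: first column wavelength_nm, one column per
    dilution, header row carrying the concentrations."""
    from .spectra import DilutionSeries
    path = Path(path)
    metadata, n_header = _read_metadata_header(path)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm")
    try:
        concs = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: dilution column headers must be concentrations") from exc
    return DilutionSeries(df["wavelength_nm"].to_numpy(), concs,
                          df.iloc[:, 1:].to_numpy(),
                          float(metadata.get("pathlength_cm", pathlength)))


def write_isotherm_csv(iso: BindingIsotherm, path) -> None:
    with open(path, "w") as fh:
        fh.write("conc_M,theta" + (",sd\n" if iso.sd is not None else "\n"))
        cols = [iso.concentrations, iso.theta]
        if iso.sd is not None:
            cols.append(iso.sd)
        np.savetxt(fh, np.column_stack(cols), delimiter=",", fmt=_FLOAT_FMT)


def read_isotherm_csv(path) -> BindingIsotherm:
    path = Path(path)
    _, n_header = _read_metadata_header(path)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    _require_columns(df, {"conc_M", "theta"}, path)
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    return BindingIsotherm(df["conc_M"].to_numpy(), df["theta"].to_numpy(), sd)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA records as {id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _packaged_fasta(name: str) -> dict[str, str]:
    ref = resources.files("aucplex.data") / name
    with resources.as_file(ref) as path:
        return read_fasta(path)


def packaged_protein_sequence() -> str:
    """Synthetic stand-in for the repressor monomer sequence.

    Matches the published compositional facts (263 residues, 2 Trp + 2 Tyr,
    homodimer ~59 kDa); the residue order is arbitrary.
    """
    return next(iter(_packaged_fasta("nanr_dimer_synthetic.fasta").values()))


def packaged_operator_duplex() -> tuple[str, str]:
    """Synthetic stand-in (top, bottom) strands of the 35-bp operator duplex."""
    recs = _packaged_fasta("operator_duplex_synthetic.fasta")
    return (recs["operator_top_synthetic"], recs["operator_bottom_synthetic"])


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
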