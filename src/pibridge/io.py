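"""File formats and configuration.

Adhesion tables are CSV (UTF-8, '.' decimal, mandatory header) with columns
``surface_label, salt, ionic_strength_mM, adhesion_mJ_per_m2, replicate``
plus optional ``sd`` and ``fixed_t_conc_mM``.  Coordinates are written as
extended XYZ (key=value comment line, 6-decimal precision) or PDB
(fixed-width, 3-decimal precision, read through gemmi); ring membership and
cation sites are declared in a sidecar JSON index, with atoms addressed by
their 0-based position in file order.  Configs are YAML (JSON is a subset);
unknown keys are rejected and every run's resolved config is echoed into
its outputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .adhesion_fit import AdhesionCurve, AdhesionPoint, SaltSpec
from .ringgeom import CATION_SPECIES, CationSite, RingGroup

__all__ = [
    "SCHEMA_VERSION",
    "SALT_VALENCES",
    "ConfigError",
    "CsvSchemaError",
    "salt_from_name",
    "read_adhesion_csv",
    "write_adhesion_csv",
    "read_coordinates",
    "write_coordinates",
    "write_ring_index",
    "load_config",
]

SCHEMA_VERSION = "1"

REQUIRED_ADHESION_COLUMNS = [
    "surface_label",
    "salt",
    "ionic_strength_mM",
    "adhesion_mJ_per_m2",
    "replicate",
]
OPTIONAL_ADHESION_COLUMNS = ["sd", "fixed_t_conc_mM"]

SALT_VALENCES = {
    "KNO3": 1,
    "KCl": 1,
    "K": 1,
    "NaCl": 1,
    "Mg(NO3)2": 2,
    "MgCl2": 2,
    "Mg": 2,
    "Y(NO3)3": 3,
    "YCl3": 3,
    "Y": 3,
}

_ELEMENT_FOR_SPECIES = {"K+": "K", "Y3+": "Y", "NH3+": "N"}


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


class CsvSchemaError(ValueError):
    """CSV file does not match the adhesion-table schema."""


def salt_from_name(name: str) -> SaltSpec:
    if name not in SALT_VALENCES:
        raise CsvSchemaError(
            f"unknown salt {name!r}; known salts: {sorted(SALT_VALENCES)}"
        )
    return SaltSpec(name=name, cation_valence=SALT_VALENCES[name])


def read_adhesion_csv(path: str | Path) -> list[AdhesionCurve]:
    """Read an adhesion table, grouping rows into curves.

    Curves are keyed by (surface_label, salt, fixed_t_conc) and their
    points sorted by ionic strength.  Malformed rows are reported with
    1-based file line numbers (header is line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_ADHESION_COLUMNS if c not in df.columns]
    if missing:
        raise CsvSchemaError(f"{path}: missing required column(s) {missing}")
    if "fixed_t_conc_mM" not in df.columns:
        df["fixed_t_conc_mM"] = 0.0
    if "sd" not in df.columns:
        df["sd"] = np.nan

    errors = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if not np.isfinite(row["ionic_strength_mM"]) or row["ionic_strength_mM"] < 0:
            errors.append(f"line {line}: ionic_strength_mM must be >= 0")
        if not np.isfinite(row["adhesion_mJ_per_m2"]):
            errors.append(f"line {line}: adhesion_mJ_per_m2 is not a number")
        if row["salt"] not in SALT_VALENCES:
            errors.append(f"line {line}: unknown salt {row['salt']!r}")
    if errors:
        raise CsvSchemaError(f"{path}: " + "; ".join(errors))

    curves = []
    keys = ["surface_label", "salt", "fixed_t_conc_mM"]
    for (label, salt_name, t_conc), group in df.groupby(keys, sort=True):
        points = [
            AdhesionPoint(
                ionic_strength=float(r["ionic_strength_mM"]),
                adhesion_energy=float(r["adhesion_mJ_per_m2"]),
                replicate_id=str(r["replicate"]),
                uncertainty=None if pd.isna(r["sd"]) else float(r["sd"]),
            )
            for _, r in group.iterrows()
        ]
        curves.append(
            AdhesionCurve(
                points=points,
                salt=salt_from_name(str(salt_name)),
                surface_label=str(label),
                fixed_t_conc=float(t_conc),
            )
        )
    return curves


def write_adhesion_csv(curves: list[AdhesionCurve], path: str | Path) -> None:
    rows = []
    for curve in curves:
        for p in curve.points:
            rows.append(
                {
                    "surface_label": curve.surface_label,
                    "salt": curve.salt.name,
                    "ionic_strength_mM": p.ionic_strength,
                    "adhesion_mJ_per_m2": p.adhesion_energy,
                    "replicate": p.replicate_id,
                    "sd": "" if p.uncertainty is None else p.uncertainty,
                    "fixed_t_conc_mM": curve.fixed_t_conc,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# --- coordinates -----------------------------------------------------------


def _flatten_atoms(rings: list[RingGroup], cations: list[CationSite]):
    """File atom order: all ring atoms (6 each) then all cation atoms."""
    elements, coords = [], []
    ring_entries, cation_entries = [], []
    for ring in rings:
        start = len(coords)
        for xyz in ring.atom_coords:
            elements.append("C")
            coords.append(xyz)
        ring_entries.append(
            {
                "ring_id": ring.ring_id,
                "residue_id": ring.residue_id,
                "layer": ring.layer,
                "snapshot_index": ring.snapshot_index,
                "atom_indices": list(range(start, start + 6)),
            }
        )
    for cat in cations:
        cation_entries.append(
            {
                "site_id": cat.site_id,
                "species": cat.species,
                "layer": cat.layer,
                "snapshot_index": cat.snapshot_index,
                "atom_index": len(coords),
            }
        )
        elements.append(_ELEMENT_FOR_SPECIES[cat.species])
        coords.append(cat.coord)
    return elements, np.asarray(coords, float), ring_entries, cation_entries


def write_ring_index(
    rings: list[RingGroup], cations: list[CationSite], path: str | Path
) -> dict:
    """Write the sidecar JSON declaring rings and cation sites."""
    _, _, ring_entries, cation_entries = _flatten_atoms(rings, cations)
    index = {
        "schema_version": SCHEMA_VERSION,
        "rings": ring_entries,
        "cations": cation_entries,
    }
    Path(path).write_text(json.dumps(index, indent=2, sort_keys=True) + "\n")
    return index


def write_coordinates(
    rings: list[RingGroup],
    cations: list[CationSite],
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write coordinates as extended XYZ (default) or PDB.

    XYZ carries 6 decimals; PDB is fixed-width with the format's 3-decimal
    precision.  The companion ring index must be written separately with
    :func:`write_ring_index`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    elements, coords, _, _ = _flatten_atoms(rings, cations)
    if fmt == "xyz":
        lines = [str(len(elements)), "pibridge=extended-xyz units=angstrom"]
        for el, (x, y, z) in zip(elements, coords):
            lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        lines = []
        for i, (el, (x, y, z)) in enumerate(zip(elements, coords), start=1):
            name = el.rjust(2).ljust(4)
            lines.append(
                f"HETATM{i:5d} {name} LIG A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown coordinate format {fmt!r}")


def _read_xyz_atoms(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    coords = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        for ln in block:
            parts = ln.split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        i += 2 + n
    return np.asarray(coords, float)


def _read_pdb_atoms(path: Path) -> np.ndarray:
    structure = gemmi.read_structure(str(path))
    coords = []
    saw_altloc = False
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("\0", "", "A"):
                        saw_altloc = True
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if saw_altloc:
        warnings.warn(f"{path}: alternate locations present; first altloc used", stacklevel=2)
    return np.asarray(coords, float)


def read_coordinates(
    path: str | Path, ring_index: str | Path | dict
) -> tuple[list[RingGroup], list[CationSite]]:
    """Read a PDB or extended-XYZ file with its ring/cation index.

    ``ring_index`` is the sidecar JSON (path or already-parsed dict)
    mapping 0-based atom indices to rings (exactly 6 atoms each) and
    cation sites.  Ring planarity is validated on load.
    """
    path = Path(path)
    if isinstance(ring_index, (str, Path)):
        index_path = Path(ring_index)
        if not index_path.exists():
            raise FileNotFoundError(
                f"ring index {index_path} not found (required for {path})"
            )
        index = json.loads(index_path.read_text())
    else:
        index = ring_index

    if path.suffix.lower() == ".pdb":
        coords = _read_pdb_atoms(path)
    else:
        coords = _read_xyz_atoms(path)

    rings = []
    for entry in index.get("rings", []):
        atom_indices = entry["atom_indices"]
        if len(atom_indices) != 6:
            raise ValueError(
                f"ring {entry.get('ring_id')!r}: index maps {len(atom_indices)} atoms, expected 6"
            )
        rings.append(
            RingGroup(
                atom_coords=coords[atom_indices],
                ring_id=str(entry["ring_id"]),
                residue_id=str(entry.get("residue_id", "")),
                layer=entry.get("layer", "upper"),
                snapshot_index=int(entry.get("snapshot_index", 0)),
            )
        )
    cations = []
    for entry in index.get("cations", []):
        species = entry["species"]
        if species not in CATION_SPECIES:
            raise ValueError(
                f"site {entry.get('site_id')!r}: unknown cation species {species!r}"
            )
        cations.append(
            CationSite(
                coord=coords[int(entry["atom_index"])],
                species=species,
                site_id=str(entry["site_id"]),
                layer=entry.get("layer", "bath"),
                snapshot_index=int(entry.get("snapshot_index", 0)),
            )
        )
    return rings, cations


# --- configuration ---------------------------------------------------------


def load_config(path: str | Path, allowed_keys: dict) -> dict:
    """Load a YAML/JSON config, rejecting unknown keys and filling defaults.

    ``allowed_keys`` maps key name -> default value (a default of
    ``Ellipsis`` marks the key required).  Returns the resolved config with
    ``schema_version`` set.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    raw.pop("schema_version", None)
    unknown = sorted(set(raw) - set(allowed_keys))
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {unknown}")
    resolved = {}
    for key, default in allowed_keys.items():
        if key in raw:
            resolved[key] = raw[key]
        elif default is Ellipsis:
            raise ConfigError(f"{path}: missing required config key {key!r}")
        else:
            resolved[key] = default
    resolved["schema_version"] = SCHEMA_VERSION
    return resolved
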