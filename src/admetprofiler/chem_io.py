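"""Structure and descriptor-table input/output.

Reads 3D structures (SDF, SMILES) into lightweight :class:`MoleculeRecord`
objects, reads/writes per-compound descriptor tables as
:class:`CompoundProfile` lists, and maps external column headers (including
the QikProp export dialect) onto a canonical descriptor registry.

Missing descriptor values are represented by an *absent key*, never by a NaN
or zero sentinel, so downstream compliance scoring can distinguish
"out of range" from "unknown".
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml

__all__ = [
    "Atom",
    "Bond",
    "MoleculeRecord",
    "CompoundProfile",
    "RegistryEntry",
    "DescriptorRegistry",
    "default_registry",
    "read_structures",
    "read_descriptor_table",
    "write_profiles",
    "ChemIOError",
]

_DATA_DIR = Path(__file__).parent / "data"

COUNT_DESCRIPTORS = frozenset({"HBA", "HBD", "NRB", "metab", "stars"})


class ChemIOError(ValueError):
    """Raised for parse errors, duplicate ids and contract violations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    z: float
    formal_charge: int = 0


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float = 1.0


@dataclass
class MoleculeRecord:
    """A molecule as elements, 3D coordinates and bonds.

    ``properties`` carries SDF tags verbatim.  ``has_3d`` is False for
    records built from SMILES, whose coordinates are placeholders; geometry
    descriptors refuse such records.
    """

    id: str
    name: str = ""
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)
    has_3d: bool = True

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemIOError(
                    f"molecule {self.id!r}: bond ({b.i},{b.j}) references "
                    f"missing atom (n={n})"
                )
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ChemIOError(f"molecule {self.id!r}: non-finite coordinate")

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out


@dataclass
class CompoundProfile:
    """One compound's canonical-named descriptor values.

    ``provenance`` records, per descriptor, whether the value was computed
    by this package or imported from an external table.
    """

    id: str
    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def validate(self, registry: "DescriptorRegistry") -> None:
        for key, val in self.values.items():
            if key in COUNT_DESCRIPTORS:
                if val < 0 or val != int(val):
                    raise ChemIOError(
                        f"{self.id}: count descriptor {key}={val} must be a "
                        "non-negative integer"
                    )
            if key == "cns" and not -2 <= val <= 2:
                raise ChemIOError(f"{self.id}: CNS score {val} outside -2..+2")

    def get(self, key: str) -> float | None:
        return self.values.get(key)


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    units: str
    description: str
    aliases: tuple[str, ...] = ()


class DescriptorRegistry:
    """Canonical descriptor names with many-to-one external aliases."""

    def __init__(self, entries: Iterable[RegistryEntry]):
        self.entries: dict[str, RegistryEntry] = {}
        self._alias_map: dict[str, str] = {}
        for e in entries:
            if e.name in self.entries:
                raise ChemIOError(f"duplicate canonical name {e.name!r}")
            self.entries[e.name] = e
        for e in self.entries.values():
            for alias in e.aliases:
                key = alias.lower()
                if key in self._alias_map and self._alias_map[key] != e.name:
                    raise ChemIOError(f"alias {alias!r} maps to two names")
                if alias in self.entries and alias != e.name:
                    raise ChemIOError(
                        f"canonical name {alias!r} cannot be an alias of {e.name!r}"
                    )
                self._alias_map[key] = e.name

    def resolve(self, header: str) -> str | None:
        """Map an external header to its canonical name (idempotent)."""
        h = header.strip()
        if h in self.entries:
            return h
        return self._alias_map.get(h.lower())

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DescriptorRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            RegistryEntry(
                name=name,
                units=spec.get("units", ""),
                description=spec.get("description", ""),
                aliases=tuple(spec.get("aliases", [])),
            )
            for name, spec in raw.items()
        )


_DEFAULT_REGISTRY: DescriptorRegistry | None = None


def default_registry() -> DescriptorRegistry:
    """The shipped registry (descriptor names, units, QikProp-export aliases)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = DescriptorRegistry.from_yaml(
            _DATA_DIR / "registry.yaml"
        )
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# Structure readers
# ---------------------------------------------------------------------------

def _record_from_rdkit(mol, idx: int, has_3d: bool) -> MoleculeRecord:
    from rdkit import Chem

    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for a in mol.GetAtoms():
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            xyz = (p.x, p.y, p.z)
        else:
            xyz = (0.0, 0.0, 0.0)
        atoms.append(Atom(a.GetSymbol(), *xyz, a.GetFormalCharge()))
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    props = {
        k: mol.GetProp(k) for k in mol.GetPropNames() if not k.startswith("_")
    }
    rec_id = name or f"mol{idx}"
    return MoleculeRecord(
        id=rec_id, name=name, atoms=atoms, bonds=bonds,
        properties=props, has_3d=has_3d,
    )


def read_structures(
    path: str | Path, format: Literal["sdf", "smiles"]
) -> list[MoleculeRecord]:
    """Read an SDF file or a SMILES list into molecule records.

    SDF records keep explicit hydrogens, 3D coordinates and property tags.
    SMILES lines (``SMILES [name]``) get explicit hydrogens added but carry
    no geometry (``has_3d`` is False).  An unparseable record raises
    :class:`ChemIOError` naming its 1-based index.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    records: list[MoleculeRecord] = []
    if format == "sdf":
        suppl = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for i, mol in enumerate(suppl, start=1):
            if mol is None:
                raise ChemIOError(f"unparseable SDF record {i} in {path}")
            records.append(_record_from_rdkit(mol, i, has_3d=True))
    elif format == "smiles":
        for i, line in enumerate(
            (l for l in path.read_text().splitlines() if l.strip()), start=1
        ):
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                raise ChemIOError(f"unparseable SMILES record {i} in {path}")
            mol = Chem.AddHs(mol)
            rec = _record_from_rdkit(mol, i, has_3d=False)
            if len(parts) > 1:
                rec.name = parts[1].strip()
                rec.id = rec.name
            rec.properties.setdefault("smiles", parts[0])
            records.append(rec)
    else:
        raise ChemIOError(f"unknown structure format {format!r}")
    if not records:
        warnings.warn(f"{path}: no molecules found", stacklevel=2)
    return records


# ---------------------------------------------------------------------------
# Descriptor tables
# ---------------------------------------------------------------------------

def _profiles_from_frame(
    df: pd.DataFrame, registry: DescriptorRegistry
) -> list[CompoundProfile]:
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ChemIOError(f"duplicate compound ids: {sorted(set(dup))}")
    colmap: dict[str, str] = {}
    for col in df.columns[1:]:
        canon = registry.resolve(str(col))
        if canon is None:
            warnings.warn(
                f"column {col!r} not in descriptor registry; kept under its "
                "raw name", stacklevel=3,
            )
            canon = str(col)
        colmap[col] = canon
    profiles = []
    for row_i, (_, row) in enumerate(df.iterrows()):
        values: dict[str, float] = {}
        prov: dict[str, str] = {}
        for col, canon in colmap.items():
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) \
                    or (isinstance(cell, str) and not cell.strip()):
                continue  # missing cell -> absent key, never imputed
            try:
                values[canon] = float(cell)
            except (TypeError, ValueError):
                raise ChemIOError(
                    f"non-numeric cell {cell!r} at row {row_i + 1}, "
                    f"column {col!r}"
                ) from None
            prov[canon] = "imported"
        p = CompoundProfile(id=str(row[id_col]), values=values, provenance=prov)
        p.validate(registry)
        profiles.append(p)
    return profiles


def read_descriptor_table(
    path: str | Path,
    dialect: Literal["generic_csv", "qikprop_export", "sdf_tags"] = "generic_csv",
    registry: DescriptorRegistry | None = None,
) -> list[CompoundProfile]:
    """Read a per-compound descriptor table.

    ``generic_csv`` and ``qikprop_export`` are comma-separated with a header
    row, "." decimal, first column the compound id; they differ only in which
    alias table the headers are expected to hit (both resolve through the
    same registry, so the distinction is informational).  ``sdf_tags`` pulls
    numeric property tags out of an SDF file.
    """
    registry = registry or default_registry()
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if dialect in ("generic_csv", "qikprop_export"):
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 1:
            raise ChemIOError(f"{path}: no columns")
        return _profiles_from_frame(df, registry)
    if dialect == "sdf_tags":
        records = read_structures(path, "sdf")
        rows = []
        for rec in records:
            row: dict[str, str] = {"id": rec.id}
            row.update(rec.properties)
            rows.append(row)
        df = pd.DataFrame(rows)
        # drop non-numeric tag columns (e.g. smiles strings)
        keep = ["id"]
        for col in df.columns[1:]:
            series = pd.to_numeric(df[col], errors="coerce")
            if series.notna().any():
                keep.append(col)
        return _profiles_from_frame(df[keep], registry)
    raise ChemIOError(f"unknown table dialect {dialect!r}")


def write_profiles(
    profiles: list[CompoundProfile],
    path: str | Path,
    format: Literal["csv", "json"] = "csv",
    registry: DescriptorRegistry | None = None,
) -> None:
    """Write profiles so that :func:`read_descriptor_table` round-trips them.

    Values are written with 10 significant digits (round-trip fidelity well
    inside the 6-significant-digit contract).  Keys outside the registry are
    written under their raw names with a warning.
    """
    if not profiles:
        raise ChemIOError("refusing to write an empty profile list")
    registry = registry or default_registry()
    path = Path(path)
    keys: list[str] = []
    for p in profiles:
        for k in p.values:
            if k not in keys:
                keys.append(k)
    for k in keys:
        if k not in registry:
            warnings.warn(
                f"descriptor {k!r} is not registered; written under its raw "
                "name", stacklevel=2,
            )
    if format == "csv":
        rows = []
        for p in profiles:
            row: dict[str, object] = {"id": p.id}
            for k in keys:
                v = p.values.get(k)
                row[k] = "" if v is None else f"{v:.10g}"
            rows.append(row)
        pd.DataFrame(rows, columns=["id", *keys]).to_csv(path, index=False)
    elif format == "json":
        payload = [
            {"id": p.id, "values": p.values, "provenance": p.provenance}
            for p in profiles
        ]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif format == "sdf_tags":
        # descriptor-only export: each record is a placeholder single-carbon
        # molblock carrying the values as property tags
        blocks = []
        for p in profiles:
            lines = [
                p.id, "  admetprofiler", "",
                "  1  0  0  0  0  0  0  0  0  0999 V2000",
                "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0",
                "M  END",
            ]
            for k in keys:
                v = p.values.get(k)
                if v is not None:
                    lines += [f">  <{k}>", f"{v:.10g}", ""]
            lines.append("$$$$")
            blocks.append("\n".join(lines))
        path.write_text("\n".join(blocks) + "\n")
    else:
        raise ChemIOError(f"unknown profile format {format!r}")
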