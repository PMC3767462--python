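"""Formula-defined physico-chemical descriptors computed from 3D structures.

Implements the descriptors that are defined by an explicit formula or
geometric construction: molecular weight, hydrogen-bond acceptor/donor
counts, rotatable bonds, solvent-accessible surface area (total and
hydrophobic), solvent-accessible volume, globularity and the cohesion
index.  QSPR-model descriptors (logS, permeabilities, logHERG, ...) are
never computed here — they enter the pipeline as imported columns.

Geometry conventions
--------------------
SASA uses per-atom sphere sampling on a deterministic golden-spiral point
lattice over van der Waals spheres inflated by the solvent probe radius
(default 1.4 Å); a sample point contributes if it is not buried inside any
other inflated sphere.  Volume integrates the union of the inflated spheres
on a uniform Cartesian grid.  Hydrogens are explicit and included in both.
All functions are pure: identical input, parameters and seed give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chem_io import MoleculeRecord

__all__ = [
    "AtomRadiusTable",
    "SurfaceParams",
    "BONDI_RADII",
    "ATOMIC_MASSES",
    "molecular_weight",
    "count_hba",
    "count_hbd",
    "count_rotatable_bonds",
    "sasa_total",
    "sasa_per_atom",
    "sasa_hydrophobic",
    "molecular_volume",
    "globularity",
    "cohesion_index",
    "estimate_logp",
    "register_logp_backend",
    "DescriptorError",
]


class DescriptorError(ValueError):
    pass


# Bondi (1964) van der Waals radii, Å; Si/B from common extensions.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "K": 2.75, "Br": 1.85, "I": 1.98, "Se": 1.90,
}

# IUPAC 2021 standard atomic weights (conventional values).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.003, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.904, "Se": 78.971, "Fe": 55.845, "Zn": 65.38,
}

# Atoms counted as hydrophobic for S_mol,hfob: carbon, the heavy halogens,
# and hydrogens attached to carbon.  Editable via the hydrophobic_elements
# argument of sasa_hydrophobic.
HYDROPHOBIC_ELEMENTS = frozenset({"C", "Cl", "Br", "I"})


@dataclass(frozen=True)
class AtomRadiusTable:
    """Van der Waals radii in Å; defaults to the Bondi set."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if r <= 0:
                raise DescriptorError(f"non-positive radius for {el}")

    def get(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise DescriptorError(
                f"no van der Waals radius for element {element!r}"
            ) from None


@dataclass(frozen=True)
class SurfaceParams:
    """Sampling parameters for surface and volume integration.

    probe_radius : solvent probe in Å (water: 1.4).
    sphere_points : lattice points per atom sphere; accuracy ~O(1/n).
    grid_spacing : Cartesian grid step in Å for volume integration.
    seed : RNG seed, used only when ``jitter`` is enabled.
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    grid_spacing: float = 0.2
    seed: int = 0
    jitter: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise DescriptorError("probe_radius must be >= 0")
        if self.sphere_points < 32:
            raise DescriptorError("sphere_points must be >= 32")
        if self.grid_spacing <= 0:
            raise DescriptorError("grid_spacing must be > 0")


def _require_3d(mol: MoleculeRecord) -> None:
    if not mol.has_3d:
        raise DescriptorError(f"molecule {mol.id!r} has no 3D coordinates")
    if not mol.atoms:
        raise DescriptorError(f"molecule {mol.id!r} has no atoms")


# ---------------------------------------------------------------------------
# Count / weight descriptors
# ---------------------------------------------------------------------------

def molecular_weight(mol: MoleculeRecord, masses: dict[str, float] | None = None) -> float:
    """Sum of standard atomic masses over all (explicit) atoms, in Da."""
    masses = masses or ATOMIC_MASSES
    total = 0.0
    for a in mol.atoms:
        try:
            total += masses[a.element]
        except KeyError:
            raise DescriptorError(
                f"unknown element {a.element!r} in molecule {mol.id!r}"
            ) from None
    return total


#: default structural pattern set for H-bond counting; editable.  Donors use
#: the heavy-atom convention: one donor per N/O carrying >=1 hydrogen.
DEFAULT_HBOND_PATTERNS = {
    "acceptor_elements": ("N", "O"),
    "donor_elements": ("N", "O"),
}


def count_hba(mol: MoleculeRecord, patterns: dict | None = None) -> int:
    """Hydrogen-bond acceptor count: one per acceptor-element heavy atom."""
    patterns = patterns or DEFAULT_HBOND_PATTERNS
    acceptors = set(patterns["acceptor_elements"])
    return sum(1 for a in mol.atoms if a.element in acceptors)


def count_hbd(mol: MoleculeRecord, patterns: dict | None = None) -> int:
    """Hydrogen-bond donor count, heavy-atom convention.

    An N/O atom with at least one attached hydrogen counts once, however
    many hydrogens it carries (so water has HBD = 1).
    """
    patterns = patterns or DEFAULT_HBOND_PATTERNS
    donors = set(patterns["donor_elements"])
    n = 0
    for i, a in enumerate(mol.atoms):
        if a.element not in donors:
            continue
        if any(mol.atoms[j].element == "H" for j in mol.neighbors(i)):
            n += 1
    return n


def _ring_bonds(mol: MoleculeRecord) -> set[frozenset[int]]:
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    ring: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(g):
        for k in range(len(cycle)):
            ring.add(frozenset((cycle[k], cycle[(k + 1) % len(cycle)])))
    return ring


def _is_amide_cn(mol: MoleculeRecord, i: int, j: int) -> bool:
    # amide C-N: the carbon end carries a double bond to oxygen
    for c, n in ((i, j), (j, i)):
        if mol.atoms[c].element == "C" and mol.atoms[n].element == "N":
            for b in mol.bonds:
                if b.order == 2 and {b.i, b.j} & {c}:
                    other = b.j if b.i == c else b.i
                    if {b.i, b.j} == {c, other} and mol.atoms[other].element == "O":
                        return True
    return False


def count_rotatable_bonds(mol: MoleculeRecord) -> int:
    """Single, acyclic, non-terminal heavy-atom bonds; amide C-N excluded."""
    ring = _ring_bonds(mol)
    heavy_degree = [0] * len(mol.atoms)
    for b in mol.bonds:
        if mol.atoms[b.i].element != "H" and mol.atoms[b.j].element != "H":
            heavy_degree[b.i] += 1
            heavy_degree[b.j] += 1
    n = 0
    for b in mol.bonds:
        if b.order != 1:
            continue
        if mol.atoms[b.i].element == "H" or mol.atoms[b.j].element == "H":
            continue
        if frozenset((b.i, b.j)) in ring:
            continue
        if heavy_degree[b.i] < 2 or heavy_degree[b.j] < 2:
            continue  # terminal
        if _is_amide_cn(mol, b.i, b.j):
            continue
        n += 1
    return n


# ---------------------------------------------------------------------------
# Surface area and volume
# ---------------------------------------------------------------------------

def _sphere_lattice(n: int, seed: int, jitter: bool) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere lattice (n x 3)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    if jitter:
        rng = np.random.default_rng(seed)
        phi = phi + rng.uniform(0, 2 * math.pi / n, size=n)
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    return np.column_stack(
        (sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta)
    )


def _inflated(mol: MoleculeRecord, params: SurfaceParams,
              radii: AtomRadiusTable) -> tuple[np.ndarray, np.ndarray]:
    coords = np.array([[a.x, a.y, a.z] for a in mol.atoms])
    rr = np.array([radii.get(a.element) + params.probe_radius for a in mol.atoms])
    return coords, rr


def sasa_per_atom(
    mol: MoleculeRecord,
    params: SurfaceParams | None = None,
    radii: AtomRadiusTable | None = None,
) -> np.ndarray:
    """Solvent-accessible surface area of each atom, Å²."""
    params = params or SurfaceParams()
    radii = radii or AtomRadiusTable()
    _require_3d(mol)
    coords, rr = _inflated(mol, params, radii)
    lattice = _sphere_lattice(params.sphere_points, params.seed, params.jitter)
    n_atoms = len(coords)
    areas = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + rr[i] * lattice
        buried = np.zeros(len(pts), dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            buried |= d2 < rr[j] ** 2
        frac = 1.0 - buried.mean()
        areas[i] = frac * 4.0 * math.pi * rr[i] ** 2
    return areas


def sasa_total(
    mol: MoleculeRecord,
    params: SurfaceParams | None = None,
    radii: AtomRadiusTable | None = None,
) -> float:
    """Total solvent-accessible surface area S_mol, Å²."""
    return float(sasa_per_atom(mol, params, radii).sum())


def sasa_hydrophobic(
    mol: MoleculeRecord,
    params: SurfaceParams | None = None,
    radii: AtomRadiusTable | None = None,
    hydrophobic_elements: frozenset[str] = HYDROPHOBIC_ELEMENTS,
) -> float:
    """Hydrophobic surface S_mol,hfob: SASA summed over carbon, Cl/Br/I and
    carbon-attached hydrogens.  Burial is still tested against all atoms."""
    areas = sasa_per_atom(mol, params, radii)
    total = 0.0
    for i, a in enumerate(mol.atoms):
        if a.element in hydrophobic_elements:
            total += areas[i]
        elif a.element == "H" and any(
            mol.atoms[j].element == "C" for j in mol.neighbors(i)
        ):
            total += areas[i]
    return float(total)


def molecular_volume(
    mol: MoleculeRecord,
    params: SurfaceParams | None = None,
    radii: AtomRadiusTable | None = None,
) -> float:
    """Volume enclosed by the solvent-accessible surface V_mol, Å³.

    Integrates the union of probe-inflated atom spheres on a uniform grid;
    the error is bounded by the grid spacing (default 0.2 Å).
    """
    params = params or SurfaceParams()
    radii = radii or AtomRadiusTable()
    _require_3d(mol)
    coords, rr = _inflated(mol, params, radii)
    h = params.grid_spacing
    lo = (coords - rr[:, None]).min(axis=0) - h
    hi = (coords + rr[:, None]).max(axis=0) + h
    axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    inside = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])), dtype=bool)
    for c, r in zip(coords, rr):
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        inside |= d2 < r * r
    return float(inside.sum()) * h**3


def globularity(v_mol: float, s_mol: float) -> float:
    """Glob = 4πr²/S_mol with r the radius of the equal-volume sphere.

    1.0 for a perfect sphere; smaller for elongated shapes (isoperimetric
    inequality), up to sampling noise.
    """
    if v_mol <= 0 or s_mol <= 0:
        raise DescriptorError("globularity requires positive volume and area")
    r = (3.0 * v_mol / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 4.0 * math.pi * r**2 / s_mol


def cohesion_index(hba: int, hbd: int, s_mol: float) -> float:
    """Cohesion-in-solids index Ind_coh = HBA × HBD / S_mol."""
    if s_mol <= 0:
        raise DescriptorError("cohesion_index requires S_mol > 0")
    if hba < 0 or hbd < 0:
        raise DescriptorError("H-bond counts must be non-negative")
    return hba * hbd / s_mol


# ---------------------------------------------------------------------------
# log P backends
# ---------------------------------------------------------------------------

# Crude per-element lipophilicity contributions for the shipped default
# backend; sums over all explicit atoms.  Deliberately simple and fully
# documented — swap in a better backend via register_logp_backend.
ATOM_LOGP_CONTRIB: dict[str, float] = {
    "C": 0.36, "H": 0.12, "N": -0.80, "O": -0.65, "S": 0.40, "P": -0.50,
    "F": 0.22, "Cl": 0.65, "Br": 0.85, "I": 1.10,
}


def _logp_zero(mol: MoleculeRecord) -> float:
    return 0.0


def _logp_atom_contrib(mol: MoleculeRecord) -> float:
    total = 0.0
    for a in mol.atoms:
        try:
            total += ATOM_LOGP_CONTRIB[a.element]
        except KeyError:
            raise DescriptorError(
                f"no log P contribution for element {a.element!r}"
            ) from None
    return total


def _logp_crippen(mol: MoleculeRecord) -> float:
    # Wildman-Crippen via RDKit; requires a "smiles" property on the record
    from rdkit import Chem
    from rdkit.Chem import Crippen

    smi = mol.properties.get("smiles")
    if not smi:
        raise DescriptorError(
            f"crippen backend needs a 'smiles' property on {mol.id!r}"
        )
    m = Chem.MolFromSmiles(smi)
    if m is None:
        raise DescriptorError(f"invalid SMILES on {mol.id!r}")
    return float(Crippen.MolLogP(m))


_LOGP_BACKENDS = {
    "zero": _logp_zero,
    "atom_contrib": _logp_atom_contrib,
    "crippen": _logp_crippen,
}


def register_logp_backend(name: str, fn) -> None:
    """Register a custom log P estimator callable(MoleculeRecord) -> float."""
    _LOGP_BACKENDS[name] = fn


def estimate_logp(mol: MoleculeRecord, backend: str = "atom_contrib") -> float:
    """Estimate log P with a pluggable backend; deterministic per backend."""
    try:
        fn = _LOGP_BACKENDS[backend]
    except KeyError:
        raise DescriptorError(
            f"unregistered log P backend {backend!r}; "
            f"known: {sorted(_LOGP_BACKENDS)}"
        ) from None
    return float(fn(mol))
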