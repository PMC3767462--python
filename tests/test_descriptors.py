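"""Geometry and count descriptors against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from admetprofiler import (
    AtomRadiusTable,
    SurfaceParams,
    cohesion_index,
    count_hba,
    count_hbd,
    count_rotatable_bonds,
    estimate_logp,
    globularity,
    molecular_volume,
    molecular_weight,
    sasa_hydrophobic,
    sasa_total,
)
from admetprofiler.chem_io import Atom, Bond, MoleculeRecord
from admetprofiler.descriptors import (
    ATOM_LOGP_CONTRIB,
    BONDI_RADII,
    DescriptorError,
)

from conftest import two_sphere_sasa, two_sphere_volume

R_C = BONDI_RADII["C"] + 1.4  # probe-inflated carbon radius


# ---------------------------------------------------------------------------
# molecular weight
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mol_id,expected", [
    ("H_atom", 1.008),
    ("benzene", 78.11),
    ("water", 18.015),
])
def test_molecular_weight(fixture_mols, mol_id, expected):
    assert molecular_weight(fixture_mols[mol_id]) == pytest.approx(
        expected, abs=0.01
    )


def test_unknown_element_errors():
    mol = MoleculeRecord("x", atoms=[Atom("Xx", 0, 0, 0)])
    with pytest.raises(DescriptorError, match="Xx"):
        molecular_weight(mol)


# ---------------------------------------------------------------------------
# H-bond and rotatable-bond counts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mol_id,hba,hbd", [
    ("methane", 0, 0),
    ("water", 1, 1),   # heavy-atom donor convention: one donor O
    ("ethanol", 1, 1),
])
def test_hbond_counts(fixture_mols, mol_id, hba, hbd):
    assert count_hba(fixture_mols[mol_id]) == hba
    assert count_hbd(fixture_mols[mol_id]) == hbd


def _chain(n_carbons):
    """Linear all-anti alkane with explicit hydrogens (geometry unused)."""
    atoms = [Atom("C", 1.54 * k, 0, 0) for k in range(n_carbons)]
    bonds = [Bond(k, k + 1) for k in range(n_carbons - 1)]
    nh = len(atoms)
    for k in range(n_carbons):
        count = 4 - (0 < k < n_carbons - 1) * 2 - (n_carbons > 1)
        for j in range(count):
            atoms.append(Atom("H", 1.54 * k, 1.0 + 0.3 * j, 0.5))
            bonds.append(Bond(k, nh))
            nh += 1
    return MoleculeRecord(f"C{n_carbons}", atoms=atoms, bonds=bonds)


@pytest.mark.parametrize("n_c,expected", [(2, 0), (4, 1), (5, 2)])
def test_rotatable_bonds_alkanes(n_c, expected):
    assert count_rotatable_bonds(_chain(n_c)) == expected


def test_rotatable_bonds_ring_and_amide(fixture_mols):
    assert count_rotatable_bonds(fixture_mols["benzene"]) == 0
    # N-methylacetamide: CH3-C(=O)-NH-CH3; the central C-N is excluded,
    # both C-C and N-C are terminal -> 0 rotatable
    atoms = [
        Atom("C", 0, 0, 0), Atom("C", 1.5, 0, 0), Atom("O", 2.1, 1.1, 0),
        Atom("N", 2.2, -1.2, 0), Atom("C", 3.6, -1.3, 0),
        Atom("H", 2.0, -2.2, 0),
    ]
    bonds = [Bond(0, 1), Bond(1, 2, 2.0), Bond(1, 3), Bond(3, 4), Bond(3, 5)]
    assert count_rotatable_bonds(MoleculeRecord("nma", atoms=atoms,
                                                bonds=bonds)) == 0


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_sasa_single_atom_analytic(fixture_mols):
    assert sasa_total(fixture_mols["C_atom"]) == pytest.approx(
        4 * math.pi * R_C**2, rel=0.01
    )


def test_sasa_additivity_far_pair(fixture_mols):
    single = sasa_total(fixture_mols["C_atom"])
    assert sasa_total(fixture_mols["C2_far"]) == pytest.approx(
        2 * single, rel=0.005
    )


def test_sasa_overlapping_dimer_closed_form(fixture_mols):
    expected = two_sphere_sasa(R_C, 1.5)
    assert sasa_total(fixture_mols["C2_dimer"]) == pytest.approx(
        expected, rel=0.01
    )


def test_sasa_probe_monotone_and_exact_on_sphere(fixture_mols):
    mol = fixture_mols["C_atom"]
    prev = 0.0
    for probe in (0.0, 0.7, 1.4, 2.0):
        s = sasa_total(mol, SurfaceParams(probe_radius=probe))
        analytic = 4 * math.pi * (BONDI_RADII["C"] + probe) ** 2
        assert s == pytest.approx(analytic, rel=1e-9)
        assert s > prev
        prev = s


def test_sasa_convergence(fixture_mols):
    mol = fixture_mols["ethanol"]
    a = sasa_total(mol, SurfaceParams(sphere_points=960))
    b = sasa_total(mol, SurfaceParams(sphere_points=1920))
    assert abs(a - b) / b < 0.005


def test_sasa_requires_coordinates():
    mol = MoleculeRecord("flat", atoms=[Atom("C", 0, 0, 0)], has_3d=False)
    with pytest.raises(DescriptorError, match="3D"):
        sasa_total(mol)


def test_sasa_cross_check_against_freesasa():
    """Independent oracle: FreeSASA (via RDKit) on an embedded 3D molecule."""
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdFreeSASA

    m = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    AllChem.EmbedMolecule(m, randomSeed=12)
    conf = m.GetConformer()
    atoms = [
        Atom(a.GetSymbol(), *map(float, conf.GetAtomPosition(a.GetIdx())))
        for a in m.GetAtoms()
    ]
    rec = MoleculeRecord("ethanol3d", atoms=atoms)
    radii = [BONDI_RADII[a.GetSymbol()] for a in m.GetAtoms()]
    opts = rdFreeSASA.SASAOpts(
        rdFreeSASA.SASAAlgorithm.ShrakeRupley,
        rdFreeSASA.SASAClassifier.Protor, 1.4,
    )
    reference = rdFreeSASA.CalcSASA(m, radii, confIdx=-1, opts=opts)
    ours = sasa_total(rec, SurfaceParams(sphere_points=1920))
    assert ours == pytest.approx(reference, rel=0.02)


# ---------------------------------------------------------------------------
# hydrophobic SASA
# ---------------------------------------------------------------------------

def test_hydrophobic_sasa_bounds(fixture_mols):
    methane = fixture_mols["methane"]
    assert sasa_hydrophobic(methane) == pytest.approx(sasa_total(methane))
    assert sasa_hydrophobic(fixture_mols["water"]) == 0.0
    eth = fixture_mols["ethanol"]
    hfob = sasa_hydrophobic(eth)
    assert 0.0 < hfob < sasa_total(eth)


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

def test_volume_single_atom_analytic(fixture_mols):
    assert molecular_volume(fixture_mols["C_atom"]) == pytest.approx(
        4.0 / 3.0 * math.pi * R_C**3, rel=0.01
    )


def test_volume_additivity_and_overlap(fixture_mols):
    single = molecular_volume(fixture_mols["C_atom"])
    assert molecular_volume(fixture_mols["C2_far"]) == pytest.approx(
        2 * single, rel=0.01
    )
    assert molecular_volume(fixture_mols["C2_dimer"]) == pytest.approx(
        two_sphere_volume(R_C, 1.5), rel=0.01
    )


# ---------------------------------------------------------------------------
# globularity & cohesion index
# ---------------------------------------------------------------------------

def test_globularity_sphere_and_dimer_limits():
    r = 2.0
    v, s = 4 / 3 * math.pi * r**3, 4 * math.pi * r**2
    assert globularity(v, s) == pytest.approx(1.0)
    assert globularity(2 * v, 2 * s) == pytest.approx(2 ** (-1 / 3), abs=1e-9)
    with pytest.raises(DescriptorError):
        globularity(-1.0, 10.0)


def test_globularity_of_fixtures_bounded(fixture_mols):
    for mol_id in ("methane", "water", "ethanol", "benzene"):
        mol = fixture_mols[mol_id]
        g = globularity(molecular_volume(mol), sasa_total(mol))
        assert 0.0 < g <= 1.02  # isoperimetric bound + sampling tolerance


def test_cohesion_index():
    assert cohesion_index(0, 5, 400.0) == 0.0
    assert cohesion_index(4, 2, 500.0) == pytest.approx(0.016)
    assert cohesion_index(4, 2, 1000.0) == pytest.approx(0.008)
    with pytest.raises(DescriptorError):
        cohesion_index(4, 2, 0.0)


# ---------------------------------------------------------------------------
# log P backends
# ---------------------------------------------------------------------------

def test_logp_backends(fixture_mols):
    eth = fixture_mols["ethanol"]
    assert estimate_logp(eth, "zero") == 0.0
    assert estimate_logp(eth, "atom_contrib") == estimate_logp(
        eth, "atom_contrib"
    )
    # hand summation of the shipped contribution table: 2 C, 6 H, 1 O
    expected = (
        2 * ATOM_LOGP_CONTRIB["C"]
        + 6 * ATOM_LOGP_CONTRIB["H"]
        + ATOM_LOGP_CONTRIB["O"]
    )
    assert estimate_logp(eth, "atom_contrib") == pytest.approx(expected)
    with pytest.raises(DescriptorError, match="nosuch"):
        estimate_logp(eth, "nosuch")


def test_radius_table_invariants():
    with pytest.raises(DescriptorError):
        AtomRadiusTable({"C": -1.0})
    with pytest.raises(DescriptorError, match="Xq"):
        AtomRadiusTable().get("Xq")
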