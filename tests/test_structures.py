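"""Complex parsing, pharmacophore role rules and contact detection."""

import numpy as np
import pytest

from pharmboost.errors import (
    AmbiguousLigandError,
    LigandSelectorError,
    MalformedInputError,
)
from pharmboost.structures import (
    InteractionParams,
    InteractionType,
    PharmRole,
    assign_pharm_roles,
    detect_interactions,
    interactions_to_tsv,
    read_complex,
)

from conftest import make_atom, make_complex, pdb_line

IT = InteractionType
PR = PharmRole


# ---------------------------------------------------------------------------
# read_complex


def test_minimal_two_record_pdb():
    text = "\n".join([
        pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_line("HETATM", 2, "C1", "LIG", "A", 9, 5.0, 0.0, 0.0, "C"),
    ]) + "\n"
    cx = read_complex(text, "LIG")
    assert len(cx.protein_atoms) == 1
    assert len(cx.ligand_atoms) == 1
    assert cx.ligand_atoms[0].is_ligand


def test_selector_matching_nothing_raises():
    text = "\n".join([
        pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_line("HETATM", 2, "C1", "LIG", "A", 9, 5.0, 0.0, 0.0, "C"),
    ]) + "\n"
    with pytest.raises(LigandSelectorError):
        read_complex(text, "XYZ")


def test_fixture_counts_waters_dropped(fixture_pdb_text):
    cx = read_complex(fixture_pdb_text, "LIG")
    assert len(cx.protein_atoms) == 10
    assert len(cx.ligand_atoms) == 5
    assert all(a.residue_name != "HOH"
               for a in cx.protein_atoms + cx.ligand_atoms)
    # coordinates preserved to PDB precision
    o1 = cx.ligand_atom_by_serial(12)
    assert o1.coords == (5.0, 5.9, 1.7)
    assert o1.formal_charge == -1


def test_ambiguous_selector_lists_candidates():
    text = "\n".join([
        pdb_line("ATOM", 1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_line("HETATM", 2, "C1", "LIG", "A", 9, 5.0, 0.0, 0.0, "C"),
        pdb_line("HETATM", 3, "C1", "LIG", "B", 9, 8.0, 0.0, 0.0, "C"),
    ]) + "\n"
    with pytest.raises(AmbiguousLigandError) as exc:
        read_complex(text, "LIG")
    assert len(exc.value.candidates) == 2
    # a chain-qualified selector resolves it
    cx = read_complex(text, "LIG:B:9")
    assert len(cx.ligand_atoms) == 1
    assert cx.ligand_atoms[0].chain_id == "B"


def test_no_protein_atoms_is_malformed():
    text = pdb_line("HETATM", 1, "C1", "LIG", "A", 9, 0.0, 0.0, 0.0, "C") + "\n"
    with pytest.raises(MalformedInputError):
        read_complex(text, "LIG")


# ---------------------------------------------------------------------------
# role assignment


def _carboxylate_ligand():
    # CH3-C(=O)O(-): C2 methyl, C1 carboxyl carbon, O1 charged, O2 neutral
    c2 = make_atom(1, "C", -1.5, 0.0, 0.0)
    c1 = make_atom(2, "C", 0.0, 0.0, 0.0)
    o1 = make_atom(3, "O", 0.6, 1.05, 0.0, charge=-1)
    o2 = make_atom(4, "O", 0.6, -1.05, 0.0)
    bonds = {1: {2}, 2: {1, 3, 4}, 3: {2}, 4: {2}}
    prot = [make_atom(99, "C", 50.0, 50.0, 50.0, name="CA", res="GLY",
                      chain="A", seq=1, is_ligand=False)]
    return make_complex(prot, [c2, c1, o1, o2], bonds)


def test_carboxylate_oxygens_are_anionic_acceptors():
    cx = assign_pharm_roles(_carboxylate_ligand())
    assert cx.ligand_roles[3] == {PR.ACCEPTOR, PR.ANION}
    # the charge is delocalised: the sibling terminal O matches the same rule
    assert cx.ligand_roles[4] == {PR.ACCEPTOR, PR.ANION}


def test_aliphatic_carbon_is_hydrophobe():
    cx = assign_pharm_roles(_carboxylate_ligand())
    assert cx.ligand_roles[1] == {PR.HYDROPHOBE}      # methyl C, only C neighbour
    assert cx.ligand_roles[2] == frozenset()          # carboxyl C touches O


def test_ligand_without_nos_has_no_hbond_roles():
    atoms = [make_atom(i, "C", float(i) * 10, 0.0, 0.0) for i in range(1, 4)]
    prot = [make_atom(99, "C", 50.0, 50.0, 50.0, name="CA", res="GLY",
                      chain="A", seq=1, is_ligand=False)]
    cx = assign_pharm_roles(make_complex(prot, atoms))
    donors = {PR.DONOR, PR.ACCEPTOR, PR.DONOR_OR_ACCEPTOR}
    assert all(not (roles & donors) for roles in cx.ligand_roles.values())


def test_unknown_element_warns_and_gets_no_roles():
    b = make_atom(1, "XE", 0.0, 0.0, 0.0)
    prot = [make_atom(99, "C", 50.0, 50.0, 50.0, name="CA", res="GLY",
                      chain="A", seq=1, is_ligand=False)]
    with pytest.warns(UserWarning, match="no role rule"):
        cx = assign_pharm_roles(make_complex(prot, [b]))
    assert cx.ligand_roles[1] == frozenset()


# ---------------------------------------------------------------------------
# interaction detection


def test_carboxylate_near_lysine_gives_single_ionic_interaction():
    o1 = make_atom(1, "O", 0.0, 0.0, 0.0, charge=-1)
    nz = make_atom(50, "N", 3.0, 0.0, 0.0, name="NZ", res="LYS", chain="A",
                   seq=7, is_ligand=False)
    cx = assign_pharm_roles(make_complex([nz], [o1]))
    found = detect_interactions(cx)
    assert len(found) == 1                       # the salt bridge, not also an HB
    assert found[0].itype is IT.IONIC_LIG_ANION
    assert found[0].contact_distance == pytest.approx(3.0)


def test_all_atoms_beyond_cutoffs_gives_empty_list():
    lig = [make_atom(1, "O", 0.0, 0.0, 0.0, charge=-1),
           make_atom(2, "C", 2.0, 0.0, 0.0)]
    prot = [make_atom(50, "NZ"[:1], 8.0, 0.0, 0.0, name="NZ", res="LYS",
                      chain="A", seq=7, is_ligand=False)]
    cx = assign_pharm_roles(make_complex(prot, lig, {1: {2}, 2: {1}}))
    assert detect_interactions(cx) == []


def test_hydroxyl_without_hydrogens_gives_undetermined_hbond():
    # terminal O with a 1.43 A C-O bond: could be C-OH or deprotonated; the
    # ligand-side ambiguity makes the bond undetermined even against a pure
    # acceptor (backbone carbonyl O).
    o = make_atom(1, "O", 0.0, 0.0, 0.0)
    c = make_atom(2, "C", 1.43, 0.0, 0.0)
    bb_o = make_atom(50, "O", -2.9, 0.0, 0.0, name="O", res="GLY", chain="A",
                     seq=3, is_ligand=False)
    cx = assign_pharm_roles(make_complex([bb_o], [o, c], {1: {2}, 2: {1}}))
    found = detect_interactions(cx)
    assert [x.itype for x in found] == [IT.HB_UNDETERMINED]


def test_detection_is_rigid_motion_invariant(rng):
    base_cx = _carboxylate_ligand()
    prot = [
        make_atom(50, "N", 0.6, 1.05, 3.0, name="NZ", res="LYS", chain="A",
                  seq=7, is_ligand=False),
        make_atom(51, "C", -1.5, 0.0, 4.0, name="CD1", res="LEU", chain="A",
                  seq=8, is_ligand=False),
    ]
    cx = assign_pharm_roles(make_complex(prot, base_cx.ligand_atoms,
                                         {k: set(v) for k, v
                                          in base_cx.explicit_bonds.items()}))
    base = detect_interactions(cx)
    assert len(base) >= 2                       # ionic + hydrophobic present
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    moved = detect_interactions(cx.transformed(Q, np.array([3.0, -7.0, 11.0])))
    assert [(x.itype, x.ligand_atom.serial, x.protein_atom.serial)
            for x in base] == [
        (x.itype, x.ligand_atom.serial, x.protein_atom.serial) for x in moved]
    for a, b in zip(base, moved):
        assert a.contact_distance == pytest.approx(b.contact_distance, abs=1e-9)


def test_enlarging_cutoffs_never_removes_interactions():
    o1 = make_atom(1, "O", 0.0, 0.0, 0.0, charge=-1)
    c1 = make_atom(2, "C", 4.0, 0.0, 0.0)
    nz = make_atom(50, "N", 3.2, 0.0, 0.0, name="NZ", res="LYS", chain="A",
                   seq=7, is_ligand=False)
    cd = make_atom(51, "C", 4.0, 4.2, 0.0, name="CD1", res="LEU", chain="A",
                   seq=8, is_ligand=False)
    cx = assign_pharm_roles(make_complex([nz, cd], [o1, c1]))
    small = detect_interactions(cx, InteractionParams(
        hbond_max_dist=3.0, ionic_max_dist=3.5, hydrophobic_max_dist=4.0))
    large = detect_interactions(cx, InteractionParams(
        hbond_max_dist=3.6, ionic_max_dist=4.5, hydrophobic_max_dist=5.0))
    small_keys = {(x.itype, x.ligand_atom.serial, x.protein_atom.serial)
                  for x in small}
    large_keys = {(x.itype, x.ligand_atom.serial, x.protein_atom.serial)
                  for x in large}
    assert small_keys <= large_keys
    assert (IT.HYDROPHOBIC, 2, 51) in large_keys - small_keys


def test_two_runs_are_byte_identical(fixture_pdb_text):
    def run():
        cx = assign_pharm_roles(read_complex(fixture_pdb_text, "LIG"))
        return interactions_to_tsv(cx.complex_id, detect_interactions(cx))

    assert run() == run()


def test_interaction_tsv_layout():
    o1 = make_atom(1, "O", 0.0, 0.0, 0.0, charge=-1)
    nz = make_atom(50, "N", 3.0, 0.0, 0.0, name="NZ", res="LYS", chain="A",
                   seq=7, is_ligand=False)
    cx = assign_pharm_roles(make_complex([nz], [o1]))
    tsv = interactions_to_tsv("c1", detect_interactions(cx))
    lines = tsv.strip().splitlines()
    assert lines[0].split("\t") == [
        "complex_id", "itype", "ligand_serial", "protein_serial", "distance"]
    assert lines[1].split("\t") == ["c1", "IONIC_LIG_ANION", "1", "50", "3.0000"]
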