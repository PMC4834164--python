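"""Shared fixtures: hand-built PDB text and tiny synthetic configurations."""

import numpy as np
import pytest

from pharmboost.structures import Atom, ProteinComplex
from pharmboost.synthetic import SynthConfig


def pdb_line(rec, serial, name, res, chain, seq, x, y, z, elem, charge=""):
    name_f = name if len(name) >= 4 else f" {name:<3}"
    return (f"{rec:<6}{serial:>5} {name_f:<4} {res:<3} {chain}{seq:>4} "
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{elem:>2}{charge:<2}")


@pytest.fixture
def fixture_pdb_text():
    """10 protein atoms (GLY + SER), a 5-atom carboxylate ligand, 3 waters.

    The ligand carboxylate O1 (charge -1) sits 3.0 A from the serine OG;
    the ligand methyl carbon sits 4.0 A from the GLY backbone (too specific
    contacts are not the point here - the parser counts are).
    """
    lines = [
        # GLY backbone (4 atoms)
        pdb_line("ATOM", 1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line("ATOM", 2, "CA", "GLY", "A", 1, 1.45, 0.0, 0.0, "C"),
        pdb_line("ATOM", 3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0, "C"),
        pdb_line("ATOM", 4, "O", "GLY", "A", 1, 1.3, 2.4, 0.0, "O"),
        # SER (6 atoms)
        pdb_line("ATOM", 5, "N", "SER", "A", 2, 3.3, 1.5, 0.0, "N"),
        pdb_line("ATOM", 6, "CA", "SER", "A", 2, 4.0, 2.75, 0.0, "C"),
        pdb_line("ATOM", 7, "C", "SER", "A", 2, 5.5, 2.6, 0.0, "C"),
        pdb_line("ATOM", 8, "O", "SER", "A", 2, 6.1, 1.55, 0.0, "O"),
        pdb_line("ATOM", 9, "CB", "SER", "A", 2, 3.6, 3.6, 1.2, "C"),
        pdb_line("ATOM", 10, "OG", "SER", "A", 2, 4.1, 4.9, 1.1, "O"),
        # ligand: acetate-like CC(=O)O- plus a methyl and an amine N (5 atoms)
        pdb_line("HETATM", 11, "C1", "LIG", "A", 101, 6.0, 6.0, 1.0, "C"),
        pdb_line("HETATM", 12, "O1", "LIG", "A", 101, 5.0, 5.9, 1.7, "O", "1-"),
        pdb_line("HETATM", 13, "O2", "LIG", "A", 101, 7.0, 6.6, 1.5, "O"),
        pdb_line("HETATM", 14, "C2", "LIG", "A", 101, 6.1, 5.4, -0.37, "C"),
        pdb_line("HETATM", 15, "N1", "LIG", "A", 101, 7.3, 4.6, -0.5, "N"),
        # waters
        pdb_line("HETATM", 16, "O", "HOH", "A", 201, 9.0, 9.0, 9.0, "O"),
        pdb_line("HETATM", 17, "O", "HOH", "A", 202, 10.0, 9.0, 9.0, "O"),
        pdb_line("HETATM", 18, "O", "HOH", "A", 203, 11.0, 9.0, 9.0, "O"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def make_atom(serial, element, x, y, z, *, name=None, res="LIG", chain="L",
              seq=900, charge=0, is_ligand=True):
    return Atom(serial=serial, element=element,
                name=name or f"{element}{serial}", residue_name=res,
                chain_id=chain, residue_seq=seq, coords=(x, y, z),
                formal_charge=charge, is_ligand=is_ligand)


def make_complex(protein_atoms, ligand_atoms, bonds=None, cid="test"):
    bonds = bonds or {}
    # fully explicit ligand connectivity so geometry cannot add surprise bonds
    for a in ligand_atoms:
        bonds.setdefault(a.serial, set())
    return ProteinComplex(complex_id=cid, protein_atoms=protein_atoms,
                          ligand_atoms=ligand_atoms, explicit_bonds=bonds)


@pytest.fixture
def tiny_synth_config():
    """Reduced-size benchmark for fast classifier tests."""
    return SynthConfig(n_active_train=30, n_decoy_train=300,
                       n_active_test_compounds=20, n_decoy_test=150,
                       poses_per_compound=2, n_scaffolds=10, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
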