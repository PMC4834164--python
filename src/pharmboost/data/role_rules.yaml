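# Default pharmacophore role rules.
#
# ligand_rules: ordered, first match wins, evaluated per atom against the
# element rules below.  Predicates:
#   element            - chemical element symbol (required)
#   charge             - "negative" | "positive" | "zero" | integer; effective
#                        formal charge after carboxylate-style group spreading
#   has_hydrogen       - atom has an explicit bonded hydrogen in the file
#   min_heavy_degree / max_heavy_degree - count of bonded non-H neighbours
#   neighbors_only     - all bonded neighbours drawn from this element list
#                        (vacuously true for an unbonded atom)
#   short_bond_to      - {element, max_length}: a bonded neighbour of that
#                        element at most max_length angstrom away (e.g. a
#                        1.23 A C=O distinguishes carbonyl from hydroxyl O)
#
# protein_roles: residue/atom lookup applied to standard residues before the
# element rules; "*" matches any residue (backbone atoms).  Charged entries
# carry CATION/ANION directly, so no charge column is needed on ATOM records.

ligand_rules:
  # --- oxygen ---
  - element: O
    charge: negative
    roles: [ACCEPTOR, ANION]
  - element: O
    has_hydrogen: true
    roles: [DONOR, ACCEPTOR]
  - element: O
    max_heavy_degree: 1
    short_bond_to: {element: C, max_length: 1.30}
    roles: [ACCEPTOR]            # carbonyl / carboxyl C=O
  - element: O
    min_heavy_degree: 2
    roles: [ACCEPTOR]            # ether / ester bridging O
  - element: O
    roles: [DONOR_OR_ACCEPTOR]   # terminal O, no explicit H: C-OH vs C=O open
  # --- nitrogen ---
  - element: N
    charge: positive
    roles: [DONOR, CATION]
  - element: N
    has_hydrogen: true
    roles: [DONOR]
  - element: N
    min_heavy_degree: 3
    roles: [ACCEPTOR]            # tertiary amine / substituted aromatic N
  - element: N
    roles: [DONOR_OR_ACCEPTOR]   # NH count unknown without explicit H
  # --- sulfur ---
  - element: S
    has_hydrogen: true
    roles: [DONOR]
  - element: S
    roles: [ACCEPTOR]            # thioether / thione: weak acceptor
  # --- carbon ---
  - element: C
    neighbors_only: [C, H]
    roles: [HYDROPHOBE]
  - element: C
    roles: []

protein_roles:
  "*":
    N:   [DONOR]                 # backbone amide NH
    O:   [ACCEPTOR]              # backbone carbonyl
    OXT: [ACCEPTOR, ANION]       # C-terminal carboxylate
  ALA: {CB: [HYDROPHOBE]}
  ARG:
    NE:  [DONOR, CATION]
    NH1: [DONOR, CATION]
    NH2: [DONOR, CATION]
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
  ASN: {OD1: [ACCEPTOR], ND2: [DONOR], CB: [HYDROPHOBE]}
  ASP: {OD1: [ACCEPTOR, ANION], OD2: [ACCEPTOR, ANION], CB: [HYDROPHOBE]}
  CYS: {SG: [DONOR]}
  GLN: {OE1: [ACCEPTOR], NE2: [DONOR], CB: [HYDROPHOBE], CG: [HYDROPHOBE]}
  GLU:
    OE1: [ACCEPTOR, ANION]
    OE2: [ACCEPTOR, ANION]
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
  GLY: {}
  HIS: {ND1: [DONOR_OR_ACCEPTOR], NE2: [DONOR_OR_ACCEPTOR], CB: [HYDROPHOBE]}
  ILE:
    CB:  [HYDROPHOBE]
    CG1: [HYDROPHOBE]
    CG2: [HYDROPHOBE]
    CD1: [HYDROPHOBE]
  LEU:
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
    CD1: [HYDROPHOBE]
    CD2: [HYDROPHOBE]
  LYS:
    NZ:  [DONOR, CATION]
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
    CD:  [HYDROPHOBE]
  MET: {SD: [ACCEPTOR], CB: [HYDROPHOBE], CE: [HYDROPHOBE]}
  PHE:
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
    CD1: [HYDROPHOBE]
    CD2: [HYDROPHOBE]
    CE1: [HYDROPHOBE]
    CE2: [HYDROPHOBE]
    CZ:  [HYDROPHOBE]
  PRO: {CB: [HYDROPHOBE], CG: [HYDROPHOBE]}
  SER: {OG: [DONOR, ACCEPTOR]}
  THR: {OG1: [DONOR, ACCEPTOR], CG2: [HYDROPHOBE]}
  TRP:
    NE1: [DONOR]
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
    CD2: [HYDROPHOBE]
    CE3: [HYDROPHOBE]
    CZ2: [HYDROPHOBE]
    CZ3: [HYDROPHOBE]
    CH2: [HYDROPHOBE]
  TYR:
    OH:  [DONOR, ACCEPTOR]
    CB:  [HYDROPHOBE]
    CG:  [HYDROPHOBE]
    CD1: [HYDROPHOBE]
    CD2: [HYDROPHOBE]
    CE1: [HYDROPHOBE]
    CE2: [HYDROPHOBE]
  VAL: {CB: [HYDROPHOBE], CG1: [HYDROPHOBE], CG2: [HYDROPHOBE]}
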