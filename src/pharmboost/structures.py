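"""Protein-ligand complexes: PDB input, pharmacophore roles, contact detection.

A complex is one protein chain set plus one bound ligand residue.  Ligand atoms
are classified into pharmacophore roles (H-bond donor/acceptor, cation, anion,
hydrophobe) by a data-driven rule table, and protein-ligand contacts are
detected as one of six interaction types:

    hydrogen bond with ligand acceptor / with ligand donor / undetermined role,
    ionic with ligand cation / with ligand anion, and hydrophobic.

Geometric cutoffs are configurable (`InteractionParams`); the defaults follow
common medicinal-chemistry conventions: heavy-atom H-bond distance 3.5 A (with
a D-H...A angle test only when explicit hydrogens are present), ionic 4.0 A
between opposite formal charges, apolar carbon-carbon 4.5 A.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import (
    AmbiguousLigandError,
    LigandSelectorError,
    MalformedInputError,
)

__all__ = [
    "Atom",
    "PharmRole",
    "InteractionType",
    "Interaction",
    "InteractionParams",
    "ProteinComplex",
    "RoleRules",
    "load_default_rules",
    "read_complex",
    "assign_pharm_roles",
    "detect_interactions",
    "interactions_to_tsv",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})

#: metal/halide ions take no part in detection (whether protein-bound metals
#: mediate ionic contacts is a modelling choice; excluded by default)
ION_RESNAMES = frozenset({"NA", "K", "MG", "CA", "ZN", "MN", "FE", "CL", "BR"})

# Covalent radii (angstrom) for distance-based bond perception.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
}
_BOND_SLACK = 0.4  # added to the covalent-radius sum


class PharmRole(Enum):
    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"
    DONOR_OR_ACCEPTOR = "DONOR_OR_ACCEPTOR"
    CATION = "CATION"
    ANION = "ANION"
    HYDROPHOBE = "HYDROPHOBE"


class InteractionType(Enum):
    HB_LIG_ACCEPTOR = "HB_LIG_ACCEPTOR"
    HB_LIG_DONOR = "HB_LIG_DONOR"
    HB_UNDETERMINED = "HB_UNDETERMINED"
    IONIC_LIG_CATION = "IONIC_LIG_CATION"
    IONIC_LIG_ANION = "IONIC_LIG_ANION"
    HYDROPHOBIC = "HYDROPHOBIC"


#: canonical declaration order, used for deterministic sorting
_ITYPE_ORDER = {t: i for i, t in enumerate(InteractionType)}


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record: identity, position (angstrom), formal charge."""

    serial: int
    element: str
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: tuple[float, float, float]
    formal_charge: int = 0
    is_ligand: bool = False
    insertion_code: str = ""

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.xyz - other.xyz))


@dataclass(frozen=True)
class Interaction:
    """A detected protein-ligand contact of one of the six types."""

    itype: InteractionType
    ligand_atom: Atom
    protein_atom: Atom
    contact_distance: float

    def __post_init__(self):
        if self.contact_distance <= 0:
            raise ValueError("contact distance must be positive")


@dataclass(frozen=True)
class InteractionParams:
    """Geometric cutoffs for contact detection (angstrom / degrees)."""

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    ionic_max_dist: float = 4.0
    hydrophobic_max_dist: float = 4.5

    def __post_init__(self):
        for name in ("hbond_max_dist", "ionic_max_dist", "hydrophobic_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.hbond_min_angle <= 180:
            raise ValueError("hbond_min_angle must be in (0, 180]")

    @property
    def max_dist(self) -> float:
        return max(self.hbond_max_dist, self.ionic_max_dist,
                   self.hydrophobic_max_dist)


@dataclass
class ProteinComplex:
    """Parsed protein + ligand atoms; the unit the fingerprint encoder consumes."""

    complex_id: str
    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    ligand_roles: dict[int, frozenset[PharmRole]] | None = None
    explicit_bonds: dict[int, set[int]] = field(default_factory=dict)

    def __post_init__(self):
        serials = [a.serial for a in self.protein_atoms + self.ligand_atoms]
        if len(serials) != len(set(serials)):
            raise MalformedInputError("duplicate atom serials in complex")
        if self.ligand_roles is not None:
            lig = {a.serial for a in self.ligand_atoms}
            bad = set(self.ligand_roles) - lig
            if bad:
                raise ValueError(f"ligand_roles keys {bad} are not ligand atoms")

    def ligand_atom_by_serial(self, serial: int) -> Atom:
        for a in self.ligand_atoms:
            if a.serial == serial:
                return a
        raise KeyError(serial)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinComplex":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def move(atom: Atom) -> Atom:
            return replace(atom, coords=tuple(R @ atom.xyz + t))

        return ProteinComplex(
            complex_id=self.complex_id,
            protein_atoms=[move(a) for a in self.protein_atoms],
            ligand_atoms=[move(a) for a in self.ligand_atoms],
            ligand_roles=dict(self.ligand_roles) if self.ligand_roles is not None else None,
            explicit_bonds={k: set(v) for k, v in self.explicit_bonds.items()},
        )


# ---------------------------------------------------------------------------
# role-rule table


class RoleRules:
    """Data-driven pharmacophore role table (element rules + protein lookup)."""

    def __init__(self, config: Mapping):
        self.ligand_rules: list[dict] = list(config.get("ligand_rules", []))
        self.protein_roles: dict[str, dict[str, list[str]]] = {
            str(res): {str(at): list(rs) for at, rs in table.items()}
            for res, table in (config.get("protein_roles") or {}).items()
        }

    @classmethod
    def from_yaml(cls, text: str) -> "RoleRules":
        return cls(yaml.safe_load(text))

    def protein_lookup(self, atom: Atom) -> frozenset[PharmRole] | None:
        """Residue/atom table hit, trying the residue first then backbone '*'."""
        for key in (atom.residue_name, "*"):
            table = self.protein_roles.get(key)
            if table and atom.name in table:
                return frozenset(PharmRole(r) for r in table[atom.name])
        return None

    def match(self, atom: Atom, neighbors: Sequence[Atom],
              effective_charge: int) -> frozenset[PharmRole] | None:
        """First matching ligand rule, or None if no rule covers the element."""
        heavy = [n for n in neighbors if n.element != "H"]
        has_h = any(n.element == "H" for n in neighbors)
        for rule in self.ligand_rules:
            if rule["element"] != atom.element:
                continue
            if "charge" in rule and not _charge_ok(rule["charge"], effective_charge):
                continue
            if "has_hydrogen" in rule and rule["has_hydrogen"] != has_h:
                continue
            if "min_heavy_degree" in rule and len(heavy) < rule["min_heavy_degree"]:
                continue
            if "max_heavy_degree" in rule and len(heavy) > rule["max_heavy_degree"]:
                continue
            if "neighbors_only" in rule:
                allowed = set(rule["neighbors_only"])
                if not all(n.element in allowed for n in neighbors):
                    continue
            if "short_bond_to" in rule:
                spec = rule["short_bond_to"]
                if not any(n.element == spec["element"]
                           and atom.distance_to(n) <= spec["max_length"]
                           for n in neighbors):
                    continue
            return frozenset(PharmRole(r) for r in rule["roles"])
        return None


def _charge_ok(spec, charge: int) -> bool:
    if spec == "negative":
        return charge < 0
    if spec == "positive":
        return charge > 0
    if spec == "zero":
        return charge == 0
    return charge == int(spec)


def load_default_rules() -> RoleRules:
    text = resources.files("pharmboost.data").joinpath("role_rules.yaml").read_text()
    return RoleRules.from_yaml(text)


# ---------------------------------------------------------------------------
# PDB input


def read_complex(pdb_text: str, ligand_selector: str,
                 complex_id: str = "complex") -> ProteinComplex:
    """Parse PDB text into a :class:`ProteinComplex`.

    ``ligand_selector`` is a residue name (``"LIG"``), a chain/residue spec
    (``"A:301"``), or both (``"LIG:A:301"``); it must match exactly one HETATM
    residue group.  Waters are dropped; altLoc records other than blank/'A'
    are ignored; residue numbering is taken verbatim from the file.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise MalformedInputError("no models in PDB input")
    model = st[0]

    protein_atoms: list[Atom] = []
    het_groups: dict[tuple, list[Atom]] = {}
    n_records = 0
    for chain in model:
        for res in chain:
            if res.is_water() or res.name in WATER_RESNAMES:
                continue
            is_het = res.het_flag == "H"
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                n_records += 1
                rec = Atom(
                    serial=atom.serial,
                    element=atom.element.name.upper(),
                    name=atom.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    formal_charge=atom.charge,
                    is_ligand=is_het,
                    insertion_code=(res.seqid.icode or "").strip(),
                )
                if is_het:
                    key = (res.name, chain.name, res.seqid.num,
                           (res.seqid.icode or "").strip())
                    het_groups.setdefault(key, []).append(rec)
                else:
                    protein_atoms.append(rec)

    if n_records == 0:
        raise MalformedInputError("PDB input contains no ATOM or HETATM records")

    matches = [key for key in het_groups if _selector_matches(ligand_selector, key)]
    if not matches:
        raise LigandSelectorError(
            f"ligand selector {ligand_selector!r} matched no HETATM residue; "
            f"available: {sorted(het_groups)}"
        )
    if len(matches) > 1:
        raise AmbiguousLigandError(ligand_selector, sorted(matches))
    if not protein_atoms:
        raise MalformedInputError("complex has no protein (ATOM) atoms")

    ligand_atoms = het_groups[matches[0]]
    bonds = _parse_conect(pdb_text)
    return ProteinComplex(
        complex_id=complex_id,
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        explicit_bonds=bonds,
    )


def _selector_matches(selector: str, key: tuple) -> bool:
    resname, chain, seq, icode = key
    parts = selector.split(":")
    if len(parts) == 1:
        return parts[0] == resname
    if len(parts) == 2:
        return parts[0] == chain and parts[1] == f"{seq}{icode}"
    if len(parts) == 3:
        return (parts[0] == resname and parts[1] == chain
                and parts[2] == f"{seq}{icode}")
    raise ValueError(f"unparsable ligand selector {selector!r}")


def _parse_conect(pdb_text: str) -> dict[int, set[int]]:
    bonds: dict[int, set[int]] = {}
    for line in pdb_text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[i:i + 5] for i in range(6, min(len(line), 31), 5)]
        serials = [int(f) for f in fields if f.strip()]
        if len(serials) < 2:
            continue
        a = serials[0]
        for b in serials[1:]:
            bonds.setdefault(a, set()).add(b)
            bonds.setdefault(b, set()).add(a)
    return bonds


# ---------------------------------------------------------------------------
# bond perception and role assignment


def _infer_bonds(atoms: Sequence[Atom],
                 explicit: Mapping[int, set[int]] | None = None) -> dict[int, list[Atom]]:
    """Neighbour lists: explicit CONECT bonds when available for an atom pair,
    else interatomic distance < covalent-radius sum + 0.4 A."""
    by_serial = {a.serial: a for a in atoms}
    neighbors: dict[int, list[Atom]] = {a.serial: [] for a in atoms}
    have_explicit = {
        s for s in (explicit or {}) if s in by_serial
    }
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            if a.serial in have_explicit or b.serial in have_explicit:
                bonded = b.serial in (explicit or {}).get(a.serial, set())
            else:
                ra = _COVALENT_RADII.get(a.element, 0.75)
                rb = _COVALENT_RADII.get(b.element, 0.75)
                bonded = a.distance_to(b) < ra + rb + _BOND_SLACK
            if bonded:
                neighbors[a.serial].append(b)
                neighbors[b.serial].append(a)
    return neighbors


def _effective_charges(atoms: Sequence[Atom],
                       neighbors: Mapping[int, list[Atom]]) -> dict[int, int]:
    """Formal charges with carboxylate-style group spreading: a terminal O
    sharing its carbon with a negatively charged terminal O is itself treated
    as negative (the charge is delocalised over the group)."""
    eff = {a.serial: a.formal_charge for a in atoms}
    for a in atoms:
        if a.element != "C":
            continue
        terminal_o = [n for n in neighbors[a.serial]
                      if n.element == "O"
                      and len([m for m in neighbors[n.serial] if m.element != "H"]) == 1]
        if len(terminal_o) >= 2 and any(o.formal_charge < 0 for o in terminal_o):
            for o in terminal_o:
                if eff[o.serial] == 0:
                    eff[o.serial] = -1
    return eff


def assign_pharm_roles(complex: ProteinComplex,
                       rules: RoleRules | None = None) -> ProteinComplex:
    """Fill ``ligand_roles`` by applying the rule table to every ligand atom.

    Deterministic given the rules.  Elements with no covering rule get an
    empty role set with a warning (hydrogens silently get no roles).
    """
    if rules is None:
        rules = load_default_rules()
    neighbors = _infer_bonds(complex.ligand_atoms, complex.explicit_bonds)
    charges = _effective_charges(complex.ligand_atoms, neighbors)
    roles: dict[int, frozenset[PharmRole]] = {}
    for atom in complex.ligand_atoms:
        if atom.element == "H":
            roles[atom.serial] = frozenset()
            continue
        matched = rules.match(atom, neighbors[atom.serial], charges[atom.serial])
        if matched is None:
            warnings.warn(
                f"no role rule for element {atom.element!r} "
                f"(atom {atom.serial} {atom.name}); assigning no roles",
                stacklevel=2,
            )
            matched = frozenset()
        roles[atom.serial] = matched
    out = replace(complex)
    out.ligand_roles = roles
    return out


def _protein_roles_for(atoms: Sequence[Atom], all_protein: Sequence[Atom],
                       rules: RoleRules) -> dict[int, frozenset[PharmRole]]:
    """Roles for candidate protein atoms: residue/atom lookup first, element
    rules (with locally inferred bonds) as fallback for non-standard residues."""
    out: dict[int, frozenset[PharmRole]] = {}
    fallback: list[Atom] = []
    for a in atoms:
        if a.residue_name in ION_RESNAMES:
            out[a.serial] = frozenset()
            continue
        hit = rules.protein_lookup(a)
        if hit is not None:
            out[a.serial] = hit
        else:
            fallback.append(a)
    if fallback:
        coords = np.array([a.xyz for a in all_protein])
        tree = cKDTree(coords)
        for a in fallback:
            if a.element == "H":
                out[a.serial] = frozenset()
                continue
            idx = tree.query_ball_point(a.xyz, r=2.0)
            local = [all_protein[i] for i in idx]
            nbrs = _infer_bonds(local).get(a.serial, [])
            matched = rules.match(a, nbrs, a.formal_charge)
            out[a.serial] = matched if matched is not None else frozenset()
    return out


# ---------------------------------------------------------------------------
# interaction detection


def _can_donate(roles: frozenset[PharmRole]) -> bool:
    return PharmRole.DONOR in roles or PharmRole.DONOR_OR_ACCEPTOR in roles


def _can_accept(roles: frozenset[PharmRole]) -> bool:
    return PharmRole.ACCEPTOR in roles or PharmRole.DONOR_OR_ACCEPTOR in roles


def _hbond_type(lig_roles: frozenset[PharmRole],
                prot_roles: frozenset[PharmRole]) -> InteractionType | None:
    """Resolve the H-bond type from the ligand atom's pharmacophore role.

    The type labels the ligand-side feature, so an ambiguous ligand atom
    (DONOR_OR_ACCEPTOR, i.e. hydrogens absent) gives HB_UNDETERMINED even
    against a single-role partner.
    """
    if not (_can_donate(prot_roles) or _can_accept(prot_roles)):
        return None
    lig_donor = PharmRole.DONOR in lig_roles
    lig_acceptor = PharmRole.ACCEPTOR in lig_roles
    if PharmRole.DONOR_OR_ACCEPTOR in lig_roles:
        return InteractionType.HB_UNDETERMINED
    if lig_donor and lig_acceptor:
        # e.g. hydroxyl with explicit H: partner decides the direction
        pa, pd = _can_accept(prot_roles), _can_donate(prot_roles)
        if pa and pd:
            return InteractionType.HB_UNDETERMINED
        if pa:
            return InteractionType.HB_LIG_DONOR
        return InteractionType.HB_LIG_ACCEPTOR
    if lig_donor and _can_accept(prot_roles):
        return InteractionType.HB_LIG_DONOR
    if lig_acceptor and _can_donate(prot_roles):
        return InteractionType.HB_LIG_ACCEPTOR
    return None


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _donor_angle_ok(donor: Atom, acceptor: Atom,
                    donor_neighbors: Sequence[Atom], min_angle: float) -> bool:
    """D-H...A angle test, applied only when the donor has explicit hydrogens."""
    hydrogens = [n for n in donor_neighbors if n.element == "H"]
    if not hydrogens:
        return True
    return any(_angle_deg(donor.xyz, h.xyz, acceptor.xyz) >= min_angle
               for h in hydrogens)


def detect_interactions(complex: ProteinComplex,
                        params: InteractionParams | None = None,
                        rules: RoleRules | None = None) -> list[Interaction]:
    """Detect the six interaction types between ligand and protein atoms.

    Requires ``ligand_roles`` (see :func:`assign_pharm_roles`).  For an atom
    pair qualifying as both ionic and hydrogen bond (salt bridge), only the
    ionic interaction is emitted.  Output is sorted by (ligand serial, protein
    serial, type) and is invariant under rigid motion of the complex.
    """
    if params is None:
        params = InteractionParams()
    if rules is None:
        rules = load_default_rules()
    if complex.ligand_roles is None:
        raise ValueError("ligand roles not assigned; call assign_pharm_roles first")
    if not complex.ligand_atoms:
        return []

    prot = complex.protein_atoms
    tree = cKDTree(np.array([a.xyz for a in prot]))
    lig_neighbors = _infer_bonds(complex.ligand_atoms, complex.explicit_bonds)

    # roles only for protein atoms near any ligand atom
    candidate_idx = sorted({
        i
        for lig in complex.ligand_atoms
        for i in tree.query_ball_point(lig.xyz, r=params.max_dist)
    })
    prot_roles = _protein_roles_for([prot[i] for i in candidate_idx], prot, rules)

    out: list[Interaction] = []
    for lig in complex.ligand_atoms:
        lroles = complex.ligand_roles.get(lig.serial, frozenset())
        if not lroles:
            continue
        for i in tree.query_ball_point(lig.xyz, r=params.max_dist):
            patom = prot[i]
            proles = prot_roles.get(patom.serial, frozenset())
            if not proles:
                continue
            d = lig.distance_to(patom)
            if d <= 0:
                continue
            ionic = None
            if d <= params.ionic_max_dist:
                if PharmRole.CATION in lroles and PharmRole.ANION in proles:
                    ionic = InteractionType.IONIC_LIG_CATION
                elif PharmRole.ANION in lroles and PharmRole.CATION in proles:
                    ionic = InteractionType.IONIC_LIG_ANION
            if ionic is not None:
                out.append(Interaction(ionic, lig, patom, d))
            elif d <= params.hbond_max_dist:
                hb = _hbond_type(lroles, proles)
                if hb is not None and _hb_geometry_ok(
                        hb, lig, patom, lig_neighbors[lig.serial], params):
                    out.append(Interaction(hb, lig, patom, d))
            if (d <= params.hydrophobic_max_dist
                    and PharmRole.HYDROPHOBE in lroles
                    and PharmRole.HYDROPHOBE in proles):
                out.append(Interaction(InteractionType.HYDROPHOBIC, lig, patom, d))
    out.sort(key=lambda x: (x.ligand_atom.serial, x.protein_atom.serial,
                            _ITYPE_ORDER[x.itype]))
    return out


def _hb_geometry_ok(hb: InteractionType, lig: Atom, patom: Atom,
                    lig_nbrs: Sequence[Atom], params: InteractionParams) -> bool:
    if hb is InteractionType.HB_LIG_DONOR:
        return _donor_angle_ok(lig, patom, lig_nbrs, params.hbond_min_angle)
    # protein-side hydrogens are typically absent; no angle test there
    return True


def interactions_to_tsv(complex_id: str,
                        interactions: Iterable[Interaction]) -> str:
    """Interaction list as TSV: complex_id, itype, ligand/protein serial, distance."""
    lines = ["complex_id\titype\tligand_serial\tprotein_serial\tdistance"]
    for x in interactions:
        lines.append(
            f"{complex_id}\t{x.itype.value}\t{x.ligand_atom.serial}"
            f"\t{x.protein_atom.serial}\t{x.contact_distance:.4f}"
        )
    return "\n".join(lines) + "\n"
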