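"""Pharm-IF encoding: pharmacophore-pair fingerprints with soft distance bins.

Every unordered pair of detected interactions whose ligand atoms differ is
characterised by the pair of interaction types t and the distance d between
the two ligand atoms.  Each pair spreads unit weight over the two integer
distance bins flanking d:

    A_k(d) = max(0, 1 - |k - d|),        H_{t,k} = sum over pairs of A_k(d_i)

so a donor-acceptor pair 4.3 A apart contributes 0.7 to bin 4 and 0.3 to
bin 5 of that channel.  With 6 interaction types there are 21 unordered
type-pair channels; bins run 1..k_max (default 20 A), giving a 21*k_max
feature vector.  Pairs with d >= k_max + 1 contribute nothing; for d < 1 the
weight share of the nonexistent bin 0 is dropped (total mass < 1 at that
boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import Interaction, InteractionType

__all__ = [
    "TypePair",
    "InteractionPair",
    "Fingerprint",
    "TYPE_PAIRS",
    "DEFAULT_K_MAX",
    "canonical_type_pair",
    "type_pair_label",
    "feature_names",
    "feature_index",
    "enumerate_pairs",
    "bin_weight",
    "encode",
    "encode_complex",
    "to_feature_matrix",
    "write_dense_csv",
    "read_dense_csv",
    "write_sparse_tsv",
    "read_sparse_tsv",
]

TypePair = tuple[InteractionType, InteractionType]

DEFAULT_K_MAX = 20

#: the 21 canonical unordered type pairs, lexicographic by type name
TYPE_PAIRS: list[TypePair] = list(
    combinations_with_replacement(sorted(InteractionType, key=lambda t: t.value), 2)
)
_PAIR_INDEX = {t: i for i, t in enumerate(TYPE_PAIRS)}


def canonical_type_pair(a: InteractionType, b: InteractionType) -> TypePair:
    """Unordered pair in canonical (lexicographic-by-name) order."""
    return (a, b) if a.value <= b.value else (b, a)


def type_pair_label(t: TypePair) -> str:
    return f"{t[0].value}~{t[1].value}"


def _pair_from_label(label: str) -> TypePair:
    a, b = label.split("~")
    return (InteractionType(a), InteractionType(b))


def feature_names(k_max: int = DEFAULT_K_MAX) -> list[str]:
    """Column names 't/k' in the canonical (type pair) x (bin ascending) order."""
    return [f"{type_pair_label(t)}/{k}" for t in TYPE_PAIRS
            for k in range(1, k_max + 1)]


def feature_index(t: TypePair, k: int, k_max: int = DEFAULT_K_MAX) -> int:
    """Flat column index of channel (t, k)."""
    if not 1 <= k <= k_max:
        raise ValueError(f"bin {k} outside 1..{k_max}")
    return _PAIR_INDEX[t] * k_max + (k - 1)


@dataclass(frozen=True)
class InteractionPair:
    """Two interactions on distinct ligand atoms; d = ligand-ligand distance."""

    t: TypePair
    d: float
    source: tuple[Interaction, Interaction]

    def __post_init__(self):
        if self.d <= 0 or not math.isfinite(self.d):
            raise ValueError("interaction-pair distance must be positive and finite")


@dataclass
class Fingerprint:
    """Sparse H_{t,k} map; semantically all 21*k_max cells exist (zeros omitted)."""

    H: dict[tuple[TypePair, int], float] = field(default_factory=dict)
    k_max: int = DEFAULT_K_MAX
    complex_id: str = ""

    def value(self, t: TypePair, k: int) -> float:
        return self.H.get((t, k), 0.0)

    def to_dense(self) -> np.ndarray:
        v = np.zeros(len(TYPE_PAIRS) * self.k_max)
        for (t, k), val in self.H.items():
            v[feature_index(t, k, self.k_max)] = val
        return v

    @classmethod
    def from_dense(cls, row: np.ndarray, k_max: int,
                   complex_id: str = "") -> "Fingerprint":
        H = {}
        for t in TYPE_PAIRS:
            for k in range(1, k_max + 1):
                val = float(row[feature_index(t, k, k_max)])
                if val != 0.0:
                    H[(t, k)] = val
        return cls(H=H, k_max=k_max, complex_id=complex_id)


def enumerate_pairs(interactions: Sequence[Interaction]) -> list[InteractionPair]:
    """All unordered pairs of interactions with distinct ligand atoms.

    Pairs sharing a ligand atom are excluded (their ligand-ligand distance is
    zero, not a pharmacophore-pair geometry); two interactions on the same two
    ligand atoms through different protein atoms count as distinct pairs.
    """
    out: list[InteractionPair] = []
    for a, b in combinations(interactions, 2):
        if a.ligand_atom.serial == b.ligand_atom.serial:
            continue
        d = a.ligand_atom.distance_to(b.ligand_atom)
        out.append(InteractionPair(
            t=canonical_type_pair(a.itype, b.itype), d=d, source=(a, b)))
    return out


def bin_weight(k: int, d: float) -> float:
    """Soft-bin weight A_k(d) = max(0, 1 - |k - d|) for integer bin k >= 1."""
    if not math.isfinite(d):
        raise ValueError("distance must be finite")
    if d <= 0:
        raise ValueError("distance must be positive")
    k = int(k)
    if k < 1:
        raise ValueError("bin index must be >= 1")
    return max(0.0, 1.0 - abs(k - d))


def encode(pairs: Iterable[InteractionPair], k_max: int = DEFAULT_K_MAX,
           complex_id: str = "") -> Fingerprint:
    """Sum soft-bin weights of all interaction pairs into H_{t,k}."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    H: dict[tuple[TypePair, int], float] = {}
    for p in pairs:
        lo = math.floor(p.d)
        for k in (lo, lo + 1):
            if 1 <= k <= k_max:
                w = bin_weight(k, p.d)
                if w > 0.0:
                    H[(p.t, k)] = H.get((p.t, k), 0.0) + w
    return Fingerprint(H=H, k_max=k_max, complex_id=complex_id)


def encode_complex(complex, params=None, rules=None,
                   k_max: int = DEFAULT_K_MAX) -> Fingerprint:
    """Full chain: assign roles if needed, detect contacts, pair, encode."""
    from .structures import assign_pharm_roles, detect_interactions

    if complex.ligand_roles is None:
        complex = assign_pharm_roles(complex, rules)
    interactions = detect_interactions(complex, params, rules)
    return encode(enumerate_pairs(interactions), k_max=k_max,
                  complex_id=complex.complex_id)


def to_feature_matrix(fingerprints: Sequence[Fingerprint]
                      ) -> tuple[np.ndarray, list[str]]:
    """Stack fingerprints into a samples-by-features matrix (fixed column order)."""
    if not fingerprints:
        raise ValueError("no fingerprints given")
    k_max = fingerprints[0].k_max
    if any(f.k_max != k_max for f in fingerprints):
        raise ValueError("fingerprints have mixed k_max")
    X = np.vstack([f.to_dense() for f in fingerprints])
    return X, feature_names(k_max)


# ---------------------------------------------------------------------------
# serialization (dense CSV and sparse triplet TSV)


def write_dense_csv(fingerprints: Sequence[Fingerprint], path) -> None:
    X, names = to_feature_matrix(fingerprints)
    ids = [f.complex_id for f in fingerprints]
    pd.DataFrame(X, index=pd.Index(ids, name="complex_id"),
                 columns=names).to_csv(path)


def read_dense_csv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (matrix, feature names, complex ids)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index]


def write_sparse_tsv(fingerprints: Sequence[Fingerprint], path) -> None:
    rows = []
    for f in fingerprints:
        for t in TYPE_PAIRS:
            for k in range(1, f.k_max + 1):
                v = f.value(t, k)
                if v != 0.0:
                    rows.append((f.complex_id, type_pair_label(t), k, v))
    pd.DataFrame(rows, columns=["complex_id", "t_label", "k", "value"]).to_csv(
        path, sep="\t", index=False)


def read_sparse_tsv(path, k_max: int = DEFAULT_K_MAX) -> list[Fingerprint]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, group in df.groupby("complex_id", sort=False):
        H = {(_pair_from_label(r.t_label), int(r.k)): float(r.value)
             for r in group.itertuples()}
        out.append(Fingerprint(H=H, k_max=k_max, complex_id=str(cid)))
    return out
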