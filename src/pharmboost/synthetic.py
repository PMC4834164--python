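"""Synthetic benchmark data with the statistical structure of a docking screen.

Two generators live here:

* :func:`gen_pocket_complex` builds a pocket-scale protein-ligand complex with
  *planted* interaction geometry: ligand pharmacophore atoms placed at
  requested mutual distances, each with a protein partner atom inside its
  interaction cutoff, so that the structures -> fingerprint chain recovers the
  planted (type pair, distance) list exactly.  It exercises the whole encoding
  pipeline end to end.

* :func:`gen_fingerprint_samples` emulates the composition of a real
  screening experiment directly in fingerprint space: 100 active vs 2000
  decoy training rows (20:1 imbalance), a test set of 100 active and 2000
  decoy compounds with 5 correlated docking poses each (10500 rows), and a
  wrong-docking-pose noise process that replaces a fraction of the positive
  training rows with decoy-distributed features while keeping their +1 label.

Decoy fingerprints are sparse non-negative noise (Poisson-many channels with
exponential magnitudes, mimicking sums of sub-unit soft-bin weights), mixed
with one of a pool of scaffold archetype vectors: screening libraries are
clustered by chemotype, and a decoy's fingerprint is partly its family's.
The scaffold structure is what makes wrong-pose label noise consequential —
a corrupted positive drags its whole scaffold family up the ranking, not just
itself.  Actives add extra mass on a fixed set of signal channels, standing
in for the conserved pharmacophore geometry of true binders.  Real docking
data differs in ways the generator does not model: decoys that are
near-actives, scaffold overlap between actives and decoys, and pose noise
that is geometrically (not just distributionally) decoy-like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .structures import Atom, InteractionType, ProteinComplex
from .pharmif import (
    DEFAULT_K_MAX,
    TypePair,
    canonical_type_pair,
    feature_index,
    feature_names,
    type_pair_label,
)
from .ensemble import LabeledSample

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "DEFAULT_SIGNAL_CHANNELS",
    "gen_pocket_complex",
    "gen_fingerprint_samples",
    "corrupt_labels",
    "complex_to_pdb",
]

_IT = InteractionType

#: (type pair, bin) channels carrying active-class signal by default: a
#: plausible conserved binding motif (donor/acceptor pairs at medium range,
#: a hydrophobic cluster, one salt bridge).
DEFAULT_SIGNAL_CHANNELS: list[tuple[TypePair, int]] = [
    ((_IT.HB_LIG_ACCEPTOR, _IT.HB_LIG_DONOR), 5),
    ((_IT.HB_LIG_ACCEPTOR, _IT.HB_LIG_DONOR), 8),
    ((_IT.HB_LIG_ACCEPTOR, _IT.HYDROPHOBIC), 6),
    ((_IT.HB_LIG_DONOR, _IT.HYDROPHOBIC), 7),
    ((_IT.HYDROPHOBIC, _IT.HYDROPHOBIC), 4),
    ((_IT.HYDROPHOBIC, _IT.HYDROPHOBIC), 9),
    ((_IT.HB_LIG_ACCEPTOR, _IT.IONIC_LIG_CATION), 7),
    ((_IT.HYDROPHOBIC, _IT.IONIC_LIG_ANION), 10),
]


@dataclass(frozen=True)
class SynthConfig:
    """Benchmark composition and noise process.

    Defaults reproduce the reference experiment's table: 100 positive and
    2000 negative training samples (2100 rows, 20:1), and a test set of 100
    active plus 2000 decoy compounds with 5 poses each (10500 rows).
    ``pose_noise_rate`` is the fraction of positive training rows replaced by
    decoy-distributed features (label kept +1) — the wrong-binding-mode noise
    the boosted ensemble is built to resist.
    """

    n_active_train: int = 100
    n_decoy_train: int = 2000
    n_active_test_compounds: int = 100
    poses_per_compound: int = 5
    n_decoy_test: int = 2000
    pose_noise_rate: float = 0.15
    signal_channels: tuple[tuple[TypePair, int], ...] = tuple(DEFAULT_SIGNAL_CHANNELS)
    signal_strength: float = 0.8
    signal_presence: float = 0.8
    signal_jitter: float = 0.3
    weak_active_rate: float = 0.35
    baseline_channels: float = 25.0
    baseline_scale: float = 0.6
    n_scaffolds: int = 40
    scaffold_mixing: float = 0.5
    n_wrong_motifs: int = 4
    pose_correlation: float = 0.7
    k_max: int = DEFAULT_K_MAX
    seed: int = 0

    def __post_init__(self):
        for name in ("n_active_train", "n_decoy_train", "n_active_test_compounds",
                     "poses_per_compound", "n_decoy_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.pose_noise_rate < 1:
            raise ValueError("pose_noise_rate must be in [0, 1)")

    @property
    def n_features(self) -> int:
        return 21 * self.k_max

    def signal_indices(self) -> np.ndarray:
        return np.array([feature_index(t, k, self.k_max)
                         for t, k in self.signal_channels])

    def log_dict(self) -> dict:
        d = asdict(self)
        d["signal_channels"] = [
            f"{type_pair_label(t)}/{k}" for t, k in self.signal_channels]
        return d


@dataclass
class SynthDataset:
    """Generated train/test samples plus ground truth about the noise."""

    train: list[LabeledSample]
    test: list[LabeledSample]
    is_corrupted: np.ndarray
    compound_of: dict[str, str]
    generator_log: dict
    config: SynthConfig

    def train_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.vstack([s.features for s in self.train]),
                np.array([s.label for s in self.train], int))

    def test_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.vstack([s.features for s in self.test]),
                np.array([s.label for s in self.test], int))

    def save(self, outdir) -> None:
        """Dense feature CSVs + label TSVs + generator log JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = feature_names(self.config.k_max)
        for split, samples in (("train", self.train), ("test", self.test)):
            X = np.vstack([s.features for s in samples])
            ids = [s.sample_id for s in samples]
            pd.DataFrame(X, index=pd.Index(ids, name="complex_id"),
                         columns=names).to_csv(outdir / f"{split}_features.csv")
            rows = []
            for i, s in enumerate(samples):
                rows.append({
                    "sample_id": s.sample_id,
                    "label": s.label,
                    "compound": self.compound_of.get(s.sample_id, s.sample_id),
                    "is_corrupted": (int(self.is_corrupted[i])
                                     if split == "train" else 0),
                })
            pd.DataFrame(rows).to_csv(outdir / f"{split}_labels.tsv",
                                      sep="\t", index=False)
        (outdir / "generator_log.json").write_text(
            json.dumps(self.generator_log, indent=2))


# ---------------------------------------------------------------------------
# fingerprint-space generator


def _baseline_row(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    x = np.zeros(cfg.n_features)
    nnz = min(int(rng.poisson(cfg.baseline_channels)), cfg.n_features)
    if nnz:
        idx = rng.choice(cfg.n_features, size=nnz, replace=False)
        x[idx] = rng.exponential(cfg.baseline_scale, size=nnz)
    return x


def _scaffold_pool(cfg: SynthConfig) -> np.ndarray:
    """Chemotype archetype fingerprints, reproducible from the config seed."""
    rng = np.random.default_rng(cfg.seed + 7919)
    return np.vstack([_baseline_row(rng, cfg) for _ in range(cfg.n_scaffolds)])


def _decoy_row(rng: np.random.Generator, cfg: SynthConfig,
               pool: np.ndarray) -> np.ndarray:
    lam = cfg.scaffold_mixing
    arch = pool[rng.integers(len(pool))]
    return lam * arch + (1.0 - lam) * _baseline_row(rng, cfg)


def _draw_expression(rng: np.random.Generator, cfg: SynthConfig) -> float:
    """Per-compound signal expression: zero for a ``weak_active_rate``
    fraction (the docking failed to reproduce the binding geometry, so no
    pose of that compound shows the motif), graded otherwise.  The zero
    fraction caps attainable AUC below 1 for every classifier."""
    if rng.random() < cfg.weak_active_rate:
        return 0.0
    return 0.7 + 0.6 * rng.random()


def _active_row(rng: np.random.Generator, cfg: SynthConfig,
                pool: np.ndarray, expression: float | None = None) -> np.ndarray:
    """An active is a library compound (scaffold mixture like any decoy) plus
    signal mass on the motif channels scaled by the expression level."""
    x = _decoy_row(rng, cfg, pool)
    if expression is None:
        expression = _draw_expression(rng, cfg)
    for j in cfg.signal_indices():
        if rng.random() < cfg.signal_presence:
            jitter = 1.0 + cfg.signal_jitter * (2.0 * rng.random() - 1.0)
            x[j] += cfg.signal_strength * expression * jitter
    return x


def gen_fingerprint_samples(config: SynthConfig | None = None,
                            **overrides) -> SynthDataset:
    """Generate the class-conditional fingerprint benchmark (see module doc).

    Fully reproducible from ``config.seed``.  The configured
    ``pose_noise_rate`` is applied to the positive training rows via
    :func:`corrupt_labels`.
    """
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        from dataclasses import replace
        config = replace(config, **overrides)
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pool = _scaffold_pool(cfg)

    train: list[LabeledSample] = []
    for i in range(cfg.n_active_train):
        train.append(LabeledSample(_active_row(rng, cfg, pool), +1,
                                   f"tr-act-{i:04d}"))
    for i in range(cfg.n_decoy_train):
        train.append(LabeledSample(_decoy_row(rng, cfg, pool), -1,
                                   f"tr-dec-{i:04d}"))

    test: list[LabeledSample] = []
    compound_of: dict[str, str] = {}
    rho = cfg.pose_correlation
    for kind, n_comp, label in (("act", cfg.n_active_test_compounds, +1),
                                ("dec", cfg.n_decoy_test, -1)):
        for c in range(n_comp):
            # expression is a compound property shared by all of its poses
            expr = _draw_expression(rng, cfg) if label == +1 else None

            def draw():
                return (_active_row(rng, cfg, pool, expression=expr)
                        if label == +1 else _decoy_row(rng, cfg, pool))

            core = draw()
            comp_id = f"cmpd-{kind}-{c:04d}"
            for p in range(cfg.poses_per_compound):
                pose = rho * core + (1.0 - rho) * draw()
                sid = f"te-{kind}-{c:04d}-p{p}"
                test.append(LabeledSample(pose, label, sid))
                compound_of[sid] = comp_id

    dataset = SynthDataset(
        train=train,
        test=test,
        is_corrupted=np.zeros(len(train), bool),
        compound_of=compound_of,
        generator_log={"config": cfg.log_dict(), "seed": cfg.seed},
        config=cfg,
    )
    if cfg.pose_noise_rate > 0:
        # decorrelate the corruption stream from the base stream
        dataset = corrupt_labels(dataset, cfg.pose_noise_rate,
                                 seed=cfg.seed + 1_000_003)
    return dataset


def corrupt_labels(dataset: SynthDataset, rate: float,
                   seed: int) -> SynthDataset:
    """Replace floor(rate * n_pos) positive training rows by fresh decoy draws.

    Labels stay +1 (mislabeled positives — the wrong-docking-pose process);
    ``is_corrupted`` records the truth.  Docking errors are systematic rather
    than uniform — a docking program favours a few spurious binding motifs —
    so the corrupted rows are decoy draws concentrated on
    ``config.n_wrong_motifs`` scaffold families from the library pool.
    Selection and replacement depend only on (dataset composition, rate,
    seed), so the operation is idempotent for a fixed seed.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    cfg = dataset.config
    pool = _scaffold_pool(cfg)
    pos_idx = np.array([i for i, s in enumerate(dataset.train) if s.label == +1])
    n_corrupt = int(np.floor(rate * len(pos_idx)))
    rng = np.random.default_rng(seed)
    chosen = (rng.choice(pos_idx, size=n_corrupt, replace=False)
              if n_corrupt else np.array([], int))
    motif_idx = rng.choice(len(pool),
                           size=min(cfg.n_wrong_motifs, len(pool)),
                           replace=False)
    motif_pool = pool[motif_idx]
    train = list(dataset.train)
    corrupted = np.zeros(len(train), bool)
    for i in sorted(chosen.tolist()):
        old = train[i]
        train[i] = LabeledSample(_decoy_row(rng, cfg, motif_pool), +1,
                                 old.sample_id)
        corrupted[i] = True
    log = dict(dataset.generator_log)
    log["corruption"] = {"rate": rate, "seed": seed, "n_corrupted": int(n_corrupt)}
    return SynthDataset(
        train=train, test=dataset.test, is_corrupted=corrupted,
        compound_of=dataset.compound_of, generator_log=log, config=cfg,
    )


# ---------------------------------------------------------------------------
# structural generator


# per-type recipe: ligand main atom (element, charge, explicit H?), optional
# bonded companion (element, bond length), protein partner (residue, atom
# name, element, charge) and contact distance.
_FEATURE_RECIPES = {
    _IT.HB_LIG_DONOR: dict(lig=("N", 0), lig_h=True, companion=None,
                           partner=("GLY", "O", "O", 0), r=3.0),
    _IT.HB_LIG_ACCEPTOR: dict(lig=("O", 0), lig_h=False, companion=("C", 1.23),
                              partner=("GLY", "N", "N", 0), r=3.0),
    _IT.HB_UNDETERMINED: dict(lig=("O", 0), lig_h=False, companion=("C", 1.43),
                              partner=("SER", "OG", "O", 0), r=3.0),
    _IT.IONIC_LIG_CATION: dict(lig=("N", +1), lig_h=False, companion=None,
                               partner=("ASP", "OD1", "O", 0), r=3.5),
    _IT.IONIC_LIG_ANION: dict(lig=("O", -1), lig_h=False, companion=None,
                              partner=("LYS", "NZ", "N", 0), r=3.5),
    _IT.HYDROPHOBIC: dict(lig=("C", 0), lig_h=False, companion=None,
                          partner=("LEU", "CD1", "C", 0), r=4.0),
}

_CLUSTER_SPACING = 40.0  # > k_max + max cutoffs: clusters cannot interact


class _ComplexBuilder:
    def __init__(self, complex_id: str):
        self.complex_id = complex_id
        self.serial = 0
        self.res_seq = 0
        self.protein: list[Atom] = []
        self.ligand: list[Atom] = []
        self.bonds: dict[int, set[int]] = {}

    def _next(self) -> int:
        self.serial += 1
        return self.serial

    def add_protein(self, res: str, name: str, element: str, charge: int,
                    pos: np.ndarray) -> Atom:
        self.res_seq += 1
        a = Atom(self._next(), element, name, res, "A", self.res_seq,
                 tuple(float(v) for v in pos), charge, is_ligand=False)
        self.protein.append(a)
        return a

    def add_ligand(self, element: str, charge: int, pos: np.ndarray,
                   bonded_to: Atom | None = None) -> Atom:
        a = Atom(self._next(), element, f"{element}{self.serial}", "LIG", "L",
                 900, tuple(float(v) for v in pos), charge, is_ligand=True)
        self.ligand.append(a)
        self.bonds.setdefault(a.serial, set())
        if bonded_to is not None:
            self.bonds[a.serial].add(bonded_to.serial)
            self.bonds.setdefault(bonded_to.serial, set()).add(a.serial)
        return a

    def place_feature(self, itype: InteractionType, pos: np.ndarray,
                      out: np.ndarray, perp: np.ndarray) -> Atom:
        """Ligand pharmacophore atom at ``pos`` with its protein partner along
        ``out``; companions go along ``perp`` so they shadow nothing."""
        recipe = _FEATURE_RECIPES[itype]
        elem, charge = recipe["lig"]
        main = self.add_ligand(elem, charge, pos)
        if recipe["lig_h"]:
            self.add_ligand("H", 0, pos + out * 1.0, bonded_to=main)
        if recipe["companion"]:
            c_elem, c_len = recipe["companion"]
            self.add_ligand(c_elem, 0, pos + perp * c_len, bonded_to=main)
        res, name, p_elem, p_charge = recipe["partner"]
        self.add_protein(res, name, p_elem, p_charge, pos + out * recipe["r"])
        return main

    def build(self, rng: np.random.Generator) -> ProteinComplex:
        if not self.protein:  # keep the complex valid even with nothing planted
            self.add_protein("GLY", "CA", "C", 0, np.array([50.0, 50.0, 50.0]))
        cx = ProteinComplex(
            complex_id=self.complex_id,
            protein_atoms=self.protein,
            ligand_atoms=self.ligand,
            explicit_bonds=self.bonds,
        )
        # random rigid motion: the encoding must not depend on the frame
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        t = rng.uniform(-20, 20, size=3)
        return cx.transformed(Q, t)


def _embed_distances(dist: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Classical MDS embedding of a full distance matrix; raises
    GenerationError if the distances are not Euclidean (triangle violation)."""
    n = len(dist)
    D2 = dist ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(G)
    if w.min() < -tol * max(1.0, w.max()):
        raise GenerationError(
            "planted distances are not Euclidean-embeddable "
            "(triangle inequality violated)")
    w = np.clip(w, 0.0, None)
    X = V * np.sqrt(w)
    got = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    if not np.allclose(got, dist, atol=1e-6):
        raise GenerationError("distance embedding failed to reproduce inputs")
    return X[:, ::-1][:, :3] if X.shape[1] >= 3 else np.pad(
        X[:, ::-1], ((0, 0), (0, 3 - X.shape[1])))


def gen_pocket_complex(
        seed: int = 0,
        n_ligand_atoms: int | None = None,
        planted: Sequence[tuple[TypePair, float]] = (),
) -> ProteinComplex:
    """Synthetic complex whose encoded fingerprint is exactly the planted list.

    ``planted`` holds (type pair, ligand-ligand distance) items with distances
    in (1, k_max).  By default each planted pair becomes an isolated two-atom
    pharmacophore dyad, far enough from the others that no spurious in-range
    pair arises.  If ``n_ligand_atoms`` is given and C(n, 2) equals the number
    of planted items, the items are instead assigned to the atom pairs of one
    shared n-atom ligand (combinations order) and the full distance matrix is
    embedded; infeasible distance sets raise :class:`GenerationError`.  Each
    pharmacophore atom must then carry a single consistent interaction type.

    The finished complex is randomly rotated and translated (seeded), which
    the detection chain must be invariant to.
    """
    rng = np.random.default_rng(seed)
    planted = [((canonical_type_pair(*t)), float(d)) for t, d in planted]
    for _, d in planted:
        if not 1.0 < d < DEFAULT_K_MAX:
            raise GenerationError(
                f"planted distance {d} outside the encodable range (1, {DEFAULT_K_MAX})")

    builder = _ComplexBuilder(f"synth-{seed}")

    if (n_ligand_atoms is not None
            and n_ligand_atoms * (n_ligand_atoms - 1) // 2 == len(planted)
            and n_ligand_atoms >= 2):
        n = n_ligand_atoms
        atom_types: dict[int, InteractionType] = {}
        dist = np.zeros((n, n))
        for (pair, (t, d)) in zip(combinations(range(n), 2), planted):
            i, j = pair
            dist[i, j] = dist[j, i] = d
            for idx, it in zip((i, j), t):
                if atom_types.setdefault(idx, it) is not it:
                    raise GenerationError(
                        f"atom {idx} assigned conflicting interaction types")
        coords = _embed_distances(dist)
        centroid = coords.mean(axis=0)
        for i in range(n):
            out = coords[i] - centroid
            nrm = np.linalg.norm(out)
            out = out / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            perp = _any_perpendicular(out)
            builder.place_feature(atom_types[i], coords[i], out, perp)
    else:
        for idx, (t, d) in enumerate(planted):
            base = np.array([_CLUSTER_SPACING * idx, 0.0, 0.0])
            a_pos = base
            b_pos = base + np.array([d, 0.0, 0.0])
            builder.place_feature(t[0], a_pos, np.array([-1.0, 0.0, 0.0]),
                                  np.array([0.0, 1.0, 0.0]))
            builder.place_feature(t[1], b_pos, np.array([1.0, 0.0, 0.0]),
                                  np.array([0.0, 1.0, 0.0]))
        if not planted:
            builder.add_ligand("C", 0, np.array([0.0, 0.0, 0.0]))

    return builder.build(rng)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# PDB export of synthetic complexes


def complex_to_pdb(complex: ProteinComplex) -> str:
    """Serialize a (synthetic) complex as PDB text with CONECT records for
    the ligand's explicit bonds."""
    lines = []
    for atom in complex.protein_atoms + complex.ligand_atoms:
        rec = "HETATM" if atom.is_ligand else "ATOM  "
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
        charge = ""
        if atom.formal_charge > 0:
            charge = f"{atom.formal_charge}+"
        elif atom.formal_charge < 0:
            charge = f"{-atom.formal_charge}-"
        x, y, z = atom.coords
        lines.append(
            f"{rec}{atom.serial:>5} {name:<4} {atom.residue_name:<3} "
            f"{atom.chain_id}{atom.residue_seq:>4}{atom.insertion_code or ' ':1}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2}{charge:<2}"
        )
    ligand_serials = {a.serial for a in complex.ligand_atoms}
    for a in sorted(complex.explicit_bonds):
        partners = sorted(complex.explicit_bonds[a])
        if a in ligand_serials and partners:
            lines.append("CONECT" + "".join(f"{s:>5}" for s in [a] + partners))
    lines.append("END")
    return "\n".join(lines) + "\n"
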