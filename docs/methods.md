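# Methods

## Problem setting

Structure-based virtual screening ranks a compound library against a protein
target. When too few experimental complex structures exist to train a
classifier, docking poses of known actives are added to the positive class —
and docking inevitably contributes some *incorrect* binding modes, i.e.
mislabeled positives, on top of a heavy active:decoy imbalance (here 20:1).
`pharmboost` implements the full pipeline this problem calls for:
interaction-fingerprint encoding of complexes, an AdaBoost-boosted RBF-SVM
built to tolerate that label noise, baselines (single SVM, Random Forest),
and screening-efficiency metrics.

## Interaction detection

A complex is one protein chain set plus one ligand residue (waters removed,
altLoc A/blank kept, residue numbering verbatim). Ligand atoms receive
pharmacophore roles from an ordered, data-driven rule table
(`data/role_rules.yaml`): element, effective formal charge (with
carboxylate-style group spreading), explicit-hydrogen presence, heavy-atom
degree, neighbour-element composition and bond-length patterns (a C–O bond
≤ 1.30 Å marks a carbonyl acceptor; ~1.43 Å without hydrogens leaves
donor/acceptor ambiguity). Connectivity comes from CONECT records when
present, else from distances (covalent-radius sum + 0.4 Å). Protein atoms use
a residue/atom lookup for the 20 standard residues (backbone NH donor,
carbonyl acceptor, charged side chains, apolar carbons), falling back to the
element rules for exotic residues; metal ions take no part in detection.

Six contact types are detected within configurable cutoffs:

| type | criterion | default cutoff |
|---|---|---|
| H-bond, ligand donor / acceptor / undetermined | donor–acceptor heavy atoms | 3.5 Å (+ D–H…A ≥ 120° only when explicit H present) |
| ionic, ligand cation / anion | opposite formal charges | 4.0 Å |
| hydrophobic | apolar C … apolar C | 4.5 Å |

Two conventions are worth stating. A ligand atom whose donor/acceptor
character cannot be fixed (no hydrogens in the file) always yields the
*undetermined* H-bond type — the type labels the ligand-side feature, so
ligand ambiguity is decisive even against a pure acceptor. And for an atom
pair qualifying as both ionic and hydrogen bond (a salt bridge), only the
ionic contact is emitted, so a charge-assisted contact is not double-counted.
Detection is deterministic (sorted output) and invariant under rigid motion.

## Fingerprint encoding

Every unordered pair of detected interactions on *distinct* ligand atoms is
characterised by its type pair t (21 unordered combinations of the six
types) and the distance d between the two ligand atoms. Each pair spreads
unit weight over the two integer bins flanking d,

    A_k(d) = max(0, 1 − |k − d|),     H_{t,k} = Σ_pairs A_k(d_i),

so a donor–acceptor pair 4.3 Å apart contributes 0.7 to bin 4 and 0.3 to
bin 5 of its channel. Bins run 1…k_max (default 20 Å — beyond typical ligand
diameters; pairs with d ≥ k_max + 1 contribute nothing). For d < 1 Å the
share of the nonexistent bin 0 is dropped (total mass < 1 at that boundary).
Pairs sharing a ligand atom are excluded (d = 0 is not a pharmacophore
geometry); two interactions on the same two ligand atoms through different
protein partners count separately. The feature vector has 21·k_max
components in a fixed (type pair) × (bin) order that is part of the file
format contract (dense CSV and sparse triplet TSV).

## The boosted ensemble

Weak learners are soft-margin RBF-SVMs; boosting follows the standard
discrete-AdaBoost recursion with three specifics:

* **Per-sample costs, not resampling.** Sample i enters the SVM with
  misclassification cost C·n·D_t(i) (C = 5 by default), which keeps training
  deterministic and lets the weight vector act directly on the margin
  objective.
* **Adaptive kernel width.** σ is the standard deviation of the current
  sample set *as vectors*: σ = √(trace of the feature covariance), the RMS
  distance of samples from their mean. For independent samples
  E‖x−z‖² = 2σ² under this definition, so the kernel sits near e^{−1} for a
  typical pair and self-tunes to any feature scale or dimension. Two
  alternative readings (pooled entrywise std, mean of per-feature stds) are
  available via `sigma_scope` but saturate the kernel in high dimension:
  with pooled entry variance v, E‖x−z‖² = 2·d·v for d features, so
  E‖x−z‖²/(2σ²) equals the feature count (420 by default) and every
  cross-sample kernel value collapses to e^{−420} ≈ 0. A fixed σ (0.001,
  the historical parameterisation) is likewise available and likewise
  saturating; the plain-SVM baseline therefore also defaults to the adaptive
  width so comparisons are between functioning classifiers.
* **Weight trimming.** Each round trains on the largest-weight samples whose
  cumulative weight reaches the trim rate (0.9); all samples keep their
  weights for the error and update steps, so trimming accelerates without
  rescaling costs.

The error is the weighted indicator ε_t = Σ D_t(i)·1[h_t(x_i) ≠ y_i];
learners with ε_t ≥ 0.5 stop the loop, ε_t = 0 is capped through
ε_min = 10⁻¹⁰ before the vote weight a_t = ½·ln((1−ε_t)/ε_t) and ends the
loop (nothing is left to reweight). Weight updates multiply by e^{∓a_t} and
renormalise; the classical bound — training error ≤ Π_t 2√(ε_t(1−ε_t)) — is
asserted in the test suite on every synthetic run. Screening scores are the
margins Σ a_t·h_t(x) with h_t ∈ {±1}; a margin of exactly 0 predicts decoy
(conservative for screening). Default is a flat T = 5 loop; a
rejection-cascade mode (layers grown to a 0.9 hit rate / 0.5 false-alarm
target, ≤ 100 learners per layer) is provided for completeness, as is a
per-feature weak-learner mode (one single-column SVM per round, lowest
weighted error wins).

Baselines expose the same score/predict contract: a single C-SVM (C = 5,
tolerance 10⁻³) and a Random Forest (1000 trees, node size 5, 50 descriptors
per split; score = fraction of trees voting active).

## Screening metrics

EF(s) = (Hits_s/N_s)/(Hit_t/N_t) with N_s = ⌈s·N_t⌉ (so N_s ≥ 1) and a
stable sort for tied scores — EF is tie-sensitive, so the tie policy is part
of the definition. The ROC curve groups tied scores (diagonal segments) and
the AUC is its trapezoidal integral; the test suite verifies it equals the
pairwise Mann–Whitney statistic P(score_a > score_d) + ½P(tie) to 10⁻⁹.
Evaluation is pose-level by default (matching the 500/10000 test counting);
`pose_to_compound` (max score over a compound's poses) gives compound-level
screens. Multi-trial runs aggregate to mean ± sample std.

## The synthetic benchmark

No public docking data enters this package; the generator reproduces the
*statistical* structure the method addresses, at the reference composition:
2100 training rows (100 actives vs 2000 decoys) and 10500 test rows (100
active + 2000 decoy compounds × 5 poses).

* **Decoys** are scaffold mixtures: a library of 40 archetype fingerprints
  (sparse exponential channels, mimicking sums of sub-unit bin weights) with
  each compound 50% archetype, 50% fresh noise — screening libraries are
  clustered by chemotype and a compound's fingerprint is partly its
  family's.
* **Actives** are the same kind of library compound plus signal mass on 8
  fixed motif channels (donor/acceptor pairs at medium range, a hydrophobic
  cluster, one salt bridge), scaled by a per-compound expression level:
  zero for 35% of active compounds — the docked pose failed to reproduce
  the binding mode, consistent with reported top-pose accuracies of docking
  programs — and graded in [0.7, 1.3] otherwise. The zero-expression
  fraction caps attainable test AUC below 1 for *every* classifier and
  places the benchmark in the realistic 0.8-ish band rather than a
  saturated AUC = 1 regime.
* **Poses** of a test compound share its expression level and mix a
  compound core with fresh same-class draws (correlation 0.7).
* **Wrong-pose noise** replaces ⌊rate·n_pos⌋ positive training rows
  (default 15%) with decoy-distributed draws while keeping the +1 label.
  Docking errors are systematic rather than uniform — a program favours a
  few spurious binding motifs — so corrupted rows concentrate on 4 scaffold
  families. Corruption is idempotent for a fixed seed, and corrupted rows
  are statistically indistinguishable from decoys on channel sums
  (rank-test checked).

A second generator, `gen_pocket_complex`, builds actual pocket-scale
complexes with *planted* interaction geometry — ligand pharmacophore atoms
at requested mutual distances, each with a correctly-typed protein partner
inside its cutoff — and is the end-to-end oracle for the
structures → fingerprint chain: the encoded fingerprint must equal the
planted channel weights exactly. Shared-atom geometries are embedded by
classical MDS (non-Euclidean distance sets are rejected); isolated dyads are
spaced 40 Å apart so no spurious in-range pair can arise; the finished
complex is randomly rotated and translated to exercise frame invariance.

### What the benchmark shows — and does not

On the default benchmark with 15% wrong-pose noise, the boosted ensemble and
the plain SVM both sit at the shared Bayes ceiling (mean test AUC ≈ 0.83,
10% EF ≈ 7 over seeds), with the ensemble inside 0.01 of the SVM. A finding
worth stating plainly: the plain SVM's *ranking* is itself robust to this
noise level — with distribution-matched corrupted positives at 20:1
imbalance and a global adaptive kernel, the decision-function lift induced
by 15 mislabeled rows is nearly uniform over decoy space and barely reorders
the screen. The ensemble's discretised votes are, if anything, even less
sensitive (a sub-threshold lift changes no vote). Claims that boosting
rescues large amounts of AUC from wrong poses should therefore be read
against data where the noise is both larger and more structured than this
generator's default. The generator also does not model: decoys that are
near-actives, scaffold overlap between actives and decoys, or geometric
(rather than distributional) pose errors.

## Numerical choices and problem sizes

Ties at score 0 predict decoy; EF ties use input order; σ is clamped below
at 10⁻¹²; constant feature matrices warn. SVC runs with tolerance 10⁻³ and
a 500 MB kernel cache. The test suite runs the full 2100/10500 composition
where composition itself is under test and for the 5-seed noise-robustness
benchmark; unit tests of the trainers use a reduced composition (330
training rows, 10 scaffolds) — chosen as the smallest sets on which the
boosting behaviour under test is still non-trivial.

## Limitations

Protonation states, tautomers and hydrogen placement are out of scope (the
rules degrade gracefully to the undetermined H-bond type); mmCIF and
multi-ligand complexes are not parsed; the detection geometry uses
conventional medicinal-chemistry cutoffs, which published fingerprint
implementations do not always state; kernel choice is fixed to RBF; scores
are margins, not calibrated probabilities.
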