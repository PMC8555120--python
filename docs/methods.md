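# Methods

## Problem and model

`pocketgnn` predicts whether a small-molecule compound is active against
a protein target, using only graph representations of the compound and
of the target's ligand-binding pocket.

**Compound graph.** A SMILES string is parsed (RDKit) into an undirected
heavy-atom graph. Vertex labels are element symbols with the aromatic
flag folded in (`C` vs `C*`); edge labels are the bond class (single /
double / triple / aromatic, no kekulization). Hydrogens, charges,
isotopes and stereochemistry are ignored. SMILES with dots encode
several disconnected components and are excluded from datasets (an
explicit `ExclusionMark`, never a silent drop); unparsable strings are
errors, kept distinct from exclusion.

**Pocket graph.** The pocket is the set of residues in contact with a
co-crystallized ligand. Contact is defined as a minimum heavy-atom
distance ≤ 4.5 Å (configurable) — an explicit, reproducible criterion in
the range standard for structural contact analysis. Each of the 20
standard amino-acid types gets a one-hot vertex label (alphabetical
three-letter order, ALA=0 … VAL=19); non-standard residues and residues
without a Cα are dropped with warnings. Every residue pair whose Cα–Cα
distance lies in one of five bins — I [1.0, 4.8), II [4.8, 7.0),
III [7.0, 9.2), IV [9.2, 11.4), V [11.4, 13.6) Å — receives an edge of
that class. The printed bin boundaries are shared between adjacent
classes, so half-open intervals were adopted: a gap-free, deterministic
tiling in which 4.8 Å belongs to class II. Distances below 1.0 Å (steric
clashes) yield no edge rather than an error. Inter-chain edges are
admitted: distance is the only criterion. For multi-copy ligands the
first matching HETATM residue is used; first alternate locations are
kept; insertion codes are part of residue identity.

**r-radius subgraph embedding.** The embedding unit is the isomorphism
class of a vertex's (or edge's) r-hop neighborhood. Canonical
identifiers are computed by iterative sorted neighborhood relabeling
(Weisfeiler–Lehman colouring) rather than explicit subgraph extraction
plus canonization — equivalent at the small radii used here (r ≤ 2) and
far simpler; the testable contract is that radius-(r+1) classes refine
radius-r classes and that isomorphic rooted neighborhoods always share a
fingerprint. An edge fingerprint combines the edge's own label with the
unordered pair of its endpoints' radius-r vertex fingerprints (the
construction for edges was an open choice; this one is symmetric and
minimal). Fingerprints are deterministic strings, never process-salted
hashes, so vocabularies are bit-reproducible. Each vocabulary reserves
index 0 as UNK; neighborhoods unseen at fit time map there at
prediction time, and the count is reported.

**Network.** Per branch: embedding lookup, then L transition rounds

    h_i' = relu( h_i + Σ_{j∈N(i)} W_l (h_j + e_ij) ),

then the arithmetic mean of the final vertex vectors. The verbal
two-step description this implements ("add adjacent vertex and edge
vectors, then update through the non-linear function") leaves the
parameterization open; the choice here is residual with per-layer d×d
weights and static edge vectors across layers (whether edge vectors
should also update is ambiguous; static is the simpler, testable
reading). ReLU is the documented choice of non-linearity. The two
branches have separate parameters. The classifier is

    z = W_output [y_molecule; y_protein] + b_output,  W_output ∈ R^{2×2d},

with softmax over z = [y0, y1] and index 1 = active (recorded in the
model file header). Loss is cross-entropy, the canonical companion of a
softmax head.

## Hyperparameters

Defaults (all overridable in `TrainingConfig` / the CLI):

| parameter | default | note |
|---|---|---|
| feature dimension d | 10 | |
| compound subgraph radius | 2 | |
| pocket subgraph radius | 1 | |
| transition layers (each branch) | 3 | |
| learning rate | 0.001 | Adam |
| lr decay | 0.5 | at epoch boundaries |
| decay interval | 10 epochs | |
| epochs | 100 | |
| batch size | 1 | order reshuffled per epoch from the seed |

No early stopping, weight decay or dropout. Parameters initialize from
scaled uniform distributions (±0.1 embeddings, ±1/√d transition
weights, ±1/√(2d) output head) under a recorded seed; training is
bitwise reproducible given data and seed. Gradients are analytic
(hand-derived backprop in NumPy) and are validated against central
finite differences to a relative error below 1e-4 in the test suite.
Note the step-decay schedule shrinks the learning rate by 2^-10 over
100 epochs; single-example memorization checks therefore run at a
constant rate (decay 1.0), otherwise the optimizer freezes before
convergence.

## Synthetic data: what it emulates, what it does not

Real screening corpora need external downloads, so all tests run on
generated data.

* **Toy complexes**: PDB files with each residue's nearest atom placed
  at an exact planned distance from the ligand, giving ground-truth
  contact sets for any cutoff.
* **Pockets**: 10–16 residues (the scale of a ligand-contact shell)
  placed by rejection sampling in a 12 Å box with 3.6 Å minimum
  spacing; edges always derive from the real binning code so the whole
  geometric path is exercised and all five edge classes occur across a
  population.
* **Planted rule**: a pair is active iff the compound contains an ether
  oxygen (an O bonded to two carbons) AND the pocket contains ≥ 3
  tryptophans. The conjunction means neither motif alone determines the
  label, so above-chance conditional performance requires both
  branches. Non-motif compounds include primary alcohols, whose
  hydroxyl oxygen is distinguishable from an ether oxygen only at
  radius ≥ 1 — the subgraph embedding is therefore load-bearing, not
  just atom counting. Non-motif pockets occasionally carry one stray
  tryptophan, below threshold, so the count criterion matters.
* **Target-panel structure**: pockets are drawn from a fixed panel
  (default 40, half motif-bearing) that many compounds are screened
  against, mirroring per-target active/decoy corpora; held-out pairs
  combine new compounds with the same panel (a compound split). An
  earlier draft generated a fresh pocket per pair; then every held-out
  pocket fingerprint was novel, mapped to UNK, and the pocket branch
  carried zero information on held-out pairs for any model honoring the
  UNK policy. That is a degenerate emulation of screening data, not a
  property of the method, and the panel design replaced it.
* **Mixtures**: the balanced mixture samples (both motifs, compound
  only, pocket only, neither) at (1/2, 1/6, 1/6, 1/6) — 50% label
  prevalence. For pocket-ablation experiments a pocket-dependent
  mixture (1/2, 1/2, 0, 0) gives every compound the motif so the pocket
  alone decides the label; scrambling the pocket assignment across the
  whole dataset before splitting (the standard permutation-test
  protocol) then leaves no recoverable signal, while a conjunctive
  mixture would still let the compound motif rank at ~0.83 AUROC.
  Scrambling only the training split is not equivalent: the model can
  memorize chance per-pocket label frequencies that correlate with the
  intact held-out labels, making the statistic heavy-tailed around 0.5.

What passing these tests does **not** show: performance on real
chemistry (ring systems, charged species, conformational variation),
real pocket geometry (secondary structure, chain topology), or
generalization to unseen targets — the panel design deliberately tests
a compound split, not a target split.

## Numerical and degenerate-input choices

* Half-open distance bins (above); negative distances are errors.
* AUROC via threshold sweep + trapezoid (scikit-learn ROC points);
  ties are handled so the value equals the Mann–Whitney statistic,
  checked against a brute-force pairwise count.
* TPR/FPR with zero denominators raise `UndefinedMetric`; AUROC on a
  single class likewise. F1 with zero true positives is 0 by
  convention. The F1 threshold defaults to p_active ≥ 0.5, the softmax
  head's natural boundary, and is exposed as a flag.
* Isolated vertices update as relu(h); single-vertex graphs are valid;
  empty pockets and empty ligands are errors.
* Softmax is computed shifted by the max logit; the loss clamps
  probabilities at 1e-300 before the log.

## Problem sizes

Default experiment sizes were chosen to run comfortably on one CPU
core: learnability uses 600 pairs (400 train / 200 held-out) over a
40-pocket panel, five seeds; the gradient check uses d = 2, one layer;
oracle comparisons use 100–1,000 random instances. `scripts/acceptance.py`
reruns all of these from scratch.

## Known limitations

* The contact criterion is a distance cutoff, not a
  surface-complementarity analysis; it is a documented stand-in, not a
  reimplementation of any specific contacts program.
* WL fingerprints identify neighborhoods only up to WL
  distinguishability (sufficient at r ≤ 2 on these graph sizes; the
  tests assert only the sound direction of the equivalence).
* Mini-batching averages per-example gradients; batch size 1 (the
  default) makes example order matter, which is why the epoch shuffle
  is seeded.
* PDB parsing handles ATOM/HETATM single-model files; mmCIF and
  biological assemblies are out of scope.
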