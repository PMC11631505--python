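# Methods

This note documents the models, numerical choices and limitations of
`epipatch`, and what the synthetic benchmark does and does not show.

## Solvent accessibility

SASA is computed with our own Shrake–Rupley implementation rather than
an external viewer's routine, so results are bit-stable across runs and
machines.  Design choices:

* **Point set.** A deterministic golden-spiral lattice (default 960
  points per atom; `n_points` configurable, minimum 100).  The lattice
  is expressed in the principal axes of the frame's atom-position
  covariance, with eigenvector signs fixed by the coordinate skewness
  along each axis; this makes the computed SASA exactly invariant under
  any common rigid-body transform of the frame (verified at 1e-6
  relative tolerance).  For molecules with degenerate covariance (a
  single atom) the orientation cannot matter and the identity is used.
* **Radii.** Fixed van der Waals table: C 1.70, N 1.55, O 1.52,
  S 1.80 Å; probe 1.4 Å.  Hydrogens are dropped on loading and ignored
  everywhere — input trajectories may or may not contain them, and a
  fixed convention avoids dialect drift.  Unknown elements are an
  error, never silently defaulted.
* **Accuracy.** The isolated-atom closed form 4π(r+probe)² is
  reproduced within 1 % at 960 points; against a 10×-density
  random-point oracle, per-residue values agree within ~2 % for exposed
  residues, with up to ~2.5 % relative (≤ ~2 Å² absolute) deviation for
  partially occluded ones.  Error decreases monotonically with point
  count.
* **RSASA.** Relative SASA uses the theoretical maximum ASA per residue
  type ("theoretical" tripeptide reference values, e.g. Ala 129.0, Gly
  104.0, Trp 285.0 Å²), shipped as constants.  Values are deliberately
  *not* capped at 100 %: conformations more exposed than the reference
  state are informative.

A residue is solvent-accessible when its mean RSASA over all frames is
**strictly greater than** 20 %.  The boundary convention is explicit
and configurable; the accessibility literature uses both > and ≥ at
this threshold, and at trajectory-averaged precision the choice is
immaterial in practice.

Residues whose name is not one of the 20 standard amino acids are kept
as *occluder pseudo-atoms*: they shield their surroundings from solvent
but receive no profile of their own.  This is also the mechanism the
synthetic generator uses to bury residues.

## Flexibility

Per-atom RMSF is computed after rigid-body superposition of all frames
(Kabsch on Cα atoms; two passes — align to frame 0, then to the mean
structure — a standard protocol).  Per-residue RMSF averages the
side-chain heavy atoms (Cα for glycine), because the flexibility of
interest is side-chain mobility at the antigen surface.  N-RMSF
z-scores the RMSF over the solvent-accessible residues, excluding five
residues at each chain terminus, whose flexibility is artefactual; all
residues, inside or outside that population, are normalized with the
same mean and standard deviation.  N-RMSF is treated as dimensionless
(z-units) throughout.

## Patches and descriptors

Patches use a closed 15 Å ball around the central residue's
mass-weighted centre (standard atomic masses), evaluated per frame:
the roster is the union over frames and each member's weight is its
frame-presence fraction, so a residue inside the radius in even one
frame is a member with weight 1/n_frames.  Distances use per-frame
centres, consistent with per-frame membership.

Of the 18 descriptors, the static patch aggregates (hydrophobicity
min/max/mean, charge sums) are unweighted; only the RSASA patch
aggregates (`S_patch_*`) and the flexibility patch average
(`F_patch_avg`) carry the frame-presence weights, normalized by Σw.
Each member's per-frame RSASA statistics are taken over *all* frames —
RSASA is a property of the residue, not of its patch membership —
even when the member is inside the patch only part of the time.  The
central residue is included in every patch-level aggregate.

## Labeling, redundancy, splits

*Epitope*: the central residue belongs to an antibody-verified eplet
carried by the antigen.  *Nonepitope*: neither the centre nor any
member belongs to any eplet — verified or unconfirmed — and the member
positions are not all locus-conserved (conserved positions cannot raise
an alloimmune response, so an all-conserved patch could be an unlabeled
positive).  Everything else is *Ineligible* and excluded from training.

Eplet registry positions refer to a per-locus reference numbering; for
alleles with insertions or deletions, a gap-aware pairwise alignment to
the reference translates positions before matching, so homologous
patches are pooled across indel-shifted alleles.

Redundancy reduction clusters allele sequences at 90 % global-alignment
identity (identity = matches / alignment length) with a greedy,
deterministic algorithm: sequences processed in decreasing length then
lexicographic id, joined to the first cluster whose founder matches at
threshold.  Antigens with two polymorphic chains follow their β-chain
sequence.  Per cluster, the antigen with the most Nonepitope patches
becomes the representative (ties: lexicographic id) and contributes all
Nonepitope patches; Epitope patches are pooled over the cluster and
deduplicated on the central residue's (chain, position, amino acid),
preferring the representative's patch, then the lowest antigen id.

Train/test splits are stratified random 90/10 pairs (default ten, seeds
0–9), preserving the class ratio within one sample.

## Learning

All three classifiers are scikit-learn estimators: CART decision tree
(Gini), `ExtraTreesClassifier` (500 trees), and
`GradientBoostingClassifier` (1000 trees, logistic link so patch scores
are probabilities in [0, 1]).  Model selection (`grid_select`)
maximizes mean F1 — Epitope always the positive class — over repeated
stratified cross-validation on each training set of a split plan; ties
keep the first-listed combination.  The benchmark studies use fixed
representative hyperparameters instead of a full grid search: the
decision tree is pruned with `min_samples_leaf=3` (matching the shipped
model family, whose tree has no leaf below three samples), the
ensembles use their default tree counts.  Every stochastic step (splits,
CV shuffling, tree training) is seeded and recorded.

MDI feature importances are the Gini impurity reductions normalized to
sum to 1; for ensembles the standard deviation over trees is reported
(0 for a single tree).  Rule extraction walks the decision tree and
returns the root-to-leaf threshold conjunctions of pure Epitope leaves
with at least 3 samples, ordered by leaf population.  The KNN baseline
(k = 3, majority vote, Euclidean distance over standardized
descriptors) is intended for redundant datasets, where instance-based
prediction exploits near-duplicate patches.

## Eplet scores

Single eplet: `S_r` = arithmetic mean of the patch scores over the
antigens carrying the eplet.  Composite eplet: per antigen, the maximum
over the eplet's solvent-accessible residues, then the mean over
antigens.  Antigens contributing no scored residue are dropped from the
average rather than counted as zero — averaging in missing data would
silently deflate scores.  Confirmation uses `score ≥ 0.50`; the
inclusive boundary is the operative convention of the score tables this
mirrors, and it is configurable.  Eplets with no accessible residue on
any carrier are reported as unpatchable rather than scored.

## Synthetic benchmark

The generator emulates the *statistical* structure of the real data,
not its physics: pseudo-protein chains (Cα + one side-chain pseudo-atom
per residue) on a smooth extended curve, per-frame Gaussian jitter, and
occluder shells around buried residues.  Everything the pipeline
computes depends only on coordinates, masses, radii and residue
identities, all faithfully represented.

Reference study conditions (the `SynthConfig` defaults): 40 antigens —
10 alleles in each of 4 loci — with two 30-residue chains, 50 frames,
burial fraction 0.5, and per locus one verified single eplet, one
verified composite eplet and two unconfirmed eplets of which one is a
true epitope in the ground truth.  Carriers are 70 % of a locus's
alleles; polymorphic positions mutate at rate 0.04; half the positions
are locus-conserved.

The planted signal mirrors the class differences the method is designed
to detect.  Baseline side-chain jitter is bimodal — half the residues
are mobile (up to 1.5 Å per axis), half quiet (0.6–0.9 Å) — so an
ordinary surface patch almost surely contains at least one very
flexible member.  In epitope zones (carrier antigens only) the mobile
component is capped 0.5 Å below the baseline maximum: the patch-maximum
flexibility descriptor drops sharply while patch averages move only
mildly, which is what makes `F_patch_max` specifically recoverable by
feature-importance analysis.  A 0.3 fraction of zone positions is
additionally replaced by lysine/arginine in carriers (positive-charge
signal).  The occluder-shell geometry (radius 2.6 Å, 24 atoms) is
calibrated so that a burial fraction of 0.5 yields about half the
residues below the 20 % accessibility cutoff without shadowing exposed
neighbours.

What passing the benchmark shows: the pipeline computes the intended
quantities, and the learning stack can recover a flexibility/charge
signal of realistic direction from them at realistic sample sizes
(~500 labeled patches).  What it does not show: performance on real HLA
trajectories, where class differences are far subtler, descriptors are
correlated through actual physics, and label noise comes from registry
incompleteness rather than from a generative model.

Benchmark problem sizes (ten antigen sets of 40 antigens × 60 residues
× 50 frames, with ensembles of 500/1000 trees) keep the full recovery
study at a few minutes on one CPU.

## Degenerate inputs and tie-breaks

Empty trajectory files, inconsistent atom rosters across frames (the
offending model is named), unknown elements, nonstandard residues in
profiles, zero-variance flexibility populations, single-class training
data and empty prediction maps are all hard errors.  Sequence-cluster
ties, epitope-dedup ties and grid-search ties break deterministically
(lexicographic / first-listed).  The worked fixture (8-residue chains)
uses a 1-residue terminus exclusion because the standard 5-residue
exclusion would empty the normalization population.

## Known limitations

* The loader reads multi-model PDB only; binary trajectory codecs
  (DCD/XTC) would need to be added behind the same reader contract.
* Greedy identity clustering depends on processing order (made
  deterministic); it approximates, not reproduces, dedicated clustering
  tools.
* MDI importance inherits its known biases (correlated features share
  or swap credit); the benchmark's feature-recovery check is designed
  around that fact rather than pretending it away.
* The synthetic generator plants a strong, clean signal; absolute F1
  values on it say nothing about F1 on real antigens.
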