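# epipatch

HLA B-cell epitope prediction from **dynamic 3D-surface patch
descriptors**.

Organ transplants fail mostly through donor-specific antibodies that
recognize B-cell epitopes on the donor's HLA antigens.  Those epitopes
are anchored by *eplets* — small clusters of polymorphic surface
residues — but many polymorphic positions have never been confirmed by
antibody-binding experiments.  `epipatch` implements a prediction
pipeline that decides, from molecular-dynamics structure ensembles of
HLA antigens, whether a surface region behaves like an antibody-bound
epitope.  It is aimed at structural immunologists and
histocompatibility researchers who have trajectory ensembles of HLA
extracellular domains and an eplet registry table, and want per-eplet
confirmation scores.

## Method

1. **Dynamic accessibility.** For each residue `r` and frame `t`,
   Shrake–Rupley SASA (deterministic golden-spiral lattice, 960 points,
   1.4 Å probe) is converted to relative SASA,
   `RSASA(r,t) = 100 · SASA(r,t) / maxASA(aa_r)`, using theoretical
   per-residue maxima.  A residue is *solvent-accessible* when its mean
   RSASA over the trajectory exceeds 20 %.
2. **3D-surface patches.** A patch is centred on an accessible residue
   and contains every accessible residue whose centre of mass lies
   within 15 Å (per frame).  Each member carries a weight
   `w(r) =` fraction of frames spent inside the patch.
3. **18 descriptors per patch.** Kyte–Doolittle hydrophobicity and
   positive/negative charge of the central residue and of the patch
   (`H_*`, `Pos_*`, `Neg_*`); per-frame RSASA statistics of the central
   residue and weighted averages of member RSASA extrema (`S_*`); and
   side-chain flexibility `F_*` as N-RMSF — per-residue RMSF after
   rigid-body superposition, z-scored over the accessible residues with
   five residues per chain terminus excluded.  Weighted aggregates use
   `Σ w(r)·x(r) / Σ w(r)`.
4. **Labeling and redundancy reduction.** A patch is *Epitope* when its
   centre belongs to an antibody-verified eplet carried by the antigen,
   *Nonepitope* only when no member touches any eplet (verified or not)
   and the members are not all locus-conserved.  Alleles are clustered
   at 90 % sequence identity; each cluster contributes Nonepitope
   patches from one representative and deduplicated Epitope patches
   from all members.
5. **Learning and eplet scores.** A CART decision tree, extremely
   randomized trees (500) and gradient-boosted trees (1000) are trained
   with Epitope as positive class (F1 model selection over stratified
   splits).  Per-patch probabilities `pred(r,a)` aggregate to eplet
   scores: `S_r = mean_a pred(r,a)` for single eplets and
   `S_e = mean_a max_{r∈e} pred(r,a)` for composite eplets; a score
   ≥ 0.50 confirms the eplet.

A fully synthetic generator (`epipatch.synthetic`) emits trajectory
PDBs, allele FASTA and registry CSV with a planted, tunable epitope
signal, so the whole pipeline is testable offline.

## Worked example

`examples/03_train_and_interpret.py` generates a 12-antigen synthetic
set, trains the three models and interprets the decision tree:

```
157 eligible patches (32 Epitope / 125 Nonepitope)
DT: held-out F1=0.80 precision=1.00 recall=0.67
ET: held-out F1=0.80 precision=1.00 recall=0.67
GT: held-out F1=0.80 precision=1.00 recall=0.67

decision-tree MDI top 3 (importances sum to 1):
  F_patch_max    0.655
  S_central_avg  0.265
  S_central_min  0.041
complexity: {'n_trees': 1, 'total_nodes': 15, 'mean_nodes_per_tree': 15.0, 'mean_depth': 5.0, 'n_leaves': 8}

rules for the most populated pure Epitope leaves:
  n=28: F_patch_max <= 0.8123 AND S_central_avg > 52.89
```

The held-out F1 of 0.80 on this small set comes from one missed epitope
in a 16-patch test split; the mean-decrease-in-impurity ranking shows
the model has recovered the planted signal — epitope patches are
distinguished by a low *maximum* side-chain flexibility
(`F_patch_max`, in z-units of N-RMSF) — and the extracted rule reads as
"rigid and well-exposed".  The other examples cover accessibility
profiles (`01`), patch construction and descriptors (`02`) and
eplet-level scoring of unconfirmed eplets (`04`).

## Command-line interface

The same pipeline is scriptable over a working directory of trajectory
PDBs, an allele FASTA and a registry CSV:

```sh
epipatch synth --out work --seed 3 --n-antigens 8
epipatch all work --seed 1          # sasa -> patches -> descriptors ->
                                    # label -> reduce -> train -> predict
                                    # -> eplet-score (+ manifest.json)
```

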