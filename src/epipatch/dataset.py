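"""Dataset assembly: labeling, redundancy reduction and splits.

Patches become training samples through three steps:

1. **Labeling** (:func:`label_patch`).  A patch is *Epitope* when its
   central residue belongs to an antibody-verified eplet carried by the
   antigen.  It is *Nonepitope* only when neither the central residue
   nor any member belongs to any eplet (verified or not) and the member
   positions are not all locus-conserved - conserved positions cannot
   raise an alloimmune response, so an all-conserved patch would be a
   "positive unlabeled" trap for the negative class.  Everything else is
   ineligible and excluded from training.

2. **Redundancy reduction** (:func:`reduce_redundancy`).  HLA alleles
   are >90% identical within a locus, so patches are massively
   redundant.  Antigen sequences are clustered at 90% identity; each
   cluster contributes Nonepitope patches only from the member with the
   most Nonepitope patches (the representative) and Epitope patches
   from all members, deduplicated on the central eplet residue.

3. **Splitting** (:func:`make_splits`).  Ten stratified random
   train/test splits (90%/10%) with fixed seeds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .descriptors import DescriptorVector
from .patches import Patch
from .registry import EpletRegistry, PositionMap


class Label(str, enum.Enum):
    EPITOPE = "Epitope"
    NONEPITOPE = "Nonepitope"
    INELIGIBLE = "Ineligible"


@dataclass
class LabeledPatch:
    patch: Patch
    descriptors: DescriptorVector
    label: Label


def conserved_positions(
    alleles: Mapping[str, Sequence[str]],
) -> set[tuple[str, int]]:
    """Locus-conserved positions from per-chain allele sequence sets.

    ``alleles`` maps a chain label to the allele sequences of that
    chain (pre-aligned: equal length, ``-`` for gaps).  Returns the
    (chain, 1-based position) pairs where every allele carries the same
    amino acid.
    """
    conserved: set[tuple[str, int]] = set()
    for chain, seqs in alleles.items():
        seqs = list(seqs)
        if not seqs:
            raise ValueError(f"no allele sequences for chain {chain!r}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"chain {chain!r}: allele sequences must be aligned "
                f"(lengths {sorted(lengths)})"
            )
        for pos in range(lengths.pop()):
            column = {s[pos] for s in seqs}
            if len(column) == 1 and "-" not in column:
                conserved.add((chain, pos + 1))
    return conserved


def label_patch(
    patch: Patch,
    registry: EpletRegistry,
    conserved: set[tuple[str, int]],
    position_map: PositionMap | None = None,
) -> Label:
    """Label one patch as Epitope / Nonepitope / Ineligible (rules above)."""
    any_pos, verified_pos = registry.residue_sets(
        patch.central.antigen_id, position_map
    )
    central_key = (patch.central.chain, patch.central.position)
    if central_key in verified_pos:
        return Label.EPITOPE
    member_keys = [(m.chain, m.position) for m, _ in patch.members]
    if central_key in any_pos:
        return Label.INELIGIBLE
    if any(k in any_pos for k in member_keys):
        return Label.INELIGIBLE
    if all(k in conserved for k in member_keys):
        return Label.INELIGIBLE
    return Label.NONEPITOPE


# ---------------------------------------------------------------------------
# Sequence clustering at 90% identity
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """Partition of sequence ids into identity clusters."""

    clusters: list[tuple[list[str], str]]  # (member ids, representative id)
    identity_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self) -> dict[str, int]:
        return {m: i for i, (members, _) in enumerate(self.clusters) for m in members}


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2.0,
        mismatch_score=-1.0,
        open_gap_score=-4.0,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_sequences(
    seqs: Mapping[str, str], threshold: float = 0.90
) -> ClusterSet:
    """Greedy incremental identity clustering.

    Sequences are processed in decreasing length then lexicographic id;
    a sequence joins the first cluster whose founder it matches at
    ``>= threshold`` global identity, otherwise it founds a new cluster.
    Cluster representatives default to the founder until reassigned by
    :func:`reduce_redundancy`.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    founders: list[str] = []
    members: list[list[str]] = []
    for sid in order:
        placed = False
        for ci, founder in enumerate(founders):
            if pairwise_identity(seqs[sid], seqs[founder]) >= threshold:
                members[ci].append(sid)
                placed = True
                break
        if not placed:
            founders.append(sid)
            members.append([sid])
    return ClusterSet(
        [(sorted(m), f) for m, f in zip(members, founders)], threshold
    )


def reduce_redundancy(
    clusters: ClusterSet, labeled: Iterable[LabeledPatch]
) -> list[LabeledPatch]:
    """Build the non-redundant (NRd) dataset from clustered antigens.

    Per cluster: the antigen with the most Nonepitope patches becomes
    the representative (ties broken by lexicographic antigen id) and
    only its Nonepitope patches are kept; Epitope patches are pooled
    over all cluster members and deduplicated on the central residue's
    (chain, position, aa), preferring the representative's patch, then
    the lowest antigen id.
    """
    labeled = [lp for lp in labeled if lp.label is not Label.INELIGIBLE]
    assignment = clusters.cluster_of()
    for lp in labeled:
        if lp.patch.central.antigen_id not in assignment:
            raise ValueError(
                f"antigen {lp.patch.central.antigen_id!r} is not in any cluster"
            )

    nonep_counts: dict[int, dict[str, int]] = {}
    for lp in labeled:
        if lp.label is Label.NONEPITOPE:
            ci = assignment[lp.patch.central.antigen_id]
            bucket = nonep_counts.setdefault(ci, {})
            aid = lp.patch.central.antigen_id
            bucket[aid] = bucket.get(aid, 0) + 1

    representatives: dict[int, str] = {}
    for ci, (member_ids, _) in enumerate(clusters.clusters):
        counts = nonep_counts.get(ci, {})
        representatives[ci] = min(member_ids, key=lambda a: (-counts.get(a, 0), a))

    out: list[LabeledPatch] = []
    epitope_seen: dict[tuple[int, str, int, str], LabeledPatch] = {}
    for lp in labeled:
        aid = lp.patch.central.antigen_id
        ci = assignment[aid]
        if lp.label is Label.NONEPITOPE:
            if aid == representatives[ci]:
                out.append(lp)
        else:
            c = lp.patch.central
            key = (ci, c.chain, c.position, c.aa)
            prev = epitope_seen.get(key)
            if prev is None:
                epitope_seen[key] = lp
            else:
                prev_aid = prev.patch.central.antigen_id
                rep = representatives[ci]
                if (aid == rep and prev_aid != rep) or (
                    prev_aid != rep and aid < prev_aid
                ):
                    epitope_seen[key] = lp
    out.extend(epitope_seen.values())
    out.sort(key=lambda lp: (lp.patch.central.antigen_id, lp.patch.central.chain,
                             lp.patch.central.position))
    return out


# ---------------------------------------------------------------------------
# Stratified splits
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Reproducible stratified train/test index pairs."""

    n_splits: int
    pairs: list[tuple[np.ndarray, np.ndarray]]
    seeds: list[int]


def make_splits(
    labels: Sequence[str],
    n_splits: int = 10,
    test_fraction: float = 0.10,
    seeds: Sequence[int] | None = None,
) -> SplitPlan:
    """Stratified random splits preserving the class ratio (within one sample)."""
    from sklearn.model_selection import train_test_split

    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for stratified splits")
    if seeds is None:
        seeds = list(range(n_splits))
    if len(seeds) != n_splits:
        raise ValueError("need one seed per split")
    idx = np.arange(len(labels))
    pairs = []
    for seed in seeds:
        train, test = train_test_split(
            idx, test_size=test_fraction, stratify=labels, random_state=seed
        )
        pairs.append((np.sort(train), np.sort(test)))
    return SplitPlan(n_splits, pairs, list(seeds))


def labeled_to_frame(labeled: Iterable[LabeledPatch]):
    """Descriptor matrix with identity and label columns (one row per patch)."""
    import pandas as pd

    rows = []
    for lp in labeled:
        c = lp.patch.central
        row = {
            "antigen_id": c.antigen_id,
            "chain": c.chain,
            "position": c.position,
            "aa": c.aa,
            "label": lp.label.value,
        }
        row.update(lp.descriptors.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
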