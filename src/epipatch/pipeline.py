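"""End-to-end wiring: trajectories -> profiles -> patches -> descriptors
-> labeled dataset.

These functions are the single path from raw ensembles to the feature
matrix; the command-line interface and the benchmark study both call
them, so file-based and in-memory runs share every numerical choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    PATCH_RADIUS,
    PROBE_RADIUS,
    RSASA_THRESHOLD,
    SASA_N_POINTS,
    TERMINI_EXCLUDED,
)
from .dataset import Label, LabeledPatch, conserved_positions, label_patch
from .descriptors import FEATURE_NAMES, compute_descriptors
from .patches import Patch, build_all_patches, identify_accessible
from .registry import EpletRegistry, PositionMap
from .trajectory import (
    AccessibilityProfile,
    FlexibilityProfile,
    ResidueId,
    TrajectoryEnsemble,
    compute_rmsf,
    compute_rsasa,
    compute_sasa,
    normalize_rmsf,
)


@dataclass
class PipelineParams:
    """Numerical knobs of the patch pipeline with their standard defaults."""

    probe: float = PROBE_RADIUS
    n_points: int = SASA_N_POINTS
    rsasa_threshold: float = RSASA_THRESHOLD
    radius: float = PATCH_RADIUS
    termini_excluded: int = TERMINI_EXCLUDED


@dataclass
class AntigenResult:
    """All per-antigen intermediates of the patch pipeline."""

    ensemble: TrajectoryEnsemble
    accessibility: AccessibilityProfile
    flexibility: FlexibilityProfile
    accessible: set[ResidueId]
    patches: list[Patch]
    descriptors: dict[ResidueId, "object"] = field(default_factory=dict)


def process_antigen(
    ensemble: TrajectoryEnsemble, params: PipelineParams | None = None
) -> AntigenResult:
    """Profiles, accessible set, patches and descriptors for one antigen."""
    params = params or PipelineParams()
    sasa = compute_sasa(ensemble, probe=params.probe, n_points=params.n_points)
    acc = compute_rsasa(ensemble, sasa)
    accessible = identify_accessible(acc, params.rsasa_threshold)
    rmsf = compute_rmsf(ensemble)
    flex = normalize_rmsf(ensemble, rmsf, accessible, params.termini_excluded)
    patches = build_all_patches(ensemble, accessible, params.radius)
    descriptors = {p.central: compute_descriptors(p, acc, flex) for p in patches}
    return AntigenResult(ensemble, acc, flex, accessible, patches, descriptors)


def label_antigen(
    result: AntigenResult,
    registry: EpletRegistry,
    conserved: set[tuple[str, int]],
    position_map: PositionMap | None = None,
) -> list[LabeledPatch]:
    """Labeled patches (all three labels, including Ineligible) of one antigen."""
    out = []
    for p in result.patches:
        lab = label_patch(p, registry, conserved, position_map)
        out.append(LabeledPatch(p, result.descriptors[p.central], lab))
    return out


def conserved_from_locus_alleles(
    locus_alleles: dict[str, list[str]],
) -> set[tuple[str, int]]:
    """Locus-conserved (chain, position) set from per-chain allele lists."""
    return conserved_positions(locus_alleles)


def features_matrix(labeled: list[LabeledPatch]) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) over the eligible (Epitope/Nonepitope) patches only."""
    eligible = [lp for lp in labeled if lp.label is not Label.INELIGIBLE]
    X = np.array([lp.descriptors.as_array() for lp in eligible])
    y = np.array([lp.label.value for lp in eligible])
    return X, y


def descriptor_frame(results: list[AntigenResult], labeled=None):
    """One row per patch: ids, optional label, 18 descriptor columns."""
    import pandas as pd

    label_of = {}
    if labeled:
        label_of = {lp.patch.central: lp.label.value for lp in labeled}
    rows = []
    for res in results:
        for p in res.patches:
            c = p.central
            row = {
                "antigen_id": c.antigen_id,
                "chain": c.chain,
                "position": c.position,
                "aa": c.aa,
            }
            if label_of:
                row["label"] = label_of.get(c, "")
            row.update(res.descriptors[c].as_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    ordered = [c for c in ("antigen_id", "chain", "position", "aa", "label")
               if c in df.columns] + list(FEATURE_NAMES)
    return df[ordered]
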