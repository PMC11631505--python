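"""Dynamic 3D-surface patches.

A patch is centered on a solvent-accessible residue and collects all
other solvent-accessible residues whose center of mass lies within a
fixed radius (default 15 A, the footprint of an antibody epitope) of the
central residue's center of mass.  Membership is evaluated per frame;
each member carries a weight equal to the fraction of frames in which it
is inside the radius, so the patch roster is the union over frames and
the weights encode how persistently each residue belongs to the patch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .constants import PATCH_RADIUS, RSASA_THRESHOLD
from .trajectory import AccessibilityProfile, ResidueId, TrajectoryEnsemble


@dataclass
class Patch:
    """Surface patch: central residue plus weighted member roster."""

    central: ResidueId
    members: list[tuple[ResidueId, float]]
    radius: float
    n_frames: int

    def __post_init__(self) -> None:
        weights = dict(self.members)
        if self.central not in weights or weights[self.central] != 1.0:
            raise ValueError("central residue must be a member with weight 1.0")
        if any(not (0.0 < w <= 1.0) for w in weights.values()):
            raise ValueError("member weights must lie in (0, 1]")

    @property
    def weights(self) -> dict[ResidueId, float]:
        return dict(self.members)


def identify_accessible(
    profile: AccessibilityProfile, threshold: float = RSASA_THRESHOLD
) -> set[ResidueId]:
    """Residues whose mean RSASA over the trajectory is strictly above threshold (%)."""
    mean = profile.rsasa_mean
    return {r for r, m in zip(profile.residues, mean) if m > threshold}


def residue_center(
    ensemble: TrajectoryEnsemble, frame: int, residue: ResidueId
) -> np.ndarray:
    """Mass-weighted center of the residue's heavy atoms in one frame."""
    idx = ensemble.residue_index(residue)
    atoms = ensemble.residue_atoms[idx]
    if len(atoms) == 0:
        raise ValueError(f"residue {residue} has no heavy atoms")
    m = ensemble.masses[atoms]
    return (ensemble.coords[frame, atoms] * m[:, None]).sum(axis=0) / m.sum()


def all_residue_centers(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Per-frame mass-weighted residue centers, shape ``(n_frames, n_res, 3)``."""
    n_frames, n_res = ensemble.n_frames, len(ensemble.residues)
    out = np.empty((n_frames, n_res, 3))
    for r, atoms in enumerate(ensemble.residue_atoms):
        m = ensemble.masses[atoms]
        out[:, r] = (ensemble.coords[:, atoms] * m[None, :, None]).sum(axis=1) / m.sum()
    return out


def build_patch(
    central: ResidueId,
    ensemble: TrajectoryEnsemble,
    accessible: Iterable[ResidueId],
    radius: float = PATCH_RADIUS,
    centers: np.ndarray | None = None,
) -> Patch:
    """Build the patch around ``central`` (must itself be accessible).

    For every frame the member set is the accessible residues whose
    center of mass is within ``radius`` (closed ball) of the central
    residue's center; the returned roster is the union over frames with
    frame-presence fractions as weights.
    """
    accessible = set(accessible)
    if central not in accessible:
        raise ValueError(f"central residue {central} is not solvent-accessible")
    if centers is None:
        centers = all_residue_centers(ensemble)
    c = ensemble.residue_index(central)
    acc_idx = np.array(
        sorted(ensemble.residue_index(r) for r in accessible), dtype=np.intp
    )
    d = np.linalg.norm(centers[:, acc_idx] - centers[:, c : c + 1], axis=2)
    counts = (d <= radius).sum(axis=0)  # per accessible residue
    members: list[tuple[ResidueId, float]] = []
    for i, cnt in zip(acc_idx, counts):
        if i == c:
            members.append((ensemble.residues[i], 1.0))
        elif cnt > 0:
            members.append((ensemble.residues[i], cnt / ensemble.n_frames))
    return Patch(central, members, radius, ensemble.n_frames)


def build_all_patches(
    ensemble: TrajectoryEnsemble,
    accessible: Iterable[ResidueId],
    radius: float = PATCH_RADIUS,
) -> list[Patch]:
    """One patch per solvent-accessible residue, sharing one center computation."""
    accessible = set(accessible)
    centers = all_residue_centers(ensemble)
    order = sorted(accessible, key=lambda r: (r.chain, r.position))
    return [
        build_patch(r, ensemble, accessible, radius, centers=centers) for r in order
    ]


def patches_to_frame(patches: Iterable[Patch]):
    """Tidy member-level table of a patch collection."""
    import pandas as pd

    rows = []
    for p in patches:
        for member, w in p.members:
            rows.append(
                {
                    "antigen_id": p.central.antigen_id,
                    "central_chain": p.central.chain,
                    "central_position": p.central.position,
                    "central_aa": p.central.aa,
                    "member_chain": member.chain,
                    "member_position": member.position,
                    "member_aa": member.aa,
                    "weight": w,
                }
            )
    return pd.DataFrame(rows)
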