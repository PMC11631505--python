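"""The 18 static and dynamic descriptors of a 3D-surface patch.

Static descriptors depend only on residue identity: Kyte-Doolittle
hydrophobicity of the central residue and min/max/mean over the patch,
charge indicators of the central residue and summed charges over the
patch.  Dynamic descriptors summarize the trajectory: min/max/mean RSASA
of the central residue over frames, frame-presence-weighted averages of
the members' per-frame RSASA extrema and means, and N-RMSF of the
central residue plus min/max and weighted average over members.

Patch-level hydrophobicity and charge descriptors are unweighted; only
the RSASA patch aggregates and the N-RMSF patch average carry the
frame-presence weights.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .constants import KYTE_DOOLITTLE, NEGATIVE_AAS, POSITIVE_AAS
from .patches import Patch
from .trajectory import AccessibilityProfile, FlexibilityProfile

#: Canonical descriptor order used for feature matrices.
FEATURE_NAMES: tuple[str, ...] = (
    "H_central",
    "H_patch_min",
    "H_patch_max",
    "H_patch_avg",
    "Pos_central",
    "Pos_patch",
    "Neg_central",
    "Neg_patch",
    "S_central_min",
    "S_central_max",
    "S_central_avg",
    "S_patch_min",
    "S_patch_max",
    "S_patch_avg",
    "F_central",
    "F_patch_min",
    "F_patch_max",
    "F_patch_avg",
)


def hydrophobicity(aa: str) -> float:
    """Kyte-Doolittle hydropathy of a one-letter residue code."""
    try:
        return KYTE_DOOLITTLE[aa]
    except KeyError:
        raise ValueError(f"no hydrophobicity value for residue code {aa!r}") from None


def charge_indicators(aa: str) -> tuple[int, int]:
    """(positive, negative) charge indicators: (1,0) for K/R, (0,-1) for D/E."""
    return (1 if aa in POSITIVE_AAS else 0, -1 if aa in NEGATIVE_AAS else 0)


@dataclass(frozen=True)
class DescriptorVector:
    """The 18 named features of one patch, in canonical order."""

    H_central: float
    H_patch_min: float
    H_patch_max: float
    H_patch_avg: float
    Pos_central: int
    Pos_patch: int
    Neg_central: int
    Neg_patch: int
    S_central_min: float
    S_central_max: float
    S_central_avg: float
    S_patch_min: float
    S_patch_max: float
    S_patch_avg: float
    F_central: float
    F_patch_min: float
    F_patch_max: float
    F_patch_avg: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_descriptors(
    patch: Patch,
    acc: AccessibilityProfile,
    flex: FlexibilityProfile,
) -> DescriptorVector:
    """Compute all 18 descriptors of a patch from its antigen's profiles.

    Every member's RSASA statistics are taken over all frames of the
    trajectory (RSASA is a residue property), even for members present
    in the patch only part of the time; the weights enter only in the
    weighted averages.
    """
    members = [m for m, _ in patch.members]
    weights = np.array([w for _, w in patch.members], dtype=float)

    for m in members:
        acc.index(m)
        flex.index(m)

    h = np.array([hydrophobicity(m.aa) for m in members])
    charges = np.array([charge_indicators(m.aa) for m in members])
    c = patch.central
    pos_c, neg_c = charge_indicators(c.aa)

    ci = acc.index(c)
    central_rsasa = acc.rsasa[ci]

    idx = np.array([acc.index(m) for m in members])
    s_min = acc.rsasa_min[idx]
    s_max = acc.rsasa_max[idx]
    s_avg = acc.rsasa_mean[idx]

    fidx = np.array([flex.index(m) for m in members])
    nrmsf = flex.nrmsf[fidx]
    wsum = weights.sum()

    return DescriptorVector(
        H_central=hydrophobicity(c.aa),
        H_patch_min=float(h.min()),
        H_patch_max=float(h.max()),
        H_patch_avg=float(h.mean()),
        Pos_central=int(pos_c),
        Pos_patch=int(charges[:, 0].sum()),
        Neg_central=int(neg_c),
        Neg_patch=int(charges[:, 1].sum()),
        S_central_min=float(central_rsasa.min()),
        S_central_max=float(central_rsasa.max()),
        S_central_avg=float(central_rsasa.mean()),
        S_patch_min=float((weights * s_min).sum() / wsum),
        S_patch_max=float((weights * s_max).sum() / wsum),
        S_patch_avg=float((weights * s_avg).sum() / wsum),
        F_central=float(flex.nrmsf[flex.index(c)]),
        F_patch_min=float(nrmsf.min()),
        F_patch_max=float(nrmsf.max()),
        F_patch_avg=float((weights * nrmsf).sum() / wsum),
    )
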