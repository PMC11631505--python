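"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately implemented the slow, obvious way and,
where possible, through different library code paths than the package
(random-point SASA sampling instead of the golden-spiral lattice,
scipy's rotation alignment instead of the package's Kabsch SVD, plain
double loops instead of vectorized membership tests).
"""

from __future__ import annotations

import numpy as np

from epipatch.constants import (
    ATOMIC_MASSES,
    KYTE_DOOLITTLE,
    MAX_ASA_THEORETICAL,
    NEGATIVE_AAS,
    POSITIVE_AAS,
)


def random_sphere_points(n: int, seed: int = 12345) -> np.ndarray:
    """Uniform points on the unit sphere from a seeded Gaussian draw."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def brute_atom_sasa(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, n_points: int = 9600
) -> np.ndarray:
    """Point-sampling SASA with random dense points and all-pairs occlusion."""
    coords = np.asarray(coords, dtype=float)
    rext = np.asarray(radii, dtype=float) + probe
    pts = random_sphere_points(n_points)
    out = np.empty(len(coords))
    for a in range(len(coords)):
        p = coords[a] + rext[a] * pts
        exposed = np.ones(n_points, dtype=bool)
        for b in range(len(coords)):
            if b == a:
                continue
            d2 = ((p - coords[b]) ** 2).sum(axis=1)
            exposed &= d2 >= rext[b] ** 2
        out[a] = 4.0 * np.pi * rext[a] ** 2 * exposed.mean()
    return out


def brute_residue_sasa(ensemble, probe: float = 1.4, n_points: int = 9600) -> np.ndarray:
    """Per-residue per-frame SASA by the brute-force atom oracle."""
    out = np.zeros((len(ensemble.residues), ensemble.n_frames))
    for f in range(ensemble.n_frames):
        per_atom = brute_atom_sasa(ensemble.coords[f], ensemble.radii, probe, n_points)
        for r, atoms in enumerate(ensemble.residue_atoms):
            out[r, f] = per_atom[atoms].sum()
    return out


def brute_rmsf(ensemble) -> np.ndarray:
    """Side-chain RMSF via scipy's rotation alignment (two-pass mean ref)."""
    from scipy.spatial.transform import Rotation

    ca = ensemble.ca_indices()
    coords = ensemble.coords

    def align(reference, frames):
        ref = reference[ca]
        ref_c = ref.mean(axis=0)
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            sel = frames[f][ca]
            cen = sel.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref - ref_c, sel - cen)
            out[f] = rot.apply(frames[f] - cen) + ref_c
        return out

    aligned = align(coords[0], coords)
    aligned = align(aligned.mean(axis=0), aligned)
    mean_pos = aligned.mean(axis=0)
    atom_rmsf = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    return np.array([atom_rmsf[a].mean() for a in ensemble.sidechain_atoms])


def brute_center(ensemble, frame: int, res_index: int) -> np.ndarray:
    """Mass-weighted residue center by direct summation."""
    total = np.zeros(3)
    msum = 0.0
    for a in ensemble.residue_atoms[res_index]:
        m = ATOMIC_MASSES[ensemble.elements[a]]
        total += m * ensemble.coords[frame, a]
        msum += m
    return total / msum


def brute_patch_members(
    ensemble, central, accessible, radius: float = 15.0
) -> dict:
    """Frame x residue double-loop patch membership with presence weights."""
    c_idx = ensemble.residues.index(central)
    counts: dict = {}
    for f in range(ensemble.n_frames):
        cc = brute_center(ensemble, f, c_idx)
        for r_idx, rid in enumerate(ensemble.residues):
            if rid not in accessible:
                continue
            d = np.linalg.norm(brute_center(ensemble, f, r_idx) - cc)
            if d <= radius:
                counts[rid] = counts.get(rid, 0) + 1
    weights = {rid: n / ensemble.n_frames for rid, n in counts.items()}
    weights[central] = 1.0
    return weights


def brute_descriptors(weights: dict, central, rsasa_rows: dict, nrmsf: dict) -> dict:
    """The 18 descriptors by direct arithmetic over explicit python loops.

    ``rsasa_rows`` maps residue -> per-frame RSASA list; ``nrmsf`` maps
    residue -> N-RMSF; ``weights`` is the patch roster.
    """
    members = sorted(weights, key=lambda r: (r.chain, r.position))
    h = [KYTE_DOOLITTLE[m.aa] for m in members]
    pos = [1 if m.aa in POSITIVE_AAS else 0 for m in members]
    neg = [-1 if m.aa in NEGATIVE_AAS else 0 for m in members]
    wsum = sum(weights[m] for m in members)

    def wavg(values):
        return sum(weights[m] * v for m, v in zip(members, values)) / wsum

    s_min = [min(rsasa_rows[m]) for m in members]
    s_max = [max(rsasa_rows[m]) for m in members]
    s_avg = [sum(rsasa_rows[m]) / len(rsasa_rows[m]) for m in members]
    f_vals = [nrmsf[m] for m in members]
    central_rs = rsasa_rows[central]
    return {
        "H_central": KYTE_DOOLITTLE[central.aa],
        "H_patch_min": min(h),
        "H_patch_max": max(h),
        "H_patch_avg": sum(h) / len(h),
        "Pos_central": 1 if central.aa in POSITIVE_AAS else 0,
        "Pos_patch": sum(pos),
        "Neg_central": -1 if central.aa in NEGATIVE_AAS else 0,
        "Neg_patch": sum(neg),
        "S_central_min": min(central_rs),
        "S_central_max": max(central_rs),
        "S_central_avg": sum(central_rs) / len(central_rs),
        "S_patch_min": wavg(s_min),
        "S_patch_max": wavg(s_max),
        "S_patch_avg": wavg(s_avg),
        "F_central": nrmsf[central],
        "F_patch_min": min(f_vals),
        "F_patch_max": max(f_vals),
        "F_patch_avg": wavg(f_vals),
    }


def brute_label(patch_weights, central, any_eplet, verified_eplet, conserved) -> str:
    """Labeling rules re-stated independently."""
    ck = (central.chain, central.position)
    if ck in verified_eplet:
        return "Epitope"
    member_keys = [(m.chain, m.position) for m in patch_weights]
    if ck in any_eplet or any(k in any_eplet for k in member_keys):
        return "Ineligible"
    if all(k in conserved for k in member_keys):
        return "Ineligible"
    return "Nonepitope"


def isolated_sphere_sasa(r_atom: float, probe: float = 1.4) -> float:
    """Closed form for an isolated atom: 4 pi (r + probe)^2."""
    return 4.0 * np.pi * (r_atom + probe) ** 2


def brute_conserved(seqs_by_chain: dict) -> set:
    out = set()
    for chain, seqs in seqs_by_chain.items():
        for i in range(len(seqs[0])):
            col = {s[i] for s in seqs}
            if len(col) == 1 and "-" not in col:
                out.add((chain, i + 1))
    return out
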