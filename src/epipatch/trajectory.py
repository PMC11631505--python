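"""Trajectory ensembles, solvent accessibility and side-chain flexibility.

The unit of input is a *trajectory ensemble*: heavy-atom coordinates of a
multi-chain antigen over one or more frames (typically saved from a
molecular-dynamics run).  From it this module computes

* per-residue, per-frame solvent-accessible surface area (SASA, A^2)
  with a deterministic Shrake-Rupley implementation,
* relative SASA (RSASA, %) against theoretical per-residue maxima,
* per-residue side-chain RMSF after rigid-body superposition, and
* z-score normalized RMSF (N-RMSF) over the solvent-accessible residues
  with the artefactually flexible chain termini excluded.

Only heavy atoms are considered; hydrogens present in the input are
dropped on loading.  Residues whose name is not one of the 20 standard
amino acids are kept as *occluder* pseudo-atoms: they shield other
residues from solvent but carry no profile of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .constants import (
    ATOMIC_MASSES,
    MAX_ASA_THEORETICAL,
    PROBE_RADIUS,
    SASA_N_POINTS,
    TERMINI_EXCLUDED,
    THREE_TO_ONE,
    VDW_RADII,
)


class ParseError(ValueError):
    """Raised when a trajectory file cannot be interpreted."""


class ResidueId(NamedTuple):
    """Identity of a residue: antigen, chain, 1-based position, one-letter code."""

    antigen_id: str
    chain: str
    position: int
    aa: str


@dataclass
class TrajectoryEnsemble:
    """Multi-frame heavy-atom coordinates of one antigen.

    Attributes
    ----------
    antigen_id:
        Identifier of the antigen the frames belong to.
    coords:
        Array of shape ``(n_frames, n_atoms, 3)``, Angstrom.
    elements, masses, radii:
        Per-atom element symbol, standard atomic mass and van der Waals
        radius.
    atom_residue:
        Per-atom index into :attr:`residues`, or ``-1`` for occluder
        pseudo-atoms that belong to no standard residue.
    residues:
        Ordered :class:`ResidueId` list (all chains concatenated).
    residue_atoms, sidechain_atoms:
        Per-residue arrays of atom indices; ``sidechain_atoms`` holds the
        side-chain heavy atoms (the CA atom for glycine or for residues
        modelled without a side chain).
    chains:
        Mapping from chain label to the ordered residue indices of that
        chain.
    """

    antigen_id: str
    coords: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    atom_residue: np.ndarray
    residues: list[ResidueId]
    residue_atoms: list[np.ndarray]
    sidechain_atoms: list[np.ndarray]
    chains: dict[str, list[int]]
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]
    radii: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.masses is None or self.radii is None:
            masses = np.empty(len(self.elements))
            radii = np.empty(len(self.elements))
            for i, el in enumerate(self.elements):
                try:
                    masses[i] = ATOMIC_MASSES[el]
                    radii[i] = VDW_RADII[el]
                except KeyError:
                    raise ValueError(
                        f"unknown element {el!r} for atom index {i} "
                        f"({self.atom_names[i]!r})"
                    ) from None
            self.masses, self.radii = masses, radii

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_index(self, residue: ResidueId) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue} not in ensemble") from None

    def chain_sequence(self, chain: str) -> str:
        return "".join(self.residues[i].aa for i in self.chains[chain])

    def ca_indices(self) -> np.ndarray:
        """Atom indices of CA atoms (used for rigid-body superposition)."""
        idx = [
            a
            for atoms in self.residue_atoms
            for a in atoms
            if self.atom_names[a] == "CA"
        ]
        if not idx:  # degenerate toy systems: align on every heavy atom
            idx = [a for atoms in self.residue_atoms for a in atoms]
        return np.asarray(idx, dtype=np.intp)


def load_trajectory(path: str | Path, antigen_id: str | None = None) -> TrajectoryEnsemble:
    """Read a multi-model PDB file into a :class:`TrajectoryEnsemble`.

    Every ``MODEL`` block is one frame; a file without ``MODEL`` records
    is a single-frame (static) ensemble.  Hydrogens are dropped.  All
    models must list the same atoms; a mismatch raises a
    :class:`ParseError` naming the offending model.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        _diagnose_model_mismatch(text, path)
        raise ParseError(f"{path}: inconsistent models ({exc})") from exc
    return ensemble_from_arrays(
        antigen_id or path.stem,
        coords=np.asarray(stack.coord, dtype=np.float64),
        chain_ids=stack.chain_id,
        res_ids=stack.res_id,
        res_names=stack.res_name,
        atom_names=stack.atom_name,
        elements=stack.element,
    )


def _diagnose_model_mismatch(text: str, path: Path) -> None:
    counts: list[int] = []
    current: int | None = None
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = 0
        elif line.startswith("ENDMDL"):
            counts.append(current or 0)
            current = None
        elif current is not None and line.startswith(("ATOM", "HETATM")):
            current += 1
    if counts and len(set(counts)) > 1:
        ref = counts[0]
        for m, c in enumerate(counts, start=1):
            if c != ref:
                raise ParseError(
                    f"{path}: model {m} has {c} atoms, expected {ref} "
                    f"(frames must share one atom roster)"
                )


def ensemble_from_arrays(
    antigen_id: str,
    coords: np.ndarray,
    chain_ids: Sequence[str],
    res_ids: Sequence[int],
    res_names: Sequence[str],
    atom_names: Sequence[str],
    elements: Sequence[str],
) -> TrajectoryEnsemble:
    """Assemble an ensemble from flat per-atom annotation arrays.

    Residues are renumbered 1-based per chain in order of appearance;
    non-standard residue names become occluder pseudo-atoms.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    elements = np.array([str(e).upper() for e in elements])
    keep = elements != "H"
    coords = coords[:, keep]
    chain_ids = np.asarray(chain_ids)[keep]
    res_ids = np.asarray(res_ids)[keep]
    res_names = np.asarray(res_names)[keep]
    atom_names = np.asarray(atom_names)[keep]
    elements = elements[keep]

    n_atoms = coords.shape[1]
    atom_residue = np.full(n_atoms, -1, dtype=np.intp)
    residues: list[ResidueId] = []
    residue_atoms: list[list[int]] = []
    chains: dict[str, list[int]] = {}
    chain_counter: dict[str, int] = {}
    seen: dict[tuple[str, int], int] = {}

    for a in range(n_atoms):
        name3 = str(res_names[a]).upper()
        if name3 not in THREE_TO_ONE:
            continue  # occluder pseudo-atom
        key = (str(chain_ids[a]), int(res_ids[a]))
        if key not in seen:
            chain = key[0]
            chain_counter[chain] = chain_counter.get(chain, 0) + 1
            rid = ResidueId(antigen_id, chain, chain_counter[chain], THREE_TO_ONE[name3])
            seen[key] = len(residues)
            residues.append(rid)
            residue_atoms.append([])
            chains.setdefault(chain, []).append(seen[key])
        idx = seen[key]
        atom_residue[a] = idx
        residue_atoms[idx].append(a)

    sidechain_atoms: list[np.ndarray] = []
    for atoms in residue_atoms:
        backbone = {"N", "CA", "C", "O", "OXT"}
        side = [a for a in atoms if atom_names[a] not in backbone]
        if not side:
            side = [a for a in atoms if atom_names[a] == "CA"] or list(atoms)
        sidechain_atoms.append(np.asarray(side, dtype=np.intp))

    return TrajectoryEnsemble(
        antigen_id=antigen_id,
        coords=coords,
        elements=elements,
        atom_names=atom_names,
        atom_residue=atom_residue,
        residues=residues,
        residue_atoms=[np.asarray(a, dtype=np.intp) for a in residue_atoms],
        sidechain_atoms=sidechain_atoms,
        chains=chains,
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA with a deterministic golden-spiral point set
# ---------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the golden-spiral lattice."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _anchor_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation anchoring the point lattice to the molecule.

    The lattice is expressed in the principal axes of the atom-position
    covariance, with eigenvector signs fixed by the sign of the
    coordinate skewness along each axis, so a common rigid-body
    transform of all atoms rotates the lattice along with them and the
    computed SASA is exactly invariant.  Falls back to the identity for
    degenerate cases (a single atom), where orientation cannot matter.
    """
    if len(coords) < 2:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    for k in range(3):
        s = np.sum((centered @ vecs[:, k]) ** 3)
        if s < 0:
            vecs[:, k] = -vecs[:, k]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])  # right-handed basis
    return vecs


def _neighbor_csr(coords: np.ndarray, rext: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed neighbor lists (CSR) of atoms whose extended spheres overlap."""
    from scipy.spatial import cKDTree

    cutoff = 2.0 * rext.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(coords)
    if len(pairs) == 0:
        return np.zeros(n + 1, dtype=np.intp), np.empty(0, dtype=np.intp)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    keep = d < rext[i] + rext[j]
    i, j = i[keep], j[keep]
    order = np.argsort(i, kind="stable")
    i, j = i[order], j[order]
    indptr = np.zeros(n + 1, dtype=np.intp)
    np.add.at(indptr, i + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, j.astype(np.intp)


def _atom_sasa_numpy(coords, rext, indptr, indices, pts, targets) -> np.ndarray:
    out = np.zeros(len(coords))
    for a in targets:
        nb = indices[indptr[a] : indptr[a + 1]]
        p = coords[a] + rext[a] * pts
        if len(nb):
            d2 = ((p[None, :, :] - coords[nb][:, None, :]) ** 2).sum(-1)
            exposed = (d2 >= rext[nb][:, None] ** 2).all(0)
            frac = exposed.mean()
        else:
            frac = 1.0
        out[a] = 4.0 * np.pi * rext[a] ** 2 * frac
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False)
    def _atom_sasa_kernel(coords, rext, indptr, indices, pts, targets):  # pragma: no cover
        n = coords.shape[0]
        np_pts = pts.shape[0]
        out = np.zeros(n)
        for t in range(targets.shape[0]):
            a = targets[t]
            ra = rext[a]
            cnt = 0
            for p in range(np_pts):
                x = coords[a, 0] + ra * pts[p, 0]
                y = coords[a, 1] + ra * pts[p, 1]
                z = coords[a, 2] + ra * pts[p, 2]
                exposed = True
                for k in range(indptr[a], indptr[a + 1]):
                    b = indices[k]
                    dx = x - coords[b, 0]
                    dy = y - coords[b, 1]
                    dz = z - coords[b, 2]
                    if dx * dx + dy * dy + dz * dz < rext[b] * rext[b]:
                        exposed = False
                        break
                if exposed:
                    cnt += 1
            out[a] = 4.0 * np.pi * ra * ra * cnt / np_pts
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA (A^2) for one frame.

    ``targets`` limits the computation to the given atom indices (all
    atoms still act as occluders); non-target entries are zero.
    """
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    rext = np.ascontiguousarray(radii + probe, dtype=np.float64)
    pts = np.ascontiguousarray(sphere_points(n_points) @ _anchor_frame(coords).T)
    if targets is None:
        targets = np.arange(len(coords), dtype=np.intp)
    else:
        targets = np.ascontiguousarray(targets, dtype=np.intp)
    indptr, indices = _neighbor_csr(coords, rext)
    if _HAVE_NUMBA:
        return _atom_sasa_kernel(coords, rext, indptr, indices, pts, targets)
    return _atom_sasa_numpy(coords, rext, indptr, indices, pts, targets)


def compute_sasa(
    ensemble: TrajectoryEnsemble,
    probe: float = PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
) -> np.ndarray:
    """Per-residue, per-frame SASA, shape ``(n_residues, n_frames)``.

    A residue's SASA is the sum over its heavy atoms; occluder
    pseudo-atoms shield their neighbourhood but are not reported.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    n_res = len(ensemble.residues)
    out = np.zeros((n_res, ensemble.n_frames))
    targets = np.flatnonzero(ensemble.atom_residue >= 0).astype(np.intp)
    for f in range(ensemble.n_frames):
        per_atom = atom_sasa(
            ensemble.coords[f], ensemble.radii, probe, n_points, targets=targets
        )
        for r, atoms in enumerate(ensemble.residue_atoms):
            out[r, f] = per_atom[atoms].sum()
    return out


# ---------------------------------------------------------------------------
# Accessibility and flexibility profiles
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityProfile:
    """Per-residue per-frame SASA and RSASA for one antigen.

    RSASA is expressed in percent of the residue type's theoretical
    maximum and is *not* capped at 100%.
    """

    residues: list[ResidueId]
    sasa: np.ndarray  # (n_res, n_frames), A^2
    rsasa: np.ndarray  # (n_res, n_frames), %

    def __post_init__(self) -> None:
        self._index = {r: i for i, r in enumerate(self.residues)}

    @property
    def rsasa_min(self) -> np.ndarray:
        return self.rsasa.min(axis=1)

    @property
    def rsasa_max(self) -> np.ndarray:
        return self.rsasa.max(axis=1)

    @property
    def rsasa_mean(self) -> np.ndarray:
        return self.rsasa.mean(axis=1)

    def index(self, residue: ResidueId) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise KeyError(f"no accessibility profile for residue {residue}") from None

    def to_frame(self):
        """Tidy per-(residue, frame) table: one row per residue and frame."""
        import pandas as pd

        n_res, n_frames = self.sasa.shape
        rows = {
            "antigen_id": np.repeat([r.antigen_id for r in self.residues], n_frames),
            "chain": np.repeat([r.chain for r in self.residues], n_frames),
            "position": np.repeat([r.position for r in self.residues], n_frames),
            "aa": np.repeat([r.aa for r in self.residues], n_frames),
            "frame": np.tile(np.arange(n_frames), n_res),
            "sasa": self.sasa.ravel(),
            "rsasa": self.rsasa.ravel(),
        }
        return pd.DataFrame(rows)


def compute_rsasa(
    ensemble: TrajectoryEnsemble, sasa: np.ndarray | None = None, **sasa_kwargs
) -> AccessibilityProfile:
    """Relative SASA profile: 100 * SASA / theoretical max of the residue type."""
    if sasa is None:
        sasa = compute_sasa(ensemble, **sasa_kwargs)
    sasa = np.atleast_2d(np.asarray(sasa, dtype=np.float64))
    maxima = np.empty(len(ensemble.residues))
    for i, r in enumerate(ensemble.residues):
        try:
            maxima[i] = MAX_ASA_THEORETICAL[r.aa]
        except KeyError:
            raise ValueError(f"no theoretical max ASA for residue code {r.aa!r}") from None
    rsasa = 100.0 * sasa / maxima[:, None]
    return AccessibilityProfile(list(ensemble.residues), sasa, rsasa)


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (A) and z-normalized N-RMSF for one antigen."""

    residues: list[ResidueId]
    rmsf: np.ndarray
    nrmsf: np.ndarray
    population: list[ResidueId]

    def __post_init__(self) -> None:
        self._index = {r: i for i, r in enumerate(self.residues)}

    def index(self, residue: ResidueId) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise KeyError(f"no flexibility profile for residue {residue}") from None


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix superposing centered ``mobile`` onto ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    return u @ corr @ vt


def superpose_frames(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Rigid-body superpose all frames (Kabsch on CA atoms).

    Two passes: every frame is first aligned to frame 0, the mean
    structure of the aligned frames is then used as the final reference.
    Returns aligned coordinates, same shape as ``ensemble.coords``.
    """
    ca = ensemble.ca_indices()
    coords = ensemble.coords.copy()

    def align_to(reference: np.ndarray, frames: np.ndarray) -> np.ndarray:
        ref_sel = reference[ca]
        ref_cen = ref_sel.mean(axis=0)
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            sel = frames[f][ca]
            cen = sel.mean(axis=0)
            rot = kabsch_rotation(sel - cen, ref_sel - ref_cen)
            out[f] = (frames[f] - cen) @ rot + ref_cen
        return out

    aligned = align_to(coords[0], coords)
    mean_structure = aligned.mean(axis=0)
    return align_to(mean_structure, aligned)


def compute_rmsf(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Per-residue side-chain RMSF (A) over superposed frames.

    Frames are rigid-body superposed first, so a trajectory that only
    tumbles as a rigid body has zero RMSF.  Per atom the RMSF is the
    root-mean-square deviation from the atom's mean position; per
    residue it is averaged over side-chain heavy atoms (CA for glycine).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    aligned = superpose_frames(ensemble)
    mean_pos = aligned.mean(axis=0)
    dev2 = ((aligned - mean_pos) ** 2).sum(axis=2)  # (F, A)
    atom_rmsf = np.sqrt(dev2.mean(axis=0))
    return np.array(
        [atom_rmsf[atoms].mean() for atoms in ensemble.sidechain_atoms]
    )


def normalize_rmsf(
    ensemble: TrajectoryEnsemble,
    rmsf: np.ndarray,
    accessible: Iterable[ResidueId],
    termini_excluded: int = TERMINI_EXCLUDED,
) -> FlexibilityProfile:
    """Z-score RMSF over the accessible residues, termini excluded.

    The normalization population is the set of solvent-accessible
    residues minus the first and last ``termini_excluded`` positions of
    each chain (their flexibility is artefactually high).  All residues
    - inside or outside the population - receive an N-RMSF through the
    population's mean and standard deviation.
    """
    accessible = set(accessible)
    population_idx: list[int] = []
    for chain, res_idx in ensemble.chains.items():
        n = len(res_idx)
        for k, i in enumerate(res_idx):
            if k < termini_excluded or k >= n - termini_excluded:
                continue
            if ensemble.residues[i] in accessible:
                population_idx.append(i)
    if len(population_idx) < 2:
        raise ValueError(
            "normalization population has fewer than 2 residues "
            f"({len(population_idx)} accessible non-terminal residues)"
        )
    pop = rmsf[population_idx]
    mu = pop.mean()
    sigma = pop.std(ddof=0)
    if sigma == 0:
        raise ValueError("degenerate ensemble: zero RMSF variance in population")
    nrmsf = (rmsf - mu) / sigma
    population = [ensemble.residues[i] for i in population_idx]
    return FlexibilityProfile(list(ensemble.residues), rmsf, nrmsf, population)
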