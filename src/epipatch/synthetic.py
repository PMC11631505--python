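"""Self-contained synthetic fixtures with a planted epitope signal.

The generator emits everything the pipeline consumes - multi-model PDB
trajectory ensembles, an allele FASTA, an eplet registry CSV and a
ground-truth table - with no external data.  Antigens are pseudo-protein
chains laid on a smooth extended curve, two heavy pseudo-atoms per
residue (CA backbone + CB side chain); per-frame Gaussian jitter of the
side-chain atom realizes the flexibility model and buried residues are
wrapped in a static shell of occluder pseudo-atoms that removes their
solvent accessibility.

The planted class signal mirrors what distinguishes real epitope
patches.  Baseline side-chain flexibility is bimodal - a
``flexible_fraction`` minority of residues is highly mobile - so every
ordinary surface patch contains at least one very flexible member.
Around the residues of "effect-bearing" eplets the maximal side-chain
jitter is capped ``delta_flex`` below the baseline maximum (epitopes
are rigid relative to the rest of the surface), which depresses the
patch-maximum flexibility descriptor specifically, and a
``delta_charge`` fraction of zone residues is replaced by
lysine/arginine (positive-charge patch descriptor).  Effects apply only
to antigens that actually carry the eplet, so labels derived from the
emitted registry agree with the planted signal.

Geometry is deliberately not physically realistic: every quantity the
pipeline computes depends only on coordinates, masses, radii and
residue identities, all of which are faithfully represented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .registry import EpletRecord, EpletRegistry, write_registry
from .trajectory import TrajectoryEnsemble, ensemble_from_arrays, sphere_points
from .constants import ONE_TO_THREE

AAS = "ACDEFGHIKLMNPQRSTVWY"

#: residue spacing along the chain curve (A)
_RISE = 3.2
#: lateral offset of the side-chain pseudo-atom from the backbone (A)
_CB_OFFSET = 3.5
#: occluder shell: radius (A) and number of pseudo-atoms, calibrated so
#: that a wrapped residue's mean RSASA falls well below the 20%
#: accessibility cutoff without shadowing its exposed neighbours
_SHELL_RADIUS = 2.6
_SHELL_POINTS = 24
#: inter-chain spacing (A)
_CHAIN_OFFSET = 20.0
#: positions within this many residues of an eplet residue form its
#: effect zone (covers the reach of a 15 A patch on this geometry,
#: including members that enter the patch only transiently)
_ZONE_REACH = 5


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Defaults define the reference recovery study: 40 antigens (10
    alleles in each of 4 loci), two chains of 30 residues, 50 frames,
    half the residues buried, bimodal side-chain jitter around 1.0 A
    (half the residues mobile, up to 1.5 A) with the epitope-zone
    maximum capped 0.5 A below the baseline maximum and a 0.3
    lysine/arginine enrichment fraction in epitope zones.
    """

    n_antigens: int = 40
    n_loci: int = 4
    chains: tuple[str, ...] = ("A", "B")
    residues_per_chain: int = 30
    n_frames: int = 50
    seed: int = 0
    burial_fraction: float = 0.5
    jitter_sd: float = 1.0
    jitter_spread: float = 0.5
    flexible_fraction: float = 0.5
    backbone_jitter_sd: float = 0.08
    delta_flex: float = 0.5
    delta_charge: float = 0.3
    mutation_rate: float = 0.04
    carrier_fraction: float = 0.7
    conserved_fraction: float = 0.5
    n_single_verified: int = 1
    n_composite_verified: int = 1
    n_unconfirmed_true: int = 1
    n_unconfirmed_false: int = 1

    def __post_init__(self) -> None:
        if min(self.n_antigens, self.n_loci, self.residues_per_chain, self.n_frames) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("burial_fraction", "carrier_fraction", "conserved_fraction",
                     "delta_charge", "mutation_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class PlannedEplet:
    name: str
    locus: int
    chain: str
    residues: tuple[tuple[int, str], ...]  # (position, aa)
    verified: bool
    true_epitope: bool  # whether zone effects are planted
    carriers: list[str] = field(default_factory=list)

    @property
    def zone(self) -> set[int]:
        out: set[int] = set()
        for pos, _ in self.residues:
            out.update(range(pos - _ZONE_REACH, pos + _ZONE_REACH + 1))
        return out


@dataclass
class SyntheticBundle:
    """In-memory result of :func:`generate_antigen_set`."""

    config: SynthConfig
    ensembles: list[TrajectoryEnsemble]
    sequences: dict[str, dict[str, str]]  # antigen -> chain -> sequence
    antigen_locus: dict[str, int]
    registry: EpletRegistry
    eplets: list[PlannedEplet]
    truth: "object"  # pandas DataFrame

    def locus_alleles(self, locus: int) -> dict[str, list[str]]:
        """Per-chain allele sequence lists of one locus (for conservation)."""
        out: dict[str, list[str]] = {c: [] for c in self.config.chains}
        for aid in sorted(self.sequences):
            if self.antigen_locus[aid] == locus:
                for c in self.config.chains:
                    out[c].append(self.sequences[aid][c])
        return out

    def polymorphic_chain_sequences(self) -> dict[str, str]:
        """Antigen -> sequence of its last chain (the 'beta' chain used
        for clustering when both chains are polymorphic)."""
        beta = self.config.chains[-1]
        return {aid: seqs[beta] for aid, seqs in sorted(self.sequences.items())}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write PDBs, FASTA, registry and truth table; byte-stable per seed."""
        out_dir = Path(out_dir)
        traj_dir = out_dir / "trajectories"
        traj_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for ens in self.ensembles:
            p = traj_dir / f"{ens.antigen_id}.pdb"
            _write_multimodel_pdb(ens, p)
            paths[ens.antigen_id] = p
        fasta = out_dir / "alleles.fasta"
        with open(fasta, "w") as fh:
            for aid in sorted(self.sequences):
                for chain in self.config.chains:
                    fh.write(f">{aid}_{chain} locus=L{self.antigen_locus[aid]}\n")
                    fh.write(self.sequences[aid][chain] + "\n")
        reg_path = out_dir / "registry.csv"
        write_registry(self.registry, reg_path)
        truth_path = out_dir / "truth.csv"
        self.truth.to_csv(truth_path, index=False)
        cfg_path = out_dir / "config.json"
        cfg = asdict(self.config)
        cfg["chains"] = list(cfg["chains"])
        cfg_path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
        paths.update(
            {"fasta": fasta, "registry": reg_path, "truth": truth_path,
             "config": cfg_path}
        )
        return paths


def _window_starts(length: int) -> list[int]:
    """Candidate eplet window start positions (5-wide windows) per chain."""
    margin = 6 if length >= 24 else 1
    starts = []
    s = margin + 1
    while s + 4 <= length - margin:
        starts.append(s)
        s += 12
    return starts


def _plan_eplets(cfg: SynthConfig, locus: int, base: dict[str, str],
                 rng: np.random.Generator) -> list[PlannedEplet]:
    slots = [(chain, s) for chain in cfg.chains
             for s in _window_starts(cfg.residues_per_chain)]
    kinds = (
        [("single", True, True)] * cfg.n_single_verified
        + [("composite", True, True)] * cfg.n_composite_verified
        + [("single", False, True)] * cfg.n_unconfirmed_true
        + [("single", False, False)] * cfg.n_unconfirmed_false
    )
    if len(kinds) > len(slots):
        raise ValueError(
            f"infeasible config: {len(kinds)} eplets requested but only "
            f"{len(slots)} windows fit on {cfg.residues_per_chain}-residue chains"
        )
    planned: list[PlannedEplet] = []
    for (shape, verified, true_ep), (chain, w) in zip(kinds, slots):
        if shape == "single":
            positions = (w + 2,)
        else:
            positions = (w, w + 1, w + 4)
        residues = tuple((p, base[chain][p - 1]) for p in positions)
        name = f"L{locus}-{positions[0]}" + "".join(aa for _, aa in residues)
        planned.append(PlannedEplet(name, locus, chain, residues, verified, true_ep))
    return planned


def generate_antigen_set(cfg: SynthConfig) -> SyntheticBundle:
    """Generate a full synthetic antigen set (see module docstring).

    Deterministic for a given config: all randomness flows from
    ``cfg.seed`` through a seeded generator hierarchy.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    L = cfg.residues_per_chain
    alleles_per_locus = [len(x) for x in np.array_split(np.arange(cfg.n_antigens),
                                                        cfg.n_loci)]

    aas = np.array(list(AAS))
    all_eplets: list[PlannedEplet] = []
    locus_info = []
    for locus in range(cfg.n_loci):
        base = {c: "".join(rng.choice(aas, size=L)) for c in cfg.chains}
        polymorphic = {
            c: set(np.flatnonzero(rng.random(L) > cfg.conserved_fraction) + 1)
            for c in cfg.chains
        }
        eplets = _plan_eplets(cfg, locus, base, rng)
        for ep in eplets:
            polymorphic[ep.chain].update(p for p, _ in ep.residues)
        # residues protected from burial: eplet residues and direct neighbors
        protected: set[tuple[str, int]] = set()
        for ep in eplets:
            for p, _ in ep.residues:
                for q in (p - 1, p, p + 1):
                    if 1 <= q <= L:
                        protected.add((ep.chain, q))
        candidates = [(c, p) for c in cfg.chains for p in range(1, L + 1)
                      if (c, p) not in protected]
        n_buried = round(cfg.burial_fraction * L * len(cfg.chains))
        if n_buried > len(candidates):
            raise ValueError(
                "infeasible config: burial_fraction leaves fewer exposed "
                "positions than the eplet plan requires"
            )
        buried_idx = rng.choice(len(candidates), size=n_buried, replace=False)
        buried = {candidates[i] for i in buried_idx}
        # charged-zone positions of effect-bearing eplets (locus-level plan)
        charged: dict[tuple[str, int], str] = {}
        eplet_positions = {(ep.chain, p) for ep in eplets for p, _ in ep.residues}
        for ep in eplets:
            if not ep.true_epitope:
                continue
            candidates = [
                (ep.chain, p)
                for p in sorted(ep.zone)
                if 1 <= p <= L
                and (ep.chain, p) not in eplet_positions
                and (ep.chain, p) not in buried
                and (ep.chain, p) not in charged
            ]
            n_charged = round(cfg.delta_charge * len(candidates))
            if n_charged:
                picked = rng.choice(len(candidates), size=n_charged, replace=False)
                for i in sorted(picked):
                    charged[candidates[i]] = "K" if rng.random() < 0.5 else "R"
        locus_info.append(
            dict(base=base, polymorphic=polymorphic, eplets=eplets,
                 buried=buried, charged=charged)
        )
        all_eplets.extend(eplets)

    # assign alleles to loci and carriers to eplets
    antigen_ids: list[str] = []
    antigen_locus: dict[str, int] = {}
    idx = 0
    for locus, n in enumerate(alleles_per_locus):
        members = []
        for _ in range(n):
            aid = f"AG{idx:03d}"
            antigen_ids.append(aid)
            antigen_locus[aid] = locus
            members.append(aid)
            idx += 1
        for ep in locus_info[locus]["eplets"]:
            n_carriers = max(1, round(cfg.carrier_fraction * len(members)))
            picked = rng.choice(len(members), size=n_carriers, replace=False)
            ep.carriers = sorted(members[i] for i in picked)

    sequences: dict[str, dict[str, str]] = {}
    ensembles: list[TrajectoryEnsemble] = []
    truth_rows = []
    for aid in antigen_ids:
        locus = antigen_locus[aid]
        info = locus_info[locus]
        rng_a = np.random.default_rng([cfg.seed, locus, int(aid[2:])])
        seqs, jitter, rows = _make_allele(cfg, aid, locus, info, rng_a)
        sequences[aid] = seqs
        ensembles.append(_make_ensemble(cfg, aid, seqs, jitter,
                                        info["buried"], rng_a))
        truth_rows.extend(rows)

    records = []
    presence: dict[str, set[str]] = {}
    for ep in all_eplets:
        records.append(EpletRecord(ep.name, ep.chain, ep.residues, ep.verified))
        for aid in ep.carriers:
            presence.setdefault(aid, set()).add(ep.name)
    registry = EpletRegistry(records, presence)
    truth = pd.DataFrame(truth_rows)
    return SyntheticBundle(cfg, ensembles, sequences, antigen_locus, registry,
                           all_eplets, truth)


def _make_allele(cfg: SynthConfig, aid: str, locus: int, info: dict,
                 rng: np.random.Generator):
    """Sequence, per-residue jitter and truth rows for one allele."""
    L = cfg.residues_per_chain
    aas = np.array(list(AAS))
    seqs: dict[str, str] = {}
    jitter: dict[tuple[str, int], float] = {}
    rows = []
    carried = [ep for ep in info["eplets"] if aid in ep.carriers]
    carried_positions = {(ep.chain, p): ep for ep in carried for p, _ in ep.residues}
    zone_low_flex: set[tuple[str, int]] = set()
    for ep in carried:
        if ep.true_epitope:
            zone_low_flex.update((ep.chain, p) for p in ep.zone if 1 <= p <= L)
    for chain in cfg.chains:
        base = info["base"][chain]
        seq = list(base)
        for p in range(1, L + 1):
            key = (chain, p)
            if key in carried_positions:
                ep = carried_positions[key]
                seq[p - 1] = dict(ep.residues)[p]
            elif key in info["charged"] and key in zone_low_flex:
                seq[p - 1] = info["charged"][key]
            elif p in info["polymorphic"][chain] and rng.random() < cfg.mutation_rate:
                choices = [a for a in aas if a != base[p - 1]]
                seq[p - 1] = choices[rng.integers(len(choices))]
        # non-carriers must lack the eplet: break its first residue
        for ep in info["eplets"]:
            if ep.chain != chain or aid in ep.carriers:
                continue
            p0, aa0 = ep.residues[0]
            if seq[p0 - 1] == aa0:
                seq[p0 - 1] = next(a for a in AAS if a != aa0)
        seqs[chain] = "".join(seq)
        for p in range(1, L + 1):
            key = (chain, p)
            # bimodal base flexibility: a flexible_fraction minority of
            # residues is highly mobile, so the *maximum* flexibility in
            # a normal surface patch is reliably high.  Epitope zones
            # keep the same mixture but their flexible component is
            # capped delta_flex below the base maximum (epitopes are
            # rigid): the patch maximum drops sharply while the patch
            # average moves only mildly.
            hi = cfg.jitter_sd + cfg.jitter_spread
            flexible = rng.random() < cfg.flexible_fraction
            if flexible and key in zone_low_flex:
                cap = max(0.15, hi - cfg.delta_flex)
                sd = rng.uniform(max(0.1, cap - 0.2), cap)
            elif flexible:
                sd = rng.uniform(hi - 0.2 * cfg.jitter_spread, hi)
            else:
                sd = rng.uniform(
                    max(0.05, cfg.jitter_sd - 0.8 * cfg.jitter_spread),
                    cfg.jitter_sd - 0.2 * cfg.jitter_spread,
                )
            jitter[key] = sd
            ep = carried_positions.get(key)
            rows.append(
                {
                    "antigen_id": aid,
                    "locus": locus,
                    "chain": chain,
                    "position": p,
                    "aa": seqs[chain][p - 1],
                    "buried": key in info["buried"],
                    "zone": key in zone_low_flex,
                    "eplet": ep.name if ep else "",
                    "eplet_kind": (
                        ""
                        if ep is None
                        else "verified"
                        if ep.verified
                        else "unconfirmed_true"
                        if ep.true_epitope
                        else "unconfirmed_false"
                    ),
                    "charged": key in info["charged"],
                    "jitter_sd": sd,
                }
            )
    return seqs, jitter, rows


def _backbone_curve(L: int, chain_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Base CA positions and outward side-chain directions for one chain."""
    i = np.arange(L)
    x = 2.5 * np.sin(i * 0.7) + chain_index * _CHAIN_OFFSET
    y = 2.5 * np.cos(i * 0.9)
    z = _RISE * i
    ca = np.column_stack([x, y, z])
    phi = i * 2.4
    u = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(L)])
    return ca, u


def _make_ensemble(cfg: SynthConfig, aid: str, seqs: dict[str, str],
                   jitter: dict[tuple[str, int], float],
                   buried: set[tuple[str, int]],
                   rng: np.random.Generator) -> TrajectoryEnsemble:
    L = cfg.residues_per_chain
    chain_ids, res_ids, res_names, atom_names, elements = [], [], [], [], []
    base_xyz: list[np.ndarray] = []
    atom_sd: list[float] = []

    shell_unit = sphere_points(_SHELL_POINTS)
    occluders: list[np.ndarray] = []
    for c_idx, chain in enumerate(cfg.chains):
        ca, u = _backbone_curve(L, c_idx)
        cb = ca + _CB_OFFSET * u
        for p in range(1, L + 1):
            aa = seqs[chain][p - 1]
            for name, pos, sd in (
                ("CA", ca[p - 1], cfg.backbone_jitter_sd),
                ("CB", cb[p - 1], jitter[(chain, p)]),
            ):
                chain_ids.append(chain)
                res_ids.append(p)
                res_names.append(ONE_TO_THREE[aa])
                atom_names.append(name)
                elements.append("C")
                base_xyz.append(pos)
                atom_sd.append(sd)
            if (chain, p) in buried:
                center = 0.5 * (ca[p - 1] + cb[p - 1])
                occluders.append(center + _SHELL_RADIUS * shell_unit)

    n_poly = len(base_xyz)
    if occluders:
        occ = np.vstack(occluders)
        for k in range(len(occ)):
            chain_ids.append("X")
            res_ids.append(k + 1)
            res_names.append("DUM")
            atom_names.append("C")
            elements.append("C")
            atom_sd.append(0.0)
        base = np.vstack([np.asarray(base_xyz), occ])
    else:
        base = np.asarray(base_xyz)

    sd = np.asarray(atom_sd)[None, :, None]
    noise = rng.normal(size=(cfg.n_frames, base.shape[0], 3)) * sd
    coords = base[None, :, :] + noise
    return ensemble_from_arrays(
        aid, coords, chain_ids, res_ids, res_names, atom_names, elements
    )


def _write_multimodel_pdb(ensemble: TrajectoryEnsemble, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ensemble.n_atoms
    arr = struc.AtomArray(n)
    res_ids = np.empty(n, dtype=int)
    res_names = np.empty(n, dtype="U3")
    chain_ids = np.empty(n, dtype="U1")
    for a in range(n):
        r = ensemble.atom_residue[a]
        if r >= 0:
            rid = ensemble.residues[r]
            chain_ids[a] = rid.chain
            res_ids[a] = rid.position
            res_names[a] = ONE_TO_THREE[rid.aa]
        else:
            chain_ids[a] = "X"
            res_ids[a] = a
            res_names[a] = "DUM"
    arr.chain_id = chain_ids
    arr.res_id = res_ids
    arr.res_name = res_names
    arr.atom_name = ensemble.atom_names
    arr.element = ensemble.elements
    arr.hetero = res_names == "DUM"
    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = ensemble.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def worked_fixture_params():
    """Pipeline parameters matched to the worked fixture's size.

    With 8-residue chains the standard 5-per-terminus exclusion would
    empty the flexibility-normalization population, so the fixture is
    processed with a 1-residue exclusion.
    """
    from .pipeline import PipelineParams

    return PipelineParams(termini_excluded=1)


def worked_fixture() -> SyntheticBundle:
    """Tiny hand-checkable bundle: one 2-chain antigen, 8 residues per
    chain, 3 frames, one verified single eplet on chain A.

    Process with :func:`worked_fixture_params`.
    """
    cfg = SynthConfig(
        n_antigens=1,
        n_loci=1,
        residues_per_chain=8,
        n_frames=3,
        seed=20,
        burial_fraction=0.25,
        jitter_sd=0.8,
        delta_flex=0.5,
        delta_charge=0.5,
        carrier_fraction=1.0,
        n_single_verified=1,
        n_composite_verified=0,
        n_unconfirmed_true=0,
        n_unconfirmed_false=1,
    )
    return generate_antigen_set(cfg)
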