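"""Trajectory loading, SASA/RSASA and RMSF/N-RMSF."""

import numpy as np
import pytest

from conftest import make_ensemble
from epipatch.constants import MAX_ASA_THEORETICAL, VDW_RADII
from epipatch.trajectory import (
    ParseError,
    compute_rmsf,
    compute_rsasa,
    compute_sasa,
    load_trajectory,
    normalize_rmsf,
    sphere_points,
)
from oracles import brute_residue_sasa, isolated_sphere_sasa


# ---------------------------------------------------------------------- I/O


def _write_pdb(path, models):
    lines = []
    for m, atoms in enumerate(models, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (name, res, chain, rid, xyz, elem) in enumerate(atoms, start=1):
            lines.append(
                f"ATOM  {i:5d} {name:<4s} {res:>3s} {chain}{rid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {elem:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _peptide_atoms(n_res=5, shift=0.0):
    return [
        ("CA", "ALA", "A", i + 1, (3.8 * i + shift, 0.0, 0.0), "C")
        for i in range(n_res)
    ]


def test_multimodel_roundtrip(tmp_path):
    path = tmp_path / "pep.pdb"
    _write_pdb(path, [_peptide_atoms(shift=s) for s in (0.0, 0.1, 0.2)])
    ens = load_trajectory(path)
    assert ens.n_frames == 3
    assert list(ens.chains) == ["A"]
    assert len(ens.residues) == 5
    assert ens.chain_sequence("A") == "AAAAA"
    assert np.isclose(ens.coords[1, 0, 0] - ens.coords[0, 0, 0], 0.1, atol=1e-3)


def test_single_model_is_static_ensemble(tmp_path):
    path = tmp_path / "one.pdb"
    _write_pdb(path, [_peptide_atoms()])
    assert load_trajectory(path).n_frames == 1


def test_inconsistent_model_error_names_frame(tmp_path):
    path = tmp_path / "bad.pdb"
    _write_pdb(path, [_peptide_atoms(), _peptide_atoms()[:-1], _peptide_atoms()])
    with pytest.raises(ParseError, match="model 2"):
        load_trajectory(path)


def test_empty_file_error(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("\n")
    with pytest.raises(ParseError):
        load_trajectory(path)


def test_hydrogens_dropped(tmp_path):
    path = tmp_path / "h.pdb"
    atoms = _peptide_atoms(2) + [("H", "ALA", "A", 1, (0.5, 0.5, 0.5), "H")]
    _write_pdb(path, [atoms])
    ens = load_trajectory(path)
    assert ens.n_atoms == 2
    assert all(e != "H" for e in ens.elements)


# --------------------------------------------------------------------- SASA


def test_isolated_carbon_matches_closed_form():
    ens = make_ensemble(np.zeros((1, 1, 3)), "A")
    sasa = compute_sasa(ens, probe=1.4, n_points=960)
    expected = isolated_sphere_sasa(VDW_RADII["C"], 1.4)
    assert sasa.shape == (1, 1)
    assert abs(sasa[0, 0] - expected) / expected < 0.01


def test_far_apart_atoms_are_isolated_spheres():
    coords = np.array([[[0.0, 0, 0], [100.0, 0, 0]]])
    ens = make_ensemble(coords, "AG")
    sasa = compute_sasa(ens)
    expected = isolated_sphere_sasa(VDW_RADII["C"], 1.4)
    assert np.allclose(sasa[:, 0], expected, rtol=0.01)


def test_sasa_error_decreases_with_point_density():
    rng = np.random.default_rng(0)
    coords = rng.normal(scale=2.0, size=(1, 10, 3))
    ens = make_ensemble(coords, "A" * 10)
    reference = brute_residue_sasa(ens, n_points=40000)
    errs = []
    for n in (100, 400, 1600, 6400):
        got = compute_sasa(ens, n_points=n)
        errs.append(np.abs(got - reference).max())
    assert errs == sorted(errs, reverse=True)


def test_toy_peptide_matches_brute_force_oracle():
    # extended 3-residue peptide, 2 atoms per residue
    from epipatch.trajectory import ensemble_from_arrays

    coords = np.array(
        [[[0, 0, 0], [0, 1.5, 0], [3.8, 0, 0], [3.8, 1.5, 0],
          [7.6, 0, 0], [7.6, 1.5, 0]]], dtype=float
    )
    ens = ensemble_from_arrays(
        "PEP", coords,
        chain_ids=["A"] * 6,
        res_ids=[1, 1, 2, 2, 3, 3],
        res_names=["ALA", "ALA", "GLY", "GLY", "SER", "SER"],
        atom_names=["CA", "CB"] * 3,
        elements=["C", "C", "C", "O"][:4] + ["C", "O"],
    )
    got = compute_sasa(ens, n_points=960)
    oracle = brute_residue_sasa(ens, n_points=9600)
    assert np.abs((got - oracle) / oracle).max() < 0.02


def test_total_sasa_is_sum_of_residue_sasa():
    from epipatch.trajectory import atom_sasa

    rng = np.random.default_rng(1)
    coords = rng.normal(scale=3.0, size=(1, 8, 3))
    ens = make_ensemble(coords, "ILKWVAGE")
    per_res = compute_sasa(ens)
    per_atom = atom_sasa(ens.coords[0], ens.radii)
    assert np.isclose(per_res[:, 0].sum(), per_atom.sum(), rtol=1e-12)


def test_occluding_shell_removes_sasa():
    shell = 3.5 * sphere_points(80)
    coords = np.vstack([[[0.0, 0, 0]], shell])[None]
    seq = "A" + "G" * 80
    ens = make_ensemble(coords, seq)
    sasa = compute_sasa(ens)
    assert sasa[0, 0] < 1e-9


def test_unknown_element_rejected():
    with pytest.raises(ValueError, match="element"):
        make_ensemble(np.zeros((1, 1, 3)), "A", elements=["XX"])


def test_sasa_parameter_contracts():
    ens = make_ensemble(np.zeros((1, 1, 3)), "A")
    with pytest.raises(ValueError):
        compute_sasa(ens, n_points=50)
    with pytest.raises(ValueError):
        compute_sasa(ens, probe=-1.0)


# -------------------------------------------------------------------- RSASA


def test_rsasa_uses_theoretical_maximum():
    ens = make_ensemble(np.zeros((1, 1, 3)), "A")
    profile = compute_rsasa(ens, sasa=np.array([[64.5]]))
    assert np.isclose(profile.rsasa[0, 0], 100 * 64.5 / MAX_ASA_THEORETICAL["A"])
    assert np.isclose(profile.rsasa[0, 0], 50.0)


def test_rsasa_zero_and_constant_stats():
    ens = make_ensemble(np.zeros((3, 2, 3)), "AW")
    profile = compute_rsasa(ens, sasa=np.array([[0.0, 0, 0], [57.0, 57, 57]]))
    assert profile.rsasa[0].max() == 0.0
    assert profile.rsasa_min[1] == profile.rsasa_max[1] == profile.rsasa_mean[1]


def test_rsasa_not_capped_at_100():
    ens = make_ensemble(np.zeros((1, 1, 3)), "G")
    profile = compute_rsasa(ens, sasa=np.array([[150.0]]))
    assert profile.rsasa[0, 0] > 100.0


# --------------------------------------------------------------------- RMSF


def _two_atom_res(frames):
    """n residues with CA + CB pseudo side chain from (F, n*2, 3) coords."""
    from epipatch.trajectory import ensemble_from_arrays

    frames = np.asarray(frames, dtype=float)
    n_res = frames.shape[1] // 2
    return ensemble_from_arrays(
        "T", frames,
        chain_ids=["A"] * (2 * n_res),
        res_ids=[i // 2 + 1 for i in range(2 * n_res)],
        res_names=["ALA"] * (2 * n_res),
        atom_names=["CA", "CB"] * n_res,
        elements=["C"] * (2 * n_res),
    )


def test_identical_frames_zero_rmsf():
    base = np.arange(12, dtype=float).reshape(1, 4, 3)
    ens = _two_atom_res(np.repeat(base, 3, axis=0))
    assert np.allclose(compute_rmsf(ens), 0.0, atol=1e-12)


def test_rigid_body_motion_gives_zero_rmsf():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(3)
    base = rng.normal(scale=4.0, size=(6, 3))
    frames = []
    for k in range(4):
        rot = Rotation.from_euler("xyz", rng.uniform(0, 2 * np.pi, 3))
        frames.append(rot.apply(base) + rng.normal(scale=10.0, size=3))
    ens = _two_atom_res(np.array(frames))
    assert np.allclose(compute_rmsf(ens), 0.0, atol=1e-8)


def test_alternating_displacement_rmsf_equals_d():
    d = 0.75
    # 3 residues; middle residue's CB alternates +-d along x
    base = np.array([[0, 0, 0], [0, 1.5, 0],
                     [3.8, 0, 0], [3.8, 1.5, 0],
                     [7.6, 0, 0], [7.6, 1.5, 0]], dtype=float)
    f1, f2 = base.copy(), base.copy()
    f1[3, 0] += d
    f2[3, 0] -= d
    ens = _two_atom_res(np.array([f1, f2, f1, f2]))
    rmsf = compute_rmsf(ens)
    assert np.isclose(rmsf[1], d, atol=1e-9)
    assert np.allclose(rmsf[[0, 2]], 0.0, atol=1e-9)


def test_rmsf_needs_two_frames():
    ens = _two_atom_res(np.zeros((1, 4, 3)))
    with pytest.raises(ValueError):
        compute_rmsf(ens)


def test_rmsf_rigid_body_invariance_of_pipeline_quantities(fixture_bundle):
    """SASA, RSASA and RMSF are unchanged by a common rigid transform."""
    from scipy.spatial.transform import Rotation

    from epipatch.trajectory import TrajectoryEnsemble

    ens = fixture_bundle.ensembles[0]
    rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0])
    moved = TrajectoryEnsemble(
        antigen_id=ens.antigen_id,
        coords=rot.apply(ens.coords.reshape(-1, 3)).reshape(ens.coords.shape) + 7.5,
        elements=ens.elements,
        atom_names=ens.atom_names,
        atom_residue=ens.atom_residue,
        residues=ens.residues,
        residue_atoms=ens.residue_atoms,
        sidechain_atoms=ens.sidechain_atoms,
        chains=ens.chains,
    )
    s0 = compute_sasa(ens, n_points=400)
    s1 = compute_sasa(moved, n_points=400)
    assert np.allclose(s0, s1, rtol=1e-6, atol=1e-8)
    assert np.allclose(compute_rmsf(ens), compute_rmsf(moved), rtol=1e-6, atol=1e-9)


# ------------------------------------------------------------------- N-RMSF


def _chain(n, n_frames=2):
    coords = np.zeros((n_frames, 2 * n, 3))
    coords[:, :, 0] = np.repeat(np.arange(n) * 3.8, 2)
    coords[:, 1::2, 1] = 1.5
    return _two_atom_res(coords)


def test_znorm_population_mean_zero_sd_one():
    ens = _chain(14)
    rmsf = np.linspace(0.2, 3.0, 14)
    accessible = set(ens.residues)
    flex = normalize_rmsf(ens, rmsf, accessible, termini_excluded=5)
    idx = [ens.residues.index(r) for r in flex.population]
    pop = flex.nrmsf[idx]
    assert abs(pop.mean()) < 1e-9
    assert abs(pop.std(ddof=0) - 1) < 1e-9


def test_znorm_simple_values():
    ens = _chain(5)
    rmsf = np.array([1.0, 2.0, 3.0, 1.5, 2.5])
    accessible = set(ens.residues)
    flex = normalize_rmsf(ens, rmsf, accessible, termini_excluded=1)
    # population = residues 2..4 -> {2.0, 3.0, 1.5}
    pop = np.array([2.0, 3.0, 1.5])
    mu, sd = pop.mean(), pop.std(ddof=0)
    assert np.isclose(flex.nrmsf[1], (2.0 - mu) / sd)
    # residues outside the population are normalized with the same mu/sd
    assert np.isclose(flex.nrmsf[0], (1.0 - mu) / sd)


def test_znorm_mean_and_plus_one_sigma():
    ens = _chain(5)
    rmsf = np.array([9.9, 1.0, 2.0, 3.0, 9.9])
    flex = normalize_rmsf(ens, rmsf, set(ens.residues), termini_excluded=1)
    assert abs(flex.nrmsf[2]) < 1e-12  # rmsf == population mean
    sigma = np.std([1.0, 2.0, 3.0])
    assert np.isclose(flex.nrmsf[3], (3.0 - 2.0) / sigma)


def test_znorm_terminus_exclusion_on_12_residue_chain():
    ens = _chain(12)
    rmsf = np.linspace(1, 2, 12)
    flex = normalize_rmsf(ens, rmsf, set(ens.residues), termini_excluded=5)
    positions = sorted(r.position for r in flex.population)
    assert positions == [6, 7]


def test_znorm_degenerate_population_errors():
    ens = _chain(12)
    with pytest.raises(ValueError):
        normalize_rmsf(ens, np.ones(12), set(ens.residues), termini_excluded=5)
    with pytest.raises(ValueError):
        normalize_rmsf(ens, np.ones(12), set(), termini_excluded=5)
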