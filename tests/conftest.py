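import json
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from epipatch.constants import ONE_TO_THREE
from epipatch.trajectory import ensemble_from_arrays

DATA = Path(__file__).parent / "data"


def make_ensemble(coords, sequence="A", chain="A", atom_names=None,
                  elements=None, antigen_id="TEST"):
    """Tiny ensemble builder: one atom per residue unless atom_names given.

    ``coords`` is (n_frames, n_atoms, 3); ``sequence`` a one-letter
    string with one residue per atom by default, or pass explicit
    ``res_ids`` layouts via the full ensemble_from_arrays.
    """
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    seq = sequence * n_atoms if len(sequence) == 1 else sequence
    assert len(seq) == n_atoms
    res_names = [ONE_TO_THREE[a] for a in seq]
    return ensemble_from_arrays(
        antigen_id,
        coords,
        chain_ids=[chain] * n_atoms,
        res_ids=list(range(1, n_atoms + 1)),
        res_names=res_names,
        atom_names=atom_names or ["CA"] * n_atoms,
        elements=elements or ["C"] * n_atoms,
    )


@pytest.fixture(scope="session")
def golden():
    return json.loads((DATA / "worked_fixture_golden.json").read_text())


@pytest.fixture(scope="session")
def fixture_bundle():
    from epipatch.synthetic import worked_fixture

    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_bundle):
    from epipatch.pipeline import process_antigen
    from epipatch.synthetic import worked_fixture_params

    return process_antigen(fixture_bundle.ensembles[0], worked_fixture_params())


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic antigen set shared by labeling/learning tests."""
    from epipatch.synthetic import SynthConfig, generate_antigen_set

    cfg = SynthConfig(n_antigens=8, n_loci=2, n_frames=10, seed=42)
    return generate_antigen_set(cfg)


@pytest.fixture(scope="session")
def small_labeled(small_bundle):
    from epipatch.study import build_labeled_dataset

    return build_labeled_dataset(small_bundle)
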