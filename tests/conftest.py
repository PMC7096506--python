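import numpy as np
import pytest

from kitcd import synthetic
from kitcd.core import ALL
from kitcd.synthetic import (
    EnsembleSpec,
    generate_bead_protein,
    generate_candidate_ensemble,
    generate_gaussian_trajectory,
    random_covariance_spec,
)


@pytest.fixture(scope="session")
def bead_protein():
    """Three-domain Cα-bead chain (N-lobe / KID / C-lobe analogue)."""
    return generate_bead_protein((10, 20, 10), seed=1)


@pytest.fixture(scope="session")
def gaussian_traj(bead_protein):
    """5000-frame Gaussian trajectory with a planted 3-mode spectrum
    orthogonal to the rigid-body subspace."""
    structure, scheme = bead_protein
    spec = random_covariance_spec(
        structure.n_atoms, np.array([9.0, 4.0, 1.0]), seed=2, structure=structure
    )
    traj, truth = generate_gaussian_trajectory(structure, spec, 5000, seed=3)
    return traj, truth, scheme


@pytest.fixture(scope="session")
def ideal_helix_12():
    return synthetic.ideal_helix(12)


@pytest.fixture(scope="session")
def antiparallel_sheet():
    # rigid placement of the second strand is optimised once per session
    return synthetic.ideal_antiparallel_sheet(8)


@pytest.fixture(scope="session")
def candidate_ensemble():
    spec = EnsembleSpec(n_models=200)
    return generate_candidate_ensemble(spec, seed=7)


def rigid_transform(coords, seed=0, angle_scale=1.0, shift_scale=10.0):
    """Random proper rotation + translation applied to (…, 3) coordinates."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.normal(scale=shift_scale, size=3)
    return coords @ rot.T + shift
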