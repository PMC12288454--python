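"""Shared fixtures: a small elastic-network dimer sampled once per session."""

import numpy as np
import pytest

from allosterik.synthetic import (
    ENMTrajectorySpec,
    ToyDimerSpec,
    generate_state_suite,
    generate_toy_dimer,
    sample_enm_trajectory,
)
from allosterik.trajectory import superpose


@pytest.fixture(scope="session")
def dimer_spec():
    """40-residue dimer (20 per monomer): DBD 1-6, linker 7, EO 8-20."""
    return ToyDimerSpec(residues_per_monomer=20, geometry_seed=1)


@pytest.fixture(scope="session")
def reference(dimer_spec):
    return generate_toy_dimer(dimer_spec)


@pytest.fixture(scope="session")
def enm_sample(dimer_spec):
    """5000-frame APO trajectory plus its exact analytic covariance."""
    spec = ENMTrajectorySpec(spec=dimer_spec, n_frames=5000, seed=3)
    traj, sigma = sample_enm_trajectory(spec)
    return traj, sigma


@pytest.fixture(scope="session")
def superposed(enm_sample, reference):
    traj, _ = enm_sample
    return superpose(traj, reference)


@pytest.fixture(scope="session")
def state_suite(dimer_spec):
    """Four-state (APO/E/D/ED) suite at 1500 frames for the wild type."""
    base = ENMTrajectorySpec(spec=dimer_spec, n_frames=1500, seed=11)
    return generate_state_suite(base)


@pytest.fixture(scope="session")
def domain_labels(reference):
    return list(reference.atoms["domain"])


def rigid_transform(coords, seed=0):
    """Apply one random proper rotation + translation to every frame."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return coords @ Q.T + t
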