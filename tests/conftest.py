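import numpy as np
import pytest

from tcrmsm import synthetic


@pytest.fixture(scope="session")
def two_state_hmm():
    """Small metastable two-state dihedral trajectory with ground truth."""
    spec = synthetic.HMMDihedralSpec(
        transition_matrix=[[0.95, 0.05], [0.05, 0.95]],
        psi_means={"A": [[-60.0] * 5, [120.0] * 5],
                   "B": [[-50.0] * 4, [150.0] * 4]},
        emission_sigma=15.0,
        n_frames=4000,
        seed=11,
    )
    traj, hidden = synthetic.generate_hmm_trajectory(spec)
    return spec, traj, hidden


@pytest.fixture(scope="session")
def two_domain_coupled():
    """Two-domain assembly whose interface angle is coupled to the hidden state."""
    spec = synthetic.TwoDomainSpec(
        targets_deg=[40.0, 60.0],
        label_transition_matrix=[[0.95, 0.05], [0.05, 0.95]],
        angle_sigma_deg=5.0,
        loop_psi_means=np.array([[-60.0] * 5, [120.0] * 5]),
        loop_sigma_deg=10.0,
        n_frames=4000,
        seed=23,
    )
    traj, labels = synthetic.generate_two_domain_trajectory(spec)
    return spec, traj, labels


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
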