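import numpy as np
import pandas as pd
import pytest

from confobs.trajectory import Trajectory


def make_trajectory(coords, groups=None, protons=None, res_index=None):
    """Build a small trajectory with a hand-specified topology."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if groups is None:
        groups = ["peptide"] * n_atoms
    if protons is None:
        protons = [False] * n_atoms
    if res_index is None:
        res_index = [0] * n_atoms
    top = pd.DataFrame({
        "atom_name": [f"X{i}" for i in range(n_atoms)],
        "element": ["H" if p else "C" for p in protons],
        "res_index": res_index,
        "res_name": ["ALA"] * n_atoms,
        "group": groups,
        "is_proton": protons,
    })
    return Trajectory(coords, top)


@pytest.fixture
def two_state_traj():
    """500-frame two-state ensemble with a half-time ligand contact."""
    from confobs.synthetic import EnsembleSpec, gen_conformer_ensemble

    spec = EnsembleSpec(n_residues=8, n_frames=500, helix_fraction=0.5,
                        n_ligand=4, contact_fraction=0.5, seed=11)
    return gen_conformer_ensemble(spec)


def random_rotation(seed):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
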