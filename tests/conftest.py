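import numpy as np
import pytest

from corona_thermo.io_formats import Trajectory
from corona_thermo.synthetic import GeneratorSpec


@pytest.fixture
def spec0():
    """Noise-free generator spec (seed 1)."""
    return GeneratorSpec(seed=1, noise_sd_rel=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trajectory(coords, masses=None, chains=None, res_ids=None,
                    res_names=None, names=None, elements=None,
                    charge=None) -> Trajectory:
    """Minimal Trajectory from a (n_frames, n_atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        atom_names=np.asarray(names) if names is not None else np.full(n, "X"),
        elements=np.asarray(elements) if elements is not None else np.full(n, "C"),
        residue_names=np.asarray(res_names) if res_names is not None
        else np.full(n, "UNK"),
        residue_indices=np.asarray(res_ids, dtype=int) if res_ids is not None
        else np.arange(1, n + 1),
        chain_ids=np.asarray(chains) if chains is not None else np.full(n, "A"),
        masses=np.asarray(masses, dtype=float) if masses is not None
        else np.ones(n),
        charge_class=np.asarray(charge) if charge is not None
        else np.full(n, "neutral"),
    )
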