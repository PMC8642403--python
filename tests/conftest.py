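import numpy as np
import pytest

import gridppi as g


@pytest.fixture(scope="session")
def dimer():
    return g.make_toy_dimer(5, seed=1)


@pytest.fixture(scope="session")
def profiles(dimer):
    return {c: g.make_synthetic_pssm(dimer, c, seed=2) for c in dimer.chain_ids}


@pytest.fixture(scope="session")
def dimer_grid(dimer, profiles):
    """Default featurization of the toy dimer (36 channels, 30^3 grid)."""
    return g.featurize_complex(dimer, profiles)


@pytest.fixture(scope="session")
def decoy_set(dimer):
    return g.make_decoys(dimer, g.DecoySpec(n_decoys=50, seed=3, guarantee=(5, 5)))


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """Planted-signal dataset (snr 5) plus an Adam-preset model trained on it."""
    path = tmp_path_factory.mktemp("planted") / "planted.h5"
    g.make_planted_grid_dataset(path, n_pos=100, n_neg=100, snr=5.0, seed=7)
    stream = list(g.read_selection(path, target_name="binary_class"))
    cfg = g.app2_preset(input_channels=36, max_epochs=20, seed=1)
    model = g.train(iter(stream), cfg)
    return {"path": path, "stream": stream, "model": model}


def rigid_transform(complex, seed=0):
    """A random rotation + translation applied to the whole complex."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return complex.transformed(R, t)
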