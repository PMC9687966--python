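import numpy as np
import pytest

from porewater.frames import FrameSeries
from porewater.synthetic import SyntheticChannelSpec, simulate_waters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A small but fully featured synthetic channel."""
    return SyntheticChannelSpec(
        n_waters=12,
        n_frames=200,
        diffusion=0.2,
        marker_heights=(-2.0, 5.0),
        hydronium_height=-5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_frames(small_spec):
    return simulate_waters(small_spec)


def make_frames(coords, names=None, resids=None, resnames=None, water_ids=(), dt=2.0):
    """Minimal FrameSeries around a raw (n_frames, n_atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if names is None:
        names = ["O"] * n_atoms
    if resids is None:
        resids = list(range(1, n_atoms + 1))
    if resnames is None:
        resnames = ["WAT" if r in set(water_ids) else "XXX" for r in resids]
    return FrameSeries(
        times=np.arange(coords.shape[0]) * dt,
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(["A"] * n_atoms),
        coords=coords,
        water_ids=np.array(list(water_ids), dtype=int),
    )
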