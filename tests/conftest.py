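import numpy as np
import pytest

from contrastsweep.phantom import PhantomSpec, build_phantom
from contrastsweep.relaxometry import QuantitativeMaps


def small_spec(**overrides) -> PhantomSpec:
    """Test-scale phantom: same mm geometry as the default, coarser grid."""
    kwargs = dict(shape=(64, 64, 16), spacing=(1.5, 1.5, 5.0))
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def test_phantom():
    spec = small_spec()
    maps, labels = build_phantom(spec, seed=7)
    return spec, maps, labels


@pytest.fixture()
def single_voxel_maps():
    def make(t1=1000.0, t2=100.0, pd=1.0):
        shape = (1, 1, 1)
        return QuantitativeMaps(
            t1_map=np.full(shape, t1), t2_map=np.full(shape, t2),
            pd_map=np.full(shape, pd), spacing=(1.0, 1.0, 1.0))
    return make


def random_maps(rng, shape=(6, 5, 4)):
    """Random positive quantitative maps with T1 >= T2 (physical)."""
    t2 = rng.uniform(20.0, 200.0, size=shape)
    t1 = t2 + rng.uniform(100.0, 1500.0, size=shape)
    pd = rng.uniform(0.1, 1.0, size=shape)
    return QuantitativeMaps(t1_map=t1, t2_map=t2, pd_map=pd,
                            spacing=(1.0, 1.0, 1.0))


def random_mask(rng, shape, p=0.4):
    """Random non-empty binary mask."""
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


def hd95_bruteforce(a, b, spacing, percentile=95.0):
    """Exhaustive all-pairs surface-distance oracle (O(n^2))."""
    from contrastsweep.metrics import surface_voxels
    sa = np.argwhere(surface_voxels(a)) * np.asarray(spacing)
    sb = np.argwhere(surface_voxels(b)) * np.asarray(spacing)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, percentile))
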