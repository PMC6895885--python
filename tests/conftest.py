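import numpy as np
import pytest

from dfcmanifold import RoiTimeSeries, SyntheticSpec, gen_dfc_direct


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_timeseries():
    """30 ROIs x 100 TRs of correlated noise at TR = 2 s."""
    gen = np.random.default_rng(11)
    latent = gen.standard_normal((100, 5))
    mix = gen.standard_normal((5, 30))
    data = latent @ mix + 0.5 * gen.standard_normal((100, 30))
    return RoiTimeSeries(data=data, tr_seconds=2.0,
                         roi_ids=[f"roi{i + 1}" for i in range(30)])


@pytest.fixture(scope="session")
def planted_dfc():
    """dFC matrix with 6 planted modules at snr = 3 (the study conditions)."""
    spec = SyntheticSpec(seed=7, M=6, n=435, D=120, snr=3.0)
    S, membership, prototypes = gen_dfc_direct(spec)
    return S, membership, prototypes


@pytest.fixture(scope="session")
def planar_cloud():
    """300 points exactly on a 2-D plane inside R^10."""
    gen = np.random.default_rng(1)
    return gen.uniform(size=(300, 2)) @ gen.standard_normal((2, 10))


@pytest.fixture(scope="session")
def curved_sheet():
    """Gently rolled 2-manifold in R^3 (swiss-roll-style fixture)."""
    gen = np.random.default_rng(3)
    n = 1000
    t = 0.75 * np.pi * (1 + 2 * gen.uniform(size=n))
    h = 12 * gen.uniform(size=n)
    return np.column_stack([t * np.cos(t), h, t * np.sin(t)])
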