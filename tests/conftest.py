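import numpy as np
import pytest

from manifestirt import dm, hm, sm
from manifestirt.expfam import KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def std_kernel_1d():
    return KernelSpec(mean=np.zeros(1), cov=np.eye(1))


@pytest.fixture
def sm_items():
    return [sm.SMItem(beta=0.0, d=1.0), sm.SMItem(beta=0.5, d=2.0)]


@pytest.fixture
def sm_items3():
    return [sm.SMItem(beta=-0.5, d=1.0), sm.SMItem(beta=0.0, d=1.5),
            sm.SMItem(beta=0.4, d=2.0)]


@pytest.fixture
def hm_items():
    return [hm.HMItem(alpha=1.2, beta=-0.3, phi=2.0, xi=1.0),
            hm.HMItem(alpha=0.8, beta=0.5, phi=1.5, xi=0.5)]


@pytest.fixture
def hm_kernel():
    return hm.HMKernel(rho=0.4, v_eta2=0.2)


@pytest.fixture
def dm_items():
    return [dm.DMItem(alpha=1.5, beta=0.3, t_er=0.2),
            dm.DMItem(alpha=2.0, beta=-0.4, t_er=0.2)]


def random_sm_point(rng, items):
    x = rng.integers(0, 2, size=len(items))
    t = np.array([rng.uniform(0.05, it.d - 0.05) for it in items])
    return x, t


def random_hm_point(rng, items):
    x = rng.integers(0, 2, size=len(items))
    t = rng.uniform(0.3, 4.0, size=len(items))
    return x, t


def random_dm_point(rng, items):
    x = rng.integers(0, 2, size=len(items))
    t = np.array([it.t_er + rng.uniform(0.1, 3.0) for it in items])
    return x, t
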