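import numpy as np
import pytest

from popkernel import forward_model as fm
from popkernel import kernel_builder as kb


@pytest.fixture(scope="session")
def toy_params():
    return kb.ToyKernelParams(amp_mean=1.0, amp_sd=0.5)


@pytest.fixture(scope="session")
def morphology():
    return fm.build_stylized_l5(seed=1)


@pytest.fixture(scope="session")
def solver(morphology):
    return fm.PassiveCableSolver(morphology, fm.PassiveParams(), 2.0 ** -4)


@pytest.fixture(scope="session")
def small_factory():
    """Shared biophysical kernel factory with a small out-degree."""
    cfg = kb.PopulationConfig(k_out=20, n_presyn_kernels=5, seed=7)
    return kb.KernelFactory(cfg)


@pytest.fixture(scope="session")
def small_bank(small_factory):
    return small_factory.build_bank()


def rel_err(a, b):
    a, b = np.asarray(a), np.asarray(b)
    denom = np.abs(b).max()
    return np.abs(a - b).max() / denom if denom else np.abs(a - b).max()
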