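import numpy as np
import pytest

from kernelct import PhantomSpec, generate_kernel_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter phantom shared by read-only tests."""
    return generate_kernel_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom for fast per-test measurements."""
    spec = PhantomSpec(shape=(40, 56, 56),
                       semi_axes_um=(15 * 27.0, 22 * 27.0, 19 * 27.0), seed=3)
    return generate_kernel_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
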