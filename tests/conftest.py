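import numpy as np
import pytest

from aladdin_acbv import ARTERY, GM_TISSUE, VEIN, SequenceParams
from aladdin_acbv.recon import phase_times


@pytest.fixture(scope="session")
def seq():
    """Default acquisition: TR 4.15 ms, FA 60, 10 dummies, 9x32 lines."""
    return SequenceParams()


@pytest.fixture(scope="session")
def times(seq):
    return phase_times(seq)


@pytest.fixture(scope="session", params=["artery", "vein", "tissue"])
def compartment(request):
    return {"artery": ARTERY, "vein": VEIN, "tissue": GM_TISSUE}[request.param]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """32x32 noiseless phantom shared by the round-trip tests."""
    from aladdin_acbv.synthetic_data import PhantomSpec, make_phantom

    seq = SequenceParams()
    spec = PhantomSpec(shape=(32, 32))
    ds, truth = make_phantom(spec, seq)
    return seq, spec, ds, truth
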