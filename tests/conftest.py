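import numpy as np
import pytest

from pectseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with a linear boundary and its ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mean_boundary_error(detected, truth):
    """Mean absolute column difference over the rows both polylines cover."""
    d = detected.column_at()
    t = truth.column_at()
    common = sorted(set(d) & set(t))
    assert common, "polylines share no rows"
    return float(np.mean([abs(d[r] - t[r]) for r in common]))
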