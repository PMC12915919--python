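import numpy as np
import pytest

from tamvi_norms.irt import Item, ItemBank, icc


def simulate_responses(a, b, theta, rng):
    """Bernoulli draws from the 2PL curves — the test-side oracle."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    theta = np.asarray(theta, float)
    p = icc(a, b, theta[:, None])
    return (rng.random((len(theta), len(a))) < p).astype(float)


def make_bank(a, b, trial=1):
    return ItemBank(trial=trial,
                    items=[Item(f"item_{i + 1:02d}", float(ai), float(bi))
                           for i, (ai, bi) in enumerate(zip(a, b))])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def moderate_bank(rng):
    """12 items with slopes around 1 and difficulties spanning [-2, 1]."""
    a = rng.uniform(0.7, 1.4, 12)
    b = np.linspace(-2.0, 1.0, 12)
    return make_bank(a, b)
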