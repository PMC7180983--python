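import numpy as np
import pytest

from chairstand.synthetic import SyntheticSpec, generate_signal


@pytest.fixture
def clean_signal_factory():
    """Noise-free trapezoidal chair-stand signals with known ground truth."""

    def make(n_cycles=5, period_s=5.0, seed=0, **kw):
        spec = SyntheticSpec(n_cycles=n_cycles, period_s=period_s, seed=seed, **kw)
        return generate_signal(spec)

    return make


@pytest.fixture
def clean_family():
    """The seeded noise-free signal family: 2-6 s cadence, 3-10 cycles."""

    def draw(rng):
        cyc = int(rng.integers(3, 11))
        per = float(rng.uniform(2.0, min(6.0, 30.0 / cyc)))
        return generate_signal(
            SyntheticSpec(n_cycles=cyc, period_s=per, seed=int(rng.integers(2**31)))
        )

    return draw


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
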