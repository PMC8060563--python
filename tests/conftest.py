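import numpy as np
import pytest

from facetouch import simulate as sim
from facetouch.prep import FeatureTensor


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 participants x 24 trials: enough structure for split/prep tests."""
    trials, manifest = sim.simulate_dataset(4, trials_per_condition=2, seed=11)
    return trials, manifest


def make_toy_tensor(n=200, w=23, seed=0, pid_prefix="T"):
    """Linearly separable two-class toy tensor, roughly standardized.

    Class 1 carries a sinusoidal bump on the first four channels; class 0 is
    noise only.  Returns a FeatureTensor with one participant per class half
    so leakage checks stay meaningful.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.normal(0.0, 1.0, (n, w, 14))
    bump = np.sin(np.linspace(0, np.pi, w))
    x[y == 1, :, :4] += 2.0 * bump[None, :, None]
    pids = np.array([f"{pid_prefix}{i % 4}" for i in range(n)], dtype=object)
    return FeatureTensor(x.astype(np.float32), y, pids, window_ms=253.0)
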