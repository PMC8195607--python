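import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def periodic_train():
    """SS every 20 ms for 10 s; used by several statistics tests."""
    from cerebquant.spiketrain import LabeledSpikeTrain

    times = np.arange(0.02, 10.0, 0.02)
    return LabeledSpikeTrain(times, np.full(times.size, "SS"), 10.0)


def random_ss_train(rng, n_min=30, n_max=80):
    """A pure-SS train mixing regular and irregular stretches, so the
    regularity index has nontrivial structure."""
    from cerebquant.spiketrain import LabeledSpikeTrain

    n = int(rng.integers(n_min, n_max))
    isis = []
    while len(isis) < n:
        if rng.uniform() < 0.5:
            isis.extend(rng.normal(0.02, 0.0005, size=int(rng.integers(3, 8))).clip(1e-4))
        else:
            isis.extend(rng.exponential(0.02, size=int(rng.integers(2, 6))))
    isis = np.asarray(isis[:n])
    times = np.cumsum(isis)
    return LabeledSpikeTrain(times, np.full(times.size, "SS"), float(times[-1] + 0.05))
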