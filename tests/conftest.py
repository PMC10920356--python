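import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240223)


def random_spike_train(rng, n_spikes, T=1.0):
    """Sorted distinct spike times in (0, T)."""
    t = np.sort(rng.uniform(0.0, T, size=n_spikes))
    # enforce strict increase (distinct values) for metric validity
    while len(t) > 1 and np.any(np.diff(t) <= 0):
        t = np.sort(rng.uniform(0.0, T, size=n_spikes))
    return t
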