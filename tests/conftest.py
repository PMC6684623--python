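import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def five_cluster_values():
    """Well-separated 5-cluster mixture: means 5, 27, 50, 73, 95; sd 2; 20 each."""
    rng = np.random.default_rng(4242)
    means = (5.0, 27.0, 50.0, 73.0, 95.0)
    vals = np.concatenate([rng.normal(m, 2.0, 20) for m in means])
    return np.clip(vals, 0.0, 100.0), np.repeat(np.arange(5), 20), means
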