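import numpy as np
import pytest

from dtibalance import synthdata


@pytest.fixture(scope="session")
def small_dataset():
    """A 30x30 grid with planted negatives at shift 3 (shared, read-only)."""
    cfg = synthdata.SynthConfig(
        n_drugs=30, n_proteins=30, positive_rate=0.05,
        negative_cluster_shift=3.0, seed=7,
    )
    return synthdata.generate(cfg)


@pytest.fixture(scope="session")
def separable_xy():
    """Two margin-separated Gaussian clouds, n=400 (binary labels)."""
    rng = np.random.default_rng(0)
    x = np.vstack([rng.normal(0, 1, (200, 10)), rng.normal(8, 1, (200, 10))])
    y = np.r_[np.zeros(200), np.ones(200)].astype(int)
    return x, y
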