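import numpy as np
import pytest

from tcmix import DesignSpec, preset, generate, replicate_study
from tcmix.simulate import replicate_seed


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def t1_dataset():
    """One labelled dataset from the full-model regime (low autocorrelation)."""
    cfg = preset("t1", n_genes=400, seed=3)
    return generate(cfg, seed=replicate_seed(3, 0))


@pytest.fixture(scope="session")
def t1_study():
    """Replicated full-model study with both fitters, k-means and bias table."""
    return replicate_study("t1", 20, seed=7, include_kmeans=True)


@pytest.fixture(scope="session")
def table_studies(t1_study):
    """Replicated studies for every simulation regime (reduced replicate count)."""
    studies = {"t1": t1_study}
    for tid in ("t2", "t3", "t4", "t5", "t6"):
        studies[tid] = replicate_study(tid, 15, seed=7, collect_bias=False)
    return studies


@pytest.fixture
def small_design():
    times = np.arange(24.0)
    return DesignSpec(kind="fourier", times=times, order_k=1)
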