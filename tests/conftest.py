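import numpy as np
import pytest

from combosyn.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A desk-scale planted-rule study shared by read-only tests."""
    cfg = SynthConfig(
        n_drugs=15, n_proteins=60, n_cells=4, n_clusters_true=5,
        n_samples=200, label_noise=0.0, seed=7,
    )
    bundle, truth = generate_dataset(cfg)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
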