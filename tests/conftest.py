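import numpy as np
import pytest

import mirfusion as mf


@pytest.fixture(scope="session")
def small_dataset():
    """Planted 20x15 instance, small enough for exhaustive protocols."""
    spec = mf.SyntheticSpec(n_mirna=20, n_disease=15, n_groups=3, seed=11)
    return mf.generate(spec)


@pytest.fixture(scope="session")
def small_config():
    return mf.ModelConfig(fusion=mf.FusionConfig(k_neighbors=6, iterations=4))


@pytest.fixture(scope="session")
def small_scores(small_dataset, small_config):
    assoc, kernels = small_dataset
    return mf.predict_full(assoc, kernels, small_config)


def names(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


@pytest.fixture
def tiny_assoc():
    MD = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
    return mf.AssociationData(names("m", 3), names("d", 3), MD)
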