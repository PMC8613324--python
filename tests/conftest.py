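import numpy as np
import pytest

from cvleak import DatasetSpec, generate_dataset, preprocess


@pytest.fixture
def small_dataset():
    """60x30 dataset with a little signal, preprocessed; cheap for any scorer."""
    ds = generate_dataset(
        DatasetSpec(
            n_samples=60, n_features=30, prevalence=0.5,
            n_informative=3, effect_size=1.5, seed=11,
        )
    )
    processed, _ = preprocess(ds)
    return processed


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
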