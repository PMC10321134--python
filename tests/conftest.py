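import numpy as np
import pytest

from oedl.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-sample imbalanced cohort with missingness, shared read-only."""
    cfg = SynthConfig(
        n_samples=200, n_radiomics=40, n_informative_radiomics=5,
        n_redundant_blocks=2, block_size=3, effect_size=1.2,
        missing_rate=0.08, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def separable_toy():
    """Three well-separated Gaussian blobs: any sensible learner fits them."""
    rng = np.random.default_rng(5)
    y = np.repeat([0, 1, 2], 50)
    X = rng.normal(0, 1, (150, 2)) + np.array([[0, 0], [5, 0], [0, 5]])[y]
    return X, y
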