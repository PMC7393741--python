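import numpy as np
import pytest

from hashdemux import HTOMatrix, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_hto():
    """A 5-GEM, 3-hashtag matrix in the canonical example layout."""
    return HTOMatrix(
        barcodes=["ACTAGGACCA", "TCGGACTCGG", "GCAGTAGGCA", "CCAGACATGA", "CCTAGACTTA"],
        sample_names=["HTO1", "HTO2", "HTO3"],
        counts=np.array(
            [
                [20, 45, 723],
                [56, 123, 15],
                [742, 593, 14],
                [31, 747, 39],
                [21, 15, 33],
            ]
        ),
    )


@pytest.fixture(scope="session")
def four_sample_dataset():
    """A mid-sized 4-sample synthetic dataset with 10% cross-sample doublets."""
    config = SimConfig(M=4, n_droplets=8000, msm_fraction=0.10, seed=11)
    hto, truth = simulate_dataset(config)
    return config, hto, truth
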