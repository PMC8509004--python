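import numpy as np
import pytest

from ciliascreen.data_io import write_brainspan_triplet
from ciliascreen.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset with mixed true/null pairs."""
    config = SimConfig(
        n_genes=20,
        n_donors=14,
        regions=("DLPC", "Hipp", "Cer"),
        frac_age_linear=0.4,
        slope_range=(0.5, 3.0),
        intercept_range=(150.0, 250.0),
        noise_sd=4.0,
        missing_rate=0.1,
        seed=11,
    )
    matrix, samples, ground_truth = generate_dataset(config)
    return matrix, samples, ground_truth, config


@pytest.fixture()
def triplet_dir(tmp_path, small_dataset):
    """The small dataset written out in the CSV-triplet dialect."""
    matrix, samples, _, _ = small_dataset
    write_brainspan_triplet(matrix, samples, tmp_path / "triplet")
    return tmp_path / "triplet"


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
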