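import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_history, make_visit  # noqa: E402
from l2cforecast.cohort import filter_eligible  # noqa: E402
from l2cforecast.features import augment_training_samples  # noqa: E402
from l2cforecast.simulate import SimConfig, generate_cohort  # noqa: E402


@pytest.fixture
def four_visit_history():
    """Fully observed 4-visit history with hand-checkable values."""
    specs = [
        dict(month=0.0, age=70.0, mmse=29.0, cdr_global=0.0, diagnosis="CN",
             roi_volumes={"hippocampus": 7500.0, "fusiform": 18500.0,
                          "midtemp": 20500.0, "ventricle": 30000.0,
                          "wholebrain": 1050000.0, "icv": 1500000.0}),
        dict(month=12.0, age=71.0, mmse=28.0, cdr_global=0.0, diagnosis="CN",
             roi_volumes={"hippocampus": 7300.0, "fusiform": 18200.0,
                          "midtemp": 20100.0, "ventricle": 33000.0,
                          "wholebrain": 1040000.0, "icv": 1500000.0}),
        dict(month=24.0, age=72.0, mmse=27.0, cdr_global=0.5, diagnosis="MCI",
             roi_volumes={"hippocampus": 7000.0, "fusiform": 17800.0,
                          "midtemp": 19600.0, "ventricle": 37000.0,
                          "wholebrain": 1025000.0, "icv": 1500000.0}),
        dict(month=36.0, age=73.0, mmse=25.0, cdr_global=0.5, diagnosis="MCI",
             roi_volumes={"hippocampus": 6700.0, "fusiform": 17300.0,
                          "midtemp": 19000.0, "ventricle": 42000.0,
                          "wholebrain": 1010000.0, "icv": 1500000.0}),
    ]
    return make_history(specs)


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort with default (ADNI-like) missingness."""
    return generate_cohort(SimConfig(n_participants=60, seed=7))


@pytest.fixture(scope="session")
def dense_cohort():
    """Noise-bearing cohort with every modality observed at every visit."""
    return generate_cohort(SimConfig(n_participants=40, seed=3),
                           apply_missing=False)


@pytest.fixture(scope="session")
def train_samples(small_cohort):
    samples = []
    for history in filter_eligible(small_cohort):
        samples.extend(augment_training_samples(history))
    return samples
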