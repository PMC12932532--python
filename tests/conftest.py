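import numpy as np
import pytest

from apneaformer.config import SyntheticConfig
from apneaformer.preprocess import preprocess_cohort
from apneaformer.synthetic import generate_cohort

#: Desk-scale study conditions: 6 subjects with moderate/severe apnea,
#: ~45-min recordings at 8 Hz, strong RR modulation during events.
TINY_COHORT_CONFIG = dict(
    n_subjects=6,
    severity_quota={"none": 0, "mild": 0, "moderate": 3, "severe": 3},
    duration_range=(0.7, 0.9),
    fs=8.0,
    rr_modulation_depth=0.4,
    seed=11,
)

#: Matching scaled-down model: 2 blocks, 2 heads of size 32.
TINY_MODEL_PARAMS = dict(
    num_blocks=2, num_heads=2, head_size=32, ff_hidden=32, mlp_units=128,
    epochs=8, batch_size=32,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(SyntheticConfig(**TINY_COHORT_CONFIG), signals=True)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    X, y, subjects, widx = preprocess_cohort(tiny_cohort)
    return X, y, subjects, widx


@pytest.fixture
def rng():
    return np.random.default_rng(0)
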