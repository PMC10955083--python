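import numpy as np
import pandas as pd
import pytest

from mpfusion import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide small test cohort: 8+8 patients, 32x32 images."""
    return synthdata.generate_cohort(synthdata.SynthConfig.small_mode(seed=7))


@pytest.fixture(scope="session")
def toy_patients():
    """12 patients, balanced labels, for split bookkeeping checks."""
    return pd.DataFrame({
        "patient_id": [f"P{i:02d}" for i in range(12)],
        "label": [0, 1] * 6,
    })
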