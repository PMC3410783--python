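import numpy as np
import pandas as pd
import pytest

from hyperomir import synthetic


@pytest.fixture(scope="session")
def design():
    """The study layout: 2 RA replicates x 3 timepoints, 3 O2 x 2."""
    return synthetic.generate_design(reps_ra=2, reps_o2=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_matrix(design, rng):
    """Null 50-probe matrix on the 12-sample design, fixed noise."""
    values = 8.0 + rng.normal(0, 0.5, size=(50, len(design)))
    return pd.DataFrame(values,
                        index=pd.Index([f"probe_{i:05d}" for i in range(50)], name="probe_id"),
                        columns=design["sample_id"].tolist())
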