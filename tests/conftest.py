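import numpy as np
import pytest

from stressci import baseline, cohort


@pytest.fixture
def profile():
    """A deterministic normal-schedule subject."""
    return cohort.SubjectProfile(subject_id="S001")


@pytest.fixture
def minute_grid():
    """One-minute grid over the full day, [0, 24)."""
    return np.arange(0.0, 24.0, 1.0 / 60.0)


@pytest.fixture
def cosinor_model():
    """A hand-built cosinor baseline: B(8) = 160, B(20) = 40."""
    return baseline.BaselineModel(biomarker="cortisol", family="cosinor",
                                  params=(100.0, 60.0, 8.0),
                                  window=(8.0, 22.0), data_mean=100.0)
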