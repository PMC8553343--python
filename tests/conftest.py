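import numpy as np
import pytest

from marginscreen import (
    CohortConfig,
    ImageConfig,
    SampleRecord,
    SpectraConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_spectra_cfg():
    return SpectraConfig(seed=1)


@pytest.fixture
def liver_like_cohort_cfg():
    """Cohort shaped like the liver margin test set: 9 tumor-involved and
    26 tumor-free specimens with well-separated class means."""
    return CohortConfig(n_train_pairs=9, n_test_pos=9, n_test_neg=26,
                        pos_mean=(200.0, 200.0), neg_mean=(120.0, 120.0),
                        sd=10.0, seed=42)


@pytest.fixture
def small_image_cfg():
    return ImageConfig(width=160, height=160, n_samples=5,
                       blob_radius_range=(6.0, 10.0), seed=3)


def make_record(i_ntr, i_vis, he_label=None, call=None, sample_id="s"):
    return SampleRecord(sample_id=sample_id, i_ntr=i_ntr, i_vis=i_vis,
                        he_label=he_label, call=call)
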