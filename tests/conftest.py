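import numpy as np
import pytest

import gadpipe as gp
from gadpipe.preprocess import concat_epochs


def cohort_feature_table(spec):
    """Generate, preprocess and featurise a full cohort."""
    recs = gp.generate_cohort(spec)
    epochs = concat_epochs([gp.preprocess_recording(r) for r in recs])
    return gp.build_feature_table(epochs)


@pytest.fixture(scope="session")
def effect_spec():
    """The default group-effect preset: 10+10 subjects, 60-s recordings."""
    return gp.effect_cohort_spec(n_per_group=10, duration_s=60.0, seed=101)


@pytest.fixture(scope="session")
def effect_table(effect_spec):
    return cohort_feature_table(effect_spec)


@pytest.fixture(scope="session")
def null_table():
    """Cohort with no implanted group effects (type-I calibration)."""
    return cohort_feature_table(
        gp.null_cohort_spec(n_per_group=10, duration_s=60.0, seed=202)
    )


@pytest.fixture()
def tone_epochs():
    """Single-subject epochs from a deterministic 10 Hz tone recording."""
    fs = 250.0
    t = np.arange(int(20 * fs)) / fs
    data = np.stack([np.sin(2 * np.pi * 10 * t + 0.3 * i) for i in range(16)])
    rec = gp.Recording(data=data, fs=fs, subject_id="S1", group="HC")
    return gp.preprocess_recording(rec)
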