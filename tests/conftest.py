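import numpy as np
import pytest

from narrisc.dataio import BrainMask, CohortDataset, TimeSeriesImage


def make_cohort(n_subjects=3, conditions=("a", "b"), shape=(3, 1, 1), T=20,
                tr=1.7, seed=0, data=None):
    """Small cohort of random (or caller-supplied) time series."""
    rng = np.random.default_rng(seed)
    subjects = [f"s{i + 1}" for i in range(n_subjects)]
    images = {}
    for c in conditions:
        for s in subjects:
            if data is not None and (s, c) in data:
                arr = data[(s, c)]
            else:
                arr = rng.standard_normal(shape + (T,))
            images[(s, c)] = TimeSeriesImage(data=arr, tr=tr, subject_id=s,
                                             condition=c)
    mask = BrainMask(data=np.ones(shape, dtype=bool))
    return CohortDataset(images=images, subjects=subjects,
                         conditions=list(conditions), mask=mask)


@pytest.fixture
def tiny_cohort():
    return make_cohort()
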