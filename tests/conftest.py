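import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from scnkit.cohort import cohort_from_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort_frame(
    n1=5, n2=5, n_rois=4, seed=0, group_labels=("patient", "control")
) -> pd.DataFrame:
    """Small well-formed cohort table with random positive volumes."""
    r = np.random.default_rng(seed)
    n = n1 + n2
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": [group_labels[0]] * n1 + [group_labels[1]] * n2,
            "age": r.uniform(30, 60, n).round(1),
            "sex": r.choice(["F", "M"], n),
            "tiv": r.normal(1.45e6, 1.2e5, n).round(1),
        }
    )
    for j in range(n_rois):
        frame[f"vol_roi{j + 1:03d}"] = r.normal(8000, 800, n).round(2)
    return frame


@pytest.fixture
def small_cohort():
    return cohort_from_frame(make_cohort_frame(n1=6, n2=6, n_rois=5, seed=3))


@pytest.fixture
def cohort_frame_factory():
    return make_cohort_frame
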