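import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from stridelab.sensor_io import ACTIVITIES
from stridelab.synthetic_data import CohortSpec, SubjectProfile, generate_subject


def tiny_plan(count: int = 1, lo: float = 16.0, hi: float = 22.0):
    return {a: (count, lo, hi) for a in ACTIVITIES}


@pytest.fixture
def clean_spec():
    """Small cohort spec with no artifacts, mislabels or drops."""
    return CohortSpec(rng_seed=0, artifact_rate=0.0, mislabel_rate=0.0, drop_rate=0.0,
                      lab_bout_plan=tiny_plan(), home_bout_plan=tiny_plan())


@pytest.fixture
def stroke_profile():
    return SubjectProfile("S00", "stroke", gait_speed=0.6)


@pytest.fixture
def clean_recording(clean_spec, stroke_profile):
    """One artifact-free Lab1 recording with one bout per activity."""
    return generate_subject(stroke_profile, clean_spec, "Lab1",
                            rng=np.random.default_rng(7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
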