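import numpy as np
import pandas as pd
import pytest

from bdiflow.pipeline import cohort_candidates
from bdiflow.synthetic import AcquisitionConfig, CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_acq():
    """Short acquisition (2 baseline + 3 post bursts of 128 frames)."""
    return AcquisitionConfig(
        frames_per_burst=128, baseline_duration_hr=1.5, post_duration_hr=2.0
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_acq):
    """Smallest valid cohort: 2 patients per grade, one arm, 16 wells."""
    spec = CohortSpec(
        n_patients_per_grade=(2, 2, 2), wells_per_patient=16, arms=("cisplatin",), seed=7
    )
    return generate_cohort(spec, tiny_acq)


@pytest.fixture(scope="session")
def tiny_candidates(tiny_cohort):
    candidates = cohort_candidates(tiny_cohort)
    truths = tiny_cohort.grades.set_index("patient_id")["grade"]
    return candidates, truths


@pytest.fixture(scope="session")
def separable_candidates():
    """18-patient candidate table whose informative columns track the grade."""
    rng = np.random.default_rng(42)
    grades = ["0"] * 6 + ["1"] * 6 + ["23"] * 6
    ordinal = np.repeat([0.0, 1.0, 2.0], 6)
    cols = {}
    for j in range(22):
        if j < 8:  # informative: ordinal trend plus small noise
            cols[f"c{j:02d}"] = ordinal * (1 if j % 2 else -1) + 0.05 * rng.standard_normal(18)
        else:  # pure noise
            cols[f"c{j:02d}"] = rng.standard_normal(18)
    candidates = pd.DataFrame(cols, index=[f"P{i:03d}" for i in range(18)])
    truths = pd.Series(grades, index=candidates.index)
    return candidates, truths
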