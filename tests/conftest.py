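"""Shared fixtures: synthetic cohorts at several scales.

The full-scale cohort (2565 species x 200 subjects, 54 planted effects)
matches the study design the simulator emulates and is generated once per
session; smaller cohorts keep unit tests fast.
"""

import numpy as np
import pandas as pd
import pytest

from evmir import CohortSpec, generate_cohort, preprocess
from evmir.matrix import IntensityMatrix


FULL_SEED = 7


@pytest.fixture(scope="session")
def full_cohort():
    """Default study-scale cohort: 2565 x (100+100), 48 up / 6 down at
    |log2 FC| = 1.5, 24 stage-I cancers."""
    return generate_cohort(CohortSpec(seed=FULL_SEED))


@pytest.fixture(scope="session")
def full_processed(full_cohort):
    """(normalized, log2) matrices for the full cohort."""
    return preprocess(full_cohort.matrix)


@pytest.fixture
def small_spec():
    return CohortSpec(
        n_cancer=30, n_noncancer=30, n_species=200, core_fraction=0.3,
        target_median_detected=120, n_up=8, n_down=3,
        stage_fractions={"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25},
        seed=11,
    )


@pytest.fixture
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-probe x 2-sample raw matrix with one undetected entry."""
    values = pd.DataFrame(
        [[100.0, 80.0], [10.0, 0.0], [50.0, 40.0]],
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=pd.Index(["s1", "s2"], name="sample_id"),
    )
    mask = values > 0
    return IntensityMatrix(values=values, mask=mask, state="raw")
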