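import numpy as np
import pytest

from connsev import features, synthetic


@pytest.fixture(scope="session")
def annotation():
    return features.load_annotation()


@pytest.fixture(scope="session")
def small_planted_cohort():
    """A compact cohort with strong planted signal for module-level tests.

    30 ROIs, 6 mixed-sign planted edges with slope 0.03 (population
    edge-severity correlation ~ 0.68 at 120 timepoints), so the p < 0.0023
    filter recovers the planted edges with high power at n = 40.
    """
    spec = synthetic.CohortSpec(
        n_subjects=40,
        n_rois=30,
        n_timepoints=120,
        planted_edges=((1, 4), (6, 9), (11, 15), (17, 20), (22, 25), (27, 30)),
        severity_slope=(0.03, 0.03, 0.03, -0.03, -0.03, -0.03),
        seed=7,
    )
    subjects, truth = synthetic.generate_cohort(spec)
    X = features.cohort_edge_matrix([s.timeseries for s in subjects])
    return X, truth


@pytest.fixture(scope="session")
def small_cohort_Xy(small_planted_cohort):
    X, truth = small_planted_cohort
    return X, truth.true_scores.astype(float), truth
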