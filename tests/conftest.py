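import numpy as np
import pytest

from svamech.psychometrics import DEFAULT_SCALES
from svamech.synthetic import (
    GenParams,
    NeuroGenParams,
    gen_questionnaire_cohort,
    gen_resting_parcels,
)

SVA_ITEMS = list(DEFAULT_SCALES["SVA"].items)


@pytest.fixture(scope="session")
def cohort_small():
    """400-subject questionnaire cohort with the default mediation paths."""
    return gen_questionnaire_cohort(GenParams(n_subjects=400, seed=42))


@pytest.fixture(scope="session")
def cohort_large():
    """5000-subject cohort for moment-convergence checks."""
    return gen_questionnaire_cohort(GenParams(n_subjects=5000, seed=7))


@pytest.fixture(scope="session")
def scored_small(cohort_small):
    from svamech.psychometrics import score_cohort

    table, _ = cohort_small
    return score_cohort(table)


@pytest.fixture(scope="session")
def neuro_small():
    """Small resting-state-like set: amplitude coupling in parcel 7,
    pattern coupling in parcels 2 and 9."""
    rng = np.random.default_rng(5)
    trait = rng.standard_normal(40)
    profile = trait[:, None] + 0.5 * rng.standard_normal((40, 6))
    params = NeuroGenParams(
        n_subjects=40, n_parcels=12, n_voxels_per_parcel=10, n_timepoints=128,
        tr_seconds=2.0, coupling_parcels=(7,), coupling_strength=0.5,
        pattern_coupling_parcels=(2, 9), pattern_strength=0.5, seed=5,
    )
    pts, truth = gen_resting_parcels(params, trait, item_profile=profile)
    return pts, trait, profile, truth


@pytest.fixture(scope="session")
def alff_small(neuro_small):
    from svamech.alff import alff_maps

    pts, trait, profile, truth = neuro_small
    return alff_maps(pts), trait, profile
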