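import logging

import numpy as np
import pandas as pd
import pytest

from scolisim import anatomy, metrics, planning, trial

logging.getLogger("scolisim").setLevel(logging.ERROR)

#: cohort seed for the seeded trend checks
TREND_SEED = 2026
TREND_N_SUBJECTS = 30


@pytest.fixture(scope="session")
def single_curve_case():
    """One moderate dextroscoliotic spine with its detected major curve."""
    spec = anatomy.SpineSpec(
        curves=(anatomy.CurveSpec("T9", 54.6, "dextro", 20.0, 8),),
        tk=25.9,
        ll=44.1,
        length=430.0,
        seed=1,
    )
    geom = anatomy.generate_spine(spec)
    major = max(metrics.detect_curves(geom), key=lambda c: c.cobb)
    return spec, geom, major


@pytest.fixture(scope="session")
def straight_spine():
    """Sagittal-only spine (no coronal deformity, no axial rotation)."""
    return anatomy.generate_spine(anatomy.SpineSpec(curves=(), tk=25.9, ll=44.1))


@pytest.fixture(scope="session")
def small_cohort():
    return anatomy.generate_cohort(anatomy.CohortSpec(n_subjects=5, seed=7))


@pytest.fixture(scope="session")
def trend_records():
    """Full factorial trial on the seeded 30-subject synthetic cohort.

    Shared by the trend / statics acceptance checks; roughly 30k
    simulations."""
    cohort = anatomy.generate_cohort(
        anatomy.CohortSpec(n_subjects=TREND_N_SUBJECTS, seed=TREND_SEED)
    )
    records = trial.run_trial(cohort, trial.TrialConfig(cohort_seed=TREND_SEED))
    return cohort, records
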