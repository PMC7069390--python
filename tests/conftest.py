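import logging
from datetime import datetime, timedelta

import numpy as np
import pytest

from abpscreen.core import ABPMRecord, Reading
from abpscreen.synth import CohortConfig, TruthProfile

# silence the per-row exclusion warnings the parser emits on noisy cohorts
logging.getLogger("abpscreen.core").setLevel(logging.ERROR)
logging.getLogger("abpscreen.pipeline").setLevel(logging.ERROR)

BASE = datetime(2018, 3, 1, 0, 0)


def make_record(times_and_values, subject_id="S1", fit_time=None):
    """Build an ABPMRecord from (hours_offset, sbp, dbp) triples."""
    readings = [
        Reading(BASE + timedelta(hours=h), int(s), int(d))
        for h, s, d in times_and_values
    ]
    return ABPMRecord(subject_id, readings, fit_time=fit_time)


@pytest.fixture
def flat_profile():
    """Noise-free, non-dipping subject: every reading is 120/80."""
    return TruthProfile(
        subject_id="S0001",
        day_sbp_true=120.0,
        day_dbp_true=80.0,
        dip_ratio=1.0,
        office_offset_sbp=0.0,
        office_offset_dbp=0.0,
        reading_sd_sbp=0.0,
        reading_sd_dbp=0.0,
        on_medication=False,
        age=40,
        sex="F",
        site="Kilifi",
        bmi=24.0,
        diabetes=False,
        smoker=False,
    )


@pytest.fixture
def clean_config():
    """Small cohort config without any missingness."""
    return CohortConfig(n_subjects=20, seed=11, p_dropout=0.0, p_device_removal=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def noise_free_separated_config(n_subjects, seed):
    """Cohort where office and ambulatory status agree at every threshold.

    No reading noise, no offsets, no dipping, no missingness, and latent
    classes pushed apart so hypertensives exceed 140/90 while normotensives
    stay below 130/80 on every measure.
    """
    return CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        htn_sbp24_lo=142.0,
        htn_sbp24_mean=152.0,
        htn_sbp24_sd=6.0,
        htn_dbp24_mean=92.0,
        htn_dbp24_sd=4.0,
        normo_sbp24_hi=128.0,
        normo_sbp24_mean=112.0,
        normo_dbp24_hi=78.0,
        normo_dbp24_mean=68.0,
        dip_mean=1.0,
        dip_sd=0.0,
        dip_lo=0.9,
        dip_hi=1.0,
        p_masked_given_htn=0.0,
        p_white_coat_given_normo=0.0,
        neutral_offset_mean=0.0,
        neutral_offset_sd=0.0,
        reading_sd_sbp_mean=0.0,
        reading_sd_sbp_spread=0.0,
        reading_sd_dbp_mean=0.0,
        reading_sd_dbp_spread=0.0,
        p_dropout=0.0,
        p_device_removal=0.0,
        p_medicated=0.0,
    )
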