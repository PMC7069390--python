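"""Synthetic circadian blood-pressure cohorts with known ground truth.

Generates subjects with latent daytime/nighttime pressures, a per-subject
office offset (positive = white-coat tendency, negative = masked tendency),
device-scheduled ambulatory reading series (20-min daytime / 40-min
nighttime intervals), triplicate office sessions, and record-level
missingness — then renders everything into the raw CSV formats the
pipeline ingests, alongside a truth file used only by tests.

The latent model is deliberately two-level: a daytime mean and a nighttime
mean linked by a dipping ratio, with i.i.d. Gaussian within-subject reading
noise and all emitted pressures rounded to integer mmHg. Confirmed
hypertension status is sampled first and the implied time-weighted 24-h
mean drawn conditionally on it, so cohort prevalence tracks the configured
target up to binomial error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import ABPMRecord, OfficeSession, Reading

SITES = ("Kilifi", "Kirinyaga", "Webuye")

# confirmed-hypertension reference pair applied to the implied 24-h mean
REF_SBP, REF_DBP = 130.0, 80.0


class CohortConfig(BaseModel):
    """Everything the generator needs; all fields validated by name."""

    n_subjects: int = Field(ge=1)
    seed: int = 0

    # prevalence of confirmed (ambulatory) hypertension
    htn_prevalence: float = Field(default=0.35, ge=0.0, le=1.0)

    # implied 24-h latent distributions, conditional on status; the
    # truncation bounds default to the 130/80 reference pair but can be
    # pushed apart to build fully separated cohorts
    htn_sbp24_lo: float = 130.0
    normo_sbp24_hi: float = 130.0
    normo_dbp24_hi: float = 80.0
    htn_sbp24_mean: float = 143.0
    htn_sbp24_sd: float = Field(default=10.0, gt=0)
    htn_dbp24_mean: float = 86.0
    htn_dbp24_sd: float = Field(default=7.0, gt=0)
    normo_sbp24_mean: float = 114.0
    normo_sbp24_sd: float = Field(default=8.0, gt=0)
    normo_dbp24_mean: float = 70.0
    normo_dbp24_sd: float = Field(default=5.0, gt=0)

    # nocturnal dipping ratio (night mean = day mean x ratio)
    dip_mean: float = Field(default=0.85, gt=0)
    dip_sd: float = Field(default=0.07, ge=0)
    dip_lo: float = Field(default=0.55, gt=0)
    dip_hi: float = Field(default=1.15, le=1.2)

    # office-offset mixture: masked component among hypertensives,
    # white-coat component among normotensives, neutral otherwise. The
    # neutral mean is negative because a rested, seated office measurement
    # sits below the active daytime ambulatory level.
    p_masked_given_htn: float = Field(default=0.40, ge=0.0, le=1.0)
    masked_offset_mean: float = -30.0
    masked_offset_sd: float = Field(default=6.0, ge=0)
    p_white_coat_given_normo: float = Field(default=0.17, ge=0.0, le=1.0)
    wc_offset_mean: float = 16.0
    wc_offset_sd: float = Field(default=5.0, ge=0)
    neutral_offset_mean: float = -6.5
    neutral_offset_sd: float = Field(default=7.0, ge=0)
    offset_dbp_scale: float = Field(default=0.65, ge=0)

    # within-subject reading noise
    reading_sd_sbp_mean: float = Field(default=7.0, ge=0)
    reading_sd_sbp_spread: float = Field(default=1.5, ge=0)
    reading_sd_dbp_mean: float = Field(default=5.0, ge=0)
    reading_sd_dbp_spread: float = Field(default=1.2, ge=0)

    # missingness
    p_dropout: float = Field(default=0.06, ge=0.0, le=1.0)
    p_device_removal: float = Field(default=0.20, ge=0.0, le=1.0)
    removal_start_lo: float = Field(default=21.0, ge=0.0, lt=24.0)
    removal_start_hi: float = Field(default=26.0, ge=0.0)
    removal_hours_lo: float = Field(default=5.0, gt=0)
    removal_hours_hi: float = Field(default=9.0, gt=0)

    # device schedule
    day_interval_min: float = Field(default=20.0, gt=0)
    night_interval_min: float = Field(default=40.0, gt=0)
    device_day_start: float = Field(default=6.0, ge=0.0, lt=24.0)
    device_day_end: float = Field(default=22.0, gt=0.0, le=24.0)
    fit_hour: float = Field(default=9.0, ge=0.0, lt=24.0)
    start_date: str = "2018-03-01"

    # covariates
    age_lo: int = Field(default=18, ge=18)
    age_hi: int = Field(default=80, gt=18)
    p_female: float = Field(default=0.55, ge=0.0, le=1.0)
    bmi_mean: float = Field(default=23.5, gt=0)
    bmi_sd: float = Field(default=4.5, gt=0)
    p_diabetes: float = Field(default=0.02, ge=0.0, le=1.0)
    p_smoker: float = Field(default=0.10, ge=0.0, le=1.0)
    p_medicated: float = Field(default=0.06, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_windows(self) -> "CohortConfig":
        if self.device_day_end <= self.device_day_start:
            raise ValueError("device_day_end must exceed device_day_start")
        if self.dip_hi <= self.dip_lo:
            raise ValueError("dip_hi must exceed dip_lo")
        if self.removal_hours_hi < self.removal_hours_lo:
            raise ValueError("removal_hours_hi must be >= removal_hours_lo")
        if self.age_hi <= self.age_lo:
            raise ValueError("age_hi must exceed age_lo")
        if self.htn_sbp24_lo < REF_SBP:
            raise ValueError("htn_sbp24_lo below the confirmed-hypertension cutoff")
        if self.normo_sbp24_hi > REF_SBP or self.normo_dbp24_hi > REF_DBP:
            raise ValueError("normotensive truncation bounds above the reference pair")
        return self

    @property
    def day_hours(self) -> float:
        return self.device_day_end - self.device_day_start

    @property
    def night_hours(self) -> float:
        return 24.0 - self.day_hours


@dataclass
class TruthProfile:
    """Latent generator state for one subject; the tests' ground truth."""

    subject_id: str
    day_sbp_true: float
    day_dbp_true: float
    dip_ratio: float
    office_offset_sbp: float
    office_offset_dbp: float
    reading_sd_sbp: float
    reading_sd_dbp: float
    on_medication: bool
    age: int
    sex: str
    site: str
    bmi: float
    diabetes: bool
    smoker: bool

    def __post_init__(self) -> None:
        if not 70.0 <= self.day_sbp_true <= 260.0:
            raise ValueError(f"day_sbp_true {self.day_sbp_true} outside [70, 260]")
        if not 40.0 <= self.day_dbp_true <= 160.0:
            raise ValueError(f"day_dbp_true {self.day_dbp_true} outside [40, 160]")
        if self.dip_ratio <= 0 or self.dip_ratio > 1.2:
            raise ValueError(f"dip_ratio {self.dip_ratio} outside (0, 1.2]")
        if self.reading_sd_sbp < 0 or self.reading_sd_dbp < 0:
            raise ValueError("reading sds must be non-negative")

    @property
    def night_sbp_true(self) -> float:
        return self.day_sbp_true * self.dip_ratio

    @property
    def night_dbp_true(self) -> float:
        return self.day_dbp_true * self.dip_ratio

    def implied_wt24(self, day_hours: float = 16.0) -> tuple[float, float]:
        """Closed-form time-weighted 24-h mean from the latents."""
        night_hours = 24.0 - day_hours
        w = day_hours + night_hours * self.dip_ratio
        return self.day_sbp_true * w / 24.0, self.day_dbp_true * w / 24.0

    def is_confirmed_htn(self, day_hours: float = 16.0) -> bool:
        s24, d24 = self.implied_wt24(day_hours)
        return s24 >= REF_SBP or d24 >= REF_DBP


def _truncnorm(rng, mean, sd, lo, hi, size):
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[TruthProfile]:
    """Draw a cohort of latent profiles; deterministic for a fixed seed.

    Hypertension status is Bernoulli at the configured prevalence; implied
    24-h pressures are truncated-normal draws conditioned to satisfy
    (hypertensive) or violate (normotensive) the 130/80 OR rule, then mapped
    back to daytime latents through the dipping ratio and window durations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    htn = rng.random(n) < config.htn_prevalence
    n_htn = int(htn.sum())
    n_nor = n - n_htn

    sbp24 = np.empty(n)
    dbp24 = np.empty(n)
    # hypertensive: 24-h systolic at or above its cutoff (satisfies OR rule
    # on its own); diastolic unconstrained
    sbp24[htn] = _truncnorm(
        rng, config.htn_sbp24_mean, config.htn_sbp24_sd, config.htn_sbp24_lo, 260.0, n_htn
    )
    dbp24[htn] = _truncnorm(rng, config.htn_dbp24_mean, config.htn_dbp24_sd, 40.0, 160.0, n_htn)
    # normotensive: both strictly below their cutoffs
    sbp24[~htn] = _truncnorm(
        rng, config.normo_sbp24_mean, config.normo_sbp24_sd, 75.0,
        config.normo_sbp24_hi - 1e-9, n_nor,
    )
    dbp24[~htn] = _truncnorm(
        rng, config.normo_dbp24_mean, config.normo_dbp24_sd, 45.0,
        config.normo_dbp24_hi - 1e-9, n_nor,
    )

    dip = np.clip(
        rng.normal(config.dip_mean, config.dip_sd, n), config.dip_lo, config.dip_hi
    )
    # invert the duration weighting: day latent reproducing the drawn 24-h mean
    scale = 24.0 / (config.day_hours + config.night_hours * dip)
    day_sbp = np.clip(sbp24 * scale, 70.0, 260.0)
    day_dbp = np.clip(dbp24 * scale, 40.0, 160.0)

    off_sbp = rng.normal(config.neutral_offset_mean, config.neutral_offset_sd, n)
    u = rng.random(n)
    masked = htn & (u < config.p_masked_given_htn)
    wc = ~htn & (u < config.p_white_coat_given_normo)
    off_sbp[masked] = rng.normal(
        config.masked_offset_mean, config.masked_offset_sd, int(masked.sum())
    )
    off_sbp[wc] = rng.normal(config.wc_offset_mean, config.wc_offset_sd, int(wc.sum()))
    off_dbp = off_sbp * config.offset_dbp_scale

    sd_sbp = np.clip(
        rng.normal(config.reading_sd_sbp_mean, config.reading_sd_sbp_spread, n), 0.0, None
    )
    sd_dbp = np.clip(
        rng.normal(config.reading_sd_dbp_mean, config.reading_sd_dbp_spread, n), 0.0, None
    )

    age = rng.integers(config.age_lo, config.age_hi + 1, n)
    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    site = rng.choice(SITES, n)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 48.0)
    diabetes = rng.random(n) < config.p_diabetes
    smoker = rng.random(n) < config.p_smoker
    medicated = rng.random(n) < config.p_medicated

    width = max(4, len(str(n)))
    return [
        TruthProfile(
            subject_id=f"S{i + 1:0{width}d}",
            day_sbp_true=float(day_sbp[i]),
            day_dbp_true=float(day_dbp[i]),
            dip_ratio=float(dip[i]),
            office_offset_sbp=float(off_sbp[i]),
            office_offset_dbp=float(off_dbp[i]),
            reading_sd_sbp=float(sd_sbp[i]),
            reading_sd_dbp=float(sd_dbp[i]),
            on_medication=bool(medicated[i]),
            age=int(age[i]),
            sex=str(sex[i]),
            site=str(site[i]),
            bmi=float(bmi[i]),
            diabetes=bool(diabetes[i]),
            smoker=bool(smoker[i]),
        )
        for i in range(n)
    ]


def scheduled_times(config: CohortConfig, fit: datetime) -> list[datetime]:
    """Enumerate cuff-inflation times over [fit, fit + 24 h).

    The device inflates every ``day_interval_min`` minutes while the clock
    is inside the device-day window and every ``night_interval_min``
    outside it; the interval after each inflation is set by the window the
    inflation itself falls in.
    """
    times: list[datetime] = []
    end = fit + timedelta(hours=24)
    t = fit
    while t < end:
        times.append(t)
        hour = t.hour + t.minute / 60.0 + t.second / 3600.0
        in_day = config.device_day_start <= hour < config.device_day_end
        step = config.day_interval_min if in_day else config.night_interval_min
        t = t + timedelta(minutes=step)
    return times


def simulate_abpm_series(
    profile: TruthProfile,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> ABPMRecord:
    """Simulate one subject's 24-h ambulatory series.

    Each scheduled reading is the window-appropriate latent mean plus
    independent Gaussian noise, rounded to integer mmHg; missingness is
    per-reading Bernoulli dropout plus an optional contiguous
    device-removal window (both MCAR).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fit = datetime.fromisoformat(config.start_date) + timedelta(hours=config.fit_hour)
    times = scheduled_times(config, fit)

    removal: Optional[tuple[datetime, datetime]] = None
    if rng.random() < config.p_device_removal:
        start_h = rng.uniform(config.removal_start_lo, config.removal_start_hi)
        dur_h = rng.uniform(config.removal_hours_lo, config.removal_hours_hi)
        base = datetime.fromisoformat(config.start_date) + timedelta(hours=start_h)
        if base < fit:
            base += timedelta(hours=24)
        removal = (base, base + timedelta(hours=dur_h))

    readings: list[Reading] = []
    for t in times:
        if removal is not None and removal[0] <= t < removal[1]:
            continue
        if rng.random() < config.p_dropout:
            continue
        hour = t.hour + t.minute / 60.0 + t.second / 3600.0
        in_day = config.device_day_start <= hour < config.device_day_end
        mu_s = profile.day_sbp_true if in_day else profile.night_sbp_true
        mu_d = profile.day_dbp_true if in_day else profile.night_dbp_true
        sbp = int(round(mu_s + rng.normal(0.0, profile.reading_sd_sbp)))
        dbp = int(round(mu_d + rng.normal(0.0, profile.reading_sd_dbp)))
        readings.append(Reading(t, sbp, dbp))
    return ABPMRecord(profile.subject_id, readings, fit_time=fit)


def simulate_office_session(
    profile: TruthProfile,
    config: Optional[CohortConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> OfficeSession:
    """Three readings at 1-min intervals: day latent + office offset + noise."""
    if rng is None:
        seed = config.seed if config is not None else 0
        rng = np.random.default_rng(seed)
    anchor = datetime(2000, 1, 1, 8, 0)
    readings = []
    for i in range(3):
        sbp = int(
            round(
                profile.day_sbp_true
                + profile.office_offset_sbp
                + rng.normal(0.0, profile.reading_sd_sbp)
            )
        )
        dbp = int(
            round(
                profile.day_dbp_true
                + profile.office_offset_dbp
                + rng.normal(0.0, profile.reading_sd_dbp)
            )
        )
        readings.append(Reading(anchor + timedelta(minutes=i), sbp, dbp))
    return OfficeSession(profile.subject_id, readings)


@dataclass
class CohortData:
    """A fully simulated cohort: truth plus both raw measurement streams."""

    config: CohortConfig
    profiles: list[TruthProfile]
    records: list[ABPMRecord]
    office: list[OfficeSession]


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate profiles and simulate every subject's measurements.

    A single seeded generator drives the whole cohort, so identical configs
    give byte-identical output files.
    """
    profiles = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = [simulate_abpm_series(p, config, rng) for p in profiles]
    office = [simulate_office_session(p, config, rng) for p in profiles]
    return CohortData(config, profiles, records, office)


def write_cohort_files(data: CohortData, directory) -> dict[str, Path]:
    """Render a simulated cohort into the pipeline's raw CSV formats.

    Emits ``subjects.csv``, ``office.csv``, ``abpm_readings.csv`` and the
    test-only ``truth.csv``; all round-trip losslessly through the ingest
    functions.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": directory / "subjects.csv",
        "office": directory / "office.csv",
        "readings": directory / "abpm_readings.csv",
        "truth": directory / "truth.csv",
    }

    pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "age": p.age,
                "sex": p.sex,
                "site": p.site,
                "bmi": round(p.bmi, 2),
                "diabetes": int(p.diabetes),
                "smoker": int(p.smoker),
                "on_medication": int(p.on_medication),
            }
            for p in data.profiles
        ]
    ).to_csv(paths["subjects"], index=False)

    office_rows = []
    for s in data.office:
        row = {"subject_id": s.subject_id}
        for i, r in enumerate(s.readings, start=1):
            row[f"sbp{i}"] = r.sbp
            row[f"dbp{i}"] = r.dbp
        office_rows.append(row)
    pd.DataFrame(
        office_rows,
        columns=["subject_id", "sbp1", "dbp1", "sbp2", "dbp2", "sbp3", "dbp3"],
    ).to_csv(paths["office"], index=False)

    reading_rows = [
        {
            "subject_id": rec.subject_id,
            "timestamp": r.timestamp.isoformat(),
            "sbp": r.sbp,
            "dbp": r.dbp,
        }
        for rec in data.records
        for r in rec.readings
    ]
    pd.DataFrame(
        reading_rows, columns=["subject_id", "timestamp", "sbp", "dbp"]
    ).to_csv(paths["readings"], index=False)

    pd.DataFrame([vars(p) for p in data.profiles]).to_csv(paths["truth"], index=False)
    return paths
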