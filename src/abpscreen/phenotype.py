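"""Hypertension status classification.

Maps office-session means and ambulatory summaries onto screen status,
reference (confirmed) status, and the four-way phenotype — sustained,
white-coat, masked, normotensive — at each screening cutoff. All threshold
comparisons use the guideline OR rule with non-strict >=.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import ABPMSummary

#: Reference definitions: which summary means are compared to which pair.
REFERENCE_DEFINITIONS = {
    "24h": ("wt24_sbp", "wt24_dbp", 130.0, 80.0),
    "daytime": ("day_sbp", "day_dbp", 135.0, 85.0),
    "nocturnal": ("night_sbp", "night_dbp", 120.0, 70.0),
}

#: Screening cutoffs reflecting the different international criteria.
DEFAULT_THRESHOLDS = ("130/80", "135/85", "140/90")

PHENOTYPES = ("sustained", "white_coat", "masked", "normotensive")


@dataclass(frozen=True)
class ThresholdPair:
    """A systolic/diastolic cutoff pair such as 135/85 mmHg."""

    sbp_cut: float
    dbp_cut: float
    label: str

    def __post_init__(self) -> None:
        if not self.sbp_cut > self.dbp_cut > 0:
            raise ValueError(f"require sbp_cut > dbp_cut > 0, got {self.label!r}")

    @classmethod
    def parse(cls, text: str) -> "ThresholdPair":
        """Build from a label like ``"130/80"``."""
        try:
            s, d = text.split("/")
            return cls(float(s), float(d), text.strip())
        except ValueError as exc:
            raise ValueError(f"cannot parse threshold {text!r}") from exc

    def exceeded_by(self, sbp: float, dbp: float) -> bool:
        return sbp >= self.sbp_cut or dbp >= self.dbp_cut


def screen_status(mean_sbp: float, mean_dbp: float, threshold: ThresholdPair) -> bool:
    """Screen-positive when either office mean reaches its cutoff (OR rule)."""
    return threshold.exceeded_by(mean_sbp, mean_dbp)


def reference_status(summary: ABPMSummary, reference: str = "24h") -> bool:
    """Hypertensive by the chosen ambulatory reference definition.

    24h: time-weighted means >= 130/80; daytime: >= 135/85;
    nocturnal: >= 120/70. Requires a quality-passing summary unless the
    caller has opted into the quality-failure sensitivity analysis.
    """
    try:
        sbp_field, dbp_field, scut, dcut = REFERENCE_DEFINITIONS[reference]
    except KeyError:
        raise ValueError(f"unknown reference {reference!r}") from None
    sbp = getattr(summary, sbp_field)
    dbp = getattr(summary, dbp_field)
    return sbp >= scut or dbp >= dcut


def phenotype(screen_positive: bool, confirmed: bool) -> str:
    """Four-way phenotype from screen and reference status."""
    if screen_positive:
        return "sustained" if confirmed else "white_coat"
    return "masked" if confirmed else "normotensive"


def dipping_status(summary: ABPMSummary, ratio_cut: float = 0.9) -> str:
    """Descriptive nocturnal dipping: nondipper when night/day SBP > cutoff."""
    if summary.day_sbp == 0:
        raise ValueError("daytime SBP of zero")
    return "nondipper" if summary.night_sbp / summary.day_sbp > ratio_cut else "dipper"
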