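"""Energy-expenditure handling: Schofield basal metabolic rate, METs, and
intensity classification.

Indirect calorimetry yields an energy-expenditure rate per minute; dividing by
the participant's predicted basal metabolic rate (BMR, per minute) expresses it
in metabolic equivalents (METs).  Epochs are then classified as sedentary
behavior (SB, < 1.5 METs), light physical activity (LPA, 1.5-3.0 METs, a
closed band) or moderate-to-vigorous physical activity (MVPA, > 3.0 METs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import DomainError, RangeError

MJ_TO_KCAL = 239.006
MINUTES_PER_DAY = 1440.0


class Intensity(IntEnum):
    """Activity-intensity classes, ordered SB < LPA < MVPA."""

    SB = 0
    LPA = 1
    MVPA = 2


@dataclass(frozen=True)
class AgeBand:
    lo: float  # inclusive, years
    hi: float  # exclusive (inf for the open top band)
    slope: float  # energy/day per kg
    intercept: float  # energy/day


# Weight-only BMR prediction coefficients, MJ/day, by sex and age band.
_SCHOFIELD_MJ = {
    "male": (
        AgeBand(0, 3, 0.249, -0.127),
        AgeBand(3, 10, 0.095, 2.110),
        AgeBand(10, 18, 0.074, 2.754),
        AgeBand(18, 30, 0.063, 2.896),
        AgeBand(30, 60, 0.048, 3.653),
        AgeBand(60, float("inf"), 0.049, 2.459),
    ),
    "female": (
        AgeBand(0, 3, 0.244, -0.130),
        AgeBand(3, 10, 0.085, 2.033),
        AgeBand(10, 18, 0.056, 2.898),
        AgeBand(18, 30, 0.062, 2.036),
        AgeBand(30, 60, 0.034, 3.538),
        AgeBand(60, float("inf"), 0.038, 2.755),
    ),
}


@dataclass(frozen=True)
class SchofieldTable:
    """BMR prediction coefficients keyed by (sex, age band).

    ``units`` tags the energy system of the stored coefficients; outputs can
    be requested in either system (1 MJ = 239.006 kcal).
    """

    entries: dict = field(default_factory=lambda: dict(_SCHOFIELD_MJ))
    units: str = "MJ_per_day"

    def __post_init__(self):
        if self.units not in ("MJ_per_day", "kcal_per_day"):
            raise ValueError(f"unknown unit system: {self.units!r}")
        for sex, bands in self.entries.items():
            prev_hi = None
            for band in sorted(bands, key=lambda b: b.lo):
                if not (np.isfinite(band.slope) and np.isfinite(band.intercept)):
                    raise ValueError(f"non-finite coefficients for {sex}")
                if prev_hi is not None and band.lo != prev_hi:
                    raise ValueError(f"age bands for {sex} do not partition the range")
                prev_hi = band.hi

    def band(self, sex: str, age: float) -> AgeBand:
        try:
            bands = self.entries[sex]
        except KeyError:
            raise RangeError(f"unknown sex category: {sex!r}") from None
        for b in bands:
            if b.lo <= age < b.hi:
                return b
        raise RangeError(f"age {age} outside supported bands for sex {sex!r}")


@dataclass(frozen=True)
class IntensityThresholds:
    """MET boundaries of the three intensity classes."""

    sb_met_upper: float = 1.5
    mvpa_met_lower: float = 3.0

    def __post_init__(self):
        if not 0 < self.sb_met_upper < self.mvpa_met_lower:
            raise ValueError("require 0 < sb_met_upper < mvpa_met_lower")


def schofield_bmr(
    sex: str,
    age: float,
    weight: float,
    table: SchofieldTable | None = None,
    units: str | None = None,
) -> float:
    """Predicted basal metabolic rate, energy/day.

    Linear in body weight within the (sex, age band) cell:
    ``slope * weight + intercept``.  ``units`` selects the output system
    (defaults to the table's own).
    """
    if weight <= 0:
        raise DomainError(f"weight must be positive, got {weight}")
    table = table or SchofieldTable()
    band = table.band(sex, age)
    bmr = band.slope * weight + band.intercept
    out_units = units or table.units
    if out_units != table.units:
        if table.units == "MJ_per_day" and out_units == "kcal_per_day":
            bmr *= MJ_TO_KCAL
        elif table.units == "kcal_per_day" and out_units == "MJ_per_day":
            bmr /= MJ_TO_KCAL
        else:
            raise ValueError(f"unknown unit system: {out_units!r}")
    return bmr


def mets_from_measurement(ee_rate: float, bmr: float) -> float:
    """METs = measured energy rate (energy/min) over basal rate per minute.

    ``bmr`` is energy/day; both arguments must use the same energy unit.
    """
    if bmr <= 0:
        raise DomainError(f"bmr must be positive, got {bmr}")
    if ee_rate < 0:
        raise DomainError(f"ee_rate must be non-negative, got {ee_rate}")
    return ee_rate / (bmr / MINUTES_PER_DAY)


def classify_intensity(
    mets, thresholds: IntensityThresholds | None = None
):
    """Map METs to {SB, LPA, MVPA}.

    SB strictly below ``sb_met_upper``; MVPA strictly above ``mvpa_met_lower``;
    the closed band in between (boundaries included) is LPA.  Accepts a scalar
    or an array; returns the matching shape.
    """
    thresholds = thresholds or IntensityThresholds()
    m = np.asarray(mets, dtype=float)
    if np.any(m < 0):
        raise DomainError("METs must be non-negative")
    out = np.full(m.shape, Intensity.LPA, dtype=object)
    out[m < thresholds.sb_met_upper] = Intensity.SB
    out[m > thresholds.mvpa_met_lower] = Intensity.MVPA
    if np.isscalar(mets) or np.ndim(mets) == 0:
        return Intensity(out.item())
    return np.array([Intensity(v) for v in out.ravel()]).reshape(m.shape)


def binarize_labels(classes, target: Intensity) -> np.ndarray:
    """Code each epoch 1 if its class equals ``target``, else 0."""
    classes = list(classes)
    if len(classes) == 0:
        raise DomainError("empty class sequence")
    return np.fromiter((1 if c == target else 0 for c in classes), dtype=int)
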