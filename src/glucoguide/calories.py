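"""Standard weight and daily calorie-target calculation.

The daily calorie target starts from the *standard weight* — height squared
times a sex-specific factor (21 kcal-standard for women, 22 for men) — which
is rounded up to a whole kilogram and multiplied by a kcal/kg/day band that
depends on the patient's activity class:

=========  ===================
activity   kcal per kg per day
=========  ===================
light      25 - 30
normal     30 - 35
hard       35 - 40
=========  ===================

``band_point`` selects a position inside the band; the default 0 (band
lower bound) reproduces the canonical worked example
1.65 m female -> 57.1725 kg -> 58 kg -> 58 x 25 = 1450 kcal/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ActivityBand:
    """Daily kcal-per-kg range for one activity class."""

    activity: str
    kcal_per_kg_low: float
    kcal_per_kg_high: float


#: The three activity bands, keyed by activity class.
ACTIVITY_BANDS: dict[str, ActivityBand] = {
    "light": ActivityBand("light", 25.0, 30.0),
    "normal": ActivityBand("normal", 30.0, 35.0),
    "hard": ActivityBand("hard", 35.0, 40.0),
}

#: Standard-weight multiplier (kg per m^2) by sex.  The female factor 21 is
#: the canonical constant of the formula; 22 is its conventional male
#: companion, an extrapolation since the source example covers only women.
STANDARD_WEIGHT_FACTORS: dict[str, float] = {"female": 21.0, "male": 22.0}


def standard_weight(
    height: float, sex: str, factors: dict[str, float] | None = None
) -> float:
    """Unrounded standard weight in kg: height (m) squared times the sex factor.

    >>> standard_weight(1.65, "female")
    57.172500000000014
    """
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    factors = STANDARD_WEIGHT_FACTORS if factors is None else factors
    if sex not in factors:
        raise ValueError(f"sex must be one of {sorted(factors)}, got {sex!r}")
    return height * height * factors[sex]


def round_standard_weight(weight: float) -> int:
    """Round a standard weight up to the next whole kilogram (57.1725 -> 58)."""
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return math.ceil(weight)


def daily_calories(
    rounded_weight: float, activity: str, band_point: float = 0.0
) -> float:
    """Daily calorie target in kcal for a rounded standard weight.

    ``band_point`` in [0, 1] interpolates within the activity band; 0 (the
    default) uses the band's lower bound, matching the worked example
    58 kg x 25 kcal/day = 1450 kcal.
    """
    if rounded_weight <= 0:
        raise ValueError(f"weight must be positive, got {rounded_weight}")
    if activity not in ACTIVITY_BANDS:
        raise ValueError(
            f"activity must be one of {sorted(ACTIVITY_BANDS)}, got {activity!r}"
        )
    if not 0 <= band_point <= 1:
        raise ValueError(f"band_point must lie in [0, 1], got {band_point}")
    band = ACTIVITY_BANDS[activity]
    per_kg = band.kcal_per_kg_low + band_point * (
        band.kcal_per_kg_high - band.kcal_per_kg_low
    )
    return rounded_weight * per_kg
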