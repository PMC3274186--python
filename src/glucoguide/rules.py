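"""Glucose diagnosis categories and the rule-based treatment recommender.

The diagnostic table maps fasting plasma glucose (FPG) and 2-hour post-meal
glucose to a category (normal / abnormally high / IGT / IFG / low).  The
treatment rule set maps an observation's hour of day and blood sugar to one
of the five treatment codes through time-windowed threshold rules.

Rule precedence
---------------
The rules are evaluated in tiers (lower tier first; first firing rule wins):

1. always (0-24 h): blood sugar below 70 -> rest (emergency dominates)
2. fasting windows 0-7, 9-12, 14-18, 20-23 h: over 126 -> more exercise
3. before sleeping 22-24 h: below 120 -> eat more
4. four-hours-after-meal windows 9-12, 15-17, 20-23 h:
   over 140 -> more exercise; below 100 -> eat more
5. always (0-24 h): over 180 -> take insulin
6. otherwise -> maintain

Window bounds are inclusive; all threshold comparisons are strict.  The
windowed rules outrank the always-insulin rule: a fasting-window reading of
199 mg/dL yields "more exercise", not insulin, while the same reading at an
uncovered hour (8, 13, 19) yields insulin.  A rule set is plain data and can
be serialized to/from YAML, so alternative precedence hypotheses can be
tried without code changes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from glucoguide.records import ObservationRecord, TreatmentCode


class GlucoseDiagnosis(enum.Enum):
    """Diagnostic category from fasting and post-meal glucose."""

    NORMAL = "normal"
    ABNORMALLY_HIGH = "abnormally_high"
    IGT = "impaired_glucose_tolerance"
    IFG = "impaired_fasting_glucose"
    LOW = "low_blood_sugar"
    UNCLASSIFIED = "unclassified"


def diagnose(
    fpg: float, post_meal_2h: Optional[float] = None
) -> GlucoseDiagnosis:
    """Classify fasting plasma glucose (and optional 2-h post-meal glucose).

    Low blood sugar (FPG below 70 mg/dL) needs no post-meal value and
    dominates every other row.  Combinations outside the table (for
    instance FPG 110 with post-meal 250) return ``UNCLASSIFIED`` rather
    than raising.
    """
    if fpg <= 0:
        raise ValueError(f"fpg must be positive, got {fpg}")
    if fpg < 70:
        return GlucoseDiagnosis.LOW
    if post_meal_2h is None:
        return GlucoseDiagnosis.UNCLASSIFIED
    if fpg < 100 and post_meal_2h < 140:
        return GlucoseDiagnosis.NORMAL
    if fpg > 126 and post_meal_2h > 200:
        return GlucoseDiagnosis.ABNORMALLY_HIGH
    if fpg < 100 and 140 <= post_meal_2h <= 199:
        return GlucoseDiagnosis.IGT
    if 100 <= fpg <= 125 and post_meal_2h < 140:
        return GlucoseDiagnosis.IFG
    return GlucoseDiagnosis.UNCLASSIFIED


@dataclass(frozen=True)
class Rule:
    """One time-windowed threshold rule on blood sugar.

    Fires when the observation hour falls inside any window (inclusive
    bounds) and blood sugar satisfies the strict comparison ``op threshold``.
    """

    tier: int
    windows: tuple[tuple[float, float], ...]
    op: str  # "<" or ">"
    threshold: float
    action: TreatmentCode
    name: str = ""

    def __post_init__(self) -> None:
        if self.op not in ("<", ">"):
            raise ValueError(f"op must be '<' or '>', got {self.op!r}")
        for start, end in self.windows:
            if not (0 <= start <= end <= 24):
                raise ValueError(
                    f"window [{start}, {end}] must lie within [0, 24]"
                )
        object.__setattr__(
            self, "windows", tuple((float(a), float(b)) for a, b in self.windows)
        )
        object.__setattr__(self, "action", TreatmentCode(int(self.action)))

    def fires(self, time: float, blood_sugar: float) -> bool:
        in_window = any(start <= time <= end for start, end in self.windows)
        if not in_window:
            return False
        if self.op == "<":
            return blood_sugar < self.threshold
        return blood_sugar > self.threshold


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule collection with a default (maintenance) action."""

    rules: tuple[Rule, ...]
    default_action: TreatmentCode = TreatmentCode.MAINTAIN

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.rules, key=lambda r: r.tier)
        )  # stable: ties keep sequence order
        object.__setattr__(self, "rules", ordered)
        object.__setattr__(
            self, "default_action", TreatmentCode(int(self.default_action))
        )

    def recommend(self, record: ObservationRecord) -> TreatmentCode:
        """First firing rule in tier order wins; otherwise the default."""
        if not 0 <= record.time <= 24:
            raise ValueError(f"time must lie in [0, 24], got {record.time}")
        for rule in self.rules:
            if rule.fires(record.time, record.blood_sugar):
                return rule.action
        return self.default_action

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "default_action": int(self.default_action),
            "rules": [
                {
                    "name": r.name,
                    "tier": r.tier,
                    "windows": [list(w) for w in r.windows],
                    "op": r.op,
                    "threshold": r.threshold,
                    "action": int(r.action),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleSet":
        rules = tuple(
            Rule(
                tier=r["tier"],
                windows=tuple(tuple(w) for w in r["windows"]),
                op=r["op"],
                threshold=float(r["threshold"]),
                action=TreatmentCode(int(r["action"])),
                name=r.get("name", ""),
            )
            for r in data["rules"]
        )
        return cls(
            rules=rules,
            default_action=TreatmentCode(int(data.get("default_action", 5))),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RuleSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "RuleSet":
        """The packaged default rule set (module docstring precedence)."""
        return _default_ruleset()


_FPG_WINDOWS = ((0, 7), (9, 12), (14, 18), (20, 23))
_BEFORE_SLEEP_WINDOWS = ((22, 24),)
_POST_MEAL_WINDOWS = ((9, 12), (15, 17), (20, 23))
_ALWAYS = ((0, 24),)


def _default_ruleset() -> RuleSet:
    return RuleSet(
        rules=(
            Rule(1, _ALWAYS, "<", 70, TreatmentCode.REST, "emergency-low"),
            Rule(2, _FPG_WINDOWS, ">", 126, TreatmentCode.MORE_EXERCISE,
                 "fasting-high"),
            Rule(3, _BEFORE_SLEEP_WINDOWS, "<", 120, TreatmentCode.EAT_MORE,
                 "before-sleep-low"),
            Rule(4, _POST_MEAL_WINDOWS, ">", 140, TreatmentCode.MORE_EXERCISE,
                 "post-meal-high"),
            Rule(4, _POST_MEAL_WINDOWS, "<", 100, TreatmentCode.EAT_MORE,
                 "post-meal-low"),
            Rule(5, _ALWAYS, ">", 180, TreatmentCode.TAKE_INSULIN,
                 "always-insulin"),
        ),
        default_action=TreatmentCode.MAINTAIN,
    )


def load_default_ruleset() -> RuleSet:
    """Load the default rule set from the packaged YAML file."""
    source = resources.files("glucoguide.data").joinpath("default_rules.yaml")
    with resources.as_file(source) as path:
        return RuleSet.from_yaml(path)


def recommend(
    record: ObservationRecord, rules: Optional[RuleSet] = None
) -> TreatmentCode:
    """Rule-based treatment recommendation for one observation record."""
    rules = RuleSet.default() if rules is None else rules
    return rules.recommend(record)
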