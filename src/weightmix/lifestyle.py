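"""Lifestyle questionnaire data model.

Annual Japanese health checkups include a standard self-report questionnaire.
The eleven items used here cover smoking, drinking, physical activity, eating
habits and sleep, plus a three-level "intention to improve lifestyle"
behaviour-change-stage item that modulates how answers given for the
predictive year enter the model.

Column coding in cohort tables / CSV files:

* yes/no items: 1 = yes, 0 = no
* ``eating_speed``: 0 = quicker, 1 = normal, 2 = slower
* ``drinking_score``: combined frequency/quantity scale, 0-10
* ``intention_level``: 1, 2 or 3
"""

from __future__ import annotations

from dataclasses import dataclass, fields

#: yes/no questionnaire items, in canonical column order.
BINARY_ITEMS = (
    "wants_instruction",   # wants to use health-instruction opportunity
    "heavy_smoker",
    "fast_walker",         # walks faster than peers of same age/sex
    "daily_activity",      # >=1 h/day walking or equivalent
    "exercise_habit",      # moderate exercise >=2x30 min/week for a year
    "skips_breakfast",     # skips breakfast >=3x/week
    "late_supper",         # supper within 2 h of bedtime >=3x/week
    "snacks",              # snacks / sweet beverages between meals
    "sleeps_well",
)

EATING_SPEED_LEVELS = ("quicker", "normal", "slower")

#: all questionnaire columns as they appear in cohort tables.
LIFESTYLE_COLUMNS = BINARY_ITEMS + ("drinking_score", "eating_speed", "intention_level")


@dataclass(frozen=True)
class LifestyleProfile:
    """One year's questionnaire answers for one person."""

    wants_instruction: int = 0
    heavy_smoker: int = 0
    fast_walker: int = 0
    daily_activity: int = 0
    exercise_habit: int = 0
    skips_breakfast: int = 0
    late_supper: int = 0
    snacks: int = 0
    sleeps_well: int = 1
    drinking_score: float = 0.0
    eating_speed: int = 1  # 0 quicker / 1 normal / 2 slower
    intention_level: int = 2

    def __post_init__(self) -> None:
        for item in BINARY_ITEMS:
            v = getattr(self, item)
            if v not in (0, 1):
                raise ValueError(f"{item} must be 0/1, got {v!r}")
        if self.eating_speed not in (0, 1, 2):
            raise ValueError(f"eating_speed must be 0/1/2, got {self.eating_speed!r}")
        if self.intention_level not in (1, 2, 3):
            raise ValueError(
                f"intention_level must be 1/2/3, got {self.intention_level!r}"
            )
        if self.drinking_score < 0:
            raise ValueError("drinking_score must be >= 0")

    def replace(self, **changes) -> "LifestyleProfile":
        d = self.as_dict()
        d.update(changes)
        return LifestyleProfile(**d)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_row(cls, row) -> "LifestyleProfile":
        """Build from a mapping holding the LIFESTYLE_COLUMNS keys."""
        kw = {}
        for col in LIFESTYLE_COLUMNS:
            v = row[col]
            if v is None or v != v:  # NaN check without numpy import
                raise ValueError(f"missing lifestyle item {col!r}")
            kw[col] = float(v) if col == "drinking_score" else int(v)
        return cls(**kw)
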