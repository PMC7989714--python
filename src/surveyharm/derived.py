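"""Derived health indicators and the ``Func::`` registry.

Derived variables are computed from one or more harmonized inputs after
the row-level recoding pass: body mass index from height and weight,
continuous age from age-group midpoints, smoking pack-years from the
smoking history, the ADL assistance count, and a binge-drinking flag.

Every function propagates tagged missing values: a tagged input yields a
tagged output, with ``NA::a`` (not applicable) dominating ``NA::b``
(don't know / refusal / not stated). The one deliberate exception is
documented on :func:`pack_years_fun`: a confirmed never-smoker scores 0
pack-years even though the cigarettes-per-day question was structurally
skipped for them.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple, Union

from .missing import TaggedMissing, is_tagged

Number = Union[int, float]
Value = Union[Number, TaggedMissing]

#: Closed bounds of the harmonized age groups (code -> (low, high) years).
#: The top group is open-ended; ``None`` marks its missing upper bound.
AGE_CATEGORY_BOUNDS: Dict[int, Tuple[int, Optional[int]]] = {
    1: (12, 14), 2: (15, 19), 3: (20, 24), 4: (25, 29), 5: (30, 34),
    6: (35, 39), 7: (40, 44), 8: (45, 49), 9: (50, 54), 10: (55, 59),
    11: (60, 64), 12: (65, 69), 13: (70, 74), 14: (75, 79), 15: (80, None),
}

#: Proxy age for the open-ended 80+ group. Approximates the conditional
#: mean age of that group; overridable via ``category_bounds``.
TOP_AGE_MIDPOINT = 85.0


def _tag_of(*values: Value) -> Optional[TaggedMissing]:
    return TaggedMissing.dominant(values)


def _bad(value: Value) -> bool:
    """Non-tagged but unusable input (None/NaN)."""
    if is_tagged(value):
        return False
    if value is None:
        return True
    return isinstance(value, float) and math.isnan(value)


def derive_bmi(height_m: Value, weight_kg: Value) -> Value:
    """Body mass index, kg/m², rounded to 2 decimals.

    Computed uniformly for all respondents — no age restriction, unlike
    some survey cycles' shipped BMI. Heights outside (0.5, 2.5) m or
    weights outside (20, 300) kg are implausible and yield ``NA::b``.
    """
    tag = _tag_of(height_m, weight_kg)
    if tag is not None:
        return tag
    if _bad(height_m) or _bad(weight_kg):
        return TaggedMissing.NA_B
    if not (0.5 < height_m < 2.5) or not (20 < weight_kg < 300):
        return TaggedMissing.NA_B
    return round(weight_kg / height_m ** 2, 2)


def derive_age_cont(
    age_category: Value,
    category_bounds: Optional[Mapping[int, Tuple[int, Optional[int]]]] = None,
) -> Value:
    """Continuous age as the midpoint of a harmonized age group.

    The open-ended top group (80+) maps to :data:`TOP_AGE_MIDPOINT`.
    Unknown codes yield ``NA::b``.
    """
    tag = _tag_of(age_category)
    if tag is not None:
        return tag
    if _bad(age_category):
        return TaggedMissing.NA_B
    bounds = AGE_CATEGORY_BOUNDS if category_bounds is None else category_bounds
    code = int(age_category)
    if code != age_category or code not in bounds:
        return TaggedMissing.NA_B
    lo, hi = bounds[code]
    if hi is None:
        return TOP_AGE_MIDPOINT
    return (lo + hi) / 2.0


def derive_pack_years(cigs_per_day: Value, years_smoked: Value) -> Value:
    """Pack-years: (cigarettes per day / 20) × years smoked.

    One pack is 20 cigarettes; smoking one pack a day for ten years is
    10 pack-years. Negative inputs are implausible and yield ``NA::b``.
    """
    tag = _tag_of(cigs_per_day, years_smoked)
    if tag is not None:
        return tag
    if _bad(cigs_per_day) or _bad(years_smoked):
        return TaggedMissing.NA_B
    if cigs_per_day < 0 or years_smoked < 0:
        return TaggedMissing.NA_B
    return round((cigs_per_day / 20.0) * years_smoked, 3)


def pack_years_fun(smoker_status: Value, cigs_per_day: Value,
                   age_cont: Value, age_started: Value,
                   age_quit: Value) -> Value:
    """Pack-years from the full smoking history.

    ``smoker_status``: 1 current, 2 former, 3 never. Years smoked is
    current age − age started for current smokers, and age quit − age
    started for former smokers.

    The status acts as a gate ahead of missing-value propagation: a
    never-smoker scores 0.0 even though cigarettes/day and the start and
    quit ages are structurally not applicable (``NA::a``) for them. A
    tagged *status* still propagates.
    """
    tag = _tag_of(smoker_status)
    if tag is not None:
        return tag
    if _bad(smoker_status):
        return TaggedMissing.NA_B
    status = int(smoker_status)
    if status == 3:
        return 0.0
    if status == 1:
        tag = _tag_of(cigs_per_day, age_cont, age_started)
        if tag is not None:
            return tag
        if _bad(cigs_per_day) or _bad(age_cont) or _bad(age_started):
            return TaggedMissing.NA_B
        return derive_pack_years(cigs_per_day,
                                 max(age_cont - age_started, 0.0))
    if status == 2:
        tag = _tag_of(cigs_per_day, age_quit, age_started)
        if tag is not None:
            return tag
        if _bad(cigs_per_day) or _bad(age_quit) or _bad(age_started):
            return TaggedMissing.NA_B
        return derive_pack_years(cigs_per_day,
                                 max(age_quit - age_started, 0.0))
    return TaggedMissing.NA_B


def derive_adl_score_5(*adl_items: Value) -> Value:
    """Count of the five ADL items coded 1 ("needs help").

    Items are coded 1 = needs help, 2 = does not. Any ``NA::a`` input
    makes the score ``NA::a``; otherwise any ``NA::b`` makes it
    ``NA::b``; an out-of-domain code yields ``NA::b``.
    """
    if len(adl_items) != 5:
        raise ValueError("ADL score requires exactly 5 items")
    tag = _tag_of(*adl_items)
    if tag is not None:
        return tag
    score = 0
    for item in adl_items:
        if _bad(item) or item not in (1, 2):
            return TaggedMissing.NA_B
        if item == 1:
            score += 1
    return score


#: Harmonized 5+ drinks frequency codes meaning "at least once a month".
BINGE_MONTHLY_CODES = frozenset({3, 4, 5, 6})


def derive_binge_drinker(freq_5plus_code: Value) -> Value:
    """Binge drinking flag: 1 if 5+ drinks at least monthly, else 2.

    Operates on the harmonized frequency scale 1 (never) … 6 (more than
    once a week); codes 3–6 meet the at-least-monthly threshold.
    """
    tag = _tag_of(freq_5plus_code)
    if tag is not None:
        return tag
    if _bad(freq_5plus_code):
        return TaggedMissing.NA_B
    code = int(freq_5plus_code)
    if code != freq_5plus_code or not 1 <= code <= 6:
        return TaggedMissing.NA_B
    return 1 if code in BINGE_MONTHLY_CODES else 2


def bmi_fun(height_m: Value, weight_kg: Value) -> Value:
    return derive_bmi(height_m, weight_kg)


def age_cont_fun(age_category: Value) -> Value:
    return derive_age_cont(age_category)


def adl_score_5_fun(*adl_items: Value) -> Value:
    return derive_adl_score_5(*adl_items)


def binge_drinker_fun(freq_5plus_code: Value) -> Value:
    return derive_binge_drinker(freq_5plus_code)


#: Registry resolving ``Func::<name>`` worksheet tags. Functions take one
#: scalar per declared input (in worksheet order) and return a number or
#: a tagged missing marker.
REGISTRY: Dict[str, Callable[..., Value]] = {
    "bmi_fun": bmi_fun,
    "age_cont_fun": age_cont_fun,
    "pack_years_fun": pack_years_fun,
    "adl_score_5_fun": adl_score_5_fun,
    "binge_drinker_fun": binge_drinker_fun,
}


def register(name: str, func: Callable[..., Value],
             registry: Optional[Dict[str, Callable[..., Value]]] = None
             ) -> None:
    """Register a user derived-variable function under a ``Func::`` tag."""
    target = REGISTRY if registry is None else registry
    if name in target:
        raise ValueError(f"function tag already registered: {name}")
    target[name] = func
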