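"""Synthetic raw-cycle generators: test the engine with no data download.

Two generators are provided:

* :func:`generate_cycle_fixture` is fully worksheet-driven: it reads the
  declared source domains (category codes, copy intervals, reserved
  missing codes) and emits a raw respondent table for any worksheet set.
  Values are drawn uniformly — fixtures exercise the mechanics of
  recoding, not the epidemiology of any real survey.

* :func:`generate_truth_paired_fixture` additionally returns the latent
  truths (exact age, smoking history, true ADL count, ...) used to
  construct the raw codes, enabling recovery tests for derived
  variables. It understands the semantics of the packaged demonstration
  variables and is specific to them.

Both reproduce the cycle-specific quirks of the raw files the
demonstration worksheets model: 2001/2003 carry the 15-category age
variable and e.g. ``HWTAGBMI``-style names, 2005 onward the 16-category
age variable; raw BMI is rounded to 1 decimal in 2001/2003 and 2
decimals later. Same config, same output — byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import CycleTable
from .worksheet import RecodeRule, WorksheetSet


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Deterministic recipe for one synthetic raw cycle table."""

    cycle_id: str
    n_rows: int = 200
    seed: int = 0
    missing_rate: float = 0.05
    undocumented_code_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 0:
            raise FixtureError("n_rows must be non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise FixtureError("missing_rate must be in [0, 1]")
        if not 0 <= self.undocumented_code_rate <= 1:
            raise FixtureError("undocumented_code_rate must be in [0, 1]")


#: Raw age-group structures. 2001/2003 use 15 groups; from 2005 the
#: 15-19 group is split into 15-17 and 18-19, giving 16.
RAW_AGE_15: Tuple[Tuple[int, int, int], ...] = tuple(
    [(1, 12, 14), (2, 15, 19)]
    + [(k, 20 + 5 * (k - 3), 24 + 5 * (k - 3)) for k in range(3, 15)]
    + [(15, 80, 95)]
)
RAW_AGE_16: Tuple[Tuple[int, int, int], ...] = tuple(
    [(1, 12, 14), (2, 15, 17), (3, 18, 19)]
    + [(k, 20 + 5 * (k - 4), 24 + 5 * (k - 4)) for k in range(4, 16)]
    + [(16, 80, 95)]
)

OLD_AGE_CYCLES = ("cchs2001_p", "cchs2003_p")


def raw_age_structure(cycle_id: str) -> Tuple[Tuple[int, int, int], ...]:
    return RAW_AGE_15 if cycle_id in OLD_AGE_CYCLES else RAW_AGE_16


def _age_to_raw_code(age: int, structure: Sequence[Tuple[int, int, int]]
                     ) -> int:
    for code, lo, hi in structure:
        if lo <= age <= hi:
            return code
    raise FixtureError(f"age {age} outside the fixture age range")


def _rng(config: FixtureConfig, worksheets: WorksheetSet,
         stream: int) -> np.random.Generator:
    cycle_index = worksheets.cycle_universe.index(config.cycle_id)
    return np.random.default_rng([config.seed, cycle_index, stream])


def _plain_variables(worksheets: WorksheetSet, cycle: str) -> List[str]:
    return [v for v in worksheets.applicable_variables(cycle)
            if not worksheets.is_derived(v)]


def _raw_name(worksheets: WorksheetSet, variable: str, cycle: str) -> str:
    names = {r.raw_name(cycle)
             for r in worksheets.rules_for(variable, cycle)}
    names.discard(None)
    if len(names) != 1:
        raise FixtureError(
            f"variable {variable!r}: ambiguous raw name for {cycle!r}")
    return names.pop()


def _rule_pools(rules: Sequence[RecodeRule]
                ) -> Tuple[List[float], Optional[Tuple[float, float]],
                           List[float]]:
    """(valid category codes, copy interval, reserved missing codes)."""
    codes: List[float] = []
    interval: Optional[Tuple[float, float]] = None
    missing: List[float] = []
    for rule in rules:
        spec, target = rule.rec_start, rule.rec_end
        if spec.kind == "code" and target.kind == "code":
            codes.append(spec.code)
        elif spec.kind == "interval" and target.kind == "copy":
            interval = (spec.lo, spec.hi)
        elif target.kind == "missing":
            if spec.kind == "code":
                missing.append(spec.code)
            elif spec.kind == "interval":
                lo, hi = spec.lo, spec.hi
                if lo.is_integer() and hi.is_integer() and hi - lo < 50:
                    missing.extend(float(c)
                                   for c in range(int(lo), int(hi) + 1))
                else:
                    missing.append(lo)
    return codes, interval, missing


def _undocumented_value(rules: Sequence[RecodeRule]) -> float:
    """A value no specific (non-else) rule matches."""
    specific = [r.rec_start for r in rules if r.rec_start.kind != "else"]
    for candidate in range(0, 100000):
        v = float(candidate)
        if not any(s.matches(v) for s in specific):
            return v
    raise FixtureError("no undocumented value found")  # pragma: no cover


def _draw_column(rng: np.random.Generator, n: int,
                 rules: Sequence[RecodeRule],
                 config: FixtureConfig) -> np.ndarray:
    codes, interval, missing = _rule_pools(rules)
    out = np.empty(n, dtype=float)
    u = rng.random(n)
    if interval is not None:
        lo, hi = interval
        out[:] = np.round(rng.uniform(lo, hi, size=n), 3)
    elif codes:
        out[:] = rng.choice(codes, size=n)
    else:  # only missing-code rules declared
        out[:] = missing[0] if missing else np.nan
    miss_mask = u < config.missing_rate
    if miss_mask.any() and missing:
        out[miss_mask] = rng.choice(missing, size=int(miss_mask.sum()))
    undoc_mask = (~miss_mask) & (
        u < config.missing_rate + config.undocumented_code_rate)
    if undoc_mask.any():
        out[undoc_mask] = _undocumented_value(rules)
    return out


def generate_cycle_fixture(config: FixtureConfig,
                           worksheets: WorksheetSet) -> CycleTable:
    """Emit a synthetic raw table for one cycle, driven by the worksheets.

    Columns are the raw variable names the cycle needs (per
    ``variableStart``); categorical values are drawn uniformly from the
    declared source codes, continuous values uniformly within the copy
    interval; reserved missing codes appear at ``missing_rate`` and
    undocumented codes at ``undocumented_code_rate``.
    """
    if config.cycle_id not in worksheets.cycle_universe:
        raise FixtureError(f"unknown cycle: {config.cycle_id!r}")
    data: Dict[str, np.ndarray] = {}
    for stream, variable in enumerate(
            _plain_variables(worksheets, config.cycle_id)):
        rules = worksheets.rules_for(variable, config.cycle_id)
        rng = _rng(config, worksheets, stream)
        data[_raw_name(worksheets, variable, config.cycle_id)] = \
            _draw_column(rng, config.n_rows, rules, config)
    return CycleTable(cycle_id=config.cycle_id, rows=pd.DataFrame(data))


# ---------------------------------------------------------------------------
# truth-paired generation (demonstration worksheet semantics)


def generate_truth_paired_fixture(
    config: FixtureConfig, worksheets: WorksheetSet
) -> Tuple[CycleTable, pd.DataFrame]:
    """Raw table plus the latent truths that produced it.

    The truth table carries, per respondent: exact age, sex, marital
    status, income group, height, weight, true BMI, smoking history and
    pack-years, the 5+ drinks frequency with the binge flag, and the
    true ADL assistance count. Raw codes are the truths re-expressed in
    each cycle's raw coding (age binned to the cycle's 15- or 16-group
    structure, BMI rounded to the cycle's precision, ADL counts spread
    over the five items). Reserved missing codes are injected at
    ``missing_rate`` per raw column; truths are left untouched, so
    recovery comparisons should condition on non-tagged outputs when the
    rate is nonzero.
    """
    if config.cycle_id not in worksheets.cycle_universe:
        raise FixtureError(f"unknown cycle: {config.cycle_id!r}")
    n = config.n_rows
    rng = _rng(config, worksheets, stream=1_000_003)
    cycle = config.cycle_id

    age = rng.integers(12, 96, size=n)
    sex = rng.integers(1, 3, size=n)
    marital = rng.integers(1, 5, size=n)
    income = rng.integers(1, 6, size=n)
    height = np.round(rng.uniform(1.40, 2.00, size=n), 3)
    weight = np.round(rng.uniform(45.0, 120.0, size=n), 1)
    smoker = rng.integers(1, 4, size=n)  # 1 current, 2 former, 3 never
    cigs = rng.integers(1, 41, size=n).astype(float)
    started = np.minimum(rng.integers(10, 41, size=n), age).astype(float)
    quit_frac = rng.random(n)
    quit = np.round(started + quit_frac * (age - started)).astype(float)
    alw = rng.integers(1, 7, size=n)
    adl_count = rng.integers(0, 6, size=n)

    never = smoker == 3
    current = smoker == 1
    cigs = np.where(never, np.nan, cigs)
    started = np.where(never, np.nan, started)
    quit = np.where(never | current, np.nan, quit)

    years_smoked = np.where(
        current, age - started, np.where(never, 0.0, quit - started))
    pack_years = np.where(
        never, 0.0, np.round((cigs / 20.0) * years_smoked, 3))
    bmi = np.round(weight / height ** 2, 2)

    truth = pd.DataFrame({
        "age": age, "sex": sex, "marital": marital, "income": income,
        "height_m": height, "weight_kg": weight, "bmi": bmi,
        "smoker_status": smoker, "cigs_per_day": cigs,
        "age_started": started, "age_quit": quit,
        "pack_years": pack_years,
        "alw_freq": alw,
        "binge_drinker": np.where(alw >= 3, 1, 2),
        "adl_count": adl_count,
    })

    structure = raw_age_structure(cycle)
    age_codes = np.array([_age_to_raw_code(int(a), structure) for a in age],
                         dtype=float)
    bmi_decimals = 1 if cycle in OLD_AGE_CYCLES else 2
    raw_bmi = np.round(weight / height ** 2, bmi_decimals)

    def name(var: str) -> str:
        return _raw_name(worksheets, var, cycle)

    raw: Dict[str, np.ndarray] = {
        name("DHH_SEX"): sex.astype(float),
        name("DHHGAGE"): age_codes,
        name("DHHGMS"): marital.astype(float),
        name("INCGHH"): income.astype(float),
        name("HWTGHTM"): height,
        name("HWTGWTK"): weight,
        name("HWTGBMI"): raw_bmi,
        name("SMKDSTY_A"): smoker.astype(float),
        name("SMK_204_cont"): np.where(np.isnan(cigs), 96.0, cigs),
        name("SMKG040_cont"): np.where(np.isnan(started), 996.0, started),
        name("SMKG852_cont"): np.where(np.isnan(quit), 996.0, quit),
    }
    if "ALW_5PL" in worksheets.applicable_variables(cycle):
        raw[name("ALW_5PL")] = alw.astype(float)
    for i in range(1, 6):
        var = f"ADL_0{i}"
        raw[name(var)] = np.where(adl_count >= i, 1.0, 2.0)

    if config.missing_rate > 0:
        for col_index, variable in enumerate(
                _plain_variables(worksheets, cycle)):
            col = _raw_name(worksheets, variable, cycle)
            rules = worksheets.rules_for(variable, cycle)
            _, _, missing_codes = _rule_pools(rules)
            if not missing_codes:
                continue
            col_rng = _rng(config, worksheets, stream=2_000_003 + col_index)
            mask = col_rng.random(n) < config.missing_rate
            if mask.any():
                raw[col] = raw[col].copy()
                raw[col][mask] = col_rng.choice(missing_codes,
                                                size=int(mask.sum()))

    return CycleTable(cycle_id=cycle, rows=pd.DataFrame(raw)), truth
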