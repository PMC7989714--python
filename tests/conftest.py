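import math

import pytest

from surveyharm import TaggedMissing, load_demo_worksheets


@pytest.fixture(scope="session")
def demo_ws():
    return load_demo_worksheets()


# ---------------------------------------------------------------------------
# Independent brute-force recode oracle.
#
# Deliberately written as a naive per-value loop with its own matching
# arithmetic (no reuse of the engine's SourceSpec.matches or the
# vectorized path), so engine-vs-oracle comparisons are a genuine dual
# route.


def oracle_recode_value(raw, rules):
    """Naive interpreter: first matching specific rule, else the catch-all,
    else NA::b."""
    isnan = raw is None or (isinstance(raw, float) and math.isnan(raw))
    else_rule = None
    for rule in rules:
        spec = rule.rec_start
        if spec.kind == "else":
            else_rule = rule
            continue
        if spec.kind == "na":
            hit = isnan
        elif isnan:
            hit = False
        elif spec.kind == "code":
            hit = abs(raw - spec.code) <= 1e-9
        else:
            hit = spec.lo - 1e-9 <= raw <= spec.hi + 1e-9
        if hit:
            return _oracle_target(rule, raw, isnan)
    if else_rule is not None:
        return _oracle_target(else_rule, raw, isnan)
    return TaggedMissing.NA_B


def _oracle_target(rule, raw, isnan):
    target = rule.rec_end
    if target.kind == "copy":
        return TaggedMissing.NA_B if isnan else float(raw)
    if target.kind == "missing":
        return target.tag
    code = target.code
    return int(code) if float(code).is_integer() else code


@pytest.fixture(scope="session")
def oracle():
    return oracle_recode_value
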