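"""Deterministic decision-tree engine.

Each treatment arm is a two-branch tree (survive / death).  Rolling the tree
back gives per-arm expected cost and expected QALYs; comparing two arms gives
the incremental cost, incremental effect, the incremental cost-utility ratio
(ICUR) with its dominance classification, and the net monetary benefit
NMB(lambda) = lambda * effect - cost.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .parameters import ArmModel, CurrencyError, Money, UtilityLY

__all__ = [
    "Quadrant",
    "ArmExpectation",
    "CEAResult",
    "qaly",
    "qaly_band",
    "arm_expectation",
    "expectation_from_values",
    "total_cost",
    "incremental",
    "classify",
    "icur",
    "icur_band",
    "nmb",
    "inmb",
    "compare",
    "report",
]


class Quadrant(str, enum.Enum):
    """Position of (delta_cost, delta_effect) on the cost-effectiveness plane."""

    DOMINANT = "dominant"              # cheaper and/or more effective, one strictly
    DOMINATED = "dominated"            # dearer and/or less effective, one strictly
    TRADEOFF_NE = "tradeoff_ne_quadrant"  # dearer but more effective
    TRADEOFF_SW = "tradeoff_sw_quadrant"  # cheaper but less effective
    EQUIVALENT = "equivalent"          # no difference on either axis


@dataclass(frozen=True)
class ArmExpectation:
    """Expected cost (TWD) and expected effect (QALYs) of one arm."""

    arm: str
    expected_cost: float
    expected_effect: float


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison: increments, ICUR (None when delta_effect = 0), dominance."""

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icur: float | None
    dominance: Quadrant


def qaly(utility: float, life_years: float) -> float:
    """Quality-adjusted life-years: utility (in [0, 1]) times life-years."""
    if not (0.0 <= utility <= 1.0):
        raise ValueError(f"utility {utility} outside [0, 1]")
    if life_years < 0:
        raise ValueError("life_years must be >= 0")
    return utility * life_years


def qaly_band(u: UtilityLY) -> tuple[float, float]:
    """(low, high) QALYs from the reported utility bounds at the given life-years."""
    return qaly(u.utility_low, u.life_years), qaly(u.utility_high, u.life_years)


def expectation_from_values(p_survive, cost_survive, cost_death, eff_survive, eff_death):
    """Tree rollback on raw values; broadcasts, so the PSA can vectorise over replicates."""
    p = np.asarray(p_survive, dtype=float)
    cost = p * cost_survive + (1.0 - p) * cost_death
    eff = p * eff_survive + (1.0 - p) * eff_death
    return cost, eff


def arm_expectation(model: ArmModel, at_central: bool = True) -> ArmExpectation:
    """Expected cost and effect of an arm's tree.

    ``at_central`` uses the printed central values; otherwise the analytic
    means of the fitted distributions (these differ only by fitting round-off).
    """
    surv = model.branch("survive")
    dead = model.branch("death")
    value = (lambda s: s.central) if at_central else (lambda s: s.mean())
    cost, eff = expectation_from_values(
        value(model.p_survive), value(surv.cost), value(dead.cost),
        value(surv.qaly), value(dead.qaly),
    )
    return ArmExpectation(model.name, float(cost), float(eff))


def total_cost(outpatient, inpatient):
    """Sum outpatient and inpatient costs; Money inputs must share a currency."""
    if isinstance(outpatient, Money) or isinstance(inpatient, Money):
        if not (isinstance(outpatient, Money) and isinstance(inpatient, Money)):
            raise CurrencyError("cannot add Money to a bare number")
        return outpatient + inpatient
    return outpatient + inpatient


def incremental(ref: ArmExpectation, comp: ArmExpectation) -> tuple[float, float]:
    """Signed increments (reference minus comparator): (delta_cost, delta_effect)."""
    return (ref.expected_cost - comp.expected_cost,
            ref.expected_effect - comp.expected_effect)


def classify(delta_cost: float, delta_effect: float) -> Quadrant:
    """Dominance classification from the signs of the increments."""
    if delta_cost == 0 and delta_effect == 0:
        return Quadrant.EQUIVALENT
    if delta_cost <= 0 and delta_effect >= 0:
        return Quadrant.DOMINANT
    if delta_cost >= 0 and delta_effect <= 0:
        return Quadrant.DOMINATED
    if delta_cost > 0:
        return Quadrant.TRADEOFF_NE
    return Quadrant.TRADEOFF_SW


def icur(delta_cost: float, delta_effect: float,
         reference: str = "reference", comparator: str = "comparator") -> CEAResult:
    """Incremental cost-utility ratio with dominance label.

    The ratio is undefined (None) when delta_effect = 0; the result is still
    classified, never raised, so downstream tabulation stays total.
    """
    ratio = None if delta_effect == 0 else delta_cost / delta_effect
    return CEAResult(reference, comparator, delta_cost, delta_effect,
                     ratio, classify(delta_cost, delta_effect))


def icur_band(
    delta_cost: float,
    ref_band: tuple[float, float],
    comp_band: tuple[float, float],
    matched: bool = True,
) -> tuple[float, float]:
    """ICUR at the QALY-band bounds of the two arms.

    With ``matched`` pairing (the default) the low bounds are compared with
    each other and likewise the highs, giving (icur_at_low, icur_at_high).
    Otherwise the full four-combination band (min, max) is returned.
    """
    if matched:
        de_low = ref_band[0] - comp_band[0]
        de_high = ref_band[1] - comp_band[1]
        return delta_cost / de_low, delta_cost / de_high
    ratios = [delta_cost / (r - c) for r in ref_band for c in comp_band if r != c]
    return min(ratios), max(ratios)


def nmb(wtp: float, effect: float, cost: float) -> float:
    """Net monetary benefit: wtp * effect - cost (wtp and cost in the same currency)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * effect - cost


def inmb(wtp, delta_effect, delta_cost):
    """Incremental net monetary benefit; broadcasts over arrays."""
    return np.asarray(wtp, dtype=float) * delta_effect - delta_cost


def compare(ref: ArmModel, comp: ArmModel, at_central: bool = True) -> CEAResult:
    """Full deterministic comparison of two arm models (reference minus comparator)."""
    e_ref = arm_expectation(ref, at_central=at_central)
    e_comp = arm_expectation(comp, at_central=at_central)
    dc, de = incremental(e_ref, e_comp)
    return icur(dc, de, reference=ref.name, comparator=comp.name)


def report(result: CEAResult, round_output: bool = True) -> dict:
    """Flat report of a comparison.

    Costs round to the nearest TWD and QALYs to two decimals, matching the
    precision the base-case tables are printed at.  A dominant comparison
    additionally reports |ICUR| as TWD saved per QALY gained.
    """
    d: dict = {
        "reference": result.reference,
        "comparator": result.comparator,
        "delta_cost_twd": result.delta_cost,
        "delta_effect_qaly": result.delta_effect,
        "icur_twd_per_qaly": result.icur,
        "dominance": result.dominance.value,
    }
    if result.dominance is Quadrant.DOMINANT and result.icur is not None:
        d["saved_twd_per_qaly_gained"] = abs(result.icur)
    if round_output:
        for key in ("delta_cost_twd", "icur_twd_per_qaly", "saved_twd_per_qaly_gained"):
            if d.get(key) is not None:
                d[key] = round(d[key])
        d["delta_effect_qaly"] = round(d["delta_effect_qaly"], 2)
    return d
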