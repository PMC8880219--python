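"""One-way (tornado) sensitivity analysis.

Each model parameter is swept to the endpoints of its plausible range while
every other parameter is held at its central value; the output metric is
recomputed through the decision tree at both endpoints and parameters are
ranked by the spread they induce.  No randomness is involved: the output is
a pure function of the model fixture and settings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from scipy import stats

from .parameters import AnalysisSettings, ArmModel, DistributionSpec
from .tree_model import arm_expectation, incremental, inmb

__all__ = ["TornadoEntry", "tornado"]


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram.

    ``low_output``/``high_output`` are the metric at the parameter's range
    endpoints; NaN with ``undefined=True`` marks an ICUR sweep that crossed
    delta_effect = 0.
    """

    parameter: str
    low_output: float
    high_output: float
    spread: float
    metric: str
    base_output: float
    undefined: bool = False


def _beta_95_range(spec: DistributionSpec) -> tuple[float, float]:
    a, b = spec.fitted_params
    return float(stats.beta.ppf(0.025, a, b)), float(stats.beta.ppf(0.975, a, b))


def _sweep_targets(arm: ArmModel, probability_range: str):
    """(label, attribute-path) pairs for the ten sweepable tree parameters."""
    if probability_range == "fitted95" and arm.p_survive.family == "beta":
        lo, hi = _beta_95_range(arm.p_survive)
    else:
        lo, hi = arm.p_survive.range_low, arm.p_survive.range_high
    yield f"{arm.name} survive probability", ("p_survive", None), (lo, hi)
    for branch in arm.branches:
        for kind in ("cost", "qaly"):
            spec: DistributionSpec = getattr(branch, kind)
            label = f"{arm.name} {'QALY' if kind == 'qaly' else 'cost'} ({branch.outcome})"
            yield label, (kind, branch.outcome), (spec.range_low, spec.range_high)


def _with_value(arm: ArmModel, path: tuple[str, str | None], value: float) -> ArmModel:
    """Copy of ``arm`` with one parameter's central value replaced."""
    kind, outcome = path
    if kind == "p_survive":
        spec = arm.p_survive
        return replace(arm, p_survive=DistributionSpec(
            "fixed", value, min(value, spec.range_low), max(value, spec.range_high)))
    new_branches = []
    for b in arm.branches:
        if b.outcome == outcome:
            spec = getattr(b, kind)
            swept = DistributionSpec("fixed", value,
                                     min(value, spec.range_low), max(value, spec.range_high))
            new_branches.append(replace(b, **{kind: swept}))
        else:
            new_branches.append(b)
    return replace(arm, branches=tuple(new_branches))


def _metric_value(ref: ArmModel, comp: ArmModel, metric: str, wtp: float) -> tuple[float, bool]:
    dc, de = incremental(arm_expectation(ref), arm_expectation(comp))
    if metric == "inmb":
        return float(inmb(wtp, de, dc)), False
    if de == 0:  # ICUR undefined at this sweep point
        return math.nan, True
    return dc / de, False


def tornado(
    models: tuple[ArmModel, ArmModel] | list[ArmModel],
    settings: AnalysisSettings,
    metric: Literal["inmb", "icur"] = "inmb",
    wtp: float | None = None,
    probability_range: Literal["full", "fitted95"] = "full",
) -> list[TornadoEntry]:
    """Rank all tree parameters by one-way output spread.

    ``metric`` is the incremental NMB at ``wtp`` (default: the WTP threshold,
    in TWD) or the ICUR.  ``probability_range='fitted95'`` sweeps survive
    probabilities over the fitted Beta central 95% interval instead of their
    printed (full-unit-interval) range.  Entries are sorted by descending
    spread; ties break alphabetically by parameter label.
    """
    if metric not in ("inmb", "icur"):
        raise ValueError(f"unknown metric {metric!r}")
    ref, comp = models
    if wtp is None:
        wtp = settings.wtp_threshold_twd
    base, _ = _metric_value(ref, comp, metric, wtp)

    entries: list[TornadoEntry] = []
    for which, arm in enumerate((ref, comp)):
        for label, path, (lo, hi) in _sweep_targets(arm, probability_range):
            outs = []
            undefined = False
            for endpoint in (lo, hi):
                swept = _with_value(arm, path, endpoint)
                pair = (swept, comp) if which == 0 else (ref, swept)
                val, undef = _metric_value(*pair, metric, wtp)
                outs.append(val)
                undefined |= undef
            spread = 0.0 if undefined else abs(outs[1] - outs[0])
            entries.append(TornadoEntry(label, outs[0], outs[1], spread,
                                        metric, base, undefined=undefined))
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries
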