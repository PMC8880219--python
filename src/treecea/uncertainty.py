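"""Probabilistic sensitivity analysis.

Two sampling routes feed one replicate contract:

* :func:`sample_psa` — parametric PSA: draw every tree parameter from its
  fitted Beta/Gamma distribution (independently, as only marginals are
  specified) and roll the tree back per replicate;
* :func:`bootstrap_patients` — nonparametric bootstrap: resample each arm's
  patient records with replacement at its own size and take arm means.

Both return lists of :class:`PSASample`, so the acceptability curve (CEAC),
the net-monetary-benefit curve and the cost-effectiveness plane summary run
identically on either route.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import AnalysisSettings, ArmModel, as_patient_frame
from .tree_model import expectation_from_values, inmb

__all__ = [
    "PSASample",
    "CEACCurve",
    "NMBCurve",
    "PlaneSummary",
    "sample_psa",
    "bootstrap_patients",
    "patient_qalys",
    "ceac",
    "nmb_curve",
    "plane_summary",
    "deltas",
    "samples_to_frame",
    "frame_to_samples",
]

#: Days per year used to convert patient-level survival to life-years.
DAYS_PER_YEAR = 365.25

_PARAM_ORDER = ("p_survive", "cost_survive", "cost_death", "qaly_survive", "qaly_death")


@dataclass(frozen=True)
class PSASample:
    """One replicate: sampled parameters, per-arm expectations and the increments."""

    replicate: int
    reference: str
    comparator: str
    arm_cost: dict[str, float]
    arm_effect: dict[str, float]
    delta_cost: float
    delta_effect: float
    params: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arm, ps in self.params.items():
            p = ps.get("p_survive")
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"sampled p_survive {p} for {arm} outside [0, 1]")


@dataclass(frozen=True)
class CEACCurve:
    """Probability the reference arm is cost-effective along a WTP grid (TWD/QALY)."""

    wtp_grid: tuple[float, ...]
    prob_acceptable: tuple[float, ...]
    n_replicates: int

    def __post_init__(self) -> None:
        if len(self.wtp_grid) != len(self.prob_acceptable):
            raise ValueError("curve length must equal grid length")
        if any(not (0.0 <= p <= 1.0) for p in self.prob_acceptable):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class NMBCurve:
    """Mean incremental NMB per WTP grid point, with a percentile band."""

    wtp_grid: tuple[float, ...]
    mean_inmb: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    band: tuple[float, float] = (2.5, 97.5)


@dataclass(frozen=True)
class PlaneSummary:
    """Cost-effectiveness plane: mean point and 95% uncertainty region.

    The region is described both as a per-axis percentile box and as the
    normal-approximation ellipse (sample covariance, 95% chi-square radius).
    """

    mean_delta_cost: float
    mean_delta_effect: float
    cost_interval: tuple[float, float]
    effect_interval: tuple[float, float]
    covariance: tuple[tuple[float, float], tuple[float, float]]
    ellipse_chi2: float = 5.991464547107979  # chi2(2).ppf(0.95)

    def __post_init__(self) -> None:
        if not (self.cost_interval[0] <= self.mean_delta_cost <= self.cost_interval[1]):
            raise ValueError("percentile box must contain the mean delta_cost")
        if not (self.effect_interval[0] <= self.mean_delta_effect <= self.effect_interval[1]):
            raise ValueError("percentile box must contain the mean delta_effect")


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One child generator per replicate, so results do not depend on evaluation order."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_psa(models: tuple[ArmModel, ArmModel] | list[ArmModel],
               settings: AnalysisSettings) -> list[PSASample]:
    """Parametric PSA: ``settings.n_replications`` tree rollbacks on sampled parameters.

    Fully reproducible for a fixed ``settings.rng_seed``; raises if any
    non-fixed parameter has not been fitted.
    """
    ref, comp = models
    for arm in (ref, comp):
        for spec_name, spec in _arm_specs(arm):
            if not spec.is_fitted:
                raise ValueError(f"unfitted spec {arm.name}.{spec_name}")

    samples: list[PSASample] = []
    for i, rng in enumerate(_replicate_rngs(settings.rng_seed, settings.n_replications)):
        per_arm: dict[str, dict[str, float]] = {}
        cost: dict[str, float] = {}
        eff: dict[str, float] = {}
        for arm in (ref, comp):
            draws = {name: float(spec.sample(rng)) for name, spec in _arm_specs(arm)}
            c, e = expectation_from_values(
                draws["p_survive"], draws["cost_survive"], draws["cost_death"],
                draws["qaly_survive"], draws["qaly_death"],
            )
            per_arm[arm.name] = draws
            cost[arm.name], eff[arm.name] = float(c), float(e)
        samples.append(PSASample(
            replicate=i, reference=ref.name, comparator=comp.name,
            arm_cost=cost, arm_effect=eff,
            delta_cost=cost[ref.name] - cost[comp.name],
            delta_effect=eff[ref.name] - eff[comp.name],
            params=per_arm,
        ))
    return samples


def _arm_specs(arm: ArmModel):
    surv, dead = arm.branch("survive"), arm.branch("death")
    yield "p_survive", arm.p_survive
    yield "cost_survive", surv.cost
    yield "cost_death", dead.cost
    yield "qaly_survive", surv.qaly
    yield "qaly_death", dead.qaly


def patient_qalys(df: pd.DataFrame) -> pd.Series:
    """Per-patient QALYs: utility times observed survival converted to years."""
    return df["utility"] * df["survival_days"] / DAYS_PER_YEAR


def bootstrap_patients(records, settings: AnalysisSettings,
                       reference: str | None = None,
                       comparator: str | None = None) -> list[PSASample]:
    """Nonparametric bootstrap of incremental cost and effect from patient records.

    Each replicate resamples each arm with replacement at its own size, then
    takes the arm mean of total cost (outpatient + inpatient, TWD) and of
    per-patient QALYs.  Arms default to order of first appearance.
    """
    df = as_patient_frame(records)
    arms = list(dict.fromkeys(df["arm"]))
    if reference is None or comparator is None:
        if len(arms) != 2:
            raise ValueError(f"expected exactly two arms, found {arms}")
        reference, comparator = arms[0], arms[1]

    cost = (df["outpatient_cost"] + df["inpatient_cost"]).to_numpy(float)
    effect = patient_qalys(df).to_numpy(float)
    idx = {a: np.flatnonzero((df["arm"] == a).to_numpy()) for a in (reference, comparator)}
    for a, ix in idx.items():
        if ix.size < 2:
            raise ValueError(f"arm {a!r} has fewer than 2 records")

    samples: list[PSASample] = []
    for i, rng in enumerate(_replicate_rngs(settings.rng_seed, settings.n_replications)):
        mc: dict[str, float] = {}
        me: dict[str, float] = {}
        for a in (reference, comparator):
            take = rng.choice(idx[a], size=idx[a].size, replace=True)
            mc[a] = float(cost[take].mean())
            me[a] = float(effect[take].mean())
        samples.append(PSASample(
            replicate=i, reference=reference, comparator=comparator,
            arm_cost=mc, arm_effect=me,
            delta_cost=mc[reference] - mc[comparator],
            delta_effect=me[reference] - me[comparator],
        ))
    return samples


def deltas(samples: list[PSASample]) -> tuple[np.ndarray, np.ndarray]:
    """(delta_cost, delta_effect) arrays across replicates."""
    if not samples:
        raise ValueError("empty sample list")
    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_effect for s in samples])
    return dc, de


def ceac(samples: list[PSASample], wtp_grid) -> CEACCurve:
    """Cost-effectiveness acceptability curve for the reference arm.

    At each WTP the acceptability is the fraction of replicates whose
    incremental NMB is strictly positive (ties count as not acceptable;
    under continuous sampling they have measure zero).
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    dc, de = deltas(samples)
    probs = tuple(float(np.mean(inmb(w, de, dc) > 0.0)) for w in grid)
    return CEACCurve(tuple(float(w) for w in grid), probs, len(samples))


def nmb_curve(samples: list[PSASample], wtp_grid,
              band: tuple[float, float] = (2.5, 97.5)) -> NMBCurve:
    """Mean incremental NMB along the WTP grid with a replicate percentile band."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    dc, de = deltas(samples)
    values = inmb(grid[:, None], de[None, :], dc[None, :])  # (grid, replicates)
    lo, hi = np.percentile(values, band, axis=1)
    return NMBCurve(
        tuple(float(w) for w in grid),
        tuple(float(v) for v in values.mean(axis=1)),
        tuple(float(v) for v in lo),
        tuple(float(v) for v in hi),
        band=band,
    )


def plane_summary(samples: list[PSASample], min_samples: int = 20) -> PlaneSummary:
    """Mean point and 95% region of the replicate cloud on the CE plane."""
    if len(samples) < min_samples:
        raise ValueError(f"need at least {min_samples} samples for the region estimate")
    dc, de = deltas(samples)
    c_lo, c_hi = np.percentile(dc, [2.5, 97.5])
    e_lo, e_hi = np.percentile(de, [2.5, 97.5])
    cov = np.cov(np.vstack([dc, de]))
    return PlaneSummary(
        mean_delta_cost=float(dc.mean()),
        mean_delta_effect=float(de.mean()),
        cost_interval=(float(c_lo), float(c_hi)),
        effect_interval=(float(e_lo), float(e_hi)),
        covariance=((float(cov[0, 0]), float(cov[0, 1])),
                    (float(cov[1, 0]), float(cov[1, 1]))),
    )


def samples_to_frame(samples: list[PSASample]) -> pd.DataFrame:
    """Flatten replicates to a table (replicate, per-arm cost/effect, deltas)."""
    if not samples:
        raise ValueError("empty sample list")
    ref, comp = samples[0].reference, samples[0].comparator
    rows = [{
        "replicate": s.replicate,
        "reference": ref,
        "comparator": comp,
        f"cost_{ref}": s.arm_cost[ref],
        f"cost_{comp}": s.arm_cost[comp],
        f"effect_{ref}": s.arm_effect[ref],
        f"effect_{comp}": s.arm_effect[comp],
        "delta_cost": s.delta_cost,
        "delta_effect": s.delta_effect,
    } for s in samples]
    return pd.DataFrame(rows)


def frame_to_samples(df: pd.DataFrame) -> list[PSASample]:
    """Rebuild PSASample objects from :func:`samples_to_frame` output."""
    ref, comp = str(df["reference"].iloc[0]), str(df["comparator"].iloc[0])
    return [PSASample(
        replicate=int(r["replicate"]), reference=ref, comparator=comp,
        arm_cost={ref: float(r[f"cost_{ref}"]), comp: float(r[f"cost_{comp}"])},
        arm_effect={ref: float(r[f"effect_{ref}"]), comp: float(r[f"effect_{comp}"])},
        delta_cost=float(r["delta_cost"]), delta_effect=float(r["delta_effect"]),
    ) for _, r in df.iterrows()]
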