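"""Model parameters: domain types, configuration I/O and distribution fitting.

The decision model is parameterised by per-arm branch probabilities (Beta),
branch costs and branch QALYs (Gamma), each given as a central value plus a
plausible range.  This module holds those types, fits the natural parameters
from the summary inputs (effective-sample-size fit for Beta, moment matching
for Gamma), and provides the small cost utilities (annual discounting,
TWD<->USD conversion) the analysis needs.
"""
from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Money",
    "CurrencyError",
    "DistributionSpec",
    "BranchSpec",
    "ArmModel",
    "UtilityLY",
    "AnalysisSettings",
    "PatientRecord",
    "PATIENT_COLUMNS",
    "fit_beta_from_proportion",
    "fit_gamma_moments",
    "sd_from_range",
    "discount",
    "convert_currency",
    "load_parameters",
    "dump_parameters",
    "save_parameters",
    "packaged_config_path",
    "read_patient_records",
    "write_patient_records",
    "as_patient_frame",
]

logger = logging.getLogger(__name__)

CURRENCIES = ("TWD", "USD")

#: Width of a central 95% normal interval in standard-deviation units.
_Z95_WIDTH = 3.92


class CurrencyError(ValueError):
    """Raised when an operation mixes currencies or uses an invalid rate."""


@dataclass(frozen=True)
class Money:
    """An amount of money tagged with its currency and price year.

    Signed amounts are allowed (incremental costs are differences); cost
    *inputs* are validated as non-negative where they are declared.
    """

    amount: float
    currency: str = "TWD"
    price_year: int = 2018

    def __post_init__(self) -> None:
        if self.currency not in CURRENCIES:
            raise CurrencyError(f"unknown currency {self.currency!r}; expected one of {CURRENCIES}")

    def _check_same(self, other: "Money") -> None:
        if self.currency != other.currency:
            raise CurrencyError(f"currency mismatch: {self.currency} vs {other.currency}")

    def __add__(self, other: "Money") -> "Money":
        self._check_same(other)
        return Money(self.amount + other.amount, self.currency, self.price_year)

    def __sub__(self, other: "Money") -> "Money":
        self._check_same(other)
        return Money(self.amount - other.amount, self.currency, self.price_year)

    def __mul__(self, k: float) -> "Money":
        return Money(self.amount * float(k), self.currency, self.price_year)

    __rmul__ = __mul__


@dataclass(frozen=True)
class DistributionSpec:
    """A sampled model parameter: family, central value, plausible range.

    ``fitted_params`` holds the family's natural parameters once fitted:
    (alpha, beta) for Beta, (shape, scale) for Gamma, ignored for ``fixed``.
    """

    family: Literal["beta", "gamma", "fixed"]
    central: float
    range_low: float
    range_high: float
    fitted_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.range_low <= self.central <= self.range_high):
            raise ValueError(
                f"central {self.central} outside plausible range "
                f"[{self.range_low}, {self.range_high}]"
            )
        if self.family == "beta" and not (0.0 <= self.range_low and self.range_high <= 1.0):
            raise ValueError("beta support is [0, 1]; range must lie within it")
        if self.family == "gamma" and self.range_low < 0.0:
            raise ValueError("gamma support is positive; range_low must be >= 0")

    @property
    def is_fitted(self) -> bool:
        return self.family == "fixed" or self.fitted_params is not None

    def mean(self) -> float:
        """Analytic mean of the fitted distribution (central value if fixed)."""
        if self.family == "fixed":
            return self.central
        if self.fitted_params is None:
            raise ValueError("distribution not fitted")
        a, b = self.fitted_params
        if self.family == "beta":
            return a / (a + b)
        return a * b  # gamma: shape * scale

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the fitted distribution (a constant stream if fixed)."""
        if self.family == "fixed":
            return self.central if size is None else np.full(size, self.central)
        if self.fitted_params is None:
            raise ValueError(f"cannot sample unfitted {self.family} spec")
        a, b = self.fitted_params
        if self.family == "beta":
            return rng.beta(a, b, size=size)
        return rng.gamma(shape=a, scale=b, size=size)


@dataclass(frozen=True)
class BranchSpec:
    """Cost and QALY specifications for one decision-tree outcome branch."""

    outcome: Literal["survive", "death"]
    cost: DistributionSpec  # TWD over the analysis horizon
    qaly: DistributionSpec  # quality-adjusted life-years

    def __post_init__(self) -> None:
        if self.cost.central < 0:
            raise ValueError("branch cost central value must be >= 0")
        if self.qaly.central < 0:
            raise ValueError("branch QALY central value must be >= 0")


@dataclass(frozen=True)
class UtilityLY:
    """Reported utility bounds (anchored at 0 = death, 1 = full health) and life-years."""

    utility_low: float
    utility_high: float
    life_years: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.utility_low <= self.utility_high <= 1.0):
            raise ValueError("utilities must satisfy 0 <= low <= high <= 1")
        if self.life_years < 0:
            raise ValueError("life_years must be >= 0")


@dataclass(frozen=True)
class ArmModel:
    """One treatment arm of the decision tree.

    Exactly two branches (survive, death); the death-branch probability is the
    complement of ``p_survive`` so sampled branch probabilities sum to one.
    ``utility_ly`` optionally carries the reported utility bounds and
    life-years used for the QALY band; it is not part of the tree itself.
    """

    name: str
    p_survive: DistributionSpec
    branches: tuple[BranchSpec, BranchSpec]
    n_patients: int
    utility_ly: UtilityLY | None = None
    deaths_full_followup: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_survive.central <= 1.0):
            raise ValueError(f"p_survive.central {self.p_survive.central} outside [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        outcomes = sorted(b.outcome for b in self.branches)
        if outcomes != ["death", "survive"]:
            raise ValueError("an arm needs exactly one 'survive' and one 'death' branch")

    def branch(self, outcome: str) -> BranchSpec:
        for b in self.branches:
            if b.outcome == outcome:
                return b
        raise KeyError(outcome)


@dataclass(frozen=True)
class AnalysisSettings:
    """Analysis-wide settings: WTP threshold and grid, rates, replication count."""

    wtp_threshold: Money  # per QALY
    exchange_rate: float  # TWD per USD
    discount_rate: float = 0.03  # per year
    n_replications: int = 1000
    rng_seed: int = 0
    wtp_grid: tuple[float, ...] = ()  # TWD per QALY, strictly increasing

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ValueError("exchange_rate must be > 0")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValueError("discount_rate must be in [0, 1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        grid = np.asarray(self.wtp_grid, dtype=float)
        if grid.size:
            if np.any(grid < 0):
                raise ValueError("wtp_grid values must be non-negative")
            if np.any(np.diff(grid) <= 0):
                raise ValueError("wtp_grid must be strictly increasing")

    @property
    def wtp_threshold_twd(self) -> float:
        """The WTP threshold expressed in TWD per QALY."""
        m = self.wtp_threshold
        return m.amount if m.currency == "TWD" else m.amount * self.exchange_rate

    def grid_array(self) -> np.ndarray:
        return np.asarray(self.wtp_grid, dtype=float)


# ---------------------------------------------------------------------------
# Distribution fitting from summary inputs
# ---------------------------------------------------------------------------

def fit_beta_from_proportion(p: float, n: int) -> DistributionSpec:
    """Fit a Beta distribution to a proportion via an effective sample size.

    alpha = round(p*n), beta = n - alpha, so the fitted mean is the nearest
    integer event split at the arm's own denominator.  A degenerate fit
    (alpha or beta = 0) is replaced by the +1 smoothed fit
    alpha = p*n + 1, beta = (1-p)*n + 1, with a logged warning.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"proportion {p} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha = round(p * n)
    beta = n - alpha
    if alpha == 0 or beta == 0:
        logger.warning(
            "degenerate beta fit for p=%g, n=%d (alpha=%d, beta=%d); using +1 smoothing",
            p, n, alpha, beta,
        )
        alpha, beta = p * n + 1.0, (1.0 - p) * n + 1.0
    return DistributionSpec("beta", central=p, range_low=0.0, range_high=1.0,
                            fitted_params=(float(alpha), float(beta)))


def fit_gamma_moments(
    mean: float,
    sd: float,
    range_: tuple[float, float] | None = None,
) -> DistributionSpec:
    """Fit a Gamma distribution by moment matching: shape=(mean/sd)^2, scale=sd^2/mean.

    ``range_`` records the plausible range on the spec; when omitted, a
    central 95% normal interval clipped at zero is recorded.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0 for a gamma moment fit")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    if range_ is None:
        range_ = (max(0.0, mean - 1.96 * sd), mean + 1.96 * sd)
    lo = min(range_[0], mean)
    hi = max(range_[1], mean)
    return DistributionSpec("gamma", central=mean, range_low=lo, range_high=hi,
                            fitted_params=(shape, scale))


def sd_from_range(range_low: float, range_high: float) -> float:
    """Standard deviation implied by treating a range as a central 95% interval.

    Returns (range_high - range_low) / 3.92.
    """
    if range_high <= range_low:
        raise ValueError("range_high must exceed range_low")
    return (range_high - range_low) / _Z95_WIDTH


# ---------------------------------------------------------------------------
# Cost adjustment utilities
# ---------------------------------------------------------------------------

def discount(amount: Money | float, years: float, rate: float):
    """Discount an amount back ``years`` years at an annual rate: x / (1+rate)^years."""
    if years < 0:
        raise ValueError("years must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    factor = 1.0 / (1.0 + rate) ** years
    if isinstance(amount, Money):
        return Money(amount.amount * factor, amount.currency, amount.price_year)
    return amount * factor


def convert_currency(amount: Money, exchange_rate: float) -> Money:
    """Flip a Money between TWD and USD at ``exchange_rate`` TWD per USD."""
    if exchange_rate <= 0:
        raise CurrencyError("exchange_rate must be > 0")
    if amount.currency == "TWD":
        return Money(amount.amount / exchange_rate, "USD", amount.price_year)
    return Money(amount.amount * exchange_rate, "TWD", amount.price_year)


# ---------------------------------------------------------------------------
# Configuration schema (pydantic) and loading
# ---------------------------------------------------------------------------

class _DistCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: Literal["beta", "gamma", "fixed"] = "gamma"
    central: float
    range: tuple[float, float] | None = None
    sd: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_range(self) -> "_DistCfg":
        if self.range is not None and self.range[0] > self.range[1]:
            raise ValueError("range must be (low, high) with low <= high")
        if self.family == "gamma" and self.range is not None and self.range[0] < 0:
            raise ValueError("gamma support is positive; range_low must be >= 0")
        return self


class _BranchCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cost: _DistCfg
    qaly: _DistCfg


class _BranchesCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    survive: _BranchCfg
    death: _BranchCfg


class _UtilityCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low: float = Field(ge=0, le=1)
    high: float = Field(ge=0, le=1)


class _ArmCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    n_patients: int = Field(ge=1)
    p_survive: _DistCfg
    branches: _BranchesCfg
    utility: _UtilityCfg | None = None
    life_years: float | None = Field(default=None, ge=0)
    deaths_full_followup: int | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_probability(self) -> "_ArmCfg":
        if not (0.0 <= self.p_survive.central <= 1.0):
            raise ValueError(f"p_survive.central {self.p_survive.central} outside [0, 1]")
        return self


class _MoneyCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    amount: float
    currency: Literal["TWD", "USD"] = "TWD"
    price_year: int = 2018


class _WtpGridCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_multiple: float = Field(default=3.0, gt=0)
    n_points: int = Field(default=41, ge=2)


class _SettingsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wtp_threshold: _MoneyCfg
    exchange_rate: float = Field(gt=0)
    discount_rate: float = Field(default=0.03, ge=0, lt=1)
    n_replications: int = Field(default=1000, ge=1)
    rng_seed: int = 0
    wtp_grid: _WtpGridCfg = _WtpGridCfg()


class _ConfigCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arms: list[_ArmCfg] = Field(min_length=1)
    settings: _SettingsCfg


def _prune_unknown(data, model: type[BaseModel]):
    """Drop keys not declared on ``model`` (recursively) for permissive loading."""
    if not isinstance(data, Mapping):
        return data
    out = {}
    for key, fld in model.model_fields.items():
        if key not in data:
            continue
        val = data[key]
        ann = fld.annotation
        # unwrap Optional[X]
        args = getattr(ann, "__args__", ())
        for cand in (ann, *args):
            if isinstance(cand, type) and issubclass(cand, BaseModel):
                if isinstance(val, Mapping):
                    val = _prune_unknown(val, cand)
                elif isinstance(val, list):
                    val = [_prune_unknown(v, cand) for v in val]
                break
        out[key] = val
    return out


def _fit_spec(cfg: _DistCfg, *, n: int | None = None) -> DistributionSpec:
    """Turn a config distribution entry into a fitted DistributionSpec."""
    rng = cfg.range
    if cfg.family == "beta":
        if n is None:
            raise ValueError("beta fitting needs the arm sample size")
        return fit_beta_from_proportion(cfg.central, n)
    if cfg.family == "gamma":
        if cfg.sd is not None:
            sd = cfg.sd
        elif rng is not None and rng[1] > rng[0]:
            sd = sd_from_range(rng[0], rng[1])
        else:
            raise ValueError(f"gamma parameter {cfg.central}: needs an sd or a non-degenerate range")
        return fit_gamma_moments(cfg.central, sd, range_=rng)
    # fixed
    lo, hi = rng if rng is not None else (cfg.central, cfg.central)
    return DistributionSpec("fixed", central=cfg.central, range_low=lo, range_high=hi)


def _build_arm(cfg: _ArmCfg) -> ArmModel:
    util = None
    if cfg.utility is not None and cfg.life_years is not None:
        util = UtilityLY(cfg.utility.low, cfg.utility.high, cfg.life_years)
    return ArmModel(
        name=cfg.name,
        p_survive=_fit_spec(cfg.p_survive, n=cfg.n_patients),
        branches=(
            BranchSpec("survive", _fit_spec(cfg.branches.survive.cost),
                       _fit_spec(cfg.branches.survive.qaly)),
            BranchSpec("death", _fit_spec(cfg.branches.death.cost),
                       _fit_spec(cfg.branches.death.qaly)),
        ),
        n_patients=cfg.n_patients,
        utility_ly=util,
        deaths_full_followup=cfg.deaths_full_followup,
    )


def load_parameters(
    source: str | Path | Mapping,
    permissive: bool = False,
) -> tuple[list[ArmModel], AnalysisSettings]:
    """Load arm models and analysis settings from a YAML document (or mapping).

    Every DistributionSpec in the result has its natural parameters fitted.
    Unknown keys raise a validation error naming the offending path unless
    ``permissive`` is set, in which case they are dropped.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source, "r") as fh:
            raw = yaml.safe_load(fh)
    if permissive:
        raw = _prune_unknown(raw, _ConfigCfg)
    cfg = _ConfigCfg.model_validate(raw)

    arms = [_build_arm(a) for a in cfg.arms]

    s = cfg.settings
    threshold = Money(s.wtp_threshold.amount, s.wtp_threshold.currency, s.wtp_threshold.price_year)
    threshold_twd = (threshold.amount if threshold.currency == "TWD"
                     else threshold.amount * s.exchange_rate)
    grid = np.linspace(0.0, s.wtp_grid.max_multiple * threshold_twd, s.wtp_grid.n_points)
    settings = AnalysisSettings(
        wtp_threshold=threshold,
        exchange_rate=s.exchange_rate,
        discount_rate=s.discount_rate,
        n_replications=s.n_replications,
        rng_seed=s.rng_seed,
        wtp_grid=tuple(float(x) for x in grid),
    )
    return arms, settings


def _dump_dist(spec: DistributionSpec) -> dict:
    return {
        "family": spec.family,
        "central": spec.central,
        "range": [spec.range_low, spec.range_high],
    }


def dump_parameters(arms: Sequence[ArmModel], settings: AnalysisSettings) -> dict:
    """Serialize arms and settings back to the configuration mapping."""
    out_arms = []
    for arm in arms:
        d: dict = {
            "name": arm.name,
            "n_patients": arm.n_patients,
            "p_survive": _dump_dist(arm.p_survive),
            "branches": {
                b.outcome: {"cost": _dump_dist(b.cost), "qaly": _dump_dist(b.qaly)}
                for b in arm.branches
            },
        }
        if arm.utility_ly is not None:
            d["utility"] = {"low": arm.utility_ly.utility_low,
                            "high": arm.utility_ly.utility_high}
            d["life_years"] = arm.utility_ly.life_years
        if arm.deaths_full_followup is not None:
            d["deaths_full_followup"] = arm.deaths_full_followup
        out_arms.append(d)
    grid = settings.grid_array()
    threshold_twd = settings.wtp_threshold_twd
    return {
        "arms": out_arms,
        "settings": {
            "wtp_threshold": {
                "amount": settings.wtp_threshold.amount,
                "currency": settings.wtp_threshold.currency,
                "price_year": settings.wtp_threshold.price_year,
            },
            "exchange_rate": settings.exchange_rate,
            "discount_rate": settings.discount_rate,
            "n_replications": settings.n_replications,
            "rng_seed": settings.rng_seed,
            "wtp_grid": {
                "max_multiple": float(grid[-1] / threshold_twd) if grid.size else 3.0,
                "n_points": int(grid.size) if grid.size else 41,
            },
        },
    }


def save_parameters(arms: Sequence[ArmModel], settings: AnalysisSettings,
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_parameters(arms, settings), fh, sort_keys=False)


def packaged_config_path(name: str = "table1.yaml") -> Path:
    """Path to a packaged fixture (the default is the published model-input table)."""
    return Path(importlib.resources.files("treecea") / "data" / name)


# ---------------------------------------------------------------------------
# Patient-level records
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = (
    "patient_id", "arm", "death", "survival_days",
    "outpatient_cost", "inpatient_cost", "utility",
)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: arm label, death indicator, survival and 8-month costs (TWD)."""

    patient_id: str
    arm: str
    death: int
    survival_days: float
    outpatient_cost: float
    inpatient_cost: float
    utility: float


def as_patient_frame(records) -> pd.DataFrame:
    """Normalize a list of PatientRecord or a DataFrame to a validated DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")
    _validate_patient_frame(df)
    return df[list(PATIENT_COLUMNS)]


def _validate_patient_frame(df: pd.DataFrame) -> None:
    if not df["death"].isin([0, 1]).all():
        raise ValueError("death indicator must be 0 or 1")
    for col in ("outpatient_cost", "inpatient_cost"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} must be >= 0")
    if ((df["utility"] < 0) | (df["utility"] > 1)).any():
        raise ValueError("utility must lie in [0, 1]")
    if (df["survival_days"] < 0).any():
        raise ValueError("survival_days must be >= 0")


def read_patient_records(path: str | Path, permissive: bool = False) -> pd.DataFrame:
    """Read the delimited patient-record table (costs in TWD).

    Unknown columns are rejected unless ``permissive`` is set (then dropped).
    """
    df = pd.read_csv(path)
    extra = [c for c in df.columns if c not in PATIENT_COLUMNS]
    if extra and not permissive:
        raise ValueError(f"unknown columns in patient table: {extra}")
    return as_patient_frame(df.drop(columns=extra) if extra else df)


def write_patient_records(records, path: str | Path) -> None:
    as_patient_frame(records).to_csv(path, index=False)
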