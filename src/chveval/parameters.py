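"""Model parameters: typed registry, distribution fitting, discounting.

Every quantity used downstream — cost accounts, disability weights, incidence
summaries, transition probabilities, rates and configuration defaults — is
loaded here from a hierarchical YAML file and validated on construction.
Published 95% intervals are interpreted as equal-tailed 2.5th/97.5th
percentiles, with the normal-theory width sd = (upper - lower) / 3.92 when a
standard deviation is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "BetaSummary",
    "LognormalSummary",
    "NormalSummary",
    "DiseaseParams",
    "CostAccount",
    "Constants",
    "SSAScenario",
    "ParameterSet",
    "load_params",
    "default_params_path",
    "fit_beta",
    "fit_lognormal",
    "discount_factor",
]

#: half-width of a 95% normal interval in standard deviations
Z95_RANGE = 3.92


class ParameterError(ValueError):
    """A parameter file is missing a key or violates an invariant."""


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ParameterError(f"missing key '{key}' in {context}")
    return mapping[key]


@dataclass(frozen=True)
class BetaSummary:
    """Mean and 95% interval of a probability, to be fitted as a Beta law."""

    mean: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 < self.lower <= self.mean <= self.upper < 1.0):
            raise ParameterError(
                f"beta summary must satisfy 0 < lower <= mean <= upper < 1, "
                f"got ({self.lower}, {self.mean}, {self.upper})"
            )
        sd = (self.upper - self.lower) / Z95_RANGE
        if sd > 0 and sd * sd >= self.mean * (1.0 - self.mean):
            raise ParameterError(
                f"implied variance {sd * sd:.4g} >= mean(1-mean) "
                f"{self.mean * (1 - self.mean):.4g}; cannot fit a beta"
            )


@dataclass(frozen=True)
class LognormalSummary:
    """Central value and 95% interval of a positive quantity.

    ``central`` is the arithmetic mean or the median depending on the
    convention declared where the summary is fitted.
    """

    central: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 < self.lower <= self.central <= self.upper):
            raise ParameterError(
                f"lognormal summary must satisfy 0 < lower <= central <= upper, "
                f"got ({self.lower}, {self.central}, {self.upper})"
            )


@dataclass(frozen=True)
class NormalSummary:
    mean: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.mean <= self.upper):
            raise ParameterError(
                f"normal summary must satisfy lower <= mean <= upper, "
                f"got ({self.lower}, {self.mean}, {self.upper})"
            )

    @property
    def sd(self) -> float:
        return (self.upper - self.lower) / Z95_RANGE


@dataclass(frozen=True)
class DiseaseParams:
    """Per-disease decision-tree inputs.

    Incidence is episodes per child-year; severity shares route an episode to
    mild/moderate/severe disability weights; the case fatality rate applies
    per episode as an independent branch (a config switch restricts the
    malaria CFR to severe episodes only).
    """

    name: str
    incidence: LognormalSummary
    incidence_convention: Literal["mean", "median"]
    dw_mild: BetaSummary
    dw_moderate: BetaSummary
    dw_severe: BetaSummary
    p_mild: float
    p_moderate: float
    p_severe: float
    cfr: float
    duration_days: float
    coi_nonfatal_usd: float

    def __post_init__(self):
        for label in ("p_mild", "p_moderate", "p_severe", "cfr"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{self.name}: {label}={v} outside [0, 1]")
        if self.duration_days <= 0:
            raise ParameterError(f"{self.name}: duration_days must be positive")

    @property
    def severity_shares(self) -> tuple[float, float, float]:
        return (self.p_mild, self.p_moderate, self.p_severe)


@dataclass(frozen=True)
class CostAccount:
    name: str
    category: Literal["initial", "capital", "recurrent"]
    lifespan_years: int | str  # positive int, or "once" for initial accounts
    total_cost_usd: float
    unit_cost_usd: float | None = None
    unit_cost_ghs: float | None = None

    def __post_init__(self):
        if self.total_cost_usd < 0:
            raise ParameterError(f"cost account '{self.name}': negative total cost")
        once = self.lifespan_years == "once"
        if once != (self.category == "initial"):
            raise ParameterError(
                f"cost account '{self.name}': lifespan 'once' iff category 'initial'"
            )
        if not once and (not isinstance(self.lifespan_years, int) or self.lifespan_years <= 0):
            raise ParameterError(f"cost account '{self.name}': lifespan must be a positive integer")


@dataclass(frozen=True)
class Constants:
    discount_rate: float
    pop_growth: float
    attrition: float
    horizon_years: int
    n_samples: int
    exchange_rate_ghs_per_usd: float
    gdp_per_capita_usd: float
    income_elasticity: float
    u5_population_intervention: float
    gni_per_capita_gh_usd: float
    gni_per_capita_us_usd: float
    vsl_us_usd: float
    avg_age_life_expectancy_years: float
    cho_hours_saved_per_year: float
    cho_hourly_wage_usd: float
    malaria_cfr_severe_only: bool = False
    year_convention: Literal["start", "end"] = "start"
    capital_convention: Literal["repurchase", "annualised"] = "repurchase"
    le_adjustment: Literal["capped_ratio", "ratio", "none"] = "capped_ratio"
    icer_effect_epsilon: float = 1e-8

    def __post_init__(self):
        if not 0.0 <= self.discount_rate < 1.0:
            raise ParameterError("discount_rate must lie in [0, 1)")
        if self.horizon_years < 1:
            raise ParameterError("horizon_years must be >= 1")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")


VSL_RULES = ("gni_x160", "gni_x100", "us_transfer_elasticity")
LE_RULES = ("unadjusted_avg_age", "adjusted_age2")


@dataclass(frozen=True)
class SSAScenario:
    """One cell of the standardised sensitivity analysis grid (3 VSL x 2 LE)."""

    id: str
    vsl_rule: str
    le_rule: str

    def __post_init__(self):
        if self.vsl_rule not in VSL_RULES:
            raise ParameterError(f"{self.id}: unknown vsl_rule '{self.vsl_rule}'")
        if self.le_rule not in LE_RULES:
            raise ParameterError(f"{self.id}: unknown le_rule '{self.le_rule}'")


@dataclass(frozen=True)
class ParameterSet:
    constants: Constants
    diseases: dict[str, DiseaseParams]
    life_expectancy_age2: NormalSummary
    posteriors: dict[str, LognormalSummary]
    cost_accounts: tuple[CostAccount, ...]
    cost_cv: float
    published_components_usd: dict[str, float]
    published_total_usd: float
    scenarios: tuple[SSAScenario, ...]
    ceac_thresholds_gdp_multiples: tuple[float, ...]
    provenance: dict[str, str] = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def scenario(self, sid: str) -> SSAScenario:
        for s in self.scenarios:
            if s.id == sid:
                return s
        raise KeyError(sid)


def default_params_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("chveval") / "data" / "default_params.yaml")


def load_params(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file (packaged defaults if ``path`` is None).

    Missing configuration-only keys fall back to the packaged defaults and are
    flagged ``"default"`` in :attr:`ParameterSet.provenance`; keys present in
    the user file are flagged ``"user"``; printed table values are ``"paper"``.
    """
    with open(default_params_path()) as fh:
        base = yaml.safe_load(fh)
    default_keys = set(base.get("provenance_defaults", []))

    if path is None:
        raw = base
        user_const: dict = {}
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ParameterError(f"parameter file {path} did not parse to a mapping")
        user_const = dict(raw.get("constants", {}))
        # config-only keys may be omitted by user files; table sections may not
        merged_const = {**base["constants"], **user_const}
        missing = set(base["constants"]) - default_keys - set(user_const)
        if missing and "constants" in raw:
            raise ParameterError(f"missing key(s) {sorted(missing)} in constants")
        raw = {**base, **raw, "constants": merged_const}
        for section in ("diseases", "life_expectancy_age2", "posteriors", "costs", "ssa"):
            if section not in raw:
                raise ParameterError(f"missing section '{section}'")

    const_map = raw["constants"]
    known = {f.name for f in Constants.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    constants = Constants(**{k: v for k, v in const_map.items() if k in known})

    provenance: dict[str, str] = {}
    for key in const_map:
        if key in default_keys:
            provenance[key] = "user" if key in user_const else "default"
        else:
            provenance[key] = "paper"

    diseases: dict[str, DiseaseParams] = {}
    for name, d in raw["diseases"].items():
        inc = _require(d, "incidence", f"diseases.{name}")
        diseases[name] = DiseaseParams(
            name=name,
            incidence=LognormalSummary(inc["central"], inc["lower"], inc["upper"]),
            incidence_convention=inc.get("convention", "mean"),
            dw_mild=BetaSummary(**_require(d, "dw_mild", name)),
            dw_moderate=BetaSummary(**_require(d, "dw_moderate", name)),
            dw_severe=BetaSummary(**_require(d, "dw_severe", name)),
            p_mild=_require(d, "p_mild", name),
            p_moderate=_require(d, "p_moderate", name),
            p_severe=_require(d, "p_severe", name),
            cfr=_require(d, "cfr", name),
            duration_days=_require(d, "duration_days", name),
            coi_nonfatal_usd=d.get("coi_nonfatal_usd", 0.0),
        )
        provenance[f"{name}.coi_nonfatal_usd"] = "default"  # supplement-only value

    le = raw["life_expectancy_age2"]
    life_expectancy = NormalSummary(le["mean"], le["lower"], le["upper"])

    posteriors = {
        k: LognormalSummary(v["median"], v["lower"], v["upper"])
        for k, v in raw["posteriors"].items()
    }

    costs = raw["costs"]
    accounts = tuple(CostAccount(**row) for row in costs["accounts"])

    scenarios = tuple(
        SSAScenario(id=sid, vsl_rule=s["vsl_rule"], le_rule=s["le_rule"])
        for sid, s in raw["ssa"].items()
    )
    rules = {(s.vsl_rule, s.le_rule) for s in scenarios}
    if len(scenarios) == 6 and len(rules) != 6:
        raise ParameterError("SSA grid must map the 6 ids onto 6 distinct rule pairs")

    return ParameterSet(
        constants=constants,
        diseases=diseases,
        life_expectancy_age2=life_expectancy,
        posteriors=posteriors,
        cost_accounts=accounts,
        cost_cv=costs.get("cost_cv", 0.25),
        published_components_usd=dict(costs.get("published_components_usd", {})),
        published_total_usd=costs.get("published_total_usd", float("nan")),
        scenarios=scenarios,
        ceac_thresholds_gdp_multiples=tuple(raw.get("ceac_thresholds_gdp_multiples", (0.2, 0.5, 1.0, 2.0, 3.0))),
        provenance=provenance,
        raw=raw,
    )


def fit_beta(summary: BetaSummary) -> tuple[float, float]:
    """Method-of-moments Beta shapes from a mean and 95% interval.

    sd is taken as (upper - lower)/3.92; then with nu = mean(1-mean)/var - 1,
    alpha = mean*nu and beta = (1-mean)*nu. Raises if the implied variance is
    too large for a Beta law with that mean.
    """
    sd = (summary.upper - summary.lower) / Z95_RANGE
    var = sd * sd
    m = summary.mean
    if var <= 0:
        raise ParameterError("degenerate interval: variance is zero")
    if var >= m * (1.0 - m):
        raise ParameterError(f"variance {var:.4g} >= mean(1-mean) {m * (1 - m):.4g}")
    nu = m * (1.0 - m) / var - 1.0
    return m * nu, (1.0 - m) * nu


def fit_lognormal(
    summary: LognormalSummary, convention: Literal["median", "mean"] = "median"
) -> tuple[float, float]:
    """Log-scale (mu, sigma) from a central value and 95% interval.

    sigma = (ln upper - ln lower)/3.92. Under the ``median`` convention
    mu = ln(central); under ``mean``, mu = ln(central) - sigma^2/2 so the
    arithmetic mean of the fitted law equals ``central``. A degenerate
    interval (lower == upper == central) yields sigma = 0, a point mass.
    """
    sigma = (math.log(summary.upper) - math.log(summary.lower)) / Z95_RANGE
    if convention == "median":
        mu = math.log(summary.central)
    elif convention == "mean":
        mu = math.log(summary.central) - 0.5 * sigma * sigma
    else:
        raise ValueError(f"unknown convention '{convention}'")
    return mu, sigma


def discount_factor(t, r: float):
    """Present-value factor (1+r)^-t; cycle t = 0 is undiscounted.

    ``t`` may be a scalar or array of non-negative integers.
    """
    t_arr = np.asarray(t)
    if np.any(t_arr < 0):
        raise ValueError("year index must be non-negative")
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    out = (1.0 + r) ** (-t_arr.astype(float))
    return out if out.ndim else float(out)
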