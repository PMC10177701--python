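"""Monetised benefits: statistical-life value, cost of illness, CHO time.

Health benefits price averted deaths at the value of a statistical life
(VSL) and averted non-fatal episodes at a per-episode cost of illness.
Non-health benefits value the community health officer time the volunteers
free up at the average hourly wage. The standardised sensitivity analysis
crosses three VSL rules (160 x Ghana's GNI per capita, 100 x GNI, and a US
benefit transfer with income elasticity 1.5) with two life-expectancy rules
(unadjusted average-age vs adjusted to a 2-year-old); all six scenarios
share common random numbers so per-draw differences reflect the rules alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effectiveness_model import (
    EpiDraws,
    effective_cfr,
    relative_risk_reduction,
    sample_epi_draws,
)
from .inference import PosteriorDraws
from .parameters import Constants, ParameterSet, SSAScenario, discount_factor

__all__ = [
    "BenefitDraws",
    "vsl_value",
    "life_expectancy_for_scenario",
    "total_discounted_benefit",
    "run_ssa",
]


@dataclass
class BenefitDraws:
    """Per-sample 10-year discounted benefit (2016 US$) for one SSA scenario."""

    scenario: str
    mortality: np.ndarray  # deaths averted x VSL (LE-weighted)
    morbidity: np.ndarray  # non-fatal averted episodes x cost of illness
    cho_time: np.ndarray   # CHO hours saved x hourly wage

    @property
    def total(self) -> np.ndarray:
        return self.mortality + self.morbidity + self.cho_time

    @property
    def S(self) -> int:
        return self.mortality.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.arange(self.S),
                "scenario": self.scenario,
                "benefit_total": self.total,
                "benefit_mortality": self.mortality,
                "benefit_morbidity": self.morbidity,
                "benefit_cho_time": self.cho_time,
            }
        )


def vsl_value(scenario: SSAScenario, constants: Constants) -> float:
    """Value of a statistical life under the scenario's VSL rule (2016 US$)."""
    gni_gh = constants.gni_per_capita_gh_usd
    if scenario.vsl_rule == "gni_x160":
        return 160.0 * gni_gh
    if scenario.vsl_rule == "gni_x100":
        return 100.0 * gni_gh
    if scenario.vsl_rule == "us_transfer_elasticity":
        for key in ("vsl_us_usd", "gni_per_capita_us_usd"):
            if not np.isfinite(getattr(constants, key)) or getattr(constants, key) <= 0:
                raise ValueError(f"missing constant '{key}' for the US transfer rule")
        return constants.vsl_us_usd * (gni_gh / constants.gni_per_capita_us_usd) ** (
            constants.income_elasticity
        )
    raise ValueError(f"unknown VSL rule '{scenario.vsl_rule}'")


def life_expectancy_for_scenario(
    scenario: SSAScenario, params: ParameterSet, epi: EpiDraws | None = None, S: int = 1
) -> np.ndarray:
    """Life-expectancy draws (adjusted rule) or the config constant (unadjusted)."""
    if scenario.le_rule == "adjusted_age2":
        if epi is not None:
            return epi.life_expectancy
        return np.full(S, params.life_expectancy_age2.mean)
    return np.full(S if epi is None else epi.S, params.constants.avg_age_life_expectancy_years)


def _le_weight(le_draws: np.ndarray, constants: Constants) -> np.ndarray:
    """Fraction-of-remaining-life weight applied to the VSL.

    ``capped_ratio`` (default): min(1, L / L_ref) with L_ref the unadjusted
    average-age life expectancy; ``ratio`` leaves the ratio uncapped;
    ``none`` disables the adjustment.
    """
    if constants.le_adjustment == "none":
        return np.ones_like(le_draws)
    ratio = le_draws / constants.avg_age_life_expectancy_years
    if constants.le_adjustment == "ratio":
        return ratio
    return np.minimum(1.0, ratio)


def total_discounted_benefit(
    posterior: PosteriorDraws,
    params: ParameterSet,
    scenario: SSAScenario,
    epi: EpiDraws | None = None,
    seed=0,
    point_estimate: bool = False,
) -> BenefitDraws:
    """10-year discounted benefit draws for one scenario.

    Deaths averted are priced at the scenario VSL times the remaining-life
    weight; non-fatal averted episodes at the per-episode cost of illness;
    CHO time saved at the hourly wage. All streams are discounted with the
    same year factors as the effectiveness model.
    """
    c = params.constants
    if epi is None:
        epi = sample_epi_draws(params, posterior, seed=seed, point_estimate=point_estimate)
    if epi.S != posterior.S:
        raise ValueError(f"epi draws S={epi.S} misaligned with posterior S={posterior.S}")

    t = np.arange(c.horizon_years)
    year_factor = discount_factor(t, c.discount_rate) * (1.0 + c.pop_growth) ** t * (
        1.0 - c.attrition
    ) ** t
    F = float(np.sum(year_factor))

    vsl = vsl_value(scenario, c)
    le = life_expectancy_for_scenario(scenario, params, epi=epi)
    weight = _le_weight(le, c)

    mortality = np.zeros(epi.S)
    morbidity = np.zeros(epi.S)
    for name, dis in params.diseases.items():
        severe_only = c.malaria_cfr_severe_only and name == "malaria"
        cfr = effective_cfr(dis, severe_only)
        cases = (
            c.u5_population_intervention
            * epi.incidence[name]
            * relative_risk_reduction(epi.rr[name])
            * F
        )
        mortality += cases * cfr * vsl * weight
        morbidity += cases * (1.0 - cfr) * dis.coi_nonfatal_usd

    # CHO time accrues with discounting but without the attrition/growth factors
    cho_annual = c.cho_hours_saved_per_year * c.cho_hourly_wage_usd
    cho = float(np.sum(discount_factor(t, c.discount_rate))) * cho_annual
    cho_time = np.full(epi.S, cho)

    return BenefitDraws(
        scenario=scenario.id, mortality=mortality, morbidity=morbidity, cho_time=cho_time
    )


def run_ssa(
    posterior: PosteriorDraws,
    params: ParameterSet,
    epi: EpiDraws | None = None,
    seed=0,
    point_estimate: bool = False,
) -> dict[str, BenefitDraws]:
    """Benefit draws for every SSA scenario under common random numbers."""
    if epi is None:
        epi = sample_epi_draws(params, posterior, seed=seed, point_estimate=point_estimate)
    return {
        s.id: total_discounted_benefit(posterior, params, s, epi=epi)
        for s in params.scenarios
    }
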