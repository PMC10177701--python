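"""Decision-tree effectiveness model: rate-ratio draws to discounted DALYs averted.

A one-year cycle is run over the 10-year horizon. Each cycle, the averted
episode count in the under-5 target population is the product of the
population (growing at 2.2%/year), the incidence draw, the relative risk
reduction draw (1 - RR, which may be negative — harm draws are propagated,
not truncated) and the volunteer attrition decay (1 - 0.083)^t. Averted
episodes convert to DALYs through severity-specific disability weights
(years lived with disability) and the case fatality rate times discounted
remaining life expectancy (years of life lost). No age weighting and no
half-cycle correction are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .parameters import DiseaseParams, ParameterSet, discount_factor, fit_beta, fit_lognormal

__all__ = [
    "EpiDraws",
    "DalyDraws",
    "relative_risk_reduction",
    "averted_cases_year",
    "yll_per_death",
    "daly_per_case",
    "sample_epi_draws",
    "total_dalys_averted",
]

DISEASE_TO_RR = {"diarrhoea": "rr_diarrhoea", "malaria": "rr_fever"}


def relative_risk_reduction(rr):
    """RRR = 1 - RR; negative values (harm) are kept as-is."""
    return 1.0 - np.asarray(rr, dtype=float)


def averted_cases_year(t, u5_pop0, incidence_draw, rrr_draw, growth, attrition):
    """Episodes averted in cycle ``t``: pop growth and attrition compound annually."""
    if u5_pop0 <= 0:
        raise ValueError("target population must be positive")
    return (
        u5_pop0
        * (1.0 + growth) ** t
        * (1.0 - attrition) ** t
        * np.asarray(incidence_draw)
        * np.asarray(rrr_draw)
    )


def yll_per_death(life_expectancy, r, method: str = "continuous"):
    """Discounted years of life lost per death.

    ``continuous``: (1 - e^{-rL})/r (L at r = 0); ``annuity``: sum of
    (1+r)^-t over whole remaining years.
    """
    L = np.asarray(life_expectancy, dtype=float)
    if np.any(L < 0):
        raise ValueError("life expectancy must be non-negative")
    if method == "continuous":
        if r == 0:
            return L if L.ndim else float(L)
        out = (1.0 - np.exp(-r * L)) / r
        return out if out.ndim else float(out)
    if method == "annuity":
        out = np.array([float(np.sum(discount_factor(np.arange(int(round(li))), r))) for li in np.atleast_1d(L)])
        return out if np.asarray(life_expectancy).ndim else float(out[0])
    raise ValueError(f"unknown method '{method}'")


def effective_cfr(disease: DiseaseParams, severe_only: bool = False) -> float:
    """Per-episode death probability; optionally restricted to severe episodes."""
    return disease.cfr * disease.p_severe if severe_only else disease.cfr


def daly_per_case(
    dw_mild, dw_moderate, dw_severe, disease: DiseaseParams, r: float, le_draw,
    severe_only: bool = False,
):
    """(YLD, YLL) per averted episode.

    YLD = sum_s p_s * dw_s * duration/365.25 over mild/moderate/severe;
    YLL = cfr * discounted remaining life expectancy.
    """
    dur_years = disease.duration_days / 365.25
    yld = (
        disease.p_mild * np.asarray(dw_mild)
        + disease.p_moderate * np.asarray(dw_moderate)
        + disease.p_severe * np.asarray(dw_severe)
    ) * dur_years
    yll = effective_cfr(disease, severe_only) * yll_per_death(le_draw, r)
    return yld, yll


@dataclass
class EpiDraws:
    """One aligned draw of every probabilistic epidemiological input.

    Sampling these once and passing them to both the effectiveness and the
    benefit model gives common random numbers across analyses and scenarios.
    """

    rr: dict[str, np.ndarray]          # disease -> rate-ratio draws
    incidence: dict[str, np.ndarray]   # disease -> episodes per child-year
    dw: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # mild, moderate, severe
    life_expectancy: np.ndarray        # years, at age 2

    @property
    def S(self) -> int:
        return self.life_expectancy.size


def sample_epi_draws(
    params: ParameterSet,
    posterior: PosteriorDraws,
    seed=0,
    point_estimate: bool = False,
) -> EpiDraws:
    """Sample incidence, disability-weight and life-expectancy draws aligned to S.

    ``point_estimate`` collapses every distribution (and the rate ratios) to
    its central value, for deterministic decision-tree checks.
    """
    S = posterior.S
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(16))

    rr = {"diarrhoea": posterior.rr_diarrhoea, "malaria": posterior.rr_fever}
    incidence: dict[str, np.ndarray] = {}
    dw: dict[str, tuple] = {}
    le_summary = params.life_expectancy_age2

    if point_estimate:
        rr = {d: np.full(S, float(np.median(v))) for d, v in rr.items()}
        for name, dis in params.diseases.items():
            incidence[name] = np.full(S, dis.incidence.central)
            dw[name] = tuple(
                np.full(S, w.mean) for w in (dis.dw_mild, dis.dw_moderate, dis.dw_severe)
            )
        le = np.full(S, le_summary.mean)
        return EpiDraws(rr=rr, incidence=incidence, dw=dw, life_expectancy=le)

    for name, dis in params.diseases.items():
        mu, sigma = fit_lognormal(dis.incidence, convention=dis.incidence_convention)
        rng = np.random.default_rng(next(streams))
        incidence[name] = rng.lognormal(mu, sigma, S) if sigma > 0 else np.full(S, dis.incidence.central)
        draws = []
        for w in (dis.dw_mild, dis.dw_moderate, dis.dw_severe):
            a, b = fit_beta(w)
            draws.append(np.random.default_rng(next(streams)).beta(a, b, S))
        dw[name] = tuple(draws)
    le = np.random.default_rng(next(streams)).normal(le_summary.mean, le_summary.sd, S)
    le = np.clip(le, 0.0, None)
    return EpiDraws(rr=rr, incidence=incidence, dw=dw, life_expectancy=le)


@dataclass
class DalyDraws:
    """Per-sample 10-year discounted DALYs averted, with component breakdowns."""

    total: np.ndarray
    yld: dict[str, np.ndarray]   # per disease
    yll: dict[str, np.ndarray]
    mean_trajectory: np.ndarray  # mean DALYs averted per cycle (length = horizon)

    @property
    def S(self) -> int:
        return self.total.size

    @property
    def yld_total(self) -> np.ndarray:
        return sum(self.yld.values())

    @property
    def yll_total(self) -> np.ndarray:
        return sum(self.yll.values())

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": np.arange(self.S), "dalys": self.total}
        data["yld"] = self.yld_total
        data["yll"] = self.yll_total
        for d in self.yld:
            data[f"dalys_{d}"] = self.yld[d] + self.yll[d]
        return pd.DataFrame(data)


def total_dalys_averted(
    posterior: PosteriorDraws,
    params: ParameterSet,
    epi: EpiDraws | None = None,
    seed=0,
    point_estimate: bool = False,
) -> DalyDraws:
    """Run the decision tree over the horizon for every draw.

    All probabilistic inputs are paired per sample; a pre-sampled
    :class:`EpiDraws` (aligned to the posterior) may be supplied to share
    draws with the benefit model.
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

    yld: dict[str, np.ndarray] = {}
    yll: dict[str, np.ndarray] = {}
    mean_traj = np.zeros(c.horizon_years)
    for name, dis in params.diseases.items():
        severe_only = c.malaria_cfr_severe_only and name == "malaria"
        rrr = relative_risk_reduction(epi.rr[name])
        cases_base = c.u5_population_intervention * epi.incidence[name] * rrr  # t=0 cases
        yld_pc, yll_pc = daly_per_case(
            *epi.dw[name], dis, c.discount_rate, epi.life_expectancy, severe_only
        )
        yld[name] = F * cases_base * yld_pc
        yll[name] = F * cases_base * yll_pc
        mean_traj += year_factor * float(np.mean(cases_base * (yld_pc + yll_pc)))

    total = sum(yld.values()) + sum(yll.values())
    return DalyDraws(total=total, yld=yld, yll=yll, mean_trajectory=mean_traj)
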