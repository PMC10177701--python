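"""Independent single-file oracle for the decision-tree point-estimate runs.

Deliberately written in plain scalar loops, straight from the model
description, sharing no code with the package: every quantity is recomputed
from the raw parameter values. Used to pin the effectiveness and benefit
models at their central values.
"""

import math


def oracle_dalys_point(params) -> float:
    """Total discounted DALYs averted with every distribution at its central value."""
    c = params.constants
    total = 0.0
    for name, dis in params.diseases.items():
        rr = params.posteriors["diarrhoea" if name == "diarrhoea" else "fever"].central
        rrr = 1.0 - rr
        inc = dis.incidence.central
        dw = [dis.dw_mild.mean, dis.dw_moderate.mean, dis.dw_severe.mean]
        p = [dis.p_mild, dis.p_moderate, dis.p_severe]
        yld_per_case = sum(pi * wi for pi, wi in zip(p, dw)) * dis.duration_days / 365.25
        L = params.life_expectancy_age2.mean
        r = c.discount_rate
        yll_per_death = L if r == 0 else (1.0 - math.exp(-r * L)) / r
        cfr = dis.cfr
        if c.malaria_cfr_severe_only and name == "malaria":
            cfr = dis.cfr * dis.p_severe
        for t in range(c.horizon_years):
            pop = c.u5_population_intervention * (1 + c.pop_growth) ** t * (1 - c.attrition) ** t
            cases = pop * inc * rrr
            dalys = cases * (yld_per_case + cfr * yll_per_death)
            total += dalys / (1 + r) ** t
    return total


def oracle_benefit_point(params, vsl_rule: str, le_rule: str) -> float:
    """Total discounted benefit with every distribution at its central value."""
    c = params.constants
    if vsl_rule == "gni_x160":
        vsl = 160.0 * c.gni_per_capita_gh_usd
    elif vsl_rule == "gni_x100":
        vsl = 100.0 * c.gni_per_capita_gh_usd
    else:
        vsl = c.vsl_us_usd * (c.gni_per_capita_gh_usd / c.gni_per_capita_us_usd) ** c.income_elasticity
    if le_rule == "adjusted_age2":
        le = params.life_expectancy_age2.mean
    else:
        le = c.avg_age_life_expectancy_years
    weight = min(1.0, le / c.avg_age_life_expectancy_years)

    total = 0.0
    for name, dis in params.diseases.items():
        rr = params.posteriors["diarrhoea" if name == "diarrhoea" else "fever"].central
        rrr = 1.0 - rr
        cfr = dis.cfr
        if c.malaria_cfr_severe_only and name == "malaria":
            cfr = dis.cfr * dis.p_severe
        for t in range(c.horizon_years):
            pop = c.u5_population_intervention * (1 + c.pop_growth) ** t * (1 - c.attrition) ** t
            cases = pop * dis.incidence.central * rrr
            benefit = cases * cfr * vsl * weight + cases * (1 - cfr) * dis.coi_nonfatal_usd
            total += benefit / (1 + c.discount_rate) ** t
    for t in range(c.horizon_years):
        total += c.cho_hours_saved_per_year * c.cho_hourly_wage_usd / (1 + c.discount_rate) ** t
    return total
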