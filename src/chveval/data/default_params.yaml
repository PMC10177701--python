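# Default parameter file: economic evaluation of CHV activation in rural Ghana.
# Values marked provenance "paper" are printed in the source tables; values marked
# "default" are configuration defaults for quantities the tables do not print
# (they live in an unpublished costing supplement) and may be overridden.

constants:
  discount_rate: 0.03            # per year
  pop_growth: 0.022              # annual under-5 population growth
  attrition: 0.083               # annual CHV attrition
  horizon_years: 10
  n_samples: 32000
  exchange_rate_ghs_per_usd: 3.91
  gdp_per_capita_usd: 1931       # Ghana, 2016
  income_elasticity: 1.5
  # ---- configuration defaults (not printed in the tables) ----
  u5_population_intervention: 4160   # 24,765 residents x 16.8% under-5, whole 40-community area
  gni_per_capita_gh_usd: 1380        # Ghana GNI per capita, 2016 Atlas method
  gni_per_capita_us_usd: 56810       # US GNI per capita, 2016 Atlas method
  vsl_us_usd: 9400000.0              # US value of statistical life, 2016
  avg_age_life_expectancy_years: 62.7  # Ghana life expectancy, unadjusted reference
  cho_hours_saved_per_year: 0.0      # conservative: no CHO time benefit unless configured
  cho_hourly_wage_usd: 2.0
  malaria_cfr_severe_only: false     # apply malaria CFR to all episodes (independent branch)
  year_convention: start             # cycles t = 0..H-1, t=0 undiscounted
  capital_convention: repurchase     # full repurchase at each lifespan boundary; or "annualised"
  le_adjustment: capped_ratio        # VSL weight min(1, L/L_ref); or "ratio" / "none"
  icer_effect_epsilon: 1.0e-8        # |DALYs| below this excluded from ratio summaries

provenance_defaults:   # keys above that are config defaults rather than printed values
  - u5_population_intervention
  - gni_per_capita_gh_usd
  - gni_per_capita_us_usd
  - vsl_us_usd
  - avg_age_life_expectancy_years
  - cho_hours_saved_per_year
  - cho_hourly_wage_usd
  - malaria_cfr_severe_only
  - year_convention
  - capital_convention
  - le_adjustment
  - icer_effect_epsilon

diseases:
  diarrhoea:
    incidence: {central: 2.055, lower: 1.675, upper: 2.443, convention: mean}  # episodes/child-year
    dw_mild: {mean: 0.074, lower: 0.049, upper: 0.104}
    dw_moderate: {mean: 0.188, lower: 0.125, upper: 0.264}
    dw_severe: {mean: 0.247, lower: 0.164, upper: 0.348}
    p_mild: 0.624
    p_moderate: 0.289
    p_severe: 0.042
    cfr: 0.0005
    duration_days: 4.2
    coi_nonfatal_usd: 7.0          # default (supplement-only); societal cost per non-fatal episode
  malaria:
    incidence: {central: 0.433, lower: 0.264, upper: 0.582, convention: mean}
    dw_mild: {mean: 0.006, lower: 0.002, upper: 0.012}
    dw_moderate: {mean: 0.051, lower: 0.032, upper: 0.074}
    dw_severe: {mean: 0.133, lower: 0.088, upper: 0.190}
    p_mild: 0.500
    p_moderate: 0.300
    p_severe: 0.200
    cfr: 0.024
    duration_days: 7.0
    coi_nonfatal_usd: 25.0         # default (supplement-only)

life_expectancy_age2: {mean: 65.9, lower: 64.5, upper: 67.2}   # Normal, years

# Reconstructed rate-ratio posteriors (median / 95% credible interval as published).
posteriors:
  diarrhoea: {median: 0.862, lower: 0.661, upper: 1.128}
  fever: {median: 0.860, lower: 0.670, upper: 1.107}

costs:
  accounts:
    - {name: CHV recruitment,     category: initial,   lifespan_years: once, unit_cost_usd: 8670,  unit_cost_ghs: 33900,  total_cost_usd: 10102}
    - {name: CHV initial training, category: initial,  lifespan_years: once, unit_cost_usd: 1024,  unit_cost_ghs: 4005,   total_cost_usd: 10524}
    - {name: Equipment,           category: capital,   lifespan_years: 5,    unit_cost_usd: 40000, unit_cost_ghs: 156400, total_cost_usd: 40000}
    - {name: CHV activity kits,   category: capital,   lifespan_years: 2,    unit_cost_usd: 132,   unit_cost_ghs: 518,    total_cost_usd: 10879}
    - {name: CHV consumables,     category: recurrent, lifespan_years: 1,    unit_cost_usd: 10,    unit_cost_ghs: 41,     total_cost_usd: 860}
    - {name: Medical supplies,    category: recurrent, lifespan_years: 1,    unit_cost_usd: 184,   unit_cost_ghs: 720,    total_cost_usd: 15099}
    - {name: Communication,       category: recurrent, lifespan_years: 1,    unit_cost_usd: 46,    unit_cost_ghs: 180,    total_cost_usd: 1872}
    - {name: Motivation,          category: recurrent, lifespan_years: 1,    unit_cost_usd: 1545,  unit_cost_ghs: 6044,   total_cost_usd: 14925}
    - {name: Supervision,         category: recurrent, lifespan_years: 1,    unit_cost_usd: 2635,  unit_cost_ghs: 10305,  total_cost_usd: 18841}
    - {name: Administration,      category: recurrent, lifespan_years: 1,    unit_cost_usd: 1491,  unit_cost_ghs: 5833,   total_cost_usd: 17902}
    - {name: Personnel,           category: recurrent, lifespan_years: 1,    unit_cost_usd: 50837, unit_cost_ghs: 198773, total_cost_usd: 100280}
  cost_cv: 0.25                    # lognormal sd as fraction of mean
  # Published 10-year discounted component totals (the costing supplement carries
  # structure beyond the account table, so the calibrated total drives paper runs).
  published_components_usd: {startup: 21433, capital: 251796, recurrent: 1441448}
  published_total_usd: 1714676

ssa:
  # 3 VSL rules x 2 life-expectancy rules
  SSA1: {vsl_rule: gni_x160, le_rule: unadjusted_avg_age}
  SSA2: {vsl_rule: gni_x160, le_rule: adjusted_age2}
  SSA3: {vsl_rule: gni_x100, le_rule: unadjusted_avg_age}
  SSA4: {vsl_rule: gni_x100, le_rule: adjusted_age2}
  SSA5: {vsl_rule: us_transfer_elasticity, le_rule: unadjusted_avg_age}
  SSA6: {vsl_rule: us_transfer_elasticity, le_rule: adjusted_age2}

ceac_thresholds_gdp_multiples: [0.2, 0.5, 1.0, 2.0, 3.0]
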