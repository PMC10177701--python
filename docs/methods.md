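# Methods

This note documents the models, the parameter conventions, the numerical
choices and the limits of what the test suite demonstrates.

## Statistical model

Episode counts per cluster × wave are modelled as Poisson with a log
child-time offset, an arm effect (the log rate ratio), wave fixed effects
and cluster-level Normal random intercepts. Priors are weakly informative:
Normal(0, 10) on all fixed effects and half-Normal(0, 1) on the
random-intercept standard deviation; both scales are arguments
(`GlmmPriors`). Waves are pooled with a wave fixed effect rather than
modelled with arm-by-wave interactions — an assumption, since the trial's
published analysis does not state how waves entered the model.

Sampling. The joint posterior over (β, σ_u, u₁..u_J) has the usual funnel
geometry at σ_u → 0 and ~46 dimensions, which defeats both ensemble
samplers and plain random-walk Metropolis. Instead the cluster intercepts
are integrated out per cluster with **adaptive Gauss–Hermite quadrature**
(15 nodes; the integrand's mode found by ≤12 clipped Newton steps,
curvature-scaled nodes). The remaining ~5-dimensional marginal posterior is
close to Gaussian; it is sampled by a mixture kernel alternating
multivariate-t independence proposals (df 7, scale 1.3 × the Laplace
covariance at the marginal mode) with preconditioned random-walk proposals
(scale 2.38/√d), across 4 independent chains started overdispersed.
Split-R̂ and ESS of the log rate ratio are computed with arviz and returned
in a diagnostics object; non-convergence warns but still returns draws.
Typical performance: R̂ < 1.01, ESS ≈ 900 from 4,000 draws, ~1 s per
disease on one CPU.

Posterior reconstruction. Where only a published median and 95% credible
interval exist, draws are generated from a lognormal with
σ = (ln upper − ln lower)/3.92 and μ = ln median. Published intervals are
rounded and therefore not exactly log-symmetric, so the reconstruction
reproduces the printed endpoints to ~0.5% rather than exactly. The
diarrhoea and fever draws are reconstructed independently and paired by
index; no joint posterior is published, and the economic model treats them
as independent inputs.

## Synthetic trials

`synthetic_trial` generates two-arm panels with exactly the structure the
GLMM assumes: log-normal cluster frailties, Poisson counts over a per-wave
recall window (default 14 days — the survey's actual recall window is not
published), and a multiplicative treatment effect. Defaults emulate the
study geometry (20 clusters/arm, 3 waves) at roughly one tenth of the field
sample size so that a panel simulates in milliseconds; baseline incidences
(2.055 and 1.9 episodes/child-year) and true rate ratios (0.862, 0.860)
match the evaluation's central inputs. What the generator does **not**
emulate: household-level sampling, panel attrition between waves, child-level
autocorrelation across waves, covariates, and over-dispersion beyond the
cluster frailty. Passing parameter-recovery and coverage tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Cost model

Three categories: initial outlays at t = 0 only; recurrent accounts every
cycle; capital accounts repurchased in full at t = 0, L, 2L, … within the
horizon (no salvage value). An equivalent-annual-cost convention
(`capital_convention: annualised`) is available. Cycles run t = 0..9 with
t = 0 undiscounted, so a start-up cost is never discounted; discounting is
(1+r)^−t at r = 3%/year.

The published 10-year component totals (start-up $21,433, capital $251,796,
recurrent $1,441,448) cannot be reproduced from the published account table
under any single standard discounting convention — the underlying costing
workbook clearly contains structure beyond the table (e.g. scale-up
trajectories and economic time costs). The schedule builder is therefore
validated against its own closed-form invariants (annuity sums, component
additivity, rate monotonicity, linearity), while paper-parameterised runs
use **calibrated-total mode**: the published grand total $1,714,676 as the
lognormal mean with cv = 0.25 (sd = 25% of the mean, moment-matched on the
log scale).

## Effectiveness model

Per cycle and disease: averted episodes = N₀ (1+g)^t (1−a)^t × incidence ×
(1 − RR), with g = 0.022, a = 0.083, and the relative risk reduction
1 − RR carried with its sign — harm draws (RR > 1) contribute negative
DALYs averted, so the left quadrants of the CE plane are populated rather
than truncated. Severity shares route episodes to mild/moderate/severe
disability weights (Beta-distributed, method-of-moments fits with
sd = range/3.92); YLD = Σ p_s·dw_s·duration/365.25. Deaths are an
independent branch at the per-episode case fatality rate;
YLL = cfr × (1 − e^{−rL})/r with L ~ Normal(65.9, sd from the published
bounds). No age weighting, no half-cycle correction (year-start
discounting); the annuity form of the YLL discount is a config switch.

Choices worth flagging:

- The diarrhoea severity shares sum to 0.955, not 1; they are used as
  printed, not renormalised — the remainder is treated as effectively
  asymptomatic.
- The malaria case fatality rate (0.024) applies to all episodes by
  default; `malaria_cfr_severe_only` restricts it to the severe branch.
- The under-5 target population is **not published**. The default, 4,160 ≈
  24,765 residents × 16.8% under-5, covers the whole 40-community study
  area: the phase-in design activates CHVs in the control communities after
  the trial, and the 10-year incremental cost funds the full programme, so
  the population receiving the effect must match the cost's scope. The
  value is config-flagged `default` and overridable.

## Benefit model

Averted deaths are priced at the scenario VSL × a remaining-life weight;
non-fatal averted episodes at a per-episode cost of illness; freed CHO time
at hours × hourly wage (discounted, but not subject to attrition/growth).
The SSA grid crosses VSL rules {160 × GNI_GH, 100 × GNI_GH,
VSL_US × (GNI_GH/GNI_US)^1.5} with life-expectancy rules {unadjusted
average-age, adjusted to age 2}. All scenarios share one set of draws
(common random numbers), so per-draw contrasts are deterministic functions
of the scenario constants.

The life-expectancy "adjustment" is named but never defined in the source;
here it multiplies VSL by min(1, L_scenario/L_ref) with L_ref the
average-age life expectancy (config 62.7 y). Because the age-2 draws
(64.5–67.2 y) exceed L_ref, the cap saturates at 1 under shipped defaults
and adjacent SSA columns coincide; `le_adjustment: ratio` or `none` change
this. Cost-of-illness defaults ($7 diarrhoea, $25 malaria per episode), CHO
time (0 h — conservative), GNI per capita (Ghana $1,380, US $56,810, 2016
Atlas) and the US VSL ($9.4M) are documented configuration defaults for
values that live only in the study's unpublished supplement; they are all
flagged `default` in the parameter provenance and never shadow printed
values.

## Decision analytics

The CEAC uses the net-monetary-benefit rule Pr(λ·E − C > 0), which orders
negative-effect draws correctly where "ICER < λ" would not. ICER summaries
are per-draw cost/effect ratios; draws with |effect| < 10⁻⁸ DALYs are
excluded from ratio summaries and counted. Intervals are equal-tailed 95%
credible intervals. Both the mean and the median ICER are reported: the
mean of a ratio with effect mass near zero is heavy-tailed and unstable,
and the per-draw ratio interval is much wider than a CI constructed from
cost and effect intervals separately. NPVB = B − C and CBR = B/C satisfy
NPVB = (CBR − 1)·C per draw, which is asserted as an invariant.

## Reproducibility and problem sizes

One user seed drives every stage through named `SeedSequence` substreams;
re-running with the same seed reproduces draw-level CSVs bit-identically.
The paper-parameterised run uses the full S = 32,000 draws (~2 s). Test
problem sizes were chosen for tight Monte-Carlo error at interactive
speeds: distribution round-trips use 10⁶ draws; GLMM coverage uses 100
synthetic trials at 8 clusters/arm with 2,000 draws each; unit tests use
reduced draw counts throughout.

## Known limitations

- Reconstructed posteriors are exactly lognormal; the true MCMC posterior
  of the trial may be skewed differently, and the diarrhoea/fever pairing
  ignores any posterior correlation between the two endpoints.
- The cost schedule cannot reproduce the published capital/recurrent
  components from the published account table (see above); calibrated-total
  mode inherits the published total rather than deriving it.
- Cost-benefit headline numbers depend on supplement-only constants (COI,
  CHO time value, GNI/VSL inputs, the life-expectancy adjustment); with the
  documented defaults the cost-effectiveness results reproduce closely while
  cost-benefit levels are approximate.
- No disease transmission dynamics, herd effects, comorbidity adjustment,
  budget-impact or value-of-information analysis.
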