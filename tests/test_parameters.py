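"""Parameter registry: table values, distribution fitting, discounting."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from chveval.parameters import (
    BetaSummary,
    LognormalSummary,
    ParameterError,
    default_params_path,
    discount_factor,
    fit_beta,
    fit_lognormal,
    load_params,
)


class TestPackagedDefaults:
    def test_table_values_match_printed_numbers(self, params):
        d = params.diseases["diarrhoea"]
        m = params.diseases["malaria"]
        assert (d.incidence.central, d.incidence.lower, d.incidence.upper) == (2.055, 1.675, 2.443)
        assert (m.incidence.central, m.incidence.lower, m.incidence.upper) == (0.433, 0.264, 0.582)
        assert d.dw_moderate.mean == 0.188 and d.dw_moderate.lower == 0.125
        assert m.dw_severe.upper == 0.190
        assert d.severity_shares == (0.624, 0.289, 0.042)
        assert m.severity_shares == (0.500, 0.300, 0.200)
        assert d.cfr == 0.0005 and m.cfr == 0.024
        assert d.duration_days == 4.2 and m.duration_days == 7.0
        assert params.life_expectancy_age2.mean == 65.9
        c = params.constants
        assert (c.discount_rate, c.pop_growth, c.attrition) == (0.03, 0.022, 0.083)
        assert (c.horizon_years, c.n_samples) == (10, 32000)
        assert c.exchange_rate_ghs_per_usd == 3.91 and c.gdp_per_capita_usd == 1931

    def test_cost_table_row_sums(self, params):
        by_cat = {}
        for a in params.cost_accounts:
            by_cat.setdefault(a.category, 0.0)
            by_cat[a.category] += a.total_cost_usd
        assert by_cat["initial"] == 10102 + 10524
        assert by_cat["capital"] == 40000 + 10879
        assert by_cat["recurrent"] == 169779  # annual recurrent row sum

    def test_unit_cost_currency_consistency(self, params):
        rate = params.constants.exchange_rate_ghs_per_usd
        for a in params.cost_accounts:
            if a.unit_cost_usd and a.unit_cost_usd > 100:  # small rows round coarsely
                assert a.unit_cost_ghs / a.unit_cost_usd == pytest.approx(rate, rel=0.01)

    def test_posterior_summaries(self, params):
        assert params.posteriors["diarrhoea"].central == 0.862
        assert params.posteriors["fever"].lower == 0.670

    def test_supplement_only_values_flagged_default(self, params):
        for key in ("u5_population_intervention", "cho_hourly_wage_usd", "vsl_us_usd"):
            assert params.provenance[key] == "default"
        assert params.provenance["discount_rate"] == "paper"


class TestLoadValidation:
    def test_probability_out_of_bounds_names_row(self, tmp_path):
        raw = yaml.safe_load(open(default_params_path()))
        raw["diseases"]["diarrhoea"]["p_severe"] = 1.3
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ParameterError, match="p_severe"):
            load_params(bad)

    def test_missing_required_constant_named(self, tmp_path):
        raw = yaml.safe_load(open(default_params_path()))
        del raw["constants"]["attrition"]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ParameterError, match="attrition"):
            load_params(bad)

    def test_omitted_config_default_flagged_and_overridable(self, tmp_path):
        raw = yaml.safe_load(open(default_params_path()))
        del raw["constants"]["cho_hourly_wage_usd"]
        raw["constants"]["u5_population_intervention"] = 1000
        f = tmp_path / "p.yaml"
        f.write_text(yaml.safe_dump(raw))
        p = load_params(f)
        assert p.provenance["cho_hourly_wage_usd"] == "default"
        assert p.constants.cho_hourly_wage_usd == 2.0  # packaged default applied
        assert p.provenance["u5_population_intervention"] == "user"
        assert p.constants.u5_population_intervention == 1000


class TestFitBeta:
    def test_symmetric_summary_gives_equal_shapes(self):
        a, b = fit_beta(BetaSummary(0.5, 0.4, 0.6))
        assert a == pytest.approx(b)

    def test_moderate_disability_weight_shapes(self):
        # frozen from the method-of-moments closed form with sd = (0.264-0.125)/3.92
        a, b = fit_beta(BetaSummary(0.188, 0.125, 0.264))
        assert a == pytest.approx(22.637, rel=1e-3)
        assert b == pytest.approx(97.773, rel=1e-3)

    def test_overdispersed_summary_rejected(self):
        with pytest.raises(ParameterError):
            BetaSummary(0.01, 0.005, 0.9)  # implied var >= mean(1-mean)
        with pytest.raises(ParameterError):
            BetaSummary(0.5, 0.0, 1.0)  # degenerate bounds

    def test_sampled_mean_round_trip(self, rng):
        summary = BetaSummary(0.188, 0.125, 0.264)
        a, b = fit_beta(summary)
        draws = rng.beta(a, b, 1_000_000)
        mc_se = draws.std() / 1000.0
        assert abs(draws.mean() - summary.mean) < 3 * mc_se


class TestFitLognormal:
    def test_degenerate_interval_point_mass(self):
        mu, sigma = fit_lognormal(LognormalSummary(1.0, 1.0, 1.0), "median")
        assert (mu, sigma) == (0.0, 0.0)

    def test_median_convention_matches_quantile_matching(self):
        mu, sigma = fit_lognormal(LognormalSummary(0.862, 0.661, 1.128), "median")
        assert mu == pytest.approx(-0.14850, abs=1e-4)
        assert sigma == pytest.approx(0.13634, abs=1e-4)

    def test_mean_convention_matches_quantile_matching(self):
        mu, sigma = fit_lognormal(LognormalSummary(2.055, 1.675, 2.443), "mean")
        assert sigma == pytest.approx(0.09628, abs=1e-4)
        assert mu == pytest.approx(0.71564, abs=1e-4)
        # arithmetic mean of the fitted law reproduces the central value
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(2.055, rel=1e-12)

    def test_sampled_percentiles_round_trip_median_convention(self, rng):
        # log-symmetric interval: quantile matching is exact, so the sampled
        # percentiles must agree to Monte-Carlo error
        s = LognormalSummary(0.862, 0.862 * math.exp(-0.267), 0.862 * math.exp(0.267))
        mu, sigma = fit_lognormal(s, "median")
        draws = rng.lognormal(mu, sigma, 1_000_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        # 3 MC standard errors of an empirical quantile
        for got, want, q in ((lo, s.lower, 0.025), (hi, s.upper, 0.975)):
            dens = np.exp(-0.5 * ((np.log(got) - mu) / sigma) ** 2) / (
                got * sigma * np.sqrt(2 * np.pi)
            )
            se = np.sqrt(q * (1 - q) / 1_000_000) / dens
            assert abs(got - want) < 3 * se

    def test_sampled_mean_round_trip_mean_convention(self, rng):
        # the mean convention preserves the arithmetic mean and the interval
        # ratio; the individual percentiles shift by exp(-sigma^2/2)
        s = LognormalSummary(2.055, 1.675, 2.443)
        mu, sigma = fit_lognormal(s, "mean")
        draws = rng.lognormal(mu, sigma, 1_000_000)
        mc_se = draws.std() / 1000.0
        assert abs(draws.mean() - s.central) < 3 * mc_se
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert hi / lo == pytest.approx(s.upper / s.lower, rel=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            LognormalSummary(0.0, 0.0, 1.0)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "t,r,expected",
        [(0, 0.03, 1.0), (1, 0.03, 1 / 1.03), (5, 0.0, 1.0)],
    )
    def test_closed_form(self, t, r, expected):
        assert discount_factor(t, r) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_for_positive_rate(self):
        f = discount_factor(np.arange(20), 0.03)
        assert np.all(np.diff(f) < 0)
        assert np.all(discount_factor(np.arange(20), 0.0) == 1.0)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


@settings(max_examples=200, derandomize=True)
@given(
    median=st.floats(0.05, 20.0),
    half_width=st.floats(0.0, 1.5),
    t=st.integers(0, 50),
    r=st.floats(0.0, 0.2),
)
def test_fitting_and_discounting_properties(median, half_width, t, r):
    """Quantile matching inverts exactly; discounting is bounded and monotone."""
    s = LognormalSummary(median, median * math.exp(-half_width), median * math.exp(half_width))
    mu, sigma = fit_lognormal(s, "median")
    assert math.exp(mu) == pytest.approx(median, rel=1e-12)
    assert sigma == pytest.approx(2 * half_width / 3.92, rel=1e-9, abs=1e-12)
    # mean convention never increases the log-location
    mu_mean, _ = fit_lognormal(s, "mean")
    assert mu_mean <= mu + 1e-15
    f = discount_factor(t, r)
    assert 0 < f <= 1.0
    assert discount_factor(t + 1, r) <= f
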