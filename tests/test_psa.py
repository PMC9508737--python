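"""Moment matching, sampling, Monte Carlo machinery and summaries."""

import numpy as np
import pytest
from scipy import stats

from artcea import (
    DistributionSpec,
    ValidationError,
    ce_plane,
    ceac_table,
    default_distributions,
    evaluate_strategy,
    moment_match,
    percentile_ci,
    prob_cost_effective,
    run_psa,
    sample_inputs,
)
from artcea.psa import PSAResult


# --- moment matching -------------------------------------------------------

def test_gamma_moment_match_closed_form():
    shape, scale = moment_match("gamma", 100.0, 0.1)
    assert (shape, scale) == pytest.approx((100.0, 1.0))


def test_beta_moment_match_symmetric_case():
    a, b = moment_match("beta", 0.5, 0.1)
    assert (a, b) == pytest.approx((49.5, 49.5))


@pytest.mark.parametrize(
    "family, mean, cv",
    [("beta", 0.325, 0.1), ("beta", 0.93, 0.05), ("gamma", 11720.0, 0.1)],
)
def test_matched_distribution_reproduces_first_two_moments(family, mean, cv):
    a, b = moment_match(family, mean, cv)
    dist = stats.beta(a, b) if family == "beta" else stats.gamma(a, scale=b)
    assert dist.mean() == pytest.approx(mean, abs=1e-10)
    assert dist.std() == pytest.approx(cv * mean, abs=1e-10)


def test_infeasible_beta_variance_raises():
    with pytest.raises(ValidationError, match="infeasible"):
        moment_match("beta", 0.9, 1.0)  # v = 0.81 >= m(1-m) = 0.09


@pytest.mark.parametrize(
    "family, mean, cv", [("beta", 1.2, 0.1), ("gamma", -1.0, 0.1), ("beta", 0.5, 0.0)]
)
def test_moment_match_domain_errors(family, mean, cv):
    with pytest.raises(ValidationError):
        moment_match(family, mean, cv)


# --- sampling --------------------------------------------------------------

def test_default_distributions_cover_all_probabilities_and_costs(fixture_inputs):
    dists = default_distributions(fixture_inputs)
    families = {d.target: d.family for d in dists}
    assert families["rates.standard.35"] == "beta"
    assert families["procedures.opu_rate.35-39"] == "beta"
    assert families["costs.complete_donor_cycle.out_of_pocket"] == "gamma"
    # zero-valued components (no public rebate) carry no distribution
    assert "costs.pgta.medicare_rebate" not in families
    n_rates = sum(len(s.entries) for s in fixture_inputs.rates.values())
    n_costs = sum(
        (c.medicare_rebate > 0) + (c.out_of_pocket > 0)
        for c in fixture_inputs.costs.values()
    )
    assert len(dists) == n_rates + 6 + n_costs


def test_vanishing_cv_recovers_point_estimates(fixture_inputs, rng):
    inputs = fixture_inputs.with_settings(probability_cv=1e-8, cost_cv=1e-8)
    draw = sample_inputs(inputs, rng)
    assert draw.rates["standard"][35] == pytest.approx(0.325, abs=1e-4)
    assert draw.costs["pgta"].out_of_pocket == pytest.approx(1813, rel=1e-4)


def test_sampling_is_deterministic_per_seed(fixture_inputs):
    d1 = sample_inputs(fixture_inputs, np.random.default_rng(42))
    d2 = sample_inputs(fixture_inputs, np.random.default_rng(42))
    assert d1 == d2


def test_untargeted_parameters_left_at_point_estimates(fixture_inputs, rng):
    only = [DistributionSpec("rates.standard.35", "beta", 0.325, 0.1)]
    draw = sample_inputs(fixture_inputs, rng, only)
    assert draw.rates["standard"][35] != 0.325
    assert draw.rates["standard"][36] == 0.286
    assert draw.costs == fixture_inputs.costs


def test_sample_mean_matches_target_within_clt_bound(rng):
    d = DistributionSpec("rates.standard.35", "beta", 0.325, 0.1)
    x = d.draw(rng, 10_000)
    se = x.std(ddof=1) / np.sqrt(x.size)
    assert abs(x.mean() - 0.325) <= 3 * se


# --- percentiles -----------------------------------------------------------

def test_percentile_ci_conventions():
    assert percentile_ci([7.0] * 10) == (7.0, 7.0)
    lo, hi = percentile_ci(np.arange(1, 1001, dtype=float))
    assert (lo, hi) == pytest.approx((25.975, 975.025))
    with pytest.raises(ValidationError):
        percentile_ci([])


def test_interval_may_straddle_zero():
    lo, hi = percentile_ci([-133_529.0, -50.0, 40.0, 124_370.0], 2.5, 97.5)
    assert lo < 0 < hi


# --- replicate machinery ---------------------------------------------------

def make_result(d_effects, d_costs, age=45, alt="pgta"):
    """PSAResult with a fixed standard cell and prescribed increments."""
    n = len(d_effects)
    base_e, base_c = 0.1, 10_000.0
    effect = {
        ("standard", age): np.full(n, base_e),
        (alt, age): base_e + np.asarray(d_effects, dtype=float),
    }
    cost = {
        ("standard", age): np.full(n, base_c),
        (alt, age): base_c + np.asarray(d_costs, dtype=float),
    }
    return PSAResult((age,), n, 0, effect, cost, cost)


def test_single_replicate_with_tiny_cv_equals_deterministic(fixture_inputs):
    inputs = fixture_inputs.with_settings(probability_cv=1e-8, cost_cv=1e-8)
    res = run_psa(inputs, ages=[40], n_replicates=1, seed=3)
    det = evaluate_strategy("social_freezing", 40, fixture_inputs)
    assert res.effect[("social_freezing", 40)][0] == pytest.approx(det.clbr, abs=1e-6)
    assert res.cost_societal[("social_freezing", 40)][0] == pytest.approx(
        det.cost_societal, rel=1e-6
    )


def test_identical_seeds_give_identical_results(fixture_inputs):
    a = run_psa(fixture_inputs, ages=[40], n_replicates=50, seed=11)
    b = run_psa(fixture_inputs, ages=[40], n_replicates=50, seed=11)
    for key in a.effect:
        assert np.array_equal(a.effect[key], b.effect[key])
        assert np.array_equal(a.cost_societal[key], b.cost_societal[key])


def test_ce_plane_rows_and_orientation():
    res = make_result([0.05, 0.02, -0.01], [-100.0, 50.0, 20.0])
    plane = ce_plane(res, 45, "pgta")
    assert len(plane) == 3
    assert list(plane.columns) == ["replicate", "delta_effect", "delta_cost"]
    dominant = plane[(plane.delta_effect > 0) & (plane.delta_cost < 0)]
    assert len(dominant) == 1
    with pytest.raises(ValidationError):
        ce_plane(res, 45, "standard")


def test_social_freezing_mass_lies_in_effective_half_plane(fixture_inputs):
    """Sampled uncertainty does not overturn the large effect advantage
    of banked oocytes over autologous cycles at 45."""
    res = run_psa(fixture_inputs, ages=[45], n_replicates=300, seed=5)
    plane = ce_plane(res, 45, "social_freezing")
    assert (plane.delta_effect > 0).mean() > 0.5


def test_net_monetary_benefit_rule():
    res = make_result([0.1, 0.1], [1_000.0, 10_000.0])
    # NMB = 50,000 x 0.1 - dC: positive for the 1,000 draw only
    assert prob_cost_effective(res, 50_000).probability_cost_effective.item() == 0.5
    assert prob_cost_effective(res, 200_000).probability_cost_effective.item() == 1.0
    cost_increasing = make_result([0.1, 0.2], [500.0, 700.0])
    assert prob_cost_effective(cost_increasing, 0).probability_cost_effective.item() == 0.0
    dominant = make_result([0.1, 0.2], [-500.0, -700.0])
    for wtp in (0, 50_000, 1e9):
        assert prob_cost_effective(dominant, wtp).probability_cost_effective.item() == 1.0
    with pytest.raises(ValidationError):
        prob_cost_effective(res, -1.0)


def test_ceac_is_monotone_when_all_effect_draws_positive(rng):
    d_e = rng.uniform(0.01, 0.2, 200)
    d_c = rng.normal(2_000, 3_000, 200)
    res = make_result(d_e, d_c)
    grid = [0, 5_000, 20_000, 50_000, 100_000, 500_000]
    curve = ceac_table(res, grid).probability_cost_effective.to_numpy()
    assert (np.diff(curve) >= 0).all()


def test_summary_reports_both_icer_modes(fixture_inputs):
    res = run_psa(fixture_inputs, ages=[44], n_replicates=200, seed=9)
    s = res.summary().set_index("alternative")
    row = s.loc["donor"]
    assert row.ratio_ci_low <= row.mean_ratio <= row.ratio_ci_high
    assert row.mean_delta_effect > 0
    # social freezing saves money in most draws at 44
    assert s.loc["social_freezing"].frac_dominant > 0.5
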