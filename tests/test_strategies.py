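"""Strategy construction and the cohort engine vs its oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from artcea import (
    ValidationError,
    build_strategy,
    clbr,
    enumerate_pathways,
    run_cohort,
)
from artcea.strategies import AttemptStage, StrategySpec
from artcea.synthetic import random_toy_spec

from conftest import fixture_strategy_cells

probs = st.floats(0.0, 1.0)


def toy_spec(p_opu, p_lb, cont_fail, cont_cancel, n_stages=2):
    stages = tuple(
        AttemptStage(
            index=i,
            kind="fresh_autologous",
            p_reach_opu=p_opu,
            p_live_birth_given_opu=p_lb,
            p_continue_after_failure=cont_fail,
            p_continue_after_cancellation=cont_cancel,
            cost_items_on_attempt=("complete_fresh_fet_autologous",),
            cost_items_on_cancellation=("cancelled_cycle",),
        )
        for i in range(n_stages)
    )
    return StrategySpec("standard", 35, stages)


# --- construction ----------------------------------------------------------

def test_standard_stage_parameters_at_35(fixture_inputs):
    spec = build_strategy("standard", 35, fixture_inputs)
    assert spec.n_stages == 2
    s1 = spec.stages[0]
    assert s1.p_live_birth_given_opu == 0.325
    assert s1.p_reach_opu == 0.93
    assert s1.p_continue_after_failure == 0.765
    assert s1.p_continue_after_cancellation == 0.765


def test_pgta_second_cycle_carries_reduction(fixture_inputs):
    spec = build_strategy("pgta", 40, fixture_inputs)
    assert spec.stages[0].p_live_birth_given_opu == 0.153
    assert spec.stages[1].p_live_birth_given_opu == pytest.approx(0.1377)
    assert "pgta" in spec.stages[0].cost_items_on_attempt


def test_social_freezing_upfront_storage_years(fixture_inputs):
    spec = build_strategy("social_freezing", 43, fixture_inputs)
    upfront = dict(spec.upfront_cost_items)
    assert upfront["oocyte_storage_per_year"] == 11  # 43 - freeze age 32
    assert upfront["social_freezing_banking"] == 1
    # backed-out per-transfer rate reproduces the cumulative published rate
    p = spec.stages[0].p_live_birth_given_opu
    assert 1 - (1 - p) ** 2 == pytest.approx(0.313, abs=1e-12)


def test_donor_pathway_shape(fixture_inputs):
    spec = build_strategy("donor", 38, fixture_inputs)
    kinds = [s.kind for s in spec.stages]
    assert kinds == ["fresh_autologous", "fresh_autologous", "donor_fet", "donor_fet"]
    assert spec.stages[2].p_reach_opu == 1.0  # recipients undergo transfer only
    assert spec.stages[0].p_live_birth_given_opu == 0.213  # autologous schedule


@pytest.mark.parametrize(
    "name, age",
    [("social_freezing", 39), ("standard", 34), ("standard", 46), ("nonsense", 40)],
)
def test_invalid_strategy_requests_raise(fixture_inputs, name, age):
    with pytest.raises(ValidationError):
        build_strategy(name, age, fixture_inputs)


# --- engine vs hand-derived results ---------------------------------------

def test_single_bernoulli_stage_pathways():
    spec = toy_spec(1.0, 0.3, 0.0, 0.0, n_stages=1)
    paths = {r.outcomes[-1]: r.probability for r in enumerate_pathways(spec)}
    assert paths == {"live_birth": pytest.approx(0.3), "end": pytest.approx(0.7)}


def test_two_stage_toy_matches_hand_recursion():
    """Engine, enumeration and an explicit hand recursion all agree."""
    p_opu, p_lb, cf, cc = 0.9, 0.5, 0.8, 0.5
    spec = toy_spec(p_opu, p_lb, cf, cc)

    # hand recursion, written independently of the engine:
    q = 1 - p_opu
    opu_per_entry = p_opu + q * cc * p_opu        # first attempt + one retry
    lb_per_entry = opu_per_entry * p_lb
    fail_per_entry = opu_per_entry * (1 - p_lb)
    hand = lb_per_entry + fail_per_entry * cf * lb_per_entry

    assert clbr(spec) == pytest.approx(hand, abs=1e-12)
    enum = sum(r.probability for r in enumerate_pathways(spec) if r.live_birth)
    assert enum == pytest.approx(hand, abs=1e-12)


def test_pathway_probabilities_sum_to_one(fixture_inputs):
    for name, age in fixture_strategy_cells():
        spec = build_strategy(name, age, fixture_inputs)
        total = math.fsum(r.probability for r in enumerate_pathways(spec))
        assert total == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("name, age", fixture_strategy_cells())
def test_recursion_matches_enumeration_on_fixture(fixture_inputs, name, age):
    """CLBR and expected item counts agree between the two computations."""
    spec = build_strategy(name, age, fixture_inputs)
    trace = run_cohort(spec)
    records = enumerate_pathways(spec)
    enum_clbr = math.fsum(r.probability for r in records if r.live_birth)
    assert trace.clbr == pytest.approx(enum_clbr, abs=1e-12)
    enum_items: dict[str, float] = {}
    for r in records:
        for item, count in r.accrued_cost_items:
            enum_items[item] = enum_items.get(item, 0.0) + r.probability * count
    for item in set(enum_items) | set(trace.expected_item_counts):
        assert trace.expected_item_counts[item] == pytest.approx(
            enum_items.get(item, 0.0), abs=1e-10
        )


def test_absorbing_live_birth_blocks_stage_two():
    spec = toy_spec(1.0, 1.0, 1.0, 1.0)
    trace = run_cohort(spec)
    assert trace.clbr == 1.0
    assert trace.stages[1].entered == 0.0


def test_zero_rates_give_zero_clbr():
    assert clbr(toy_spec(0.9, 0.0, 0.8, 0.5)) == 0.0


def test_no_return_means_no_live_births(fixture_inputs):
    inputs = fixture_inputs.with_settings(return_rate=0.0)
    spec = build_strategy("social_freezing", 42, inputs)
    assert clbr(spec) == 0.0
    # banking costs are sunk regardless of return
    assert dict(spec.upfront_cost_items)["social_freezing_banking"] == 1


def test_fixture_standard_clbr_monotone_in_age(fixture_inputs):
    values = [clbr(build_strategy("standard", a, fixture_inputs)) for a in range(35, 46)]
    assert (np.diff(values) <= 0).all()


def test_clbr_bounded_by_unlimited_attempts(fixture_inputs):
    """Continuation and cancellation can only lose attempts, never add."""
    for name, age in fixture_strategy_cells():
        spec = build_strategy(name, age, fixture_inputs)
        cap = 1.0 - math.prod(1 - s.p_live_birth_given_opu for s in spec.stages)
        assert clbr(spec) <= cap + 1e-12


# --- property tests over random strategies ---------------------------------

@hyp_settings(max_examples=100, deadline=None, derandomize=True)
@given(
    p_opu=probs, p_lb=probs, cf=probs, cc=probs,
    n_stages=st.integers(1, 4),
    entry=st.floats(0.0, 1.0),
)
def test_mass_conservation_and_oracle_equivalence(p_opu, p_lb, cf, cc, n_stages, entry):
    spec = StrategySpec(
        "standard", 35,
        toy_spec(p_opu, p_lb, cf, cc, n_stages).stages,
        entry_probability=entry,
    )
    trace = run_cohort(spec)
    for stage in trace.stages:
        outflow = (
            stage.live_birth
            + stage.end_after_cancellation
            + stage.end_after_failure
            + stage.continued
        )
        assert outflow == pytest.approx(stage.entered, abs=1e-12)
    assert all(b >= a - 1e-15 for a, b in zip(trace.cumulative_live_birth,
                                              trace.cumulative_live_birth[1:]))
    enum_clbr = math.fsum(r.probability for r in enumerate_pathways(spec) if r.live_birth)
    assert trace.clbr == pytest.approx(enum_clbr, abs=1e-12)


def test_random_multi_stage_specs_agree_with_enumeration(rng):
    for _ in range(50):
        spec = random_toy_spec(rng)
        trace = run_cohort(spec)
        records = enumerate_pathways(spec)
        assert trace.clbr == pytest.approx(
            math.fsum(r.probability for r in records if r.live_birth), abs=1e-10
        )
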