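"""Synthetic but structurally valid model inputs and analytic toys.

Two purposes:

* :func:`generate_inputs` draws a random, internally consistent
  parameter set with the same shape as the published one — per-age
  success probabilities that decline with age (logistic in age, i.e.
  a constant multiplicative decline in the odds per year), two-payer
  cost items, banded procedure probabilities — so every part of the
  pipeline can be exercised, property-tested and benchmarked without
  the built-in estimates.
* :func:`closed_form_toy` builds a small n-stage strategy whose CLBR
  and expected cost are written out analytically (geometric-series
  algebra, independent of the engine) for use as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .parameters import (
    STRATEGIES,
    AgeRateSchedule,
    CostItem,
    GlobalSettings,
    ModelInputs,
    ProcedureProbabilities,
    ValidationError,
)
from .strategies import AttemptStage, StrategySpec

__all__ = ["ScenarioConfig", "generate_inputs", "closed_form_toy", "random_toy_spec"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs for the random scenario generator.

    ``rate_decline`` is the multiplicative decline in the *odds* of a
    live birth per year of age (1.0 gives a flat schedule);
    ``base_rates`` are the per-strategy success probabilities at the
    youngest modelled age; ``cost_scale`` sets the typical magnitude of
    a cost item.
    """

    seed: int = 0
    rate_decline: float = 0.85
    base_rates: dict[str, float] | None = None
    cost_scale: float = 10_000.0
    probability_cv: float = 0.10
    cost_cv: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.rate_decline <= 1.0:
            raise ValidationError("rate_decline must lie in (0, 1]")
        if self.cost_scale <= 0:
            raise ValidationError("cost_scale must be > 0")


_DEFAULT_BASE_RATES = {
    "standard": 0.33,
    "pgta": 0.34,
    "social_freezing": 0.35,
    "donor": 0.38,
}

_AGE_SPANS = {
    "standard": range(35, 46),
    "pgta": range(35, 46),
    "social_freezing": range(40, 46),
    "donor": range(35, 46),
}


def _declining_schedule(name: str, base: float, decline: float) -> AgeRateSchedule:
    ages = _AGE_SPANS[name]
    base_odds = base / (1.0 - base)
    entries = {}
    for age in ages:
        odds = base_odds * decline ** (age - 35)
        entries[age] = odds / (1.0 + odds)
    return AgeRateSchedule(name, entries)


def generate_inputs(config: ScenarioConfig) -> ModelInputs:
    """Draw a random valid :class:`ModelInputs`; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    base = dict(_DEFAULT_BASE_RATES)
    if config.base_rates:
        base.update(config.base_rates)
    # jitter base rates, keeping them comfortably inside (0, 1)
    rates = {}
    for name in STRATEGIES:
        b = float(np.clip(base[name] * rng.uniform(0.7, 1.3), 0.02, 0.95))
        rates[name] = _declining_schedule(name, b, config.rate_decline)

    procedures = ProcedureProbabilities(
        opu_rate_by_ageband={
            (35, 39): float(rng.uniform(0.85, 0.98)),
            (40, 44): float(rng.uniform(0.80, 0.95)),
            (45, 45): float(rng.uniform(0.75, 0.92)),
        },
        progression_by_ageband={
            (35, 39): float(rng.uniform(0.6, 0.9)),
            (40, 44): float(rng.uniform(0.55, 0.85)),
            (45, 45): float(rng.uniform(0.55, 0.85)),
        },
    )

    costs = {}
    for name in (
        "cancelled_cycle",
        "complete_fresh_fet_autologous",
        "fet_cycle",
        "pgta",
        "complete_donor_cycle",
        "oocyte_storage_per_year",
        "social_freezing_banking",
        "social_freezing_thaw_total",
    ):
        total = config.cost_scale * float(rng.lognormal(mean=-0.5, sigma=0.6))
        rebate_share = float(rng.uniform(0.0, 0.7))
        costs[name] = CostItem(name, rebate_share * total, (1 - rebate_share) * total)

    settings = GlobalSettings(
        probability_cv=config.probability_cv,
        cost_cv=config.cost_cv,
        psa_seed=config.seed,
    )
    return ModelInputs(rates=rates, procedures=procedures, costs=costs, settings=settings)


class ToyModel(NamedTuple):
    spec: StrategySpec
    costs: dict[str, CostItem]
    expected_clbr: float
    expected_cost: float


TOY_ITEM = "complete_fresh_fet_autologous"  # any priced item works for the toy


def closed_form_toy(
    p_opu: float,
    p_lb: float,
    p_cont: float,
    n_stages: int,
    unit_cost: float,
) -> ToyModel:
    """An n-stage strategy with identical stages plus its exact solution.

    Every stage uses ``p_cont`` for both continuation hooks (after
    failure and after cancellation) and accrues ``unit_cost`` per
    attempt that reaches oocyte pick-up.  The closed form is derived
    directly from the branching algebra:

    per entering woman,
        ``A  = p_opu * (1 + (1 - p_opu) * p_cont)``   (pick-ups),
        live births ``A * p_lb``, onward mass ``t = A * (1 - p_lb) * p_cont``;
    over ``n`` stages the entering masses form the geometric series
        ``S = 1 + t + ... + t**(n-1)``,
    so ``CLBR = A * p_lb * S`` and ``cost = unit_cost * A * S``.
    """
    if not 1 <= n_stages <= 4:
        raise ValidationError("toy strategies support 1-4 stages")
    stages = tuple(
        AttemptStage(
            index=i,
            kind="fresh_autologous",
            p_reach_opu=p_opu,
            p_live_birth_given_opu=p_lb,
            p_continue_after_failure=p_cont if i < n_stages - 1 else 0.0,
            p_continue_after_cancellation=p_cont,
            cost_items_on_attempt=(TOY_ITEM,),
        )
        for i in range(n_stages)
    )
    spec = StrategySpec("standard", 35, stages)
    costs = {TOY_ITEM: CostItem(TOY_ITEM, 0.0, float(unit_cost))}

    attempts = p_opu * (1.0 + (1.0 - p_opu) * p_cont)
    onward = attempts * (1.0 - p_lb) * p_cont
    series = sum(onward**k for k in range(n_stages))
    expected_clbr = attempts * p_lb * series
    expected_cost = float(unit_cost) * attempts * series
    return ToyModel(spec, costs, expected_clbr, expected_cost)


def random_toy_spec(rng: np.random.Generator, max_stages: int = 4) -> StrategySpec:
    """A random multi-stage strategy for property tests of the engine.

    Stages differ from one another (unlike :func:`closed_form_toy`) and
    may carry distinct attempt/cancellation cost items.
    """
    n = int(rng.integers(1, max_stages + 1))
    stages = tuple(
        AttemptStage(
            index=i,
            kind="fresh_autologous",
            p_reach_opu=float(rng.uniform()),
            p_live_birth_given_opu=float(rng.uniform()),
            p_continue_after_failure=float(rng.uniform()),
            p_continue_after_cancellation=float(rng.uniform()),
            cost_items_on_attempt=("complete_fresh_fet_autologous",),
            cost_items_on_cancellation=("cancelled_cycle",),
        )
        for i in range(n)
    )
    return StrategySpec(
        "standard",
        35,
        stages,
        entry_probability=float(rng.uniform(0.5, 1.0)),
    )
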