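"""Cost accrual and cost-effectiveness measures.

Two payer perspectives are supported: *societal* (public rebate plus
patient out-of-pocket for every item) and *patient* (out-of-pocket
only).  Expected costs are exact expectations over the cohort process,
never sampled: the expected count of each cost item comes from the
cohort recursion and is priced under the chosen perspective.

The incremental cost-effectiveness ratio (ICER) of an alternative
strategy against the reference is Δcost / ΔCLBR.  Sign combinations of
the increments determine the classification:

=============  =============  ==========================================
Δeffect        Δcost          classification
=============  =============  ==========================================
> 0            < 0            ``dominant`` (more effective, cost saving)
< 0            > 0            ``dominated``
same sign      same sign      ``ratio`` (the ICER is meaningful)
0              != 0           ``undefined`` (ratio withheld)
0              0              ``equivalent``
=============  =============  ==========================================

All amounts stay un-rounded internally; rounding is for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import CostItem, GlobalSettings, ModelInputs, ValidationError
from .strategies import CohortTrace, StrategySpec, build_strategy, run_cohort

__all__ = [
    "PERSPECTIVES",
    "StrategyOutcome",
    "ICERResult",
    "item_cost",
    "expected_cost",
    "evaluate_strategy",
    "icer",
    "convert_currency",
    "outcomes_table",
    "cost_effectiveness_table",
]

PERSPECTIVES = ("societal", "patient")


def item_cost(item: CostItem, perspective: str) -> float:
    if perspective == "societal":
        return item.societal
    if perspective == "patient":
        return item.patient
    raise ValidationError(f"unknown perspective {perspective!r}; expected {PERSPECTIVES}")


def expected_cost(
    spec: StrategySpec,
    costs: ModelInputs | dict[str, CostItem],
    perspective: str,
    trace: CohortTrace | None = None,
) -> float:
    """Expected per-woman cost of a strategy under one perspective.

    Equals the pathway-probability-weighted sum of accrued item costs;
    computed here from the exact expected item counts of the cohort
    recursion (the enumeration route is used as an oracle in tests).
    """
    if isinstance(costs, ModelInputs):
        costs = dict(costs.costs)
    if trace is None:
        trace = run_cohort(spec)
    total = 0.0
    for name, count in trace.expected_item_counts.items():
        try:
            item = costs[name]
        except KeyError:
            raise ValidationError(f"strategy references unknown cost item {name!r}") from None
        total += count * item_cost(item, perspective)
    return total


@dataclass(frozen=True)
class StrategyOutcome:
    """Deterministic result for one strategy at one start age."""

    strategy: str
    start_age: int
    clbr: float
    cost_societal: float
    cost_patient: float

    def expected_cost(self, perspective: str) -> float:
        if perspective == "societal":
            return self.cost_societal
        if perspective == "patient":
            return self.cost_patient
        raise ValidationError(f"unknown perspective {perspective!r}")

    def cost_per_live_birth(self, perspective: str) -> float:
        cost = self.expected_cost(perspective)
        return cost / self.clbr if self.clbr > 0 else math.inf


def evaluate_strategy(
    name: str, start_age: int, inputs: ModelInputs, spec: StrategySpec | None = None
) -> StrategyOutcome:
    """Build, run and cost one strategy; both perspectives in one pass."""
    if spec is None:
        spec = build_strategy(name, start_age, inputs)
    trace = run_cohort(spec)
    return StrategyOutcome(
        strategy=name,
        start_age=int(start_age),
        clbr=trace.clbr,
        cost_societal=expected_cost(spec, inputs, "societal", trace),
        cost_patient=expected_cost(spec, inputs, "patient", trace),
    )


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of an alternative against the reference."""

    reference: str
    alternative: str
    start_age: int
    perspective: str
    delta_cost: float
    delta_effect: float
    classification: str  # ratio | dominant | dominated | undefined | equivalent
    icer: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def label(self) -> str:
        if self.classification == "dominant":
            return "More effective and cost saving"
        if self.classification == "dominated":
            return "Less effective and more costly"
        if self.classification == "ratio":
            return f"{self.icer:,.0f}"
        return self.classification


def icer(
    reference: StrategyOutcome,
    alternative: StrategyOutcome,
    perspective: str = "societal",
) -> ICERResult:
    """Classify and (where meaningful) compute Δcost / Δeffect."""
    if reference.start_age != alternative.start_age:
        raise ValidationError("ICER requires outcomes at the same start age")
    d_cost = alternative.expected_cost(perspective) - reference.expected_cost(perspective)
    d_eff = alternative.clbr - reference.clbr

    ratio: float | None = None
    if d_eff == 0.0:
        classification = "equivalent" if d_cost == 0.0 else "undefined"
    elif d_eff > 0.0 and d_cost < 0.0:
        classification = "dominant"
    elif d_eff < 0.0 and d_cost > 0.0:
        classification = "dominated"
    else:
        classification = "ratio"
        ratio = d_cost / d_eff

    return ICERResult(
        reference=reference.strategy,
        alternative=alternative.strategy,
        start_age=reference.start_age,
        perspective=perspective,
        delta_cost=d_cost,
        delta_effect=d_eff,
        classification=classification,
        icer=ratio,
    )


def convert_currency(amount: float, to: str, settings: GlobalSettings) -> float:
    """PPP conversion between the analysis currency (AUD) and USD.

    ``to="USD"`` treats ``amount`` as AUD and divides by the PPP rate;
    ``to="AUD"`` treats it as USD and multiplies — the two are inverse.
    """
    to = to.upper()
    if to == "AUD":
        return float(amount) * settings.ppp_aud_per_usd
    if to == "USD":
        return float(amount) / settings.ppp_aud_per_usd
    raise ValidationError(f"unknown currency {to!r}; expected AUD or USD")


def _display(amount: float, currency: str, settings: GlobalSettings) -> float:
    """Internal AUD amount expressed in the requested display currency."""
    if currency.upper() == "AUD":
        return float(amount)
    return convert_currency(amount, currency, settings)


# ---------------------------------------------------------------------------
# Result tables.
# ---------------------------------------------------------------------------

def _valid_strategies(age: int) -> list[str]:
    names = ["standard", "pgta", "donor"]
    if age >= 40:
        names.insert(2, "social_freezing")
    return names


def outcomes_table(
    inputs: ModelInputs, ages: list[int] | range = range(35, 46), currency: str = "AUD"
) -> pd.DataFrame:
    """Per-(strategy, age) CLBR and expected costs, both perspectives.

    This is the data series behind the headline per-age outcome plots:
    CLBR by strategy and age, and mean treatment cost per cumulative
    live birth.
    """
    suffix = currency.lower()
    rows = []
    for age in ages:
        for name in _valid_strategies(age):
            out = evaluate_strategy(name, age, inputs)
            conv = lambda x: _display(x, currency, inputs.settings)
            rows.append(
                {
                    "strategy": name,
                    "age": age,
                    "clbr": out.clbr,
                    f"cost_societal_{suffix}": conv(out.cost_societal),
                    f"cost_patient_{suffix}": conv(out.cost_patient),
                    f"cost_per_live_birth_societal_{suffix}": conv(
                        out.cost_per_live_birth("societal")
                    ),
                    f"cost_per_live_birth_patient_{suffix}": conv(
                        out.cost_per_live_birth("patient")
                    ),
                }
            )
    return pd.DataFrame(rows)


def cost_effectiveness_table(
    inputs: ModelInputs,
    ages: list[int] | range = range(35, 46),
    perspective: str = "societal",
    currency: str = "AUD",
) -> pd.DataFrame:
    """Deterministic ICER of each alternative vs standard, per age.

    One row per age; the social-freezing cell is empty below age 40
    (the strategy is not available before the return window).
    """
    suffix = currency.lower()
    rows = []
    for age in ages:
        ref = evaluate_strategy("standard", age, inputs)
        row: dict = {"age": age}
        for alt in ("pgta", "donor", "social_freezing"):
            if alt == "social_freezing" and age < 40:
                row[f"{alt}_classification"] = ""
                row[f"{alt}_icer_{suffix}"] = float("nan")
                continue
            res = icer(ref, evaluate_strategy(alt, age, inputs), perspective)
            row[f"{alt}_classification"] = res.classification
            row[f"{alt}_icer_{suffix}"] = (
                _display(res.icer, currency, inputs.settings)
                if res.icer is not None
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
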