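"""Treatment strategies as finite absorbing-state cohort processes.

Each strategy is an ordered sequence of attempt stages.  One stage is
one "complete cycle": an ovarian-stimulation episode (or, for donor and
banked-oocyte treatment, a transfer cycle) together with its bundled
frozen-embryo transfers.  Within a stage a woman may

* have the cycle cancelled before oocyte pick-up (probability
  ``1 - p_reach_opu``), after which she either re-attempts the stage
  once (``p_continue_after_cancellation``) or ends treatment;
* reach oocyte pick-up and achieve a live birth
  (``p_live_birth_given_opu``) — an absorbing outcome; or
* reach pick-up, fail, and either continue to the next stage
  (``p_continue_after_failure``) or end treatment.

"Live birth" and "end" are absorbing; a cohort of unit mass is pushed
through the stages and its occupancy tracked exactly (no sampling).
Two independent computations are provided: a forward cohort recursion
(:func:`run_cohort`) and brute-force enumeration of every pathway
through the finite tree (:func:`enumerate_pathways`); they must agree
to numerical precision, which the test-suite exploits as an oracle.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .parameters import ModelInputs, ValidationError, _check_prob

__all__ = [
    "AttemptStage",
    "StrategySpec",
    "StageTrace",
    "CohortTrace",
    "PathwayRecord",
    "build_strategy",
    "enumerate_pathways",
    "run_cohort",
    "clbr",
]

STAGE_KINDS = (
    "fresh_autologous",
    "fresh_autologous_pgta",
    "donor_fet",
    "stored_oocyte_fet",
)


@dataclass(frozen=True)
class AttemptStage:
    """One complete treatment cycle within a strategy pathway."""

    index: int
    kind: str
    p_reach_opu: float
    p_live_birth_given_opu: float
    p_continue_after_failure: float
    p_continue_after_cancellation: float
    cost_items_on_attempt: tuple[str, ...] = ()
    cost_items_on_cancellation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in STAGE_KINDS:
            raise ValidationError(f"unknown stage kind {self.kind!r}")
        for name in (
            "p_reach_opu",
            "p_live_birth_given_opu",
            "p_continue_after_failure",
            "p_continue_after_cancellation",
        ):
            _check_prob(getattr(self, name), f"stage {self.index}.{name}")


@dataclass(frozen=True)
class StrategySpec:
    """An executable strategy pathway for one start age.

    ``upfront_cost_items`` are ``(item_name, count)`` pairs accrued with
    certainty on entry (social freezing banks oocytes and pays storage
    before any transfer is attempted).  ``entry_probability`` is the
    mass that enters stage 1 at all; with social freezing it is the
    return rate — women who never return still accrue the upfront
    banking costs.
    """

    name: str
    start_age: int
    stages: tuple[AttemptStage, ...]
    upfront_cost_items: tuple[tuple[str, float], ...] = ()
    entry_probability: float = 1.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("a strategy needs at least one stage")
        if [s.index for s in self.stages] != list(range(len(self.stages))):
            raise ValidationError("stage indices must be 0..n-1 in order")
        _check_prob(self.entry_probability, "entry_probability")

    @property
    def n_stages(self) -> int:
        return len(self.stages)


# ---------------------------------------------------------------------------
# Strategy construction from model inputs.
# ---------------------------------------------------------------------------

def _backed_out_per_stage(cumulative: float, n_stages: int) -> float:
    """Per-attempt success rate consistent with a cumulative rate over
    ``n_stages`` guaranteed attempts: solves ``1 - (1-p)**n = cumulative``."""
    return 1.0 - (1.0 - cumulative) ** (1.0 / n_stages)


def build_strategy(name: str, start_age: int, inputs: ModelInputs) -> StrategySpec:
    """Instantiate one of the four strategy pathways at a start age.

    * ``standard`` — two complete autologous cycles (fresh plus bundled
      FETs); cancellation and progression probabilities from the age
      band, live-birth rate per cycle from the per-age schedule.
    * ``pgta`` — two complete autologous cycles with embryo screening;
      the screening cost is added per cycle and the second cycle's
      live-birth rate carries the configured reduction.
    * ``donor`` — the standard pathway followed by up to two transfer
      cycles using donated oocytes (no stimulation, hence no
      cancellation branch for the recipient).
    * ``social_freezing`` — oocytes banked at ``settings.freeze_age``
      (certain, costed upfront together with per-year storage and the
      thaw-transfer bundle), then two transfer cycles from the banked
      oocytes on return at ``start_age`` >= 40.  The published return
      rates are cumulative over the two transfers, so the per-stage
      rate is backed out as ``1 - sqrt(1 - CLBR)``.
    """
    if name not in inputs.rates:
        raise ValidationError(f"unknown strategy {name!r}")
    start_age = int(start_age)
    if name == "social_freezing":
        if not 40 <= start_age <= 45:
            raise ValidationError(
                f"social freezing return age must be 40-45, got {start_age}"
            )
    elif not 35 <= start_age <= 45:
        raise ValidationError(f"start age must be 35-45, got {start_age}")

    procs = inputs.procedures
    settings = inputs.settings
    opu = procs.opu_rate(start_age)
    cont = procs.progression(start_age)
    rate = inputs.rates[name].rate(start_age)

    if name == "standard":
        stages = tuple(
            AttemptStage(
                index=i,
                kind="fresh_autologous",
                p_reach_opu=opu,
                p_live_birth_given_opu=rate,
                p_continue_after_failure=cont if i == 0 else 0.0,
                p_continue_after_cancellation=cont,
                cost_items_on_attempt=("complete_fresh_fet_autologous",),
                cost_items_on_cancellation=("cancelled_cycle",),
            )
            for i in range(2)
        )
        return StrategySpec(name, start_age, stages)

    if name == "pgta":
        mult = settings.pgta_subsequent_cycle_multiplier
        stages = tuple(
            AttemptStage(
                index=i,
                kind="fresh_autologous_pgta",
                p_reach_opu=opu,
                p_live_birth_given_opu=rate if i == 0 else mult * rate,
                p_continue_after_failure=cont if i == 0 else 0.0,
                p_continue_after_cancellation=cont,
                cost_items_on_attempt=("complete_fresh_fet_autologous", "pgta"),
                cost_items_on_cancellation=("cancelled_cycle",),
            )
            for i in range(2)
        )
        return StrategySpec(name, start_age, stages)

    if name == "donor":
        autologous_rate = inputs.rates["standard"].rate(start_age)
        auto = tuple(
            AttemptStage(
                index=i,
                kind="fresh_autologous",
                p_reach_opu=opu,
                p_live_birth_given_opu=autologous_rate,
                # after the second autologous failure she may continue on
                # to donated-oocyte cycles
                p_continue_after_failure=cont,
                p_continue_after_cancellation=cont,
                cost_items_on_attempt=("complete_fresh_fet_autologous",),
                cost_items_on_cancellation=("cancelled_cycle",),
            )
            for i in range(2)
        )
        donor = tuple(
            AttemptStage(
                index=2 + i,
                kind="donor_fet",
                p_reach_opu=1.0,
                p_live_birth_given_opu=rate,
                p_continue_after_failure=cont if i == 0 else 0.0,
                p_continue_after_cancellation=0.0,
                cost_items_on_attempt=("complete_donor_cycle",),
            )
            for i in range(2)
        )
        return StrategySpec(name, start_age, auto + donor)

    # social freezing
    years_stored = start_age - settings.freeze_age
    if years_stored < 0:
        raise ValidationError(
            f"freeze age {settings.freeze_age} exceeds return age {start_age}"
        )
    per_stage = _backed_out_per_stage(rate, 2)
    stages = tuple(
        AttemptStage(
            index=i,
            kind="stored_oocyte_fet",
            p_reach_opu=1.0,
            p_live_birth_given_opu=per_stage,
            # the banked oocytes cover both transfers; the cumulative
            # published rate presumes both are used if needed
            p_continue_after_failure=1.0 if i == 0 else 0.0,
            p_continue_after_cancellation=0.0,
        )
        for i in range(2)
    )
    return StrategySpec(
        name,
        start_age,
        stages,
        upfront_cost_items=(
            ("social_freezing_banking", 1.0),
            ("social_freezing_thaw_total", 1.0),
            ("oocyte_storage_per_year", float(years_stored)),
        ),
        entry_probability=settings.return_rate,
    )


# ---------------------------------------------------------------------------
# Forward cohort recursion.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageTrace:
    """Occupancy bookkeeping for one stage of the cohort run."""

    index: int
    entered: float
    live_birth: float
    end_after_cancellation: float
    end_after_failure: float
    continued: float
    opu_events: float
    cancellation_events: float


@dataclass(frozen=True)
class CohortTrace:
    """Exact occupancy of the cohort over a strategy's stages."""

    spec: StrategySpec
    stages: tuple[StageTrace, ...]
    never_entered: float
    cumulative_live_birth: tuple[float, ...]
    expected_item_counts: Counter = field(default_factory=Counter)

    @property
    def clbr(self) -> float:
        return self.cumulative_live_birth[-1] if self.cumulative_live_birth else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": st.index,
                "entered": st.entered,
                "live_birth": st.live_birth,
                "end_after_cancellation": st.end_after_cancellation,
                "end_after_failure": st.end_after_failure,
                "continued": st.continued,
                "cumulative_live_birth": self.cumulative_live_birth[st.index],
            }
            for st in self.stages
        ]
        return pd.DataFrame(rows)


def run_cohort(spec: StrategySpec) -> CohortTrace:
    """Push a unit cohort through the stages and record occupancy.

    At every stage the masses of the four outcomes (live birth, end
    after cancellation, end after failure, continue) sum to the mass
    that entered the stage; cumulative live-birth mass is the
    strategy's CLBR once the last stage resolves.
    """
    traces: list[StageTrace] = []
    cum: list[float] = []
    items: Counter = Counter()
    for item, count in spec.upfront_cost_items:
        items[item] += count

    mass = spec.entry_probability
    total_lb = 0.0
    last = spec.n_stages - 1
    for st in spec.stages:
        q = 1.0 - st.p_reach_opu
        retry = st.p_continue_after_cancellation
        # OPU attempts per unit of entering mass: the first attempt plus
        # (after a cancellation) at most one re-attempt
        opu_events = st.p_reach_opu * (1.0 + q * retry)
        cancel_events = q * (1.0 + retry * q)
        end_cancel = q * (1.0 - retry) + q * retry * q

        lb = opu_events * st.p_live_birth_given_opu
        fail = opu_events * (1.0 - st.p_live_birth_given_opu)
        p_cont = st.p_continue_after_failure if st.index < last else 0.0
        cont = fail * p_cont
        end_fail = fail - cont

        traces.append(
            StageTrace(
                index=st.index,
                entered=mass,
                live_birth=mass * lb,
                end_after_cancellation=mass * end_cancel,
                end_after_failure=mass * end_fail,
                continued=mass * cont,
                opu_events=mass * opu_events,
                cancellation_events=mass * cancel_events,
            )
        )
        for item in st.cost_items_on_attempt:
            items[item] += mass * opu_events
        for item in st.cost_items_on_cancellation:
            items[item] += mass * cancel_events

        total_lb += mass * lb
        cum.append(total_lb)
        mass *= cont

    return CohortTrace(
        spec=spec,
        stages=tuple(traces),
        never_entered=1.0 - spec.entry_probability,
        cumulative_live_birth=tuple(cum),
        expected_item_counts=items,
    )


def clbr(spec: StrategySpec) -> float:
    """Cumulative live-birth rate of the whole strategy."""
    return run_cohort(spec).clbr


# ---------------------------------------------------------------------------
# Exhaustive pathway enumeration (independent oracle).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayRecord:
    """One complete route through the strategy tree."""

    outcomes: tuple[str, ...]
    probability: float
    live_birth: bool
    accrued_cost_items: tuple[tuple[str, int], ...]

    def to_row(self) -> dict:
        return {
            "pathway": ">".join(self.outcomes),
            "probability": self.probability,
            "live_birth": self.live_birth,
            "cost_items": ";".join(f"{k}x{v}" for k, v in self.accrued_cost_items),
        }


def _stage_branches(
    st: AttemptStage, is_last: bool
) -> Iterator[tuple[tuple[str, ...], float, str, Counter]]:
    """Yield (labels, probability, terminal, items) for one stage entry.

    ``terminal`` is "lb", "end" or "next".  Cancellation may be followed
    by at most one re-attempt of the same stage.
    """
    q = 1.0 - st.p_reach_opu
    retry = st.p_continue_after_cancellation
    p = st.p_live_birth_given_opu
    cont = st.p_continue_after_failure if not is_last else 0.0
    attempt_items = Counter(st.cost_items_on_attempt)
    cancel_items = Counter(st.cost_items_on_cancellation)

    def after_opu(prefix: tuple[str, ...], prob: float, base: Counter):
        items = base + attempt_items
        yield prefix + ("live_birth",), prob * p, "lb", items
        fail = prob * (1.0 - p)
        if cont > 0.0:
            yield prefix + ("failure", "continue"), fail * cont, "next", items
        if cont < 1.0:
            yield prefix + ("failure", "end"), fail * (1.0 - cont), "end", items

    tag = f"s{st.index}"
    if st.p_reach_opu > 0.0:
        yield from after_opu((f"{tag}:opu",), st.p_reach_opu, Counter())
    if q > 0.0:
        if retry < 1.0:
            yield (f"{tag}:cancelled", "end"), q * (1.0 - retry), "end", cancel_items
        if retry > 0.0:
            if q > 0.0:
                yield (
                    (f"{tag}:cancelled", "retry", "cancelled", "end"),
                    q * retry * q,
                    "end",
                    cancel_items + cancel_items,
                )
            if st.p_reach_opu > 0.0:
                yield from after_opu(
                    (f"{tag}:cancelled", "retry", "opu"),
                    q * retry * st.p_reach_opu,
                    cancel_items,
                )


def enumerate_pathways(spec: StrategySpec) -> list[PathwayRecord]:
    """Brute-force every pathway through the finite tree.

    The records are mutually exclusive and exhaustive: their
    probabilities sum to one (including the never-entered pathway when
    the entry probability is below one).
    """
    upfront = Counter()
    for item, count in spec.upfront_cost_items:
        upfront[item] += int(count) if float(count).is_integer() else count

    records: list[PathwayRecord] = []
    if spec.entry_probability < 1.0:
        records.append(
            PathwayRecord(
                outcomes=("never_entered",),
                probability=1.0 - spec.entry_probability,
                live_birth=False,
                accrued_cost_items=tuple(sorted(upfront.items())),
            )
        )

    def walk(stage_idx: int, prefix: tuple[str, ...], prob: float, items: Counter):
        if prob == 0.0:
            return
        if stage_idx == spec.n_stages:
            records.append(
                PathwayRecord(prefix, prob, False, tuple(sorted(items.items())))
            )
            return
        st = spec.stages[stage_idx]
        is_last = stage_idx == spec.n_stages - 1
        for labels, p, terminal, st_items in _stage_branches(st, is_last):
            if p == 0.0:
                continue
            new_items = items + st_items
            path = prefix + labels
            if terminal == "lb":
                records.append(
                    PathwayRecord(path, prob * p, True, tuple(sorted(new_items.items())))
                )
            elif terminal == "end":
                records.append(
                    PathwayRecord(path, prob * p, False, tuple(sorted(new_items.items())))
                )
            else:
                walk(stage_idx + 1, path, prob * p, new_items)

    walk(0, (), spec.entry_probability, upfront)
    total = math.fsum(r.probability for r in records)
    assert abs(total - 1.0) < 1e-9, f"pathway probabilities sum to {total}"
    return records


def pathways_frame(records: list[PathwayRecord]) -> pd.DataFrame:
    """Pathway list as a table (one row per pathway) for CSV export."""
    return pd.DataFrame([r.to_row() for r in records])
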