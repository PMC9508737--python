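"""Model inputs for ART strategy cost-effectiveness analysis.

Holds, validates and loads every quantity the cohort model consumes:

* per-age live-birth rate schedules for each of the four treatment
  strategies (standard autologous, PGT-A, social freezing, donor),
* procedure probabilities by age band (reaching oocyte pick-up,
  progressing to a further fresh cycle),
* the two-payer cost schedule (public rebate + patient out-of-pocket,
  2019 values), and
* global settings (PPP rate, willingness-to-pay threshold, PSA
  configuration, the PGT-A second-cycle penalty, oocyte freeze age).

The built-in fixture carries the published registry-derived estimates;
:func:`load_inputs` / :func:`save_inputs` round-trip the same structure
through a YAML document so user scenarios are first-class.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STRATEGIES",
    "COST_ITEM_NAMES",
    "AgeRateSchedule",
    "ProcedureProbabilities",
    "CostItem",
    "GlobalSettings",
    "ModelInputs",
    "ValidationError",
    "builtin_fixture",
    "load_inputs",
    "loads_inputs",
    "save_inputs",
    "dumps_inputs",
    "interpolate_age_rates",
    "rate_table",
]

#: Strategy labels, in the order results tables print them.
STRATEGIES = ("standard", "pgta", "social_freezing", "donor")

#: Every cost item the strategy pathways may reference.
COST_ITEM_NAMES = (
    "cancelled_cycle",
    "complete_fresh_fet_autologous",
    "fet_cycle",
    "pgta",
    "complete_donor_cycle",
    "oocyte_storage_per_year",
    "social_freezing_banking",
    "social_freezing_thaw_total",
)

#: Valid start-age span per strategy (inclusive).
STRATEGY_AGE_SPAN = {
    "standard": (35, 45),
    "pgta": (35, 45),
    "social_freezing": (40, 45),
    "donor": (35, 45),
}


class ValidationError(ValueError):
    """An input document or parameter set violates the model's contracts."""


def _check_prob(value: float, what: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{what} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class AgeRateSchedule:
    """Live-birth rate by (integer) start age for one strategy.

    ``entries`` maps age in years to a probability.  Ages must form a
    contiguous integer range; which range is valid depends on the
    strategy (women return for banked oocytes only from age 40).
    """

    strategy_name: str
    entries: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.strategy_name not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy_name!r}; expected one of {STRATEGIES}"
            )
        ages = sorted(int(a) for a in self.entries)
        if not ages:
            raise ValidationError(f"rates.{self.strategy_name}: empty schedule")
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValidationError(
                f"rates.{self.strategy_name}: ages must be contiguous, got {ages}"
            )
        clean = {}
        for age in ages:
            clean[age] = _check_prob(
                self.entries[age], f"rates.{self.strategy_name}[{age}]"
            )
        object.__setattr__(self, "entries", clean)

    @property
    def ages(self) -> range:
        lo = min(self.entries)
        return range(lo, lo + len(self.entries))

    def rate(self, age: int) -> float:
        try:
            return self.entries[int(age)]
        except KeyError:
            raise ValidationError(
                f"rates.{self.strategy_name}: no rate for age {age} "
                f"(valid {min(self.entries)}-{max(self.entries)})"
            ) from None

    def __getitem__(self, age: int) -> float:
        return self.rate(age)


@dataclass(frozen=True)
class ProcedureProbabilities:
    """Per-cycle procedure probabilities, banded by age.

    Keys are ``(low, high)`` inclusive age bands; the fixture uses
    35-39 / 40-44 / 45.  ``opu_rate`` is the probability an initiated
    stimulation cycle reaches oocyte pick-up (the complement is a
    cancelled cycle); ``progression`` is the probability a woman who
    has not yet had a live birth undertakes a further fresh cycle.
    """

    opu_rate_by_ageband: Mapping[tuple[int, int], float]
    progression_by_ageband: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        for name, table in (
            ("opu_rate", self.opu_rate_by_ageband),
            ("progression", self.progression_by_ageband),
        ):
            covered: set[int] = set()
            for (lo, hi), p in table.items():
                if lo > hi:
                    raise ValidationError(f"procedures.{name}: bad band {lo}-{hi}")
                band = set(range(int(lo), int(hi) + 1))
                if band & covered:
                    raise ValidationError(f"procedures.{name}: overlapping band {lo}-{hi}")
                covered |= band
                _check_prob(p, f"procedures.{name}[{lo}-{hi}]")
            if not covered >= set(range(35, 46)):
                raise ValidationError(f"procedures.{name}: bands must cover ages 35-45")

    @staticmethod
    def _lookup(table: Mapping[tuple[int, int], float], age: int, what: str) -> float:
        for (lo, hi), p in table.items():
            if lo <= age <= hi:
                return p
        raise ValidationError(f"procedures.{what}: no band covers age {age}")

    def opu_rate(self, age: int) -> float:
        return self._lookup(self.opu_rate_by_ageband, int(age), "opu_rate")

    def progression(self, age: int) -> float:
        return self._lookup(self.progression_by_ageband, int(age), "progression")


@dataclass(frozen=True)
class CostItem:
    """One treatment cost with its public-rebate and out-of-pocket shares.

    Amounts are in the analysis currency (2019 values).  The societal
    cost of the item is the sum of both payers' shares; the patient
    cost is the out-of-pocket share alone.
    """

    name: str
    medicare_rebate: float
    out_of_pocket: float

    def __post_init__(self) -> None:
        if self.name not in COST_ITEM_NAMES:
            raise ValidationError(
                f"unknown cost item {self.name!r}; expected one of {COST_ITEM_NAMES}"
            )
        for comp in ("medicare_rebate", "out_of_pocket"):
            v = float(getattr(self, comp))
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"costs.{self.name}.{comp} must be >= 0, got {v!r}")
            object.__setattr__(self, comp, v)

    @property
    def societal(self) -> float:
        return self.medicare_rebate + self.out_of_pocket

    @property
    def patient(self) -> float:
        return self.out_of_pocket


@dataclass(frozen=True)
class GlobalSettings:
    """Analysis-wide knobs.

    ppp_aud_per_usd
        Purchasing-power-parity rate used for optional USD display
        (analysis-currency amount / rate).
    wtp_threshold
        Willingness-to-pay per additional live birth used for
        acceptability curves.
    psa_replicates, psa_seed
        Monte Carlo configuration of the probabilistic sensitivity
        analysis.
    probability_cv, cost_cv
        Coefficients of variation assigned to beta-distributed
        probabilities and gamma-distributed costs in the PSA.
    pgta_subsequent_cycle_multiplier
        Relative live-birth rate of the second PGT-A cycle (a 10%
        reduction by default).
    freeze_age
        Age at which oocytes are banked under social freezing; storage
        is charged per year between this age and the return age.
    return_rate
        Fraction of women who return to use their banked oocytes.
    """

    ppp_aud_per_usd: float = 1.41
    wtp_threshold: float = 50_000.0
    psa_replicates: int = 10_000
    psa_seed: int = 0
    probability_cv: float = 0.10
    cost_cv: float = 0.10
    pgta_subsequent_cycle_multiplier: float = 0.90
    freeze_age: int = 32
    return_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.ppp_aud_per_usd <= 0:
            raise ValidationError("settings.ppp_aud_per_usd must be > 0")
        if self.probability_cv <= 0 or self.cost_cv <= 0:
            raise ValidationError("settings cv values must be > 0")
        if not 0 < self.pgta_subsequent_cycle_multiplier <= 1:
            raise ValidationError(
                "settings.pgta_subsequent_cycle_multiplier must lie in (0, 1]"
            )
        _check_prob(self.return_rate, "settings.return_rate")
        if self.psa_replicates < 1:
            raise ValidationError("settings.psa_replicates must be >= 1")
        if self.wtp_threshold < 0:
            raise ValidationError("settings.wtp_threshold must be >= 0")


@dataclass(frozen=True)
class ModelInputs:
    """The complete parameter set the model runs from."""

    rates: Mapping[str, AgeRateSchedule]
    procedures: ProcedureProbabilities
    costs: Mapping[str, CostItem]
    settings: GlobalSettings = field(default_factory=GlobalSettings)

    def __post_init__(self) -> None:
        missing = [s for s in STRATEGIES if s not in self.rates]
        if missing:
            raise ValidationError(f"rates: missing strategies {missing}")
        for name, sched in self.rates.items():
            if sched.strategy_name != name:
                raise ValidationError(
                    f"rates[{name!r}] holds a schedule labelled {sched.strategy_name!r}"
                )
            lo, hi = STRATEGY_AGE_SPAN[name]
            if not set(range(lo, hi + 1)) <= set(sched.entries):
                raise ValidationError(
                    f"rates.{name}: must cover ages {lo}-{hi}, has {sorted(sched.entries)}"
                )
        absent = [c for c in COST_ITEM_NAMES if c not in self.costs]
        if absent:
            raise ValidationError(f"costs: missing items {absent}")

    def with_settings(self, **changes) -> "ModelInputs":
        return replace(self, settings=replace(self.settings, **changes))


# ---------------------------------------------------------------------------
# Built-in fixture: the published registry-derived estimates.
# ---------------------------------------------------------------------------

_AUTOLOGOUS_CLBR_PER_OPU = {
    35: 0.325, 36: 0.286, 37: 0.249, 38: 0.213, 39: 0.179, 40: 0.160,
    41: 0.142, 42: 0.107, 43: 0.074, 44: 0.043, 45: 0.014,
}
_SOCIAL_FREEZING_CLBR = {
    40: 0.351, 41: 0.338, 42: 0.325, 43: 0.313, 44: 0.300, 45: 0.287,
}
_PGTA_CLBR = {
    35: 0.337, 36: 0.295, 37: 0.244, 38: 0.194, 39: 0.166, 40: 0.153,
    41: 0.149, 42: 0.147, 43: 0.140, 44: 0.120, 45: 0.082,
}
_DONOR_LBR = {
    35: 0.380, 36: 0.380, 37: 0.380, 38: 0.317, 39: 0.317, 40: 0.317,
    41: 0.329, 42: 0.329, 43: 0.378, 44: 0.378, 45: 0.333,
}
_OPU_RATE = {(35, 39): 0.93, (40, 44): 0.90, (45, 45): 0.85}
_PROGRESSION = {(35, 39): 0.765, (40, 44): 0.707, (45, 45): 0.707}
_COSTS = {
    # name: (medicare rebate, out of pocket), 2019 analysis currency
    "cancelled_cycle": (1_463.0, 1_909.0),
    "complete_fresh_fet_autologous": (6_522.0, 4_325.0),
    "fet_cycle": (626.0, 1_023.0),
    "pgta": (0.0, 1_813.0),
    "complete_donor_cycle": (0.0, 11_720.0),
    "oocyte_storage_per_year": (0.0, 260.0),
    "social_freezing_banking": (0.0, 9_305.0),
    "social_freezing_thaw_total": (0.0, 3_300.0),
}


def builtin_fixture(**settings) -> ModelInputs:
    """Return the published parameter set.

    Keyword arguments override individual :class:`GlobalSettings`
    fields (e.g. ``builtin_fixture(psa_seed=7)``).
    """
    return ModelInputs(
        rates={
            "standard": AgeRateSchedule("standard", _AUTOLOGOUS_CLBR_PER_OPU),
            "pgta": AgeRateSchedule("pgta", _PGTA_CLBR),
            "social_freezing": AgeRateSchedule("social_freezing", _SOCIAL_FREEZING_CLBR),
            "donor": AgeRateSchedule("donor", _DONOR_LBR),
        },
        procedures=ProcedureProbabilities(_OPU_RATE, _PROGRESSION),
        costs={name: CostItem(name, reb, oop) for name, (reb, oop) in _COSTS.items()},
        settings=GlobalSettings(**settings),
    )


# ---------------------------------------------------------------------------
# Configuration document I/O (YAML).
# ---------------------------------------------------------------------------

def _parse_band(key) -> tuple[int, int]:
    if isinstance(key, int):
        return key, key
    text = str(key)
    if "-" in text:
        lo, hi = text.split("-", 1)
        return int(lo), int(hi)
    return int(text), int(text)


def _doc_to_inputs(doc: Mapping) -> ModelInputs:
    if not isinstance(doc, Mapping):
        raise ValidationError("configuration document must be a mapping")
    unknown = set(doc) - {"rates", "procedures", "costs", "settings"}
    if unknown:
        raise ValidationError(f"unknown top-level sections {sorted(unknown)}")

    fixture = builtin_fixture()

    rates: dict[str, AgeRateSchedule] = dict(fixture.rates)
    for name, table in (doc.get("rates") or {}).items():
        rates[name] = AgeRateSchedule(name, {int(a): float(r) for a, r in table.items()})

    procedures = fixture.procedures
    proc_doc = doc.get("procedures")
    if proc_doc:
        unknown = set(proc_doc) - {"opu_rate", "progression"}
        if unknown:
            raise ValidationError(f"procedures: unknown keys {sorted(unknown)}")
        procedures = ProcedureProbabilities(
            opu_rate_by_ageband={
                _parse_band(k): float(v)
                for k, v in (proc_doc.get("opu_rate") or _band_doc(procedures.opu_rate_by_ageband)).items()
            },
            progression_by_ageband={
                _parse_band(k): float(v)
                for k, v in (proc_doc.get("progression") or _band_doc(procedures.progression_by_ageband)).items()
            },
        )

    costs: dict[str, CostItem] = dict(fixture.costs)
    for name, comps in (doc.get("costs") or {}).items():
        if not isinstance(comps, Mapping) or set(comps) - {"medicare_rebate", "out_of_pocket"}:
            raise ValidationError(
                f"costs.{name}: expected mapping with medicare_rebate/out_of_pocket"
            )
        costs[name] = CostItem(
            name,
            float(comps.get("medicare_rebate", 0.0)),
            float(comps.get("out_of_pocket", 0.0)),
        )

    settings_doc = dict(doc.get("settings") or {})
    unknown = set(settings_doc) - set(GlobalSettings.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"settings: unknown keys {sorted(unknown)}")
    settings = GlobalSettings(**settings_doc)

    return ModelInputs(rates=rates, procedures=procedures, costs=costs, settings=settings)


def load_inputs(source: str | IO[str] | Mapping) -> ModelInputs:
    """Load a :class:`ModelInputs` from a YAML path, stream or mapping.

    Omitted sections and settings fall back to the built-in fixture /
    defaults, so a minimal document overriding a single key is valid.
    """
    if isinstance(source, Mapping):
        return _doc_to_inputs(source)
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return _doc_to_inputs(doc or {})


def loads_inputs(text: str) -> ModelInputs:
    """Load a :class:`ModelInputs` from YAML text."""
    return _doc_to_inputs(yaml.safe_load(io.StringIO(text)) or {})


def _band_doc(table: Mapping[tuple[int, int], float]) -> dict[str, float]:
    return {
        (f"{lo}-{hi}" if lo != hi else str(lo)): float(p) for (lo, hi), p in table.items()
    }


def _inputs_to_doc(inputs: ModelInputs) -> dict:
    return {
        "rates": {
            name: {int(a): float(r) for a, r in sched.entries.items()}
            for name, sched in inputs.rates.items()
        },
        "procedures": {
            "opu_rate": _band_doc(inputs.procedures.opu_rate_by_ageband),
            "progression": _band_doc(inputs.procedures.progression_by_ageband),
        },
        "costs": {
            item.name: {
                "medicare_rebate": item.medicare_rebate,
                "out_of_pocket": item.out_of_pocket,
            }
            for item in inputs.costs.values()
        },
        "settings": {
            k: getattr(inputs.settings, k)
            for k in GlobalSettings.__dataclass_fields__
        },
    }


def dumps_inputs(inputs: ModelInputs) -> str:
    """Serialize to YAML text; ``loads_inputs`` inverts this losslessly."""
    return yaml.safe_dump(_inputs_to_doc(inputs), sort_keys=True)


def save_inputs(inputs: ModelInputs, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_inputs(inputs))


# ---------------------------------------------------------------------------
# Age interpolation of banded rates.
# ---------------------------------------------------------------------------

def interpolate_age_rates(
    points: Iterable[tuple[float, float]],
    target_ages: Iterable[int],
    strategy_name: str = "standard",
) -> AgeRateSchedule:
    """Fit ``rate = logistic(a + b*age)`` through banded anchor points.

    Published success rates are often reported for 5-year age bands; a
    logistic curve in age, fitted by least squares on the logit scale,
    turns those anchors into the per-age schedule the cohort model
    needs.  With exactly two anchor points the curve passes through
    both.  Predictions are clipped to the open unit interval.
    """
    pts = [(float(a), float(r)) for a, r in points]
    if len(pts) < 2 or len({a for a, _ in pts}) < 2:
        raise ValidationError("interpolation needs >= 2 points with distinct ages")
    for a, r in pts:
        if not 0.0 < r < 1.0:
            raise ValidationError(f"anchor rate at age {a} must lie in (0, 1), got {r}")
    ages = np.array([a for a, _ in pts])
    logits = np.log([r / (1.0 - r) for _, r in pts])
    slope, intercept = np.polyfit(ages, logits, 1)
    targets = np.asarray(list(target_ages), dtype=int)
    pred = 1.0 / (1.0 + np.exp(-(intercept + slope * targets)))
    eps = 1e-12
    pred = np.clip(pred, eps, 1.0 - eps)
    return AgeRateSchedule(strategy_name, dict(zip(targets.tolist(), pred.tolist())))


def rate_table(inputs: ModelInputs) -> pd.DataFrame:
    """Per-age live-birth rate table (one column per strategy) for CSV export."""
    ages = range(35, 46)
    data = {
        name: [sched.entries.get(a, float("nan")) for a in ages]
        for name, sched in inputs.rates.items()
    }
    return pd.DataFrame(data, index=pd.Index(ages, name="age"))
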