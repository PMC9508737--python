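"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: every probability
input is given a beta distribution and every cost component a gamma
distribution, each moment-matched to the point estimate (mean) and a
coefficient of variation; one coherent draw of the whole parameter set
is taken per replicate, the strategies are rebuilt and re-evaluated,
and the replicate outcomes summarised with empirical percentiles
(linear interpolation between order statistics — numpy's default).

Outputs mirror the standard health-economics presentations: the
cost-effectiveness plane (Δeffect on x, Δcost on y, one point per
replicate), percentile intervals for replicate ICERs, and the
cost-effectiveness acceptability curve based on the net-monetary-
benefit rule ``wtp * Δeffect − Δcost > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import evaluate_strategy, icer
from .parameters import (
    AgeRateSchedule,
    CostItem,
    ModelInputs,
    ProcedureProbabilities,
    ValidationError,
)

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "moment_match",
    "default_distributions",
    "sample_inputs",
    "run_psa",
    "percentile_ci",
    "ce_plane",
    "prob_cost_effective",
    "ceac_table",
]

ALTERNATIVES = ("pgta", "donor", "social_freezing")


def moment_match(family: str, mean: float, cv: float) -> tuple[float, float]:
    """Distribution parameters whose first two moments match ``(mean, cv)``.

    beta
        Returns ``(alpha, beta)`` with ``alpha = m(m(1-m)/v - 1)`` and
        ``beta = (1-m)(m(1-m)/v - 1)`` where ``v = (cv*m)**2``; requires
        ``v < m(1-m)`` (otherwise no beta distribution has that spread).
    gamma
        Returns ``(shape, scale) = (1/cv**2, m*cv**2)``.
    """
    if cv <= 0:
        raise ValidationError("cv must be > 0")
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
        v = (cv * mean) ** 2
        bound = mean * (1.0 - mean)
        if v >= bound:
            raise ValidationError(
                f"infeasible beta variance {v:.6g} >= m(1-m) = {bound:.6g}"
            )
        nu = bound / v - 1.0
        return mean * nu, (1.0 - mean) * nu
    if family == "gamma":
        if mean <= 0:
            raise ValidationError(f"gamma mean must be > 0, got {mean}")
        return 1.0 / cv**2, mean * cv**2
    raise ValidationError(f"unknown distribution family {family!r}")


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty assignment for one parameter of :class:`ModelInputs`.

    ``target`` is a dotted path: ``rates.<strategy>.<age>``,
    ``procedures.<table>.<lo>-<hi>`` or ``costs.<item>.<component>``.
    """

    target: str
    family: str  # "beta" for probabilities, "gamma" for costs
    mean: float
    cv: float

    def params(self) -> tuple[float, float]:
        return moment_match(self.family, self.mean, self.cv)

    def draw(self, rng: np.random.Generator, size=None):
        a, b = self.params()
        if self.family == "beta":
            return rng.beta(a, b, size=size)
        return rng.gamma(a, b, size=size)


def default_distributions(inputs: ModelInputs) -> list[DistributionSpec]:
    """Beta on every probability, gamma on every non-zero cost component."""
    p_cv = inputs.settings.probability_cv
    c_cv = inputs.settings.cost_cv
    dists: list[DistributionSpec] = []
    for name, sched in inputs.rates.items():
        for age, rate in sorted(sched.entries.items()):
            dists.append(DistributionSpec(f"rates.{name}.{age}", "beta", rate, p_cv))
    for table, label in (
        (inputs.procedures.opu_rate_by_ageband, "opu_rate"),
        (inputs.procedures.progression_by_ageband, "progression"),
    ):
        for (lo, hi), p in sorted(table.items()):
            dists.append(
                DistributionSpec(f"procedures.{label}.{lo}-{hi}", "beta", p, p_cv)
            )
    for item in inputs.costs.values():
        for comp in ("medicare_rebate", "out_of_pocket"):
            value = getattr(item, comp)
            if value > 0:
                dists.append(
                    DistributionSpec(f"costs.{item.name}.{comp}", "gamma", value, c_cv)
                )
    return dists


def _apply_draws(inputs: ModelInputs, values: Mapping[str, float]) -> ModelInputs:
    """Rebuild a ModelInputs with the targeted parameters replaced."""
    rates = {n: dict(s.entries) for n, s in inputs.rates.items()}
    opu = dict(inputs.procedures.opu_rate_by_ageband)
    prog = dict(inputs.procedures.progression_by_ageband)
    costs = {n: [c.medicare_rebate, c.out_of_pocket] for n, c in inputs.costs.items()}

    for target, value in values.items():
        section, mid, leaf = target.split(".")
        if section == "rates":
            rates[mid][int(leaf)] = float(value)
        elif section == "procedures":
            lo, _, hi = leaf.partition("-")
            band = (int(lo), int(hi or lo))
            (opu if mid == "opu_rate" else prog)[band] = float(value)
        elif section == "costs":
            costs[mid][0 if leaf == "medicare_rebate" else 1] = float(value)
        else:
            raise ValidationError(f"unknown distribution target {target!r}")

    return ModelInputs(
        rates={n: AgeRateSchedule(n, e) for n, e in rates.items()},
        procedures=ProcedureProbabilities(opu, prog),
        costs={n: CostItem(n, r, o) for n, (r, o) in costs.items()},
        settings=inputs.settings,
    )


def sample_inputs(
    inputs: ModelInputs,
    rng: np.random.Generator,
    dists: Sequence[DistributionSpec] | None = None,
) -> ModelInputs:
    """One coherent random draw of the full parameter set.

    Parameters without a distribution spec are left at their point
    estimates; draws are independent across parameters.
    """
    if dists is None:
        dists = default_distributions(inputs)
    return _apply_draws(inputs, {d.target: float(d.draw(rng)) for d in dists})


def percentile_ci(
    values: Iterable[float], low: float = 2.5, high: float = 97.5
) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation convention)."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.size == 0:
        raise ValidationError("percentile_ci of an empty sequence")
    lo, hi = np.percentile(arr, [low, high])
    return float(lo), float(hi)


def _valid_cells(ages: Sequence[int]) -> list[tuple[str, int]]:
    cells = []
    for age in ages:
        cells.append(("standard", age))
        for alt in ALTERNATIVES:
            if alt == "social_freezing" and age < 40:
                continue
            cells.append((alt, age))
    return cells


@dataclass(frozen=True)
class PSAResult:
    """Replicate-level Monte Carlo outcomes for every strategy/age cell."""

    ages: tuple[int, ...]
    n_replicates: int
    seed: int
    effect: Mapping[tuple[str, int], np.ndarray]
    cost_societal: Mapping[tuple[str, int], np.ndarray]
    cost_patient: Mapping[tuple[str, int], np.ndarray]

    def cost(self, perspective: str = "societal") -> Mapping[tuple[str, int], np.ndarray]:
        if perspective == "societal":
            return self.cost_societal
        if perspective == "patient":
            return self.cost_patient
        raise ValidationError(f"unknown perspective {perspective!r}")

    def delta_effect(self, age: int, alternative: str) -> np.ndarray:
        return self.effect[(alternative, age)] - self.effect[("standard", age)]

    def delta_cost(
        self, age: int, alternative: str, perspective: str = "societal"
    ) -> np.ndarray:
        cost = self.cost(perspective)
        return cost[(alternative, age)] - cost[("standard", age)]

    def cells(self) -> list[tuple[int, str]]:
        """(age, alternative) pairs actually present in the replicates."""
        return [
            (age, alt)
            for age in self.ages
            for alt in ALTERNATIVES
            if (alt, age) in self.effect
        ]

    def summary(self, perspective: str = "societal") -> pd.DataFrame:
        """Replica of the incremental results table, one row per cell.

        ``icer_of_means`` divides the mean increments; ``mean_ratio``
        averages the per-replicate ratios (the two need not agree, and
        the latter is unstable when Δeffect straddles zero — both are
        reported, with the raw-ratio percentile interval and the
        fraction of replicates in each dominance quadrant).
        """
        rows = []
        for age, alt in self.cells():
            d_c = self.delta_cost(age, alt, perspective)
            d_e = self.delta_effect(age, alt)
            mean_dc, mean_de = float(d_c.mean()), float(d_e.mean())
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(d_e != 0, d_c / d_e, np.nan)
            finite = ratios[np.isfinite(ratios)]
            ci = percentile_ci(finite) if finite.size else (np.nan, np.nan)
            rows.append(
                {
                    "age": age,
                    "alternative": alt,
                    "perspective": perspective,
                    "mean_delta_cost": mean_dc,
                    "mean_delta_effect": mean_de,
                    "icer_of_means": mean_dc / mean_de if mean_de != 0 else np.nan,
                    "mean_ratio": float(finite.mean()) if finite.size else np.nan,
                    "ratio_ci_low": ci[0],
                    "ratio_ci_high": ci[1],
                    "frac_dominant": float(np.mean((d_e > 0) & (d_c < 0))),
                    "frac_dominated": float(np.mean((d_e < 0) & (d_c > 0))),
                }
            )
        return pd.DataFrame(rows)


def run_psa(
    inputs: ModelInputs,
    ages: Sequence[int] = tuple(range(35, 46)),
    n_replicates: int | None = None,
    seed: int | None = None,
    dists: Sequence[DistributionSpec] | None = None,
) -> PSAResult:
    """Monte Carlo re-evaluation of every strategy/age cell.

    Each replicate draws a full parameter set, rebuilds every strategy
    spec from it and recomputes CLBR and expected costs under both
    perspectives.  Identical seeds give identical results.
    """
    n = inputs.settings.psa_replicates if n_replicates is None else int(n_replicates)
    if n < 1:
        raise ValidationError("n_replicates must be >= 1")
    seed = inputs.settings.psa_seed if seed is None else int(seed)
    if dists is None:
        dists = default_distributions(inputs)
    rng = np.random.default_rng(seed)

    cells = _valid_cells(list(ages))
    effect = {c: np.empty(n) for c in cells}
    cost_soc = {c: np.empty(n) for c in cells}
    cost_pat = {c: np.empty(n) for c in cells}

    for k in range(n):
        draw = sample_inputs(inputs, rng, dists)
        for name, age in cells:
            out = evaluate_strategy(name, age, draw)
            effect[(name, age)][k] = out.clbr
            cost_soc[(name, age)][k] = out.cost_societal
            cost_pat[(name, age)][k] = out.cost_patient

    return PSAResult(
        ages=tuple(int(a) for a in ages),
        n_replicates=n,
        seed=seed,
        effect=effect,
        cost_societal=cost_soc,
        cost_patient=cost_pat,
    )


def ce_plane(
    psa: PSAResult, age: int, alternative: str, perspective: str = "societal"
) -> pd.DataFrame:
    """Cost-effectiveness plane points: one (Δeffect, Δcost) per replicate."""
    if alternative == "standard":
        raise ValidationError("the CE plane compares an alternative against standard")
    return pd.DataFrame(
        {
            "replicate": np.arange(psa.n_replicates),
            "delta_effect": psa.delta_effect(age, alternative),
            "delta_cost": psa.delta_cost(age, alternative, perspective),
        }
    )


def prob_cost_effective(
    psa: PSAResult, wtp: float, perspective: str = "societal"
) -> pd.DataFrame:
    """P(cost-effective) per cell at one willingness-to-pay threshold.

    A replicate counts as cost-effective when its net monetary benefit
    ``wtp * Δeffect − Δcost`` is positive.
    """
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be >= 0")
    rows = []
    for age, alt in psa.cells():
        nmb = wtp * psa.delta_effect(age, alt) - psa.delta_cost(age, alt, perspective)
        rows.append(
            {
                "age": age,
                "alternative": alt,
                "wtp": float(wtp),
                "probability_cost_effective": float(np.mean(nmb > 0)),
            }
        )
    return pd.DataFrame(rows)


def ceac_table(
    psa: PSAResult,
    wtp_grid: Sequence[float],
    perspective: str = "societal",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a grid of thresholds."""
    frames = [prob_cost_effective(psa, w, perspective) for w in wtp_grid]
    return pd.concat(frames, ignore_index=True)
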