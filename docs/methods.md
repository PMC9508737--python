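# Methods

## The decision problem

A woman aged 35–45 with 6–12 months of infertility can pursue assisted
reproduction along four pathways: standard autologous treatment, autologous
treatment with preimplantation genetic testing for aneuploidy (PGT-A), a
return to oocytes she banked at a younger age ("social freezing"), or cycles
using donated oocytes. The package models each pathway as a small absorbing
cohort process, computes the cumulative live-birth rate (CLBR) and the exact
expected treatment cost under two payer perspectives, compares alternatives
with incremental cost-effectiveness ratios (ICERs), and propagates parameter
uncertainty by Monte Carlo.

## Cohort model

Each strategy is an ordered sequence of *attempt stages*; one stage is one
"complete cycle" — an ovarian-stimulation episode together with its bundled
frozen-embryo transfers (FETs), or a single transfer cycle for donor and
banked-oocyte treatment. This granularity is dictated by the input data:
published success rates are cumulative per oocyte pick-up (OPU)/complete
cycle, not per transfer, so individual FETs are not simulated and their
costs ride inside the stage's cost items.

Within a stage, with the notation used in the code:

* the cycle is cancelled before OPU with probability `1 − p_reach_opu`
  (poor response or hyperstimulation). A cancelled cycle accrues the
  cancelled-cycle cost and is re-attempted at most once, with probability
  `p_continue_after_cancellation`; a second cancellation ends treatment.
  Capping re-attempts at one keeps the tree finite and matches the clinical
  description of undertaking "a second fresh cycle".
* reaching OPU accrues the stage's cost items and yields a live birth with
  probability `p_live_birth_given_opu` (absorbing). A failed stage continues
  to the next stage with probability `p_continue_after_failure`, else ends.

The published "progression to fresh cycle" probability (0.765 ages 35–39,
0.707 at 40+) feeds *both* continuation hooks, since the source describes the
end-or-continue choice identically after a cancelled and after a failed
cycle; the two hooks are kept separate so sensitivity analyses can split
them. All strategies complete within a year, so nothing is discounted and
the cohort does not age between stages.

Strategy construction from the input tables:

* **standard** — two identical autologous stages, per-cycle live-birth rate
  taken directly from the per-age schedule (the rates are "per OPU", i.e.
  already per complete cycle).
* **pgta** — two autologous stages with the screening cost added per stage;
  the second stage's rate is multiplied by 0.9 (the assumed 10% penalty for
  a subsequent screened cycle).
* **donor** — the standard pathway, then up to two donated-oocyte transfer
  cycles. Recipients undergo transfer only, so donor stages have no
  cancellation branch. The donor rate table is read as a per-cycle rate:
  the 0.317–0.380 values match the source description of "more than one in
  four cycles" ending in a live birth, and treating them as cumulative over
  two cycles would roughly double the implied cost per donor live birth,
  contradicting the published incremental results.
* **social_freezing** — two OPUs at age 32 are assumed to bank sufficient
  oocytes with certainty, so banking is a deterministic upfront cost
  (banking bundle + thaw-transfer bundle + storage × years banked), and
  `entry_probability` models the return rate (default 1.0; women who never
  return still paid for banking). The published rates here *are* cumulative
  over the two return transfers, so the per-stage rate is backed out as
  `p = 1 − √(1 − CLBR)` with certain continuation between the two transfers.

Two independent computations of the same process are maintained: an exact
forward cohort recursion over stages, and brute-force enumeration of every
pathway through the finite tree. They are required to agree to ≤1e−10 on
CLBR and on the expected count of every cost item; the test suite holds this
over all fixture strategies, 200 random strategies, and an analytic
closed-form toy (geometric-series algebra) over a full parameter grid.

## Costs and perspectives

Every cost item has a public-rebate share and an out-of-pocket share (2019
values). The *societal* perspective prices an item at the sum of both; the
*patient* perspective at the out-of-pocket share alone. Expected costs are
exact expectations (item counts from the recursion × prices), never sampled.
The complete-cycle item accrues once per stage that reaches OPU, the
cancelled-cycle item per cancellation event, the screening and donor items
per respective stage, and the social-freezing bundles upfront. Storage costs
are not discounted across the banking-to-return gap (the source is silent;
this is a deliberate simplification).

The input cost table is treated as the analysis currency throughout; the
purchasing-power-parity rate (1.41) converts to USD for display only. The
source material labels overlapping quantities as both USD and AUD; keeping
one internal currency and an explicit conversion resolves this without
guessing. Rounding to whole dollars happens only at display time.

ICER classification is decided purely by the signs of the increments
(Δeffect = ΔCLBR, Δcost): more effective and cheaper is *dominant* ("more
effective and cost saving"), less effective and dearer is *dominated*,
same-sign quadrants yield a ratio, and a zero Δeffect withholds the ratio.

## Probabilistic sensitivity analysis

Every probability input receives a beta distribution and every non-zero
cost component a gamma distribution, moment-matched to the point estimate
and a coefficient of variation (cv): beta `α = m(m(1−m)/v − 1)`,
`β = (1−m)(m(1−m)/v − 1)` with `v = (cv·m)²`; gamma `shape = 1/cv²`,
`scale = m·cv²`. The sources publish no standard errors, so cv = 0.10 for
both families is the documented default, configurable per run. Draws are
independent across parameters (no correlation structure is published) and
coherent within a replicate: each of the (default 10,000) replicates draws
one full parameter set, rebuilds every strategy and recomputes CLBR and
costs under both perspectives. Seeding `numpy.random.default_rng` makes runs
bit-reproducible.

Summaries use empirical 2.5th/97.5th percentiles (numpy's linear
interpolation between order statistics). Because the ratio of increments is
unstable when Δeffect straddles zero, the summary reports *both* the ratio
of mean increments and the mean of per-replicate ratios, with the raw-ratio
percentile interval and the fraction of replicates falling in each dominance
quadrant. Acceptability curves use the net-monetary-benefit rule
`wtp·Δeffect − Δcost > 0`.

A caution the test suite documents deliberately: the cohort outputs are
nonlinear (quadratic and higher) in the sampled probabilities, so the PSA
replicate mean differs from the deterministic result by a second-order
Jensen term of order ½·f″·σ². At cv = 0.10 and n = 10,000 that bias is tiny
in absolute terms (a few tens of currency units, ~6% of one replicate SD)
but statistically resolvable — roughly 5–7 Monte Carlo standard errors for
the worst cells, scaling linearly with cv. The deterministic values do sit
well inside the 2.5–97.5 percentile band of every cell.

## Age interpolation

Published success rates often come in 5-year bands. `interpolate_age_rates`
fits `rate = logistic(a + b·age)` by least squares on the logit scale and
evaluates it per age; with two anchor points the curve passes through both,
and monotone anchors give a monotone schedule. The built-in schedules are
already per-age, so interpolation is a provenance/utility mechanism for
user-supplied banded data, not a runtime dependency of the fixture.

## Synthetic scenarios

`generate_inputs` draws structurally valid random parameter sets that mirror
the published tables' shape: per-age schedules declining logistically in age
(a constant multiplicative decline in odds per year, default 0.85), banded
procedure probabilities, and two-payer cost items with random rebate shares
around a configurable scale. It emulates parameter-level structure only —
no registry record-level features, no correlation between rates and costs,
no secular trends — so tests passing on synthetic scenarios demonstrate
engine correctness and pipeline robustness, not clinical realism.

## Problem sizes and numerical choices

The deterministic analysis covers 11 start ages × up to 4 strategies, each a
tree of at most 4 stages — everything is exact arithmetic and runs in
milliseconds. The default PSA (10,000 replicates, all ages, ~45 sampled
parameters) runs in well under a minute on one core. Conservation of
probability mass is asserted to 1e−12 at every stage; engine-vs-enumeration
equality to 1e−10; interval estimates fix numpy's default percentile
convention. Degenerate inputs (zero rates, zero continuation, certain live
birth, zero return rate) are covered by tests and need no special-casing in
the engine.

## Known limitations

* Strategy pathways are fixed at the published designs (two cycles, plus
  two donor cycles); arbitrary pathway lengths are expressible through
  `StrategySpec` but not through `build_strategy`.
* No discounting, no aging during treatment, no multiple-birth or perinatal
  outcomes, no QALYs — the effect unit is a live birth.
* The PGT-A arm's effect advantage over standard treatment is negative or
  near zero at ages 35–39 under the published rate tables, so its ICER is
  knife-edge there; the PSA ratio intervals make that visible.
* PSA draws are independent; any real correlation between age-band
  parameters would tighten or widen the intervals.
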