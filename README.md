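# artcea

Cohort decision modelling and cost-effectiveness analysis of assisted
reproductive technology (ART) strategies for women of advanced maternal age.

Women starting fertility treatment between 35 and 45 face a choice between
standard autologous IVF, adding preimplantation genetic testing for
aneuploidy (PGT-A), returning to oocytes banked at a younger age ("social
freezing"), or using donated oocytes. `artcea` encodes each pathway as a
finite absorbing-state cohort process — stages are complete treatment
cycles; "live birth" and "end" absorb — and computes, exactly:

* the cumulative live-birth rate (CLBR) per strategy and start age,
* expected treatment cost under a **societal** (public rebate + out-of-pocket)
  and a **patient** (out-of-pocket only) perspective,
* incremental cost-effectiveness ratios ICER = ΔC/ΔE versus standard
  treatment, with dominance classification ("more effective and cost
  saving" when ΔE > 0 and ΔC < 0),
* a probabilistic sensitivity analysis (PSA): beta-distributed
  probabilities and gamma-distributed costs, moment-matched at a
  configurable coefficient of variation, 10,000 seeded Monte Carlo
  replicates, percentile intervals, cost-effectiveness planes and
  acceptability curves via the net-monetary-benefit rule.

The published per-age rate tables and the two-payer 2019 cost schedule ship
as a built-in fixture; YAML documents with the same structure define custom
scenarios, and a synthetic-scenario generator produces random valid inputs
for testing and benchmarking. See `docs/methods.md` for the model in full.

## Worked example

```python
import artcea as a

inputs = a.builtin_fixture()
for name in ("standard", "pgta", "social_freezing", "donor"):
    out = a.evaluate_strategy(name, 40, inputs)
    print(f"{name:16s} CLBR={out.clbr:.3f}  societal={out.cost_societal:,.0f}  "
          f"patient={out.cost_patient:,.0f}")

ref = a.evaluate_strategy("standard", 40, inputs)
res = a.icer(ref, a.evaluate_strategy("social_freezing", 40, inputs))
print(res.classification, f"dC={res.delta_cost:,.0f}", f"dE={res.delta_effect:.4f}")
```

prints

```
standard         CLBR=0.242  societal=17,002  patient=6,874
pgta             CLBR=0.224  societal=19,809  patient=9,650
social_freezing  CLBR=0.351  societal=14,685  patient=14,685
donor            CLBR=0.396  societal=22,694  patient=12,566
dominant dC=-2,317 dE=0.1086
```

At age 40 a cohort returning to oocytes banked at 32 has a 35.1% chance of
a live birth for an expected 14,685 (all of it out-of-pocket — banking,
storage and thaw transfers attract no public rebate), versus 24.2% and
17,002 for standard treatment: social freezing is *dominant* from the
societal perspective (more effective and cost saving, ΔC = −2,317 per woman
for +0.109 live births). Donor treatment is more effective still but costs
5,692 more per woman, a ratio of about 36,972 per additional live birth.
From the patient perspective the ordering changes: standard treatment's
out-of-pocket cost per live birth is lowest at the younger ages because
more than half of its cost is publicly rebated.

The command-line interface wraps the same calls and writes plain CSV plus a
run manifest:

```sh
artcea deterministic --fixture --ages 35-45 --outdir out     # outcomes.csv, icer_table.csv, rates.csv
artcea psa --fixture --n 10000 --seed 1 --outdir out         # psa_summary.csv, ce_plane_<age>.csv, ceac.csv
artcea synth --seed 5 --out scenario.yaml                    # random scenario, reusable via --config
```

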