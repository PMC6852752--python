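# biosavings

Biosimilar uptake and cost-savings analysis for drug purchase-audit data.

When a biosimilar enters the market at a discount to its originator biologic,
every originator unit still being bought is money left on the table. Given a
purchase audit — dollars spent and units bought per region, sector (drugstore
or hospital), month and product presentation — this package computes how much
was actually saved through biosimilar purchases, how much more a full switch
would have saved, and how biosimilar market share evolved over time. It is
aimed at pharmacoeconomists and drug-policy analysts working with
drugstore/hospital purchase audits (e.g. the Canadian CDH audit).

## Model

For each molecule, within a stratum (national or per region), unit prices are
purchase-weighted:

    p = total dollars / total units

and the per-unit price delta between originator *o* and biosimilar *b* is
`Δ = p_o − p_b` (rounded to cents first under the default convention; the
sign is preserved if the biosimilar is dearer). Savings follow as

    realized   = Δ · units_b        (what biosimilar purchases actually saved)
    unrealized = Δ · units_o        (forgone: the full-conversion potential is
    potential  = realized + unrealized        realized + unrealized)

Market-share scenarios scale the potential linearly (25/50/75/100% by
default), and an eligibility sensitivity scales the unrealized total by the
fraction of originator units assumed clinically convertible (default 0.8).
Originator presentations (dosage form, strength) with no corresponding
biosimilar presentation are excluded and carry zero savings. Deltas can be
computed nationally ("pooled") or per region ("stratified"); the two totals
differ whenever regional prices differ, and both are reported.

The package ships with:

- a packaged fixture of the published July 2016 – June 2018 Canadian national
  aggregates for insulin glargine (Lantus/Basaglar), filgrastim
  (Neupogen/Grastofil) and infliximab (Remicade/Inflectra);
- a synthetic audit generator (`biosavings.synthetic_cdh`) with configurable
  region weights, discount, uptake trajectory and noise, since real audit
  data is proprietary.

## Worked example

```sh
$ biosavings reproduce-table1 --out report
pooled: realized $46,163,359 / unrealized $1,048,663,877 / potential $1,094,827,236
stratified: realized $46,163,359 / unrealized $1,048,663,877 / potential $1,094,827,236
eligibility 80%: $838,931,102
eligibility 100%: $1,048,663,877
biosimilar dollar share: 4.11%
```

Reading: over the two-year window, purchases of the three biosimilars saved
about $46.2M, while switching every originator unit to its biosimilar at the
observed price gap would have saved a further $1.049B; if only 80% of
originator units were clinically eligible for conversion, $838.9M. Biosimilars
were 4.11% of the $2.65B spent on these six products. The stratified and
pooled conventions coincide here because the fixture has no regional
breakdown. `report/` contains `table1.csv` (per-product dollars, units, unit
prices — e.g. Remicade $1001.07/unit vs Inflectra $552.54, a 44.8% discount —
and per-molecule savings), `table2_scenarios.csv` (market-share scenarios by
region), `uptake.csv` (biosimilar share per quarter) and `summary.json`.

Other entry points:

```sh
biosavings generate --out synth.csv --seed 7     # synthetic audit CSV
biosavings analyze --input synth.csv --out report --eligibility 0.8,1.0
```

or from Python: `read_purchases` / `generate_purchases` →
`build_comparator_map` → `collapse` → `savings_national` /
`savings_stratified` → `scenario_table`, `sensitivity_eligibility`,
`uptake_series`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the two headline national totals from scratch by running the full
pipeline on the packaged national aggregates: `t1`, the total unrealized
(full-conversion) savings, and `t2`, the total realized savings, both in CAD
summed over the three molecules using cent-rounded pooled price deltas.

See `docs/methods.md` for conventions, the noise model of the synthetic
generator, and known limitations.
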