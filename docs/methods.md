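# Methods

## Data model

One purchase record is an audited cell — (region, sector, month, molecule,
brand, role, dosage form, strength) — with the dollars spent and units bought.
Dollars are integer cents and units integers throughout: the analysis is pure
aggregation and multiplication, and floating accumulation over millions of
units would perturb the final dollar figures. Records with positive dollars
and zero units are rejected outright (they would leave a unit price
undefined); zero-dollar zero-unit cells are legal.

The study window defaults to July 2016 – June 2018 and quarters are
consecutive 3-month blocks anchored at the window start (the default window's
Q1 is Jul–Sep 2016, which coincides with calendar 2016Q3; a window starting
mid-quarter would not). Every in-window month belongs to exactly one quarter.

## Comparator matching

Each molecule has one originator and one biosimilar brand (defaults: Lantus ↔
Basaglar, Neupogen ↔ Grastofil, Remicade ↔ Inflectra). Presentation keys —
(form, strength) pairs — sold by both brands are *matched*; originator-only
keys are *excluded*, because no substitutable biosimilar presentation exists,
and contribute zero savings. Excluded dollars are logged and surfaced
(`collapse(...).attrs["excluded_dollars_cents"]`), never silently discarded.
A biosimilar-only key is treated as a configuration error rather than data:
within this framework a biosimilar must have an originator counterpart. Audit
"units" are assumed comparable only within one matched presentation key; no
attempt is made to reconcile unit definitions (pens vs vials) across keys.

## Prices, deltas, savings

Unit price is total dollars / total units within a stratum — a
purchase-weighted mean, so the pooled national price is identically the
units-weighted mean of region prices. Prices are carried as exact rationals
internally and rounded half-up to cents only at the boundary fixed by
convention:

- **cent_rounded** (default): each price is rounded to cents, then
  differenced. The published savings tables this package mirrors are only
  recoverable under this convention (e.g. the insulin glargine delta 4.07 ×
  7,328,068 originator units ≈ $29.83M, where the unrounded delta would give
  ≈ $29.86M).
- **exact**: unrounded quotients are differenced; useful as a check on how
  much the rounding convention matters.

Realized (Δ × biosimilar units) and unrealized (Δ × originator units) savings
are rounded half-up to whole dollars at the end; `potential = realized +
unrealized` holds exactly after rounding by construction. A negative delta
(biosimilar dearer) is propagated with a warning, never clamped: savings
estimates should be truthful, not optimistic.

Two stratification conventions are always computed: **pooled** (one national
delta per molecule) and **stratified** (a delta per region, summed). They
differ whenever regional prices differ; both appear in the JSON summary. In a
region where one product has no purchases, no regional delta exists, yet
regions with ~0% uptake are exactly where unrealized savings live; the
default fallback applies the molecule's pooled national delta there
(configurable to skip the region instead), and every fallback use is logged
and listed in the output.

An unweighted cross-province mean delta is also available
(`province_mean_deltas`, usable via `delta_overrides`); the pooled delta is
the default because it reproduces the published national cells.

## Scenarios and sensitivity

Market-share scenarios are linear: cell(f, region) = f × regional potential.
Cells are rounded to whole dollars with exact halves toward zero — the one
place this package departs from half-up rounding, because the published
scenario rows it validates against demonstrably round .5 down (25% of the
total potential 1,094,880,242 prints as 273,720,060, not …061). The total
column sums the region cells. Eligibility sensitivity is `e × unrealized`
with e ∈ [0, 1]; the conventional e = 0.8 reflects that some patients cannot
be switched for tolerance or response reasons.

Published last-dollar figures mix truncation and rounding between rows; no
per-cell guess is attempted. Tests accept ±$2 per molecule cell and ±$5 on
totals, which absorbs exactly that inconsistency and nothing more.

## Synthetic generator

The generator emulates the audit's structure: per molecule, a monthly unit
total is split biosimilar/originator by an uptake curve interpolating a start
share to an end share (linear or rescaled-logistic in relative time), then
apportioned over region × sector cells by region weights and a
drugstore/hospital split. Apportionment uses largest remainder, so configured
totals are conserved exactly at zero dispersion, and integer counts respect
zero weights. Defaults state the studied market: the three molecules at their
national average unit prices ($19.26, $197.53, $1001.07), observed discounts
(21.1%, 17.8%, 44.8%), two-year national unit volumes spread evenly over 24
months, population-like region weights, and uptake rising between the
published first- and last-quarter shares.

Noise, where enabled, is explicit because the audit states no error model:
multiplicative lognormal price noise with a given CV (mean-corrected so the
expected price is the nominal one), and negative-binomial counts with
variance μ(1 + δμ), dispersion δ = 0 degenerating to the deterministic
apportionment. Random substreams are keyed by (seed, molecule, region,
month), so adding a region or molecule never perturbs the draws of others,
and identical configurations are byte-identical.

Realized unit prices are quantized to whole cents before multiplying by
units, keeping cell dollars exact integers as in a real audit. Consequently,
zero-noise discount recovery is *exact* when the nominal prices land on whole
cents (the tested configuration: $100.00/$80.00); with arbitrary prices the
quantization error is below half a cent per unit, orders of magnitude inside
every stated tolerance.

`generate_paperlike("table1_national")` instead spreads the packaged national
aggregates deterministically over regions, sectors and months (flat months
for originators, a linear ramp for biosimilars; dollars apportioned
proportionally to cell units so zero-unit cells carry zero dollars). It
exercises every aggregation path while re-aggregating exactly to the
published totals.

What a green synthetic test does **not** establish: the generator has no
prescriber behaviour, tendering, seasonality, confidential rebates, or
province-specific pricing policy; it validates the arithmetic pipeline, not
any adoption model.

## Limitations

- Purchase audits record intake, not dispensing; savings on purchased units
  may overstate savings on used units.
- Audit prices are list-like; confidential product-listing agreements are not
  modelled, so potential savings are upper bounds in that respect.
- No discounting of effects over time: the analysis is cross-sectional within
  its window.
- Safety/efficacy equivalence between originator and biosimilar is assumed,
  not modelled; the eligibility sensitivity is the only concession to
  non-convertibility.
- The packaged fixture is national: regional cells of the published
  provincial analysis rely on non-public inputs and are out of scope.
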