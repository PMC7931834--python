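# Methods

## Scope and structure

`vlcost` models one year of a national HIV viral-load (VL) monitoring
programme choosing among specimen-collection strategies: plasma only;
plasma at high-volume facilities with dried blood spots (DBS) or plasma
separation cards (PSC) at low-volume facilities; or a full switch to DBS
or PSC. The package is organised around a model object
(`ViralLoadScaleUpModel`) fitted from a facility panel plus a validated
parameter set, returning a results object carrying per-scenario outcomes,
the cost-effectiveness league table, and a rendered summary. The pipeline
stages live in dedicated modules (`network`, `access`, `testing`,
`costing`, `cea`, `sensitivity`, `report`) and are usable on their own.

## The facility network and its synthetic stand-in

Real inputs of the required shape come from a geospatial
transport-optimisation model: per facility, an ART cohort size, a volume
stratum (high volume means ≥10 anticipated VL specimens/day and a place on
daily plasma routes), and whether plasma transport can reach it at all.
`vlcost.network` generates synthetic panels with this schema. Facility
cohort sizes are drawn from a lognormal (ART cohorts are strongly
right-skewed; `dispersion` is the lognormal σ, default 1.0) and
integerised by the largest-remainder method so every stratum's total
matches its requested total *exactly* — all programme-level outcomes
depend only on stratum totals, so within-stratum allocation is free to
vary with the seed while results stay invariant.

The calibrated Zambia panel fixes stratum totals by inverting the access
multipliers against the published national access marginals:

- 0.8·H = 708,525 ⇒ H = 885,656 high-volume patients,
- 0.8·H + 0.4·L_reach = 814,066 ⇒ L_reach = 263,853 reachable low-volume patients,
- 0.8·(H + L_reach + L_unreach) = 965,587 ⇒ L_unreach = 57,475 unreachable patients,

with 152 high-volume, 648 reachable low-volume, and 241 unreachable
facilities (so 800 facilities are reached with plasma and 1,041 with dried
specimens). The published access decomposition ("an additional 16%" from
existing facilities plus "3%" from new ones) cannot be reconciled exactly
with these totals from the main-text figures alone; the panel reproduces
the totals (≈13% + ≈5.6%, printed as 19%), not that split. What passing
tests show is therefore fidelity to the stratum-level arithmetic, not to
any facility-level geography: the synthetic panel has no coordinates,
travel times or route structure, and says nothing about which real
facilities would be reached.

## Access

Access is deterministic. Multipliers (annual fraction of the ART cohort
obtaining a usable VL): 0.80 at high-volume sites for any specimen; 0.40
at low-volume reachable sites with plasma, 0.80 with dried specimens; 0.80
at unreachable sites, which participate only in dried scenarios. Stratum
contributions are kept as reals and rounded half-away-from-zero only at
reporting, which is what makes the reported counts (814,066; 965,587;
708,525) land exactly.

## Testing cascade and correct results

Every patient gets one initial test; every screen positive (>1000
copies/mL) gets exactly one confirmatory repeat. Tests per patient are
therefore `1 + q` with `q = p·Se + (1−p)·(1−Sp)`. Deeper cascades are out
of scope; the published volume ratios are consistent with a single repeat.

Effective `(Se, Sp)` for dried specimens is the volume-weighted mean over
platforms (CAP/CTM share 42% in the partial-PSC scenario, 61% in the
full-PSC scenario; DBS runs on CAP/CTM only). Plasma always uses the
CAP/CTM performance.

The failure prevalence `p` is not an observed input; it is calibrated by
inverting the positivity relation against the plasma-only cascade
(930,982 tests / 814,066 patients), giving p ≈ 0.1409. This inversion
requires an informative assay (Se + Sp > 1) and is exact algebra, so a
round trip (generate volumes at p*, calibrate) recovers p* to floating
precision. `p` is also a first-class sensitivity parameter
(`epi.failure_prevalence`).

Two correct-result accountings are implemented because the published
counts cannot all be reproduced by the textbook formula. The
prevalence-weighted expected accuracy `N·(p·Se + (1−p)·Sp)` is bounded
below by min(Se, Sp) per patient; the published plasma-only fraction
(795,342/814,066 = 0.9770) lies *below* the attainable range
[0.983, 0.994], so it cannot arise from that formula. The product model
`N·Se·Sp` (a patient is correct when neither error type occurs)
reproduces the plasma-only count to +0.011% and is the default for
reference comparisons; it runs 0.1–0.4% high for the dried scenarios,
whose exact published accounting is not recoverable from the main text.
These residuals are reported, not absorbed. Prospective analyses should
prefer `prevalence_weighted`.

The dried-specimen repeat volumes carry a related residual: under the
calibrated p, the partial-DBS dried volume computes to 304,861 versus
306,860 published (−0.65%), while the PSC volumes agree within 0.2%.
Tests assert dried volumes to 1%.

## Costing

Unit costs per test (USD, Roche platform pricing, single lab-analysis cost
per specimen regardless of platform): plasma 0.31 + 0.87 + 17.22 = 18.40;
DBS 0.92 + 0.47 + 17.54 = 18.93; PSC 5.00 + 0.47 + 17.54 = 23.01
(consumables + collection overhead + laboratory analysis). Components are
non-negative; totals are always the exact component sum. Money is carried
as floats in USD with fractional cents; rounding (integers for totals, two
decimals for ratios) happens only at render time.

System cost = dried testing + plasma testing + facility visits + transport.
Visits are costed at one per test performed at $3.65; the published table's
visit-count and visit-cost rows are mutually inconsistent in places (e.g.
DBS-only 1,152,640 × 3.65 ≠ 4,220,251), and the computed product is used in
model mode. Transport is a per-scenario annual network cost passed through
from the panel. Result-return costs after analysis are excluded. Capital
and equipment amortisation are out of scope. Single-year horizon: no
discounting, inflation or currency conversion.

## Run modes

`model` computes everything from primitives. `golden` pins patient/test
counts and the visit/transport cost components to the published reference
rows carried in the packaged config, while testing components are
recomputed as pinned counts × current unit costs. This keeps ratio
identities and kit-price threshold analysis exact with respect to the
reference table while remaining responsive to the unit-cost parameters
being swept; all eleven published ratio values (29.23 through 100.64)
reproduce to ±0.01 in this mode.

## Cost-effectiveness analysis

Effects are patients with correct VL results (the machinery is generic
over any scalar effect). Strict dominance is pairwise (≥ effect at ≤ cost,
one strict). Extended ("weak") dominance is the standard iterative ICER
elimination: among remaining options ordered by effect, an option whose
incremental ratio exceeds that of the next more effective option is
removed; this converges to the lower convex hull of cost versus effect,
and a brute-force mixture oracle verifies the labels property-based in the
tests. Frontier ICERs are computed against the previous undominated
option; average ratios against the least costly scenario. Ties are broken
by scenario name for determinism. Willingness-to-pay thresholds, net
monetary benefit and probabilistic CEA are out of scope — the model is
deterministic throughout.

## Sensitivity and break-even analysis

Any scalar input is addressable by a dotted path
(`unit_costs.psc.consumables`, `assays.dbs.capctm.specificity`, …); sweeps
copy the config, so evaluation is side-effect free. One-way analysis
evaluates at (low, baseline, high); defaults for assay parameters are the
stored low/high evidence bounds and ±50% for costs, all overridable.
Two-way analysis fills a grid; a single row/column reproduces the
corresponding one-way result. Break-even solving uses Brent's method on
the metric difference and requires a bracketing sign change, reporting the
endpoint values otherwise; default tolerance is $0.005 on the metric
difference. When a swept assay point estimate leaves its stored bounds,
the bounds are widened to keep the ordering invariant.

On the packaged inputs the solver puts the PSC-kit break-even against
partial DBS at ≈$2.74 per correct result and ≈$1.73 per patient with a
result (golden mode). Recomputing from the published component rows gives
$2.74/$1.73 rather than the published $2.72/$1.72 — a ≤$0.02 residual
consistent with the published rows' own internal rounding; tests accept
±1%. The DBS sensitivity/specificity break-evens (quoted as 95%→85% and
94%→89% deteriorations) depend on the under-specified correct-result
formula and are asserted at property level only (a crossing exists and
lies in the stated region).

## Numerical choices

- Counts round half away from zero, per specimen cell, at report time.
- Platform-mix weights must sum to 1 within 1e-9; dominance tie tolerance
  1e-12; threshold root tolerance 1e-10 on the parameter.
- Panel generation is deterministic given the seed
  (`numpy.random.default_rng`); identical config + seed gives
  byte-identical CSV outputs (manifest timestamps aside).
- Validation returns findings (one per violation, naming field and value)
  rather than raising per field; loading raises with all findings listed.

## Problem sizes

The packaged analysis runs five scenarios over a 1,041-facility panel
(1.2M patients); the full test suite, including the property-based
dominance-oracle and calibration-recovery checks, completes in a few
seconds on one CPU.

## Known limitations

Beyond the scope exclusions above: demand-side behaviour (adherence,
refusals) is reduced to flat multipliers; assay performance estimates for
DBS and PSC come from different study populations and are treated as
fixed; sample rejection, assay failure and turnaround time are not
modelled; and point-of-care testing is not a comparator.
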