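# vlcost

Cost and impact modelling for scaling up HIV viral-load (VL) testing with
plasma, dried blood spot (DBS) and plasma separation card (PSC) specimens.

Routine VL monitoring of patients on antiretroviral therapy (ART) is
standard of care, but plasma specimens need centrifugation, cold chain and
fast transport, so patients at small or remote facilities often go
unmonitored. Dried specimens (DBS, and the newer PSC) remove the logistics
constraint at the cost of extra misclassification at the 1000 copies/mL
failure threshold — DBS more so than PSC, which in turn costs more per
collection kit. `vlcost` is for health economists and laboratory-network
planners weighing these trade-offs at national scale: it computes, for any
assignment of specimen types to facility strata, how many patients gain
access, how many receive a *correct* VL result, what the programme costs,
and which options are (weakly) dominated.

## The model

A facility panel (output of an upstream geospatial transport model, or a
synthetic stand-in) stratifies facilities into high-volume sites (≥10
VL/day, daily plasma routes), low-volume reachable sites, and sites
unreachable for plasma transport. Annual access applies flat multipliers:
80% of ART patients at high-volume sites (any specimen), 40% at low-volume
sites with plasma rising to 80% with dried specimens, and 80% at
unreachable sites once dried specimens open them.

Each tested patient has an initial VL; every screen positive gets one
confirmatory repeat, so tests per patient are `1 + q` with positivity

```
q = p·Se + (1 − p)·(1 − Sp)
```

where `p` is the true prevalence of virological failure and `(Se, Sp)` the
effective sensitivity/specificity of the scenario's specimen–platform mix
(volume-weighted over CAP/CTM and Cobas 8800 for dried specimens). `p` is
calibrated by inverting this relation against the observed plasma-only
cascade (930,982 tests for 814,066 patients ⇒ p ≈ 0.1409). Correct results
are counted per patient as `Se·Sp` (product model, the reporting default)
or `p·Se + (1 − p)·Sp` (prevalence-weighted, for prospective analyses).

Annual system cost sums four components — dried-specimen testing, plasma
testing, facility visits (one per test at $3.65), and the scenario's
sample-transport network cost — and is divided by patients accessing and by
patients correctly classified. Scenarios are then ranked by correct
results; strictly and extendedly ("weakly") dominated options are
eliminated and incremental cost-effectiveness ratios (ICERs) computed along
the efficient frontier. A threshold solver finds break-even input values
(e.g. the PSC kit price equating two scenarios' cost per correct result).

## Worked example

```python
from vlcost import ViralLoadScaleUpModel

model = ViralLoadScaleUpModel.from_config(seed=1)   # packaged Zambia inputs
results = model.fit(mode="golden")                  # counts pinned to the published table
print(results.summary())
print(f"calibrated failure prevalence p = {results.failure_prevalence:.4f}")
```

prints

```
| quantity                                           | plasma_only | plasma_dbs | plasma_psc | dbs_only         | psc_only  |
|----------------------------------------------------|-------------|------------|------------|------------------|-----------|
| Patients accessing VL tests/y                      | 814066      | 965587     | 965587     | 965587           | 965587    |
| ART facilities reached                             | 800         | 1041       | 1041       | 1041             | 1041      |
| Patients with correct VL results                   | 795342      | 920243     | 929857     | 856476           | 884844    |
| VLs on dried specimens                             | …           | 306860     | 296308     | 1152640          | 1108200   |
| Cost of VLs on dried specimens                     | 0           | 5808860    | 6818047    | 21819475         | 25499682  |
| VLs on plasma specimens                            | 930982      | 810283     | 810283     | …                | …         |
| Cost of VLs on plasma specimens                    | 17130069    | 14909207   | 14909207   | 0                | 0         |
| Facility visits required                           | 931011      | 1117143    | 1106591    | 1152640          | 1108200   |
| Cost of facility visits                            | 3398191     | 4081157    | 4039542    | 4220251          | 4045952   |
| Transport cost                                     | 3264509     | 3637168    | 3637168    | 2390317          | 2390317   |
| Annual system cost                                 | 23792769    | 28436392   | 29403964   | 28430043         | 31935951  |
| Cost per patient with a VL result                  | 29.23       | 29.45      | 30.45      | 29.44            | 33.07     |
| Cost per patient with correct VL results           | 29.92       | 30.90      | 31.62      | 33.19            | 36.09     |
| Average cost per additional correct result vs base | …           | 37.18      | 41.71      | 75.85            | 90.98     |
| Incremental cost per additional correct result     | …           | 37.18      | 100.64     | Weakly dominated | Dominated |

calibrated failure prevalence p = 0.1409
```

Reading the table: plasma-only reaches 814,066 patients (795,342 correct
results) at $29.92 per correct result. Partial adoption of dried specimens
at low-volume and unreachable sites lifts access 19% to 965,587 patients;
plasma + DBS is the cheapest way to buy additional correct results ($37.18
each versus plasma-only), while plasma + PSC yields the most correct
results (929,857) at an ICER of $100.64 per additional correct result over
plasma + DBS. Full switches to dried specimens are dominated — they cost
more per correct result without adding access. Break-even analysis
(`vlcost.sensitivity.threshold`) shows the $5.00 PSC kit would have to fall
to ≈$2.74 for plasma + PSC to match plasma + DBS per correct result, and to
≈$1.73 to match it per patient with a result.

`mode="model"` recomputes every count from primitives instead of pinning
them to the published reference figures; `mode="golden"` is the default for
comparisons against the reference table. The same pipeline is exposed on
the command line (`vlcost run`, `vlcost fixture`, `vlcost sensitivity`,
`vlcost threshold`).

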