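# cfsa — comparative flux sampling analysis for strain design

`cfsa` finds metabolic engineering targets for **growth-uncoupled
production** in microbial cell factories. Given a genome-scale metabolic
model (GEM), a growth medium and a production pathway, it samples the
feasible flux polytope {v : S·v = 0, lb ≤ v ≤ ub} under three scenarios and
compares the resulting per-reaction flux distributions:

* **growth** — biomass flux v_bio ≥ α · max v_bio (FBA optimum), α the
  *optimality* fraction (default 0.90);
* **production** — product flux v_p ≥ α · max v_p, plus a parsimonious
  proteome-burden cap Σ_r |v_r| ≤ φ · min Σ_r |v_r| at maximal growth
  (pFBA minimum), φ the *flux fraction* (default 1.25);
* **slow growth** — a negative control with biomass capped at the highest
  growth rate compatible with the required production, but production left
  free.

Each scenario is sampled with the OptGP hit-and-run sampler, samples are
re-validated against every constraint, and per-reaction chains are screened
with the Geweke stationarity diagnostic. For each reaction the two-sample
Kolmogorov–Smirnov statistic KS1 (growth vs production) and KS2
(slow-growth vs production) quantify how much the flux distribution must
shift. Reactions passing the filter cascade (KS1, Bonferroni-corrected
p-value, minimum flux change, production-scenario standard deviation,
biomass-flux correlation, reaction category) are classified by the fold
change of mean absolute fluxes: > 1 → over-expression, < 1 →
down-regulation. Down-regulations whose production and slow-growth
distributions overlap (KS2 below threshold) merely track the slower growth
and are dismissed as false positives; down-regulations with near-zero
production flux and no essential gene are promoted to knock-outs.
Redundant same-pathway targets are clustered by absolute-flux correlation,
and each target lists its genes and potential off-target reactions.

The audience is metabolic engineers working with COBRA-style models
(SBML L3/FBC or cobra JSON) who want a ranked, filterable list of single
interventions rather than a growth-coupling design.

## Worked example

`python examples/01_end_to_end_toy_run.py` runs the complete method on the
built-in synthetic network — a carbon source feeding a precursor node from
which a biomass branch, a product branch and an overflow branch compete —
and prints (abridged):

```
production: {'max_growth': 3.96, 'pfba_min_total_flux': 56.14,
             'total_flux_cap': 70.175, 'max_production': 9.9,
             'product_lower_bound': 8.91}

          mean_growth  mean_production    ks1    ks2  fold_change   classification
BIOSYN          3.663            0.099  1.000  0.375        0.027   false_positive
PP1             0.248            9.158  1.000  0.994       36.879  over_expression
PP2             0.248            9.158  1.000  0.994       36.879  over_expression
NARt            0.248            9.158  1.000  0.994       36.879  over_expression
DEG             5.842            0.496  1.000  0.882        0.085  down_regulation
T_W             5.842            0.496  1.000  0.882        0.085  down_regulation
```

The production scenario pins product flux at 0.9 × 9.9 = 8.91 mmol/gDW/h
and caps total flux at 1.25 × 56.14. The product pathway (PP1, PP2, NARt)
must carry ~37-fold more flux than during growth → over-expression. The
overflow branch (DEG, T_W) competes for the precursor and must shrink even
relative to the slow-growth control (KS2 = 0.88) → down-regulation. The
biomass-precursor reaction BIOSYN also drops, but its distribution matches
the slow-growth control (KS2 = 0.38): its decrease is a by-product of slow
growth, not a production requirement, so the negative control flags it as a
false positive.

## Command-line use

```bash
cfsa sample --config run.yaml          # expensive stage, persists artifacts
cfsa filter --samples artifacts/ --ks1 0.75 --preset case-study
```

The filter stage is a pure function of the persisted artifacts and can be
re-run with different thresholds; a model hash refuses artifacts that do not
match. Outputs: `sampling_results.xlsx`, `filtered_results.xlsx` (one sheet
per classification, with equations, genes, off-targets and cluster ids),
CSV mirrors, and `targets_OV.pdf` / `targets_KD.pdf` distribution graphs.

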