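# Methods

## Model and procedure

The method operates on a constraint-based metabolic model: stoichiometric
matrix S, flux bounds lb ≤ v ≤ ub, boolean gene–protein–reaction (GPR)
rules, a biomass reaction and (after pathway insertion) a product exchange.
The steady-state flux polytope {v : S·v = 0, lb ≤ v ≤ ub} is sampled rather
than optimised: a single FBA optimum is one vertex of a typically large
optimal face, whereas the distribution of feasible fluxes carries
information about which reactions *must* change between phenotypes and
which are merely free to.

Three scenario polytopes are compared:

* **growth**: v_bio ≥ α · v_bio\* where v_bio\* is the FBA growth optimum
  and α ∈ [0, 1] is the optimality fraction. No total-flux cap.
* **production**: v_p ≥ α · v_p\* (product exchange optimum), plus
  Σ_r |v_r| ≤ φ · T\*, where T\* is the pFBA minimum of total absolute flux
  at maximal growth and φ ≥ 1 the flux fraction. The cap stands in for a
  finite proteome and suppresses futile cycles; its reference point is the
  *growing* phenotype, which is where the parsimony assumption is
  defensible.
* **slow growth**: v_bio ≤ (max growth attainable while v_p equals the
  minimal production rate), the product itself unconstrained, same cap.
  This is a negative control: a reaction whose production-scenario flux
  drop is reproduced here is responding to slow growth, not to production.

The minimal production rate for the slow-growth cap defaults to
α · v_p\* — the same minimum enforced in the production scenario — so the
control differs from the production scenario only in *which* constraint
binds.

Per reaction, the two-sample Kolmogorov–Smirnov statistic is computed for
growth-vs-production (KS1) and slow-growth-vs-production (KS2), with
asymptotic p-values Bonferroni-corrected over the reactions actually tested
(converged, per comparison family). With thousands of samples the test is
overpowered, so the KS statistic — the sup-distance between empirical CDFs,
a direct measure of distribution overlap — is the operative filter and the
p-value only a sanity gate.

Classification cascade (first failing filter records the rejection
reason): convergence; reaction category (required / boundary / blocked /
gene-less reactions can never be engineered); adjusted p; KS1; flux change
under the chosen metric; production-scenario standard deviation (broad
distributions mean production does not care about this reaction); |Pearson
r| with biomass flux over production samples. Survivors split on the fold
change of mean **absolute** fluxes (a reversible reaction that flips sign
but grows in magnitude is an over-expression, not a knock-down): fold > 1 →
over-expression; fold < 1 → down-regulation candidate, then KS2 <
threshold → false positive, else mean |v| in production < ko_zero_tol and
no essential gene/reaction → knock-out.

Targets are clustered per stratum (OV separately from KD/KO) by
average-linkage hierarchical clustering on 1 − |r| of absolute fluxes over
production samples, cut at 1 − cluster_corr_min, so that runs of a linear
pathway collapse into one intervention group. For every target gene, all
other reactions sharing that gene are listed as potential off-targets.

## Parameters

| parameter | default | unit / range | rationale |
|---|---|---|---|
| optimality α | 0.90 | [0, 1] | high production while still sampling sub-optimal phenotypes |
| flux fraction φ | 1.25 | ≥ 1 | moderate proteome slack above the pFBA minimum |
| n_samples | 10 000 | per scenario | stable ECDFs; desk-scale studies use 1 000–2 000 |
| thinning | 100 | steps | decorrelates hit-and-run chains on genome-scale models; 10 suffices on the ~13-reaction toy polytope |
| KS1, KS2 minimum | 0.75 | [0, 1] | recommended default; the case-study preset keeps it |
| p_adj_max | 0.05 | | weak filter by design (overpowered test) |
| min_change | 0.001 | mmol/gDW/h | default preset; the `case-study` preset uses 0.01 |
| max_std_production | 50 | mmol/gDW/h | excludes broad, production-indifferent distributions |
| biomass_corr_max | 0.9 | [0, 1] | growth-coupled reactions are handled by the slow-growth control; the correlation filter is a cheap pre-screen |
| ko_zero_tol | 1e-6 | mmol/gDW/h | numerical zero for knock-out promotion |
| cluster_corr_min | 0.95 | [0, 1] | near-redundant targets only |
| growth_cutoff_fraction | 0.01 | of wild-type growth | essentiality threshold; essentiality uses the analysis medium |
| Geweke z threshold | 1.96 | | per-chain default; see below |

### Convergence screening at desk scale

The Geweke diagnostic compares the mean of the first 10% of a chain with
the mean of its last 50%, z = (m₁ − m₂) / √(s₁²/n₁ + s₂²/n₂), using each
segment's variance of the mean (chains are pre-thinned, so no spectral
correction is applied; constant chains return z = 0 by convention). A
per-chain cutoff of 1.96 falsely discards ~5% of perfectly stationary
chains. On a genome-scale model that is background noise; on a ~13-reaction
model it can randomly delete an entire pathway, because reactions in series
carry identical flux and fail together. Small-model studies therefore use
`familywise_z_threshold(n_reactions × n_scenarios)` — the two-sided normal
quantile at 0.05 / n_tests — which controls the family-wise false-exclusion
rate at 5% instead. Both are exposed in the run config.

## The synthetic model

`make_toy_gem` builds a deterministic ~13-reaction network emulating the
situation that makes the comparison informative: a single carbon uptake
(10 mmol/gDW/h) feeding a precursor node where three branches compete —
biomass synthesis (1 precursor + 2.5 ATP per unit), a product pathway
(1 precursor + 1 ATP) and a gene-bearing overflow branch. Glycolysis
co-produces ATP 1:1 with precursor, and an unbounded ATP-maintenance drain
gives the energy balance slack, so the overflow flux is *not* a pure
function of growth — the property the slow-growth control must exploit to
separate a true down-regulation (overflow) from a biomass component
(precursor assembly, whose flux is proportional to growth). Optional
motifs: an isoenzyme pair (OR-rule essentiality), a futile cycle (pFBA cap
behaviour), a gene-less dead-end (blocked category), extra linear steps.

Expected labels are not hard-coded: they are derived from per-scenario
flux-variability intervals (production interval strictly above/below the
growth interval ⇒ over-/down-regulation).

What the toy model does **not** emulate: realistic biomass composition,
cofactor diversity, compartmental redundancy, thermodynamically infeasible
loops spanning many reactions, and the ~10³-reaction scale at which
convergence screening and Bonferroni correction operate in earnest. Passing
tests demonstrate the machinery — scenario arithmetic, constraint
integrity, statistical comparison, classification logic — not predictive
accuracy on a real organism. One stoichiometric artefact is worth noting:
at maximal growth the toy's overflow branch is *forced* (excess precursor
must drain), so its gene screens as essential; the knock-out-safety rule is
thereby exercised, and the branch is correctly reported as down-regulation
rather than knock-out.

## Numerical choices

* LPs are solved through cobrapy/optlang (GLPK). Σ|v| is linearised via the
  nonnegative forward/reverse variables of each reaction, both for the pFBA
  objective and for the cap constraint; sampled fluxes are reported net.
* Derived bounds are applied exactly; outward rounding by 1e-9 is applied
  only where a bound sits on an optimum (optimality = 1, flux fraction = 1,
  and the slow-growth biomass cap), where an exact bound could leave an
  empty interior.
* Sample validation replays steady state (|S·v|∞ ≤ 1e-6), bounds and the
  cap (tolerance 1e-6) independently of the sampler; reactions are means of
  ratios guarded by ε = 1e-9 (zero denominators give infinite fold change,
  classified from the numerator).
* Sampling is seed-reproducible at processes = 1; re-runs produce
  bitwise-identical matrices and workbooks (workbook zips are rewritten
  with fixed timestamps and sorted entries).
* Clustering treats constant columns as uncorrelated (r = 0); ties in the
  dendrogram are resolved by scipy's deterministic linkage.

## Design choices that were genuinely open

* **Unlisted exchanges** when applying a medium: uptake closed, secretion
  left open (minimal-medium semantics), with a `keep` mode for curated
  models.
* **Essentiality** is computed on the analysis medium with a 1% growth
  cutoff; no claim is made that other choices are wrong.
* **Bonferroni family**: each KS family (KS1, KS2) is corrected separately
  over the converged reactions of that comparison, not over all model
  reactions.
* **Growth scenario** constrains only the biomass *lower* bound; the upper
  bound stays free.
* **Change metric** for the `fold` option is |fold − 1|, so "change below
  threshold" reads uniformly across metrics.
* The desk-scale studies report with the biomass-correlation filter
  relaxed (threshold 1.0) so the slow-growth rule itself, rather than the
  correlation pre-screen, handles growth-coupled reactions; with defaults
  the same reactions are rejected one step earlier.

## Problem sizes used in tests and the acceptance script

Unit and property tests sample 200–1 000 points per scenario at thinning
5–10; the recovery study and the acceptance script use 2 000 points at
thinning 10 across 20 seeds. These sizes give stable ECDFs on the toy
polytope while keeping the whole suite fast.

## Known limitations

* Suggested interventions are individual; combinatorial effects and the
  quantitative strength of an up/down-regulation are out of scope.
* The flux-fraction cap transplants a growth-phase parsimony assumption
  into the production scenario; loop-less samplers would be the cleaner
  (and costlier) fix for thermodynamically infeasible cycles.
* KS statistics on heavily tied, near-degenerate distributions saturate at
  1; visual inspection of the distribution graphs remains the recommended
  final filter, particularly for reactions whose flux changes sign between
  scenarios (these are kept but flagged `direction_change`).
* Geweke screening assumes approximately independent post-thinning draws;
  severely autocorrelated chains inflate z and over-discard.
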