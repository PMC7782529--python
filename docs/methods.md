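# Methods

This note documents the models, parameter choices and numerical conventions
behind `metallonet`, and what its synthetic-data tests do and do not show
about real data.

## Pipeline overview

The package analyses metal-binding proteins in a case/control disease
setting (the motivating application is Parkinson's disease, PD):

1. **Grouping and networks.** Proteins are grouped by bound metal; groups
   with fewer than 10 proteins are dropped, and multi-metal proteins stay in
   every surviving group. Each group's metal protein network (metal-PN) is
   built by first-neighbor expansion in a reference protein–protein
   interaction (PPI) graph: the group's proteins plus their immediate
   interaction partners, with — by default — all reference edges induced on
   that node set. The reference text does not say whether edges between two
   non-seed neighbors belong to the network; the induced-subgraph reading is
   the default and a `star_only` flag keeps only seed-incident edges.
2. **Topology plausibility.** Seven topological parameters per network
   (node count, edge count, average degree, density, average clustering
   coefficient, characteristic path length and diameter; the path metrics on
   the largest connected component) feed a correlation PCA across metal,
   pathway and Erdős–Rényi random networks. The parameter set mirrors the
   headline "simple parameters" of the Cytoscape NetworkAnalyzer and is
   configurable; standardization is the default because the parameters differ
   in scale by orders of magnitude.
3. **Hub extraction.** Each metal-PN is decomposed into cohesive hubs by
   greedy cohesiveness maximisation (ClusterONE-style): f(V') =
   w_in/(w_in + w_bound + p·|V'|), growth by the single best
   add-boundary-node or remove-member step, overlap merging at
   ω(A,B) = |A∩B|²/(|A||B|) > 0.8, and filtering at minimum size 3 and
   minimum density 0.3. Defaults (p = 2, ω = 0.8, size 3, density 0.3) are
   the published defaults of that algorithm; hubs are ranked by
   cohesiveness (ties: size, then lexicographically smallest member) rather
   than a one-sided quality p-value — deterministic and monotone in the
   same quantity.
4. **Literature association.** Protein–disease association is pointwise
   mutual information over abstract co-occurrence,
   PMI = log2(n_xy·N/(n_x·n_y)), with document-level counting, exact
   uppercase-token matching for symbols (gene symbols collide with English
   words) and case-insensitive phrase matching for disease terms. Proteins
   with at least 3 co-occurring abstracts and positive PMI are called
   disease-associated; a hub is retained when it contains at least one.
   The PMI cutoff of 0 is a configurable assumption — the method defines a
   weighting but no published threshold.
5. **Expression meta-analysis.** Per dataset, a two-sided two-sample t-test
   per gene (pooled variance by default; Welch optional) on log2
   intensities; across datasets, Fisher's method X = −2Σln p ~ χ²(2k).
   By default all per-dataset p-values are combined; a
   `significant_only_fisher` fidelity flag reproduces the literal
   "combine significant p-values" reading, which is statistically unusual.
   For classification, datasets are merged on shared genes with a per-gene,
   per-batch location–scale adjustment (centre and scale each batch, restore
   the pooled moments). This is a deliberately hyperparameter-free stand-in
   for empirical-Bayes batch correction: identical intent, exactly testable
   (within-batch means agree to 1e-9 after adjustment), but it does not
   shrink batch effects across genes and will over-correct when a batch is
   severely group-imbalanced.
6. **Hub classification.** Each retained hub's member genes form a feature
   panel; a roster of ten classifiers (naive Bayes, logistic regression,
   LDA, k-NN, decision tree, random forest, gradient boosting, linear and
   RBF SVM, ridge) is evaluated under repeated stratified k-fold CV
   (10×10 by default). Confusion counts are pooled over folds and repeats —
   chosen over per-fold averaging for small-fold stability — and
   sensitivity, specificity, accuracy and Matthews correlation coefficient
   come from the pooled matrix. Features are standardized inside each
   training fold only. Hubs are ranked by median accuracy across the roster
   (mean and max available); the roster size is a parameter, not a
   compatibility promise about any specific 34-algorithm toolbox.
7. **Biomarker statistics.** Welch t-tests from group summary statistics
   (mean, SD, n) for serum/CSF metal concentrations (µg/L); qPCR relative
   expression by 2^−ΔΔCt with ΔCt = Ct(target) − Ct(housekeeping) and ΔΔCt
   the difference of group-mean ΔCt (the group-mean calibrator convention,
   recorded in the output); upper-tail hypergeometric gene-set enrichment
   with Benjamini–Hochberg adjustment (raw p also emitted, since the source
   analysis reports none); pairwise Pearson/Spearman correlations with
   pairwise-complete deletion for the metal–metal and metal–expression
   interdependency analysis. Candidate prioritization is a transparent
   co-annotation score — mean Jaccard similarity between gene-set annotation
   profiles of a candidate and the training proteins — a documented
   methodological substitution for web-service gene prioritizers, not a
   reimplementation of one.

Welch is the summary t-test default because the published cohort table shows
clearly unequal variances (e.g. copper SDs 127 vs 337); the pooled variant
is retained since the original analysis does not specify. Both reproduce
the six analytically reproducible significance bounds of that table. Three
CSF rows (copper, calcium, magnesium) are not reproducible from their own
printed summaries under any standard two-sided two-sample t-test (computed
p ≈ 0.08, 0.032, 0.0006 against printed bounds 0.029, 0.03, 0.00055); the
package reports them as findings rather than forcing them.

## Synthetic study conditions

The `synthetic_data` module generates every input with the structure the
analysis assumes. Defaults define the study conditions:

- **Interactome**: planted-partition graph, 220 proteins, ten communities of
  10–14 members (113 proteins), within-community edge probability 0.9,
  background 0.02. The first three communities are the disease signal:
  their members are literature-enriched and differentially expressed.
- **Metal annotations**: 12 metals; ten take one community each plus one
  borrowed member of another community of the same disease status
  (multi-metal proteins without signal/noise bridges); two are sparse
  background groups below the size-10 threshold, exercising the filter.
  Surviving groups are therefore all module-based, mirroring the functional
  coherence of real metal-binding families. (First-neighbor expansion makes
  any size-≥10 random protein set capture ≈20% of every community —
  1 − 0.98¹¹ — so a "random metal" above threshold would present a dense,
  possibly disease-associated community fragment as its top hub; a real
  concern for interpreting neighbor-expanded networks, documented here
  rather than emulated.)
- **Expression**: five case/control datasets of 20 vs 20 samples; Gaussian
  log2 intensities (baseline N(8,1), noise SD 1), additive per-dataset
  per-gene batch offsets (SD 1), planted genes shifted ±2 log2 units in
  cases with consistent sign (per-study noncentrality ≈ 6.3, so Fisher
  combination recovers every planted gene at α = 0.05).
- **Corpus**: 6000 abstracts, 30% mentioning the disease phrase; background
  symbol mention probability 3×10⁻⁴ per document, disease proteins 50-fold
  enriched in disease documents. These rates make null proteins rarely reach
  the 3-abstract minimum (mean null co-occurrence ≈ 0.5) while guaranteeing
  it comfortably for disease proteins (mean ≈ 27); a generated corpus that
  violates the guarantee raises instead of passing silently.
- **Cohort**: truncated-normal analyte marginals at the published serum
  (n = 87/87) and CSF (n = 42/42) means/SDs — the published coefficients of
  variation are small enough that truncation bias is negligible — linked by
  a Gaussian copula for configured correlation pairs; qPCR Ct values
  (housekeeping ACTB 18 ± 0.5; targets shifted ≈1 cycle in PD, SOD1 in the
  opposite direction).

What passing tests show: the implemented operators recover planted structure
of the kind the method assumes (dense modules, consistent expression shifts,
enriched co-mentions) at realistic sizes. What they do not show: performance
on real microarray artifacts (probe effects, heavy-tailed intensities,
confounded batches), on heavy-tailed literature symbol frequencies, or on
PPI degree distributions; no probe-level preprocessing is simulated, and the
published dataset-dependent numbers (24 metal groups, the 4384-protein
copper network, 75/39/36 meta-analysis gene counts, the published accuracy
ranges, the 56.6%/15% PCA variance split) are not reproducible without the
original data snapshots — the pipeline mirrors their table formats so real
inputs can regenerate them.

## Numerical conventions and edge cases

- Cohesiveness of a set with zero denominator (isolated singleton, p = 0)
  is 0; greedy moves require a strict improvement of 1e-12 to terminate on
  plateaus; move ties break lexicographically on node name.
- PCA component signs are fixed by making each component's
  largest-magnitude loading positive, with near-ties (within 1e-9) resolved
  to the first entry so float noise cannot flip a sign; constant parameter
  columns are dropped with a warning.
- Fisher combination rejects p = 0 and instructs the caller to floor
  explicitly; the meta-analysis floors at 1e-300. Combined p-values are
  sorted before summation so the result is exactly study-order invariant.
- Degenerate t-tests (zero variance in both groups, equal means) return
  p = 1 by convention.
- MCC is 0 whenever a denominator factor vanishes (e.g. one-class
  predictions).
- ER nulls match nodes and edges, G(n, M), by default; the node-only mode
  G(n, p) sets p to the source network's density. A finding from the
  density-matched design: the biological-vs-random contrast then lives
  almost entirely in the clustering coefficient, which loads on the third
  principal component, so separation in the first two components is weak;
  the headline two-group separation appears when random networks are
  sparser than the biological ones (as in the original comparison), which
  is how the 72-network demonstration is constructed.
- All randomness flows from a single seed recorded in the run manifest;
  generators, cross-validation folds and ER draws are pure functions of
  (config, seed).
- Stage outputs are digested into the manifest; a rerun with an identical
  config digest and verifiable outputs is reused rather than rewritten
  (`resume=True`).

## Problem sizes

The default synthetic workspace (220 proteins, 10 communities, 5 datasets of
40 samples, 6000 abstracts, 174-subject cohort) is sized so a full pipeline
pass, the recovery experiments (10 seeds for community recovery, 5 seeds for
hub-ranking recovery) and the calibration simulations (2000 null genes) run
in seconds to a few minutes on one CPU; the experiment grids use the fast
classifier subset (no tree ensembles) with 5-fold CV.
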