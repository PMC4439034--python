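# Methods

This note documents the models and procedures implemented in `sigselect`,
the parameters that matter, and the decisions taken where the methodology
admits more than one reasonable choice.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

The pipeline operates on log2 expression ratios (M values) — disease vs
control or knockout vs wild type — arranged gene × sample with class labels
on samples (ordered disease stages, or tumor subtypes).  M values are
assumed approximately symmetric around 0 for unregulated genes, which is
why simulated noise is Gaussian on the log2 scale and why the natural
two-fold regulation cut is |M| ≥ 1.

Duplicate gene rows (multiple probes per gene) are collapsed by the
arithmetic mean of their M values on read.

## Preprocessing

* **Fold-change prefilter.** A gene is kept iff |M| ≥ log2(fold) in at
  least ⌈fraction · n_samples⌉ samples, both boundaries inclusive
  (defaults: fold 2, fraction 0.20).  The ceiling convention is fixed here
  because "20% of the samples" is ambiguous for sample counts not divisible
  by five.  The filter defines the *gene universe* for everything
  downstream, including enrichment.
* **Ortholog integration.** Two matrices are joined on an ortholog map;
  one-to-many pairs are kept as separate rows (ids `"a|b"`) rather than
  collapsed — information-preserving, and collapse remains a downstream
  choice.
* **Trend smoothing.** Each gene's stage-ordered series is replaced by its
  weighted moving average (default window 4 — one disease stage's worth of
  replicates — uniform weights; the source methodology specified "weighted"
  without weights, so arbitrary non-negative weights are configurable).
  The window is centred (right-biased for even windows); at the series ends
  it is truncated and renormalized, never padded.  The moving average is
  the "trend component" of the time-course decomposition; everything it
  removes is treated as random-plus-cyclic variation.  A full seasonal
  decomposition is unidentifiable with ~4 samples per stage.

  Note that smoothing is applied once, before fold partitioning — as in the
  study design it mirrors — so it deliberately shares information across
  folds.  It also induces within-stage correlation for *all* genes, which
  inflates univariate scores uniformly; its stabilizing effect on selection
  is therefore only expected within a deregulated (prefiltered) gene
  universe, and that is how the stabilization property is measured.

## Scores and discretization

Mutual information uses the plug-in estimator in bits on discretized
values.  Default discretization is equal-frequency with 3 bins (robust at
small n; ties keep input order via a stable sort and may straddle a
quantile; a constant vector maps to one bin); a sign-threshold mode bins at
the natural ±1 two-fold cut.  Normalized MI is I/√(H·H), defined as 0 when
either entropy vanishes.  The plug-in estimator is biased upward by roughly
(B−1)²/(2N ln 2) bits at N samples and B bins; this bias cancels in
comparisons between genes but makes small absolute MI values
uninterpretable — one reason sample sizes below ~10 per class make the
MI-driven searches unreliable.

Univariate scores: F is the one-way ANOVA statistic; GS1 is the maximum
over class pairs of |μᵢ−μⱼ|/(sᵢ+sⱼ); GS2 is BSS/WSS.  The GS1/GS2
definitions follow the Golub signal-to-noise and BSS/WSS conventions; the
original reference for these names is not accessible, so these are
documented substitutes.  Denominators carry ε = 1e-12 so zero-variance
degenerate classes do not error.

GO redundancy is average pairwise Jaccard overlap of term sets (pairs with
two empty sets contribute 0).  Semantic (information-content) similarity is
out of scope.  When no dedicated annotation is supplied, the pipeline
derives one from the gene-set collection (genes sharing a pathway share a
term).

## Search strategies

* **RFE.** With gene g excluded, every sample is the discretized vector of
  the remaining genes; coefficient I(g) is the sum of sample-pair MI over
  between-class pairs minus the sum over within-class pairs.  A gene whose
  exclusion leaves the best separation is the least needed, so the m genes
  with the *largest* coefficient are removed per iteration (m defaults to
  ~1/15 of the universe; the x + y schedule bounds iterations).  Redundancy
  variants form coefficient II by *adding* the gene's average pairwise MI
  with the subset (RFE_MR) or its GO similarity (MinR_MinGO) — redundant
  genes removed sooner — while MaxR_MaxGO subtracts the GO similarity,
  protecting co-functional genes.  The removal direction was validated on
  planted data: with it, planted genes are eliminated last; with the
  opposite sign they are eliminated first.
* **MRMR.** Forward; candidate score = NMI(g; class) / mean MI(g, selected),
  the denominator floored at ε_red = 1e-6 bits so the first pick is the
  max-relevance gene.  Ties break toward the lexicographically smaller id.
* **Univariate forward.** Genes ranked once by GS1/GS2/F, prefixes grown in
  rank order.
* **GA.** Fixed-length chromosomes of distinct genes; fitness 1 − error;
  elitism (1 by default); roulette selection on min-shifted fitness;
  uniform crossover applied to parent pairs with probability
  crossover_prob, skipping position swaps that would duplicate a gene
  within a child; mutation replaces a position with a uniformly drawn
  unused gene.  Termination requires both generation > max_generations
  (default 100) and |least-squares slope of the per-generation minimum
  error over the last 20 generations| < 0.05; the 20-generation window is a
  choice (the stopping threshold was specified without one), and a hard cap
  of 4 × max_generations guards against pathological non-termination —
  with elitism the minimum-error series is non-increasing, so the slope
  criterion fires in practice.

**Selected subset.** Every run records the evaluated subsets and their
errors; the signature is the subset with minimum error.  Among equal-error
iterates the *first* is kept: the most parsimonious subset, i.e. the
smallest prefix for forward searches and the largest surviving set for
backward elimination.  With cross-validated errors quantized to multiples
of 1/n, plateaus of exact ties are common and this rule is what makes
selection reproducible across folds (the alternative — last iterate —
drags fold-specific noise tails into the signature and measurably degrades
fold-to-fold stability).

## Evaluation criteria

* **Wrapper.** Stratified k-fold CV misclassification (k = 5 by default,
  10 for the univariate hybrids), folds derived deterministically from the
  seed.  If the smallest class has fewer than k samples, k degrades to that
  class size.  `n_repeats` (default 1) averages over repeated stratified
  CV with shifted fold seeds; 2–3 repeats noticeably smooth the error
  curve that drives subset sizing.  Classifiers: linear SVM, Gaussian
  naive Bayes, kernel-density naive Bayes (per-class per-feature Gaussian
  kernels, Silverman bandwidth with a 1e-3 floor), and a tree-augmented
  naive Bayes network on median-split features (Chow-Liu tree on
  class-conditional pairwise MI, Laplace-smoothed CPTs).  The two naive
  Bayes configurations and the network classifier are this package's
  concrete choices for the loosely specified "two configurations of naive
  Bayes" and "BN".
* **Distance matrix.** Mean between-class minus mean within-class pairwise
  sample distance on the subset's rows, negated so every evaluator returns
  an error to minimize.  Pearson distance (1 − r of sample profiles) is
  the default; a single-gene subset has length-1 profiles with undefined
  correlation and falls back to Euclidean.  Because within-class profile
  correlation approaches 1 for any strongly informative pair of genes,
  this criterion structurally favours very small subsets; it is the
  natural criterion for the fixed-length GA (where subset size is pinned)
  and a poor one for sizing variable-length searches.
* **Cluster-external.** Every pool algorithm clusters the samples on the
  subset into as many clusters as classes; the partition with max Dunn or
  min FOM is scored by misclassification after optimal (Hungarian)
  cluster-to-class matching, which equals exhaustive label-permutation
  search.  The pool maps legacy names to: k-means, divisive (DIANA-style),
  a self-organizing-tree-style divisive 2-means, PAM k-medoids, CLARA
  (PAM on subsamples), and average/complete/single/Ward hierarchical
  linkage (AGNES = average); exact historical implementations are not
  reproduced.  The Dunn index returns +inf for all-singleton partitions
  (zero diameters); FOM is adapted to sample clustering by leaving out one
  *gene* at a time and scoring its RMS deviation around cluster means (a
  single-gene dataset clusters on itself, there being nothing to leave
  out).

## External resampling, stability, ensembles

Selection is external: the data is split into k stratified folds
(default 5), the search runs on each k−1 training split, and the held-out
fold supplies the error — for wrapper evaluators by training the named
classifier on the training split and scoring the held-out fold; for
distance/cluster evaluators by applying the criterion to the held-out
block alone.  Stability is the mean symmetric-difference (Hamming)
distance between the k subsets, reported both raw (AHD) and divided by the
gene-universe size (NAHD ∈ [0, 1]); both are emitted because published
ANHD values on this methodology exceed 1, so that normalization evidently
differed and cannot be recovered from the text.

Frequency aggregation ranks the union of fold subsets by selection
frequency (ties: mean within-subset insertion rank, then id), grows
prefixes on the full data, stops at the first strict error increase, and
returns the best prefix seen.  Cross-method aggregation reapplies the same
procedure with one vote per method's ensemble, so frequencies are
multiples of 1/n_methods.

## Enrichment

Gene sets are tested by the upper-tail hypergeometric probability
P(X ≥ overlap) against the *post-filter* universe (subsets are drawn from
the filtered list, so that is the correct reference population; whether
the original study used the filtered list or the whole platform is not
stated).  No multiple-testing correction is applied at the stated p < 0.05
rule, matching the source convention; a Benjamini-Hochberg option exists
but is off by default.  The pathway signature records, per set, the p per
selection run, its mean and population SD, and the frequency of runs with
p < α.  Being discrete, the test's attained level at the 0.05 cut lies
below 5%; the calibration check compares the empirical null rate to the
exactly computed attained level rather than to the nominal one.

## Cluster support (BP/AU)

Samples are clustered agglomeratively (complete linkage, Pearson distance
by default; deterministic tie handling follows the linkage
implementation's merge order).  Support: for each scale r in 0.5…1.4
(step 0.1), n_boot resamples of ⌈r · n_genes⌉ genes are drawn with
replacement and the samples reclustered; BP_r(node) is the fraction of
replicate dendrograms containing the identical sample set, and bp = BP at
r = 1.  The AU p-value comes from weighted least squares of
z_r = Φ⁻¹(1 − BP_r) on (√r, 1/√r) with binomial delta-method weights
n_boot·φ(z)²/(BP(1−BP)); au = 1 − Φ(v − c).  BP is clipped to
[1/(2 n_boot), 1 − 1/(2 n_boot)] before the probit; a node at BP ∈ {0, 1}
on every scale is unfittable and falls back to au = bp with a degenerate
flag.  n_boot < 100 is rejected (the fit is unstable below); the default
is 1000 per scale, standing in for the unspecified "thousands".
Highlighting returns the maximal proper nodes (the root excluded) with
au above the threshold, default 0.95.

## Survival stage

DEG filtering is a pooled-variance two-sided two-sample t test (Welch is a
config option; the source says only "two sample t test"), genes at
p < 0.001 by default.  Kaplan-Meier estimation and the log-rank test are
delegated to lifelines (events precede censorings at tied times, the
standard convention); the test suite checks both against hand-computed
event-table arithmetic.  Signature validation clusters the independent
cohort on the signature genes present (complete linkage, Pearson), cuts at
n_clusters (default 3), and reports the log-rank chi-square, p, per-cluster
KM curves and the assignment; a cut into as many clusters as samples is
rejected as degenerate.

## Synthetic data

The generator emulates the statistical regimes the pipeline assumes:

* **Progression.** Ordered stages (default steatosis → NASH → HCC, 5
  replicates each).  Planted genes follow monotone stage profiles with
  gene-specific onset — a linear ramp stepping by `effect_size` (log2
  units) at every boundary, or a single `effect_size` step at one boundary
  — with alternating sign, centred so M values stay symmetric around 0.
  The onset diversity makes the planted set *jointly* informative: a set
  of identical staircases would be maximally mutually redundant, which
  both defeats redundancy-penalizing searches by construction and makes
  any subset-sizing rule ill-posed (after a few shared-pattern genes the
  error curve is flat).  Gene-specific deregulation points are also the
  realistic time-course picture.  Redundant blocks are ρ·source +
  √(1−ρ²)·noise copies of randomly chosen planted genes (controllable
  Pearson r); remaining genes are N(0, noise_sd²) noise, default
  noise_sd 0.5 log2 units.
* **Survival.** Samples split into two latent subtypes (odd counts put the
  extra sample in the baseline arm); the first n_informative genes get a
  ±effect_size/2 shift by subtype; event times are exponential with rates
  differing by `hazard_ratio` (baseline 1/365 events/day, i.e. median
  survival ≈ 8 months); independent Uniform(0, u) censoring with u solved
  numerically so the expected censored fraction equals `censor_fraction`.
  Exponential times make log-rank power predictable in closed form.
* **Gene sets.** A designated "true" pathway concentrates
  `enriched_fraction` of the planted genes (padded with non-planted
  genes); background pathways are uniform draws, each gene in at most
  `max_sets_per_gene` (default 3) sets.

What the generator does *not* emulate: probe-level array artifacts, batch
effects, heavy-tailed or gene-dependent noise, correlated noise between
non-block genes, and non-proportional hazards.  Passing tests therefore
demonstrate correctness of the machinery and its behaviour under the
assumed statistical structure, not performance on real arrays.

## Problem sizes and measured properties

The test suite and acceptance script run at desk scale, chosen so each
property is measured where it is identifiable:

* Planted-gene recovery: 60 genes, 10 planted, 15 samples/class, effect
  2·σ (1.0 vs noise 0.5), no redundant blocks; every method is paired
  with the Gaussian-naive-Bayes wrapper (k = 10, 2 repeats) except the GA,
  which uses its natural fixed-length pairing, the distance criterion.
  The NB wrapper is the sharpest subset-sizing signal available here: its
  error degrades measurably per irrelevant feature, giving an interior
  minimum near the planted set, whereas the SVM plateaus (irrelevant
  features are ignored) and the distance criterion collapses to 1–2 gene
  subsets.  Redundant blocks are excluded from this measurement because
  ρ = 0.8 copies are statistically interchangeable with their sources,
  making named-gene recovery ill-posed; copy-avoidance is tested
  separately.  Recovery is reported as the mean over replicate datasets
  per method (five in the acceptance test), reflecting the stochastic
  nature of the property.
* Smoothing stabilization: 100 genes, 10 planted, 8 samples/class, effect
  1·σ, two redundant blocks, 1.5-fold prefilter, F-ranking with the
  5-fold SVM wrapper, window 4 — a regime where CV errors bottom at
  interior minima rather than saturating at 0, which is where the
  stabilizing effect of smoothing on fold-wise selection is expressed.
* Cluster support: two planted sample blocks at 3·σ separation, 200
  genes, n_boot = 1000 over 10 scales.
* Calibration: 5000 null genes for the t filter; 1000 log-rank replicates;
  1200 null (set, run) enrichment pairs.

## Known limitations

* The RFE coefficient is O(n_pairs · |subset|) per iteration even
  vectorized; universes beyond a few thousand genes need a coarser removal
  schedule (larger m).
* MI-based searches are unreliable below ~10 samples per class (plug-in
  bias swamps weak relevance).
* Subset sizing by minimum cross-validated error is intrinsically noisy;
  on a given dataset realization any method can land one or two genes
  short of the planted set.  The resampling ensemble mitigates but does
  not eliminate this.
* The SOTA/CLARA/DIANA pool members are small-n reimplementations of the
  algorithmic ideas, not faithful ports of the historical packages.
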