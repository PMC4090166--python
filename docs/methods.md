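# Methods

This note documents the model, the estimators, the defaults and the design
choices behind `coexprior`, and what the synthetic benchmarks do and do not
demonstrate.

## Co-expression model and combination across individuals

Co-expression of two genes within one individual is summarized by the
sample correlation coefficient of their log-intensity vectors across that
individual's samples.  Pearson's r is the default (it is the efficient
estimator under approximate bivariate normality of log intensities and
detects negative as well as positive relationships); Spearman's coefficient
— implemented exactly as Pearson applied to within-gene average ranks — is
available as a robustness check against outliers.  Correlations need at
least three samples; genes with zero sample variance have no defined
correlation and are dropped from the panel with a logged warning rather
than assigned r = 0.

When a resource contributes several individuals from the same time period,
their correlation matrices are combined entry-wise as a weighted sum
Σᵢ wᵢ·rᵢ.  The weight of individual *i* is the normalized inverse of
vᵢ, the sample variance (ddof = 1) of the off-diagonal entries of that
individual's reference-set correlation matrix:

    wᵢ = (1/vᵢ) / Σⱼ (1/vⱼ)

so weights are nonnegative, sum to one within a time period, and penalize
individuals whose correlation structure is more variable.  The variance is
computed over reference-set pairs (the panel the analysis is about), using
each unordered pair once.  Raw r values are combined, not Fisher-z
transforms: with weights summing to one the combination is convex, so the
combined matrix inherits symmetry, unit diagonal and entries in [−1, 1]
directly.  A single-individual (pooled) resource skips weighting.

## Edge significance: the genome-wide top-5% rule

An edge is significant when the combined |r| strictly exceeds the
empirical `quantile`-quantile (default 0.95) of |r| over the whole dataset.
The genome-wide distribution is estimated from a seeded random sample of
distinct gene pairs (default 10⁵ in the pipeline; all ~n²/2 pairs would be
wasteful at genome scale) and the quantile is nearest-rank — the
⌈q·n⌉-th order statistic — so the cut-off is a value actually observed and
the estimate is deterministic given the seed.  Fewer than 100 sampled
pairs is rejected as unstable.

## Connectivity scores

For candidate *c* against reference set R with cut-off t:

* K\*(c) — the number of reference genes g with |r(c, g)| > t;
* K(c) — the sum of |r(c, g)| over those same genes.

Each contributing edge has |r| ∈ (t, 1], giving the invariant
t·K\* ≤ K ≤ K\*; both scores are nonincreasing in t.  The absolute value
means negatively correlated reference genes count as evidence, consistent
with the role of negative co-expression in neural gene networks.  A
candidate may not belong to the reference set (its self-correlation of 1
would inflate the score).  Leave-one-out connectivity applies the same
scoring to each reference gene against the remainder, quantifying the
coherence of the reference network itself.

## Empirical FDR and selection

Random gene sets of the same size as the candidate list are drawn without
replacement from genes belonging to neither the reference nor the candidate
set — the null sets must not carry the signal being tested — and scored
identically.  For a threshold T:

    eFDR(T) = mean over resamples of #{random K > T} / #{observed K > T}

"Exceeds" is strict on both sides.  Where no observed candidate exceeds T
the ratio is undefined and reported as missing.  Ratios above 1 are
truncated to 1 for reporting; the raw ratio is retained.

The default threshold grid contains, for every unique observed K value,
both the value itself and the floating-point number just below it.  The
curve is a step function of continuous T whose observed-exceedance count
changes exactly at observed scores; the grid point just below the m-th
largest score is the threshold that admits the top m candidates, and
omitting those points would make the top-1 selection unreachable under the
strict inequality.

The raw curve is noisy, so it is monotonized scanning from high thresholds
downward: a threshold's eFDR is never reported lower than that of any
stricter threshold above it (a running maximum going down, equivalently the
upper envelope seen from above).  This makes the curve nonincreasing in T
and means `chosen_T` — the smallest T with eFDR ≤ target — is the point
where the curve crosses the target rate coming down from above; an isolated
noise dip at a lax threshold cannot claim the target while stricter
thresholds still fail it.  Candidates with K > chosen_T are prioritized; if
no threshold reaches the target, nothing is (with a warning).  The default
target rate is 0.25: the analysis is a screen for follow-up, where one
false lead among four discoveries is an acceptable price for sensitivity.

Calibration of this procedure is measured, not assumed: on all-null
benchmarks (candidates exchangeable with the resampled sets; 29 reference
genes, 50 candidates, 200 resamples, 200 replicates) the realized
false-discovery proportion at `chosen_T` averages ≈ 0.25–0.33 depending on
the seed chain, consistent with the nominal 0.25 given the Monte-Carlo
noise of the estimator at these set sizes.  Note that an eFDR target of
0.25 *by design* tolerates roughly one decoy per three true discoveries;
with 10 strongly planted candidates the expected number of admitted decoys
is ~2–3, and individual runs vary around that.

## Angular ordering and networks

PCA is performed on the correlation matrix itself (eigendecomposition;
genes are the objects, loadings come from the eigenvectors), matching the
corrplot-style practice of ordering a correlation matrix by its own leading
structure.  Each gene's angle is atan2(PC2 loading, PC1 loading) mapped to
[0, 2π); genes are sorted by ascending angle.  Eigenvector sign ambiguity
is fixed by forcing each component's largest-magnitude loading positive
(first occurrence on ties); angle ties break by gene symbol.  This makes
the ordering deterministic and invariant to input gene permutations (up to
exactly tied angles, which only arise in artificially symmetric matrices).
Applying one dataset's ordering to another's matrix (`cross_order`) tests
whether cluster structure replicates; thresholded networks keep signed r on
every edge with |r| strictly above the cut-off and are exported as TSV edge
lists and GraphML with reference/candidate node roles.  No layout is
computed, and no heatmap rendering is built in — the ordered-matrix TSV is
the exchange format for plotting.

## Group comparisons

Whether externally flagged candidates (e.g. intolerant genes, damaging
variants) have higher connectivity is tested with a one-sided two-sample
Mann–Whitney rank-sum test, alternative "flagged higher".  The asymptotic
p-value uses the normal approximation with continuity and tie correction
(scipy); the permutation p-value shuffles group labels (default 1000
times) and uses the add-one estimator (1 + #{U_perm ≥ U_obs})/(1 + N), so
it is never exactly zero.  Genes a resource did not assess are excluded
from that resource's test, not treated as unflagged.  On small samples
(n ≤ 12) both p-values track exhaustive enumeration within 0.02.

## Probe collapsing and gene matching

Probe-level arrays are collapsed to one row per gene by keeping the probe
with the highest median expression across the panel's samples, computed per
individual panel; an alternative rule keeps the probe with the longest
transcript where the probe map carries lengths.  Ties break on the
lexicographically smallest probe id.  Gene symbols are matched
case-sensitively after whitespace trimming with no alias resolution;
requested genes absent from a dataset are reported as missing data, not
errors, and excluded from that dataset's analysis.

## Synthetic data: what it emulates and what it does not

The generator uses one latent factor per module and per sample: a member
gene with signed loading λ takes λ·f + √(1−λ²)·ε, background genes are pure
ε ~ N(0, σᵢ), with independent factors and noise per individual.  At unit
noise the population correlation of two members is exactly λᵢ·λⱼ, the
closed form the tests check; per-individual noise SDs make combination
weights genuinely differ.  This emulates the features downstream stages
consume — planted positive/negative co-expression, approximately normal
expression, heterogeneous individuals — and nothing else.  It does not
model probe-level artifacts, normalization effects, sample dependence
within a brain, heavy-tailed intensities, or overlapping modules.  Passing
tests therefore demonstrate the correctness and calibration of the
*method* under its own assumptions, not its performance on any real
expression resource.

Benchmark defaults are fixed once: 29 reference genes, module loading
λ = 0.9, 10 true candidates, 50 decoys, 4 individuals × 100 samples, and a
1200-gene universe — desk-scale stand-ins for a brain atlas' handful of
donors with hundreds of arrays each and ~20k genes.  The all-null
calibration benchmark uses 2 individuals × 60 samples and a 300-gene
universe with 200 resamples so that 200 replicates run in seconds.

## Numerical and reproducibility choices

* Correlation matrices are symmetrized and clipped to [−1, 1] after
  computation to remove floating-point fuzz; diagonals are set to exactly 1.
* All sampling (pair sampling, null gene draws, eFDR resamples, label
  permutations) takes an explicit integer seed; the pipeline derives fixed
  per-stage seeds from one master seed, and a rerun with the same config is
  byte-identical.
* Ranks in connectivity tables are assigned by descending K with ties
  broken by gene symbol; probe-collapsing ties by probe id; angle ties by
  gene symbol — every ordering in the package is deterministic.
* Empty files, ragged rows, non-numeric or empty cells, duplicate gene or
  sample identifiers are parse errors naming the offending line; missing
  values are rejected rather than imputed, since input matrices are
  expected to be complete, pre-normalized exports.

## Known limitations

* The inverse-variance weights treat each individual's correlation
  variance as exchangeable noise; systematic differences between
  individuals (age, dissection) are averaged over, not modelled.
* Connectivity is a sum over direct correlations with reference genes; an
  eigengene/principal-component formulation would use indirect structure
  and is a natural refinement.
* The eFDR is an estimate from finite resampling; with few candidates its
  threshold is noisy, and at a 0.25 target a handful of false leads among
  the prioritized genes is expected behaviour, not a defect.
* Nonlinear dependence measures are deliberately out of scope; the method
  assumes a linear (or rank-linear) co-expression signal.
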