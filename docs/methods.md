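# Methods

## The model behind the single-read clock

Age-associated DNA methylation at an amplicon's neighbouring CpG sites is
treated as *stochastic drift*: each site i accumulates methylation
independently of its neighbours, with a methylation frequency that is
(approximately) linear in age. Formally, for an amplicon with n ordered
CpG sites, per-site linear functions F_i(a) = slope_i · a + intercept_i
are fit by unweighted ordinary least squares of per-sample site frequency
on chronological age, and clipped to probabilities
p_i(a) = min(max(F_i(a), 0), 1). A read's binary pattern
P ∈ {0, 1}ⁿ then has likelihood

    Pr(P, a) = ∏_i [ p_i(a) if P_i = 1 else 1 − p_i(a) ].

The estimator is deliberately grid-based: Pr(P, a) is evaluated for a =
0, 1, …, 200 years, each pattern is assigned the maximizing age a_P (the
mean of the maximizing ages when the maximum is not unique — clipping
creates genuine plateaus), and a donor's age estimate is the
multiplicity-weighted mean of a_P over its reads. The independence
assumption is an empirical observation about age-associated regions, not
a convenience: between-site correlations of per-read calls at such
amplicons are near zero, and the bundled simulator reproduces exactly
this generative process, making the simulate → fit → predict round trip
the package's principal end-to-end check.

### Numerical choices

* Likelihoods are computed in log space (36-site products underflow in
  linear space), with an exact-zero short-circuit: a clipped p_i ∈ {0, 1}
  that contradicts the pattern forces Pr = 0 regardless of other sites,
  rather than relying on `exp(−inf)` arithmetic inside a matrix product.
* Tie detection uses a relative tolerance of 1e-12 on the maximum; exact
  float equality is fragile after the log/exp round trip. Tie-averaged
  a_P may be non-integer (150.0 for a plateau, 40.5 for adjacent maxima).
* Patterns with zero likelihood at *every* grid age get an undefined
  (NaN) a_P and are excluded from the sample mean with a count; they can
  arise once clipping produces exact 0/1 probabilities. No probability
  floor is applied by default.
* Missing calls ('.') have no analogue in the likelihood model, so the
  default policy drops the whole read; `missing_policy="marginalize"`
  instead skips the missing site's factor. `pattern_likelihood` itself
  always marginalizes, since dropping is a read-selection decision, not a
  likelihood one.
* Site frequencies for fitting are computed after the ≥ 10-occurrence
  pattern filter (the read-level processing order); `min_count=1`
  disables this, and is the right setting for amplicons long enough that
  nearly every read pattern is unique.

## Age transform and linear clocks

The transform F(a) = ln(a+1) − ln(adult_age+1) for a ≤ adult_age,
(a − adult_age)/(adult_age+1) above, with adult_age = 20 years, is
continuous and strictly increasing with F(20) = 0, and is inverted in
closed form. Methylation drifts markedly faster in childhood; fitting on
F(age) linearizes pediatric trajectories and demonstrably lowers the
median error on child-heavy cohorts (a directional test covers this).
Natural logarithms throughout.

Clocks are plain OLS — penalized regression is out of scope — and r² is
reported as the squared Pearson correlation of predicted versus actual
age (the scatterplot-annotation convention in this literature), not the
regression R² of a refit; median absolute error is in years. Predictions
are not clipped at zero by default. Missing betas drop the sample, in
both fit and predict: targeted panels are small and imputation would be
silent bias. Rank-deficient designs raise an error naming the collinear
CpGs (via pivoted QR).

## Multi-study CpG screening

A CpG is selected under a criterion (Pearson-age, Spearman-age, or
Pearson-log-age, ln(age + 1)) only if its correlation meets the cutoff in
*every* study of the collection. Decisions the screen bakes in:

* The cutoff is inclusive (|r| ≥ 0.5 by default); a `strict` flag
  switches to |r| > cutoff. The inclusive form makes the boundary
  testable.
* Per-study correlations must share one sign. A marker whose direction
  flips between cohorts is not a usable monotone age marker even if every
  |r| clears the bar; this is stated as an explicit, documented rule.
* Correlations are undefined (and fail the criterion) below three
  complete pairs or at zero variance — never coerced to a number.
  Missing betas are deleted pairwise.
* The cell-subset filter uses the population (1/n) variance of betas
  across purified subsets, threshold 0.02; CpGs with missing subset
  values are reported separately rather than silently excluded.

## Droplet PCR quantification

Channel concentrations use λ = −ln(1 − p_pos) with double-positive
droplets counted positive in both channels (standard duplex accounting;
the simulator validates it), and the methylation fraction is the rate
ratio λ_m/(λ_m + λ_u) — per-droplet volume factors cancel. A saturated
channel (no negative droplets) raises an error advising dilution. The
simulator places an *exact* composition — round(f · copies) methylated
molecules — uniformly at random over droplets, so its only noise is the
partitioning the correction models; the naive positives ratio is visibly
biased toward 0.5 at ~2 copies/droplet while the corrected estimator is
not, which is the reason the correction exists. Confidence intervals are
available only as an explicit seeded droplet bootstrap.

## Enrichment and descriptive statistics

Coverage windows around a CpG at position p are [p − 250, p + 251) in
0-based half-open coordinates — 501 bases, covering 250 bp on each side
*and* the site base itself. Coverage values are quantile normalized
across samples (rank → mean-of-sorted, average ranks for ties, so each
sample's sorted vector becomes identical), then compared between target
and background CpG sets by a two-sided Mann-Whitney rank test (per sample
and pooled); sidedness is a flag. Background sets are drawn seeded,
without replacement. Extracting coverage from alignments is out of
scope — the operation consumes a precomputed value-per-CpG table.

## What the simulators do and do not emulate

`simulate_reads` draws independent Bernoulli site calls at the clipped
linear frequencies — exactly the single-read model. It does not emulate
sequencing error, bisulfite-conversion failure, or PCR amplification
bias, so passing round trips demonstrate correctness of the estimator
under its own assumptions, not robustness to those artefacts.
`simulate_study_collection` adds per-(study, CpG) Gaussian baseline
offsets (default sd 0.02) and per-measurement noise (default sd 0.05) to
planted linear age trends (default slope 0.005/yr, baseline 0.2), betas
clipped to [0, 1], ages uniform on a stated range (log-uniform under the
pediatric-skew option). Real array data additionally carry probe-type
effects, cell-composition shifts and non-Gaussian batch structure that
the generator does not model. Substreams are derived from the root seed
by stable CRC32 hashing of sample/study identifiers, so any subset of
donors regenerates identically.

## Problem sizes

The bundled end-to-end checks use 50 donors × 1000 reads × 36 sites for
single-read recovery, 7 studies × 100 samples × 2000 CpGs (20 planted)
for the screen, 20,000 droplets × 10,000 copies × 100 replicates per
fraction for the droplet correction, and exhaustive 2ⁿ enumeration up to
n = 12 sites for likelihood normalization; the full suite and the
acceptance script each run in well under a minute on one CPU.

## Known limitations

* The single-read estimator is bounded by the grid (0–200 years); reads
  whose likelihood is maximized at a boundary pile up there, and
  sample-level means inherit a mild shrinkage toward the grid interior
  for extreme donors.
* Linear site models are a local approximation; strongly logistic
  trajectories are handled only through clipping.
* The screen's all-studies rule is conservative by construction: a CpG
  missing from one study's platform is ineligible rather than evaluated
  on the remaining studies.
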