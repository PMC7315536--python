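# strandage

Targeted epigenetic age prediction from DNA methylation, for forensic and
biomedical settings where a handful of assayed CpG sites must stand in for
a genome-wide array. The package covers the full targeted workflow:

* **Multi-cohort CpG screening** — select age-associated CpGs that pass an
  absolute-correlation cutoff (Pearson with age, Spearman with age, or
  Pearson with log age; default |r| ≥ 0.5) *in every study* of a training
  collection, after exclusion masks (SNP-associated, cross-reactive,
  cell-type variable, smoking-associated, sex-chromosome, platform).
* **Transformed-age linear clocks** — ordinary-least-squares clocks on
  beta values, optionally on the log/linear transformed-age scale
  F(a) = ln(a+1) − ln(adult_age+1) for a ≤ adult_age and
  (a − adult_age)/(adult_age+1) above it, inverted exactly for reporting.
* **Droplet digital PCR quantification** — duplex droplet tallies to a
  methylation fraction via the Poisson occupancy correction
  λ = −ln(1 − p_pos) per channel, f = λ_m/(λ_m + λ_u).
* **Single-read age prediction** — the package's core: each sequenced DNA
  strand's binary methylation pattern P over an amplicon's n CpG sites
  gets a likelihood Pr(P, a) = ∏ᵢ qᵢ, with qᵢ = pᵢ(a) for a methylated
  site and 1 − pᵢ(a) otherwise, where pᵢ(a) clips a per-site linear
  frequency-versus-age regression to [0, 1]. Each pattern is assigned the
  age a_P maximizing Pr(P, a) on a 0–200-year grid (ties averaged); a
  donor's estimate is the read-count-weighted mean of a_P, and the spread
  of a_P across reads reflects the heterogeneity of epigenetic aging
  among the sampled cells.
* **A matching stochastic simulator** — independent per-site Bernoulli
  reads and multi-study beta matrices with planted age-linear CpGs and
  batch offsets, so every pipeline is testable without external data.

## Worked example

Simulate four donors' per-strand patterns at a 36-CpG amplicon, fit site
models, and predict each donor back from its individual reads:

```sh
strandage simulate reads --n-sites 36 --ages 21,45,60,72 \
    --reads-per-donor 1000 --seed 7 --out patterns.tsv
strandage single-read fit --patterns patterns.tsv --meta meta.tsv \
    --min-count 1 --out sitemodels.tsv
strandage single-read predict --models sitemodels.tsv \
    --patterns patterns.tsv --min-count 1 --out predictions.tsv
```

`predictions.tsv`:

```
sample_id   amplicon_id   predicted_age  n_reads_used  n_reads_excluded
donor000    sim_amplicon  21.591         1000          0
donor001    sim_amplicon  45.02          1000          0
donor002    sim_amplicon  59.8           1000          0
donor003    sim_amplicon  72.797         1000          0
```

Each `predicted_age` is the mean over 1000 reads of the per-read
maximum-likelihood age; all four land within ~1 year of the simulated
donor ages (21, 45, 60, 72). `n_reads_excluded` counts reads whose
pattern had zero likelihood at every grid age or carried missing calls
under the default drop policy.

The same workflow is available as library functions
(`simulate_reads`, `fit_site_models`, `predict_sample_age`, …), alongside
`select-cpgs`, `fit-clock`/`predict-age`, `ddpcr-quant`, `patterns` and
`enrichment` subcommands for the other pipelines.

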