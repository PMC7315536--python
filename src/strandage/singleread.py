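"""Per-read (single DNA strand) maximum-likelihood age prediction.

Deep bisulfite amplicon sequencing reads out the binary methylation state
of every CpG on one DNA strand.  At age-associated regions these per-strand
patterns are stochastic rather than coherently modified: each site drifts
toward its age-dependent methylation frequency independently of its
neighbours.  That observation licenses a simple generative model, and the
model in turn yields an age estimate for every individual read:

1.  For an amplicon X with n_X ordered CpG sites, fit by linear regression
    the methylation frequency of each site i as a function of donor age a,
    giving linear functions F_{X,i}(a).
2.  Clip to probabilities: p_{X,i}(a) = min(max(F_{X,i}(a), 0), 1).
3.  Under site independence, a pattern P has likelihood
    Pr(P, a) = prod_i q_i with q_i = p_{X,i}(a) if site i is methylated in
    P and 1 - p_{X,i}(a) otherwise.
4.  Each pattern is assigned the age a_P maximizing Pr(P, a) over an
    integer grid from 0 to 200 years (ties averaged), and a donor's age
    estimate is the read-count-weighted mean of the a_P.

The spread of a_P across reads of one sample is itself informative: it
reflects the heterogeneity of epigenetic aging among the cells sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ReadPatternSet, SampleMetadata, filter_rare_patterns

__all__ = [
    "SiteAgeModel",
    "AgeGrid",
    "PatternAgeResult",
    "SampleAgePrediction",
    "fit_site_models",
    "site_probability",
    "pattern_likelihood",
    "grid_likelihoods",
    "predict_pattern_age",
    "predict_sample_age",
    "read_age_distribution",
    "read_site_models",
    "write_site_models",
]

TIE_RTOL = 1e-12  # relative tolerance declaring two grid likelihoods tied

MissingPolicy = Literal["drop", "marginalize"]


@dataclass(frozen=True)
class SiteAgeModel:
    """Linear model of one CpG site's methylation frequency versus age."""

    amplicon_id: str
    site_index: int  # 1-based position within the amplicon
    slope: float     # frequency change per year
    intercept: float  # frequency at age 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("site model parameters must be finite")


@dataclass(frozen=True)
class AgeGrid:
    """Inclusive age grid over which pattern likelihoods are maximized."""

    min_age: float = 0.0
    max_age: float = 200.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be below max_age")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def ages(self) -> np.ndarray:
        n = int(round((self.max_age - self.min_age) / self.step))
        return self.min_age + self.step * np.arange(n + 1)


@dataclass
class PatternAgeResult:
    """Maximum-likelihood age assignment for one methylation pattern.

    ``age`` is NaN when the pattern has zero likelihood at every grid age
    (possible once site probabilities clip to exactly 0 or 1); such reads
    are excluded from sample-level averages.  Tie averaging can make the
    assigned age non-integer.
    """

    pattern: str
    age: float
    max_likelihood: float
    count: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.age)


@dataclass
class SampleAgePrediction:
    """Read-weighted mean of per-pattern ages for one sample and amplicon."""

    sample_id: str
    amplicon_id: str
    age: float
    results: list[PatternAgeResult] = field(default_factory=list)
    n_reads_used: int = 0
    n_reads_excluded: int = 0


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_site_models(
    pattern_sets: Sequence[ReadPatternSet],
    meta: SampleMetadata,
    min_count: int = 10,
) -> list[SiteAgeModel]:
    """Fit per-site frequency-versus-age regressions from training samples.

    Each training sample contributes one methylation frequency per site
    (multiplicity-weighted across its reads, missing calls excluded), and
    each site gets an unweighted ordinary-least-squares fit of frequency on
    age.  Patterns rarer than ``min_count`` per sample are discarded first,
    matching the read-level processing order; pass ``min_count=1`` to fit
    on unfiltered patterns.
    """
    if not pattern_sets:
        raise ValueError("no training pattern sets")
    amplicon = pattern_sets[0].amplicon_id
    n_sites = pattern_sets[0].n_sites
    for rps in pattern_sets:
        if rps.amplicon_id != amplicon or rps.n_sites != n_sites:
            raise ValueError("all training sets must share one amplicon")

    freqs, ages = [], []
    for rps in pattern_sets:
        filtered = filter_rare_patterns(rps, min_count) if min_count > 1 else rps
        if not filtered.patterns:
            continue
        freqs.append(filtered.site_frequencies())
        ages.append(float(meta.table.loc[rps.sample_id, "age"]))
    if len(ages) < 3:
        raise ValueError(
            f"need at least 3 training samples with surviving reads, got {len(ages)}"
        )

    F = np.vstack(freqs)               # samples x sites
    a = np.asarray(ages, dtype=float)
    models = []
    for i in range(n_sites):
        y = F[:, i]
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            raise ValueError(f"site {i + 1}: fewer than 3 samples with coverage")
        slope, intercept = np.polyfit(a[ok], y[ok], 1) if np.ptp(a[ok]) > 0 else (0.0, y[ok].mean())
        models.append(SiteAgeModel(amplicon, i + 1, float(slope), float(intercept)))
    return models


def site_probability(m: SiteAgeModel, age: float) -> float:
    """Clipped per-site methylation probability p(a) = clip(slope*a + b, 0, 1)."""
    return float(np.clip(m.slope * age + m.intercept, 0.0, 1.0))


def _probability_matrix(models: Sequence[SiteAgeModel], ages: np.ndarray) -> np.ndarray:
    slopes = np.array([m.slope for m in models])
    intercepts = np.array([m.intercept for m in models])
    return np.clip(ages[:, None] * slopes + intercepts, 0.0, 1.0)  # ages x sites


def _encode_patterns(patterns: Sequence[str], n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (methylated, called) matrices, one row per pattern."""
    arr = np.frombuffer("".join(patterns).encode(), dtype=np.uint8)
    arr = arr.reshape(len(patterns), n_sites)
    return arr == ord("1"), arr != ord(".")


def grid_likelihoods(
    models: Sequence[SiteAgeModel],
    patterns: Sequence[str],
    grid: AgeGrid = AgeGrid(),
) -> np.ndarray:
    """Pr(P, a) for every pattern (rows) and grid age (columns).

    Missing calls contribute no factor (their site is marginalized out).
    Computed in log space; a site whose clipped probability is exactly 0 or
    1 and contradicts the pattern short-circuits that likelihood to an
    exact 0 rather than an underflowed product.
    """
    ages = grid.ages
    p = _probability_matrix(models, ages)            # A x S
    meth, called = _encode_patterns(list(patterns), len(models))
    unmeth = called & ~meth

    with np.errstate(divide="ignore"):
        logp = np.log(p)
        logq = np.log1p(-p)
    logp_safe = np.where(p > 0, logp, 0.0)
    logq_safe = np.where(p < 1, logq, 0.0)

    M = meth.astype(float)
    U = unmeth.astype(float)
    loglik = M @ logp_safe.T + U @ logq_safe.T        # N x A
    impossible = (M @ (p == 0).T.astype(float) + U @ (p == 1).T.astype(float)) > 0
    lik = np.exp(loglik)
    lik[impossible] = 0.0
    return lik


def pattern_likelihood(
    models: Sequence[SiteAgeModel], pattern: str, age: float
) -> float:
    """Pr(P, a) under site independence; '.' sites are skipped."""
    if len(pattern) != len(models):
        raise ValueError(
            f"pattern length {len(pattern)} does not match {len(models)} site models"
        )
    p = _probability_matrix(models, np.array([age]))[0]
    q = np.ones(len(models))
    for i, ch in enumerate(pattern):
        if ch == "1":
            q[i] = p[i]
        elif ch == "0":
            q[i] = 1.0 - p[i]
    return float(np.prod(q))


def predict_pattern_age(
    models: Sequence[SiteAgeModel],
    pattern: str,
    grid: AgeGrid = AgeGrid(),
    count: int = 1,
) -> PatternAgeResult:
    """Assign the grid age maximizing Pr(P, a); ties are averaged.

    Two ages tie when their likelihoods agree within a relative tolerance
    of 1e-12 of the maximum (exact float equality is fragile after the
    log/exp round trip).  A pattern impossible at every grid age gets a
    NaN age.
    """
    lik = grid_likelihoods(models, [pattern], grid)[0]
    best = float(lik.max())
    if best == 0.0:
        return PatternAgeResult(pattern, float("nan"), 0.0, count)
    tied = lik >= best * (1.0 - TIE_RTOL)
    return PatternAgeResult(pattern, float(grid.ages[tied].mean()), best, count)


def predict_sample_age(
    models: Sequence[SiteAgeModel],
    rps: ReadPatternSet,
    grid: AgeGrid = AgeGrid(),
    missing_policy: MissingPolicy = "drop",
) -> SampleAgePrediction:
    """Donor age as the read-count-weighted mean of per-pattern ages.

    ``rps`` is expected to be pre-filtered for rare patterns.  Reads with a
    missing call are dropped under the default policy or kept with the
    missing site marginalized out under ``missing_policy="marginalize"``.
    Patterns with zero likelihood everywhere are excluded and counted.
    """
    if len(models) != rps.n_sites:
        raise ValueError(
            f"{len(models)} site models for an amplicon with {rps.n_sites} sites"
        )
    excluded = 0
    items = []
    for pat, cnt in sorted(rps.patterns.items()):
        if "." in pat and missing_policy == "drop":
            excluded += cnt
            continue
        items.append((pat, cnt))

    results: list[PatternAgeResult] = []
    if items:
        lik = grid_likelihoods(models, [p for p, _ in items], grid)
        for (pat, cnt), row in zip(items, lik):
            best = float(row.max())
            if best == 0.0:
                results.append(PatternAgeResult(pat, float("nan"), 0.0, cnt))
                excluded += cnt
                continue
            tied = row >= best * (1.0 - TIE_RTOL)
            results.append(
                PatternAgeResult(pat, float(grid.ages[tied].mean()), best, cnt)
            )

    used = [(r.age, r.count) for r in results if r.defined]
    n_used = sum(c for _, c in used)
    if n_used == 0:
        age = float("nan")
    else:
        age = float(sum(a * c for a, c in used) / n_used)
    return SampleAgePrediction(rps.sample_id, rps.amplicon_id, age,
                               results, n_used, excluded)


def read_age_distribution(
    results: Iterable[PatternAgeResult],
    bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative read count per predicted-age bin for one sample.

    Returns (bin_edges, masses); masses are weighted by pattern
    multiplicity and normalized to sum to 1.  Default bins are 1-year wide
    over 0..200 (the prediction grid), with the final bin closed.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 202.0, 1.0)
    ages = [r.age for r in results if r.defined]
    weights = [r.count for r in results if r.defined]
    if not ages:
        raise ValueError("no defined pattern ages to bin")
    counts, edges = np.histogram(ages, bins=bin_edges, weights=np.asarray(weights, float))
    return edges, counts / counts.sum()


# ---------------------------------------------------------------------------
# site-model files: TSV with amplicon_id, site_index, slope, intercept
# ---------------------------------------------------------------------------

def write_site_models(models: Sequence[SiteAgeModel], path: str | Path) -> None:
    pd.DataFrame(
        [(m.amplicon_id, m.site_index, repr(m.slope), repr(m.intercept)) for m in models],
        columns=["amplicon_id", "site_index", "slope", "intercept"],
    ).to_csv(path, sep="\t", index=False)


def read_site_models(path: str | Path) -> list[SiteAgeModel]:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str},
                     float_precision="round_trip")
    return [
        SiteAgeModel(str(r.amplicon_id), int(r.site_index), float(r.slope), float(r.intercept))
        for r in df.itertuples(index=False)
    ]
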