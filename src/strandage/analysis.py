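"""Amplicon-level descriptive statistics and windowed enrichment tests.

Covers three descriptive views of amplicon data — the per-site
age-correlation profile (whose bell shape flags regulatory elements such
as CTCF binding sites near the correlation peak), the site-by-site
correlation matrix (near-diagonal structure distinguishes coherent from
stochastic methylation), and the sorted pattern-frequency table — plus a
generic enrichment statistic comparing quantile-normalized coverage at a
target CpG set against a background set within fixed windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationMatrix, ReadPatternSet, SampleMetadata

__all__ = [
    "AmpliconProfile",
    "WindowEnrichmentResult",
    "site_age_correlation_profile",
    "pairwise_site_correlation",
    "pattern_frequency_table",
    "quantile_normalize",
    "cpg_windows",
    "sample_background",
    "window_enrichment",
]

WINDOW_HALF_WIDTH = 250  # bases each side of the CpG


@dataclass
class AmpliconProfile:
    """Per-site Pearson correlation with age, ordered along the amplicon."""

    amplicon_id: str
    site_index: np.ndarray        # 1-based position within the amplicon
    correlation: np.ndarray       # NaN where undefined (constant site)

    def peak_site(self) -> int:
        """1-based index of the site with the largest |r| (NaN ignored)."""
        return int(self.site_index[np.nanargmax(np.abs(self.correlation))])


def _site_frequency_table(
    pattern_sets: list[ReadPatternSet], meta: SampleMetadata
) -> tuple[np.ndarray, np.ndarray, str]:
    amplicon = pattern_sets[0].amplicon_id
    n_sites = pattern_sets[0].n_sites
    for rps in pattern_sets:
        if rps.amplicon_id != amplicon or rps.n_sites != n_sites:
            raise ValueError("pattern sets must share one amplicon")
    freqs = np.vstack([rps.site_frequencies() for rps in pattern_sets])
    ages = np.array([float(meta.table.loc[rps.sample_id, "age"]) for rps in pattern_sets])
    return freqs, ages, amplicon


def site_age_correlation_profile(
    pattern_sets: list[ReadPatternSet], meta: SampleMetadata
) -> AmpliconProfile:
    """Pearson r of per-sample site frequency versus age, per site."""
    freqs, ages, amplicon = _site_frequency_table(pattern_sets, meta)
    n_sites = freqs.shape[1]
    r = np.full(n_sites, np.nan)
    for i in range(n_sites):
        y = freqs[:, i]
        ok = ~np.isnan(y)
        if ok.sum() >= 3 and np.ptp(y[ok]) > 0 and np.ptp(ages[ok]) > 0:
            r[i] = stats.pearsonr(y[ok], ages[ok]).statistic
    return AmpliconProfile(amplicon, np.arange(1, n_sites + 1), r)


def site_age_correlation_profile_from_matrix(
    matrix: MethylationMatrix, meta: SampleMetadata, amplicon_id: str = "amplicon"
) -> AmpliconProfile:
    """Profile from a beta matrix whose rows are the amplicon's sites in order."""
    ages = meta.table.loc[matrix.sample_ids, "age"].to_numpy(dtype=float)
    vals = matrix.values.to_numpy(dtype=float)
    n_sites = vals.shape[0]
    r = np.full(n_sites, np.nan)
    for i in range(n_sites):
        y = vals[i]
        ok = ~np.isnan(y) & ~np.isnan(ages)
        if ok.sum() >= 3 and np.ptp(y[ok]) > 0 and np.ptp(ages[ok]) > 0:
            r[i] = stats.pearsonr(y[ok], ages[ok]).statistic
    return AmpliconProfile(amplicon_id, np.arange(1, n_sites + 1), r)


def pairwise_site_correlation(
    pattern_sets: list[ReadPatternSet], meta: SampleMetadata | None = None
) -> pd.DataFrame:
    """Site-by-site Pearson correlation of per-sample frequencies.

    Symmetric with unit diagonal where defined; rows/columns of
    zero-variance sites are NaN.  Requires at least three samples.
    """
    amplicon = pattern_sets[0].amplicon_id
    n_sites = pattern_sets[0].n_sites
    for rps in pattern_sets:
        if rps.amplicon_id != amplicon or rps.n_sites != n_sites:
            raise ValueError("pattern sets must share one amplicon")
    if len(pattern_sets) < 3:
        raise ValueError("need at least three samples")
    freqs = np.vstack([rps.site_frequencies() for rps in pattern_sets])
    df = pd.DataFrame(freqs, columns=np.arange(1, n_sites + 1))
    corr = df.corr(method="pearson", min_periods=3)
    # pandas leaves the diagonal 1 even for constant columns; mark undefined
    constant = df.std(ddof=0).to_numpy() == 0
    corr.values[constant, :] = np.nan
    corr.values[:, constant] = np.nan
    return corr


def pattern_frequency_table(rps: ReadPatternSet) -> pd.DataFrame:
    """Patterns with counts and relative frequencies.

    Sorted by count descending, ties broken lexicographically on the
    pattern string, so output is deterministic.
    """
    if not rps.patterns:
        raise ValueError("empty pattern set")
    rows = sorted(rps.patterns.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(c for _, c in rows)
    return pd.DataFrame(
        {"pattern": [p for p, _ in rows],
         "count": [c for _, c in rows],
         "frequency": [c / total for _, c in rows]}
    )


# ---------------------------------------------------------------------------
# windowed enrichment
# ---------------------------------------------------------------------------

def cpg_windows(positions: pd.DataFrame, half_width: int = WINDOW_HALF_WIDTH) -> pd.DataFrame:
    """±``half_width`` bp windows around CpGs, 0-based half-open.

    A CpG at position p yields [p - half_width, p + half_width + 1): the
    window covers half_width bases on each side *and* the site base itself
    (501 bp at the default 250).  Starts are floored at 0.  ``positions``
    needs columns cpg_id, chrom, pos.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    out = positions.copy()
    out["start"] = np.maximum(out["pos"].to_numpy(dtype=int) - half_width, 0)
    out["end"] = out["pos"].to_numpy(dtype=int) + half_width + 1
    return out[["chrom", "start", "end", "cpg_id"]]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization across columns (samples).

    Each column's sorted values are replaced by the mean of sorted values
    across columns; ranks within a column are preserved and tied values
    receive the mean of their would-be quantiles.
    """
    ranks = values.rank(method="average")
    sorted_mean = np.sort(values.to_numpy(dtype=float), axis=0).mean(axis=1)
    n = len(values)
    # interpolate for fractional (tied) ranks
    grid = np.arange(1, n + 1, dtype=float)
    out = {
        col: np.interp(ranks[col].to_numpy(dtype=float), grid, sorted_mean)
        for col in values.columns
    }
    return pd.DataFrame(out, index=values.index)


def sample_background(
    universe: list[str], n: int, exclude: set[str] | None = None, seed: int = 0
) -> list[str]:
    """Seeded draw of background CpGs without replacement."""
    pool = [c for c in universe if not exclude or c not in exclude]
    if n > len(pool):
        raise ValueError(f"cannot draw {n} background CpGs from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


@dataclass
class WindowEnrichmentResult:
    """Enrichment of coverage at target CpGs versus a background set."""

    normalized: pd.DataFrame          # quantile-normalized coverage, CpG x sample
    target_ids: list[str]
    background_ids: list[str]
    per_sample: pd.DataFrame          # columns: sample, statistic, p_value
    pooled_statistic: float
    pooled_p_value: float
    half_width: int = WINDOW_HALF_WIDTH


def window_enrichment(
    coverage: pd.DataFrame,
    target_ids: list[str],
    background_ids: list[str],
    alternative: str = "two-sided",
    half_width: int = WINDOW_HALF_WIDTH,
) -> WindowEnrichmentResult:
    """Mann-Whitney rank test of target versus background window coverage.

    ``coverage`` holds one precomputed value per CpG (rows) and sample
    (columns) — e.g. read counts within the ±250 bp window.  Columns are
    quantile normalized first; the test runs per sample and on the pooled
    normalized values.  Target and background must be disjoint.
    """
    overlap = set(target_ids) & set(background_ids)
    if overlap:
        raise ValueError(f"target and background overlap: {sorted(overlap)[:5]}")
    missing = (set(target_ids) | set(background_ids)) - set(coverage.index)
    if missing:
        raise KeyError(f"CpGs missing from coverage table: {sorted(missing)[:5]}")
    if not target_ids or not background_ids:
        raise ValueError("both groups need at least one CpG")

    norm = quantile_normalize(coverage)
    rows = []
    for col in norm.columns:
        res = stats.mannwhitneyu(
            norm.loc[target_ids, col], norm.loc[background_ids, col],
            alternative=alternative,
        )
        rows.append((col, float(res.statistic), float(res.pvalue)))
    pooled = stats.mannwhitneyu(
        norm.loc[target_ids].to_numpy().ravel(),
        norm.loc[background_ids].to_numpy().ravel(),
        alternative=alternative,
    )
    return WindowEnrichmentResult(
        normalized=norm,
        target_ids=list(target_ids),
        background_ids=list(background_ids),
        per_sample=pd.DataFrame(rows, columns=["sample", "statistic", "p_value"]),
        pooled_statistic=float(pooled.statistic),
        pooled_p_value=float(pooled.pvalue),
        half_width=half_width,
    )
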