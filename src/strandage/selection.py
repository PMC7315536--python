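"""Multi-cohort screening for age-associated CpG sites.

The screen proceeds in two stages.  First, CpGs are removed by exclusion
masks (SNP-associated probes, cross-reactive probes, probes variable across
hematopoietic cell subsets, smoking-associated probes, sex-chromosome
probes, probes absent from newer array platforms).  Second, the surviving
CpGs are tested for association with chronological age by up to three
criteria — Pearson correlation with age, Spearman rank correlation with
age, and Pearson correlation with log-transformed age — and a CpG is
selected for a criterion only if it meets the absolute-correlation cutoff,
with a consistent sign, in *every* study of the training collection.
Requiring each cohort to pass individually guards against inter-study batch
effects manufacturing spurious pooled correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationMatrix, SampleMetadata

__all__ = [
    "StudyCollection",
    "SelectionCriteria",
    "ExclusionMasks",
    "SelectionResult",
    "apply_exclusion_masks",
    "subset_variance_filter",
    "per_study_correlation",
    "select_candidates",
    "CORRELATION_METHODS",
]

CorrelationMethod = Literal["pearson_age", "spearman_age", "pearson_log_age"]
CORRELATION_METHODS: tuple[CorrelationMethod, ...] = (
    "pearson_age", "spearman_age", "pearson_log_age",
)

MIN_PAIRS = 3  # fewest (beta, age) pairs for which a correlation is defined


@dataclass
class StudyCollection:
    """Beta matrices plus metadata for one or more cohorts.

    Studies may cover different probe sets; analyses use each study's own
    probes and `common_cpgs` exposes the intersection.
    """

    studies: list[tuple[MethylationMatrix, SampleMetadata]]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("a StudyCollection needs at least one study")
        for matrix, meta in self.studies:
            meta.check_covers(matrix)
            n_aged = meta.table.loc[matrix.sample_ids, "age"].notna().sum()
            if n_aged < MIN_PAIRS:
                raise ValueError(
                    f"study with samples {matrix.sample_ids[:3]}... has only "
                    f"{n_aged} aged samples; need >= {MIN_PAIRS}"
                )

    def __len__(self) -> int:
        return len(self.studies)

    @property
    def common_cpgs(self) -> list[str]:
        common = set(self.studies[0][0].cpg_ids)
        for matrix, _ in self.studies[1:]:
            common &= set(matrix.cpg_ids)
        # keep first study's order for determinism
        return [c for c in self.studies[0][0].cpg_ids if c in common]


@dataclass
class SelectionCriteria:
    """Cutoffs controlling the correlation screen.

    r_cutoff : absolute correlation threshold, inclusive (default 0.5).
    methods : which correlation criteria to evaluate.
    subset_variance_cutoff : variance above which a CpG is considered
        cell-type driven (default 0.02, on beta values).
    log_offset : years added to age before taking the natural log
        (default 1, so age 0 is representable).
    strict : use a strict inequality (|r| > cutoff) instead of >=.
    """

    r_cutoff: float = 0.5
    methods: tuple[CorrelationMethod, ...] = CORRELATION_METHODS
    subset_variance_cutoff: float = 0.02
    log_offset: float = 1.0
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.r_cutoff < 1.0:
            raise ValueError("r_cutoff must be in (0, 1)")
        if not self.methods:
            raise ValueError("at least one correlation method is required")
        unknown = set(self.methods) - set(CORRELATION_METHODS)
        if unknown:
            raise ValueError(f"unknown correlation methods: {sorted(unknown)}")

    def passes(self, r: float) -> bool:
        if np.isnan(r):
            return False
        return abs(r) > self.r_cutoff if self.strict else abs(r) >= self.r_cutoff


@dataclass
class ExclusionMasks:
    """Named CpG blacklists applied before the correlation screen."""

    snp_associated: list[str] = field(default_factory=list)
    cross_reactive: list[str] = field(default_factory=list)
    subset_variable: list[str] = field(default_factory=list)
    smoking: list[str] = field(default_factory=list)
    sex_chromosome: list[str] = field(default_factory=list)
    not_on_epic: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "snp_associated": self.snp_associated,
            "cross_reactive": self.cross_reactive,
            "subset_variable": self.subset_variable,
            "smoking": self.smoking,
            "sex_chromosome": self.sex_chromosome,
            "not_on_epic": self.not_on_epic,
        }


def apply_exclusion_masks(
    universe: Sequence[str], masks: ExclusionMasks
) -> tuple[list[str], dict[str, int]]:
    """Remove masked CpGs from ``universe``, preserving order.

    Returns the retained ids and a report: per-mask counts of ids actually
    present in the universe, the size of the union removed, and the count of
    mask ids that were absent from the universe (ignored).
    """
    uset = set(universe)
    union: set[str] = set()
    report: dict[str, int] = {}
    absent = 0
    for name, ids in masks.as_dict().items():
        present = uset & set(ids)
        report[name] = len(present)
        absent += len(set(ids) - uset)
        union |= present
    report["union_removed"] = len(union)
    report["mask_ids_not_in_universe"] = absent
    return [c for c in universe if c not in union], report


def subset_variance_filter(
    subset_matrix: MethylationMatrix, cutoff: float = 0.02
) -> tuple[list[str], list[str]]:
    """CpGs whose beta variance across cell subsets exceeds ``cutoff``.

    Columns are purified cell subsets (e.g. six sorted leukocyte types);
    the variance is the population variance (1/n).  Returns the ids to
    exclude and, separately, ids with any missing subset value (these are
    reported, never silently excluded).
    """
    df = subset_matrix.values
    has_missing = df.isna().any(axis=1)
    variances = df.var(axis=1, ddof=0)
    exclude = df.index[(~has_missing) & (variances > cutoff)].tolist()
    return exclude, df.index[has_missing].tolist()


def _study_correlations(
    matrix: MethylationMatrix,
    meta: SampleMetadata,
    method: CorrelationMethod,
    log_offset: float,
) -> pd.Series:
    """Correlation of every CpG's betas with age for a single study.

    Pairwise deletion of missing betas; NaN where fewer than MIN_PAIRS
    pairs remain or either vector is constant.
    """
    betas = matrix.values
    ages = meta.table.loc[betas.columns, "age"].to_numpy(dtype=float)
    if method == "pearson_log_age":
        y = np.log(ages + log_offset)
    else:
        y = ages

    out = pd.Series(np.nan, index=betas.index, dtype=float)
    x = betas.to_numpy(dtype=float)
    valid = ~np.isnan(x) & ~np.isnan(y)[None, :]
    n_pairs = valid.sum(axis=1)

    complete = valid.all(axis=1)
    if np.isnan(y).any():
        complete &= False  # fall back to per-row handling below

    if method in ("pearson_age", "pearson_log_age"):
        if complete.any():
            xs = x[complete]
            xc = xs - xs.mean(axis=1, keepdims=True)
            yc = y - y.mean()
            denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                out.loc[betas.index[complete]] = np.where(
                    denom > 0, (xc * yc).sum(axis=1) / denom, np.nan
                )
        rows = np.nonzero(~complete & (n_pairs >= MIN_PAIRS))[0]
        for i in rows:
            m = valid[i]
            xi, yi = x[i, m], y[m]
            if np.ptp(xi) == 0 or np.ptp(yi) == 0:
                continue
            out.iloc[i] = stats.pearsonr(xi, yi).statistic
    else:  # spearman_age
        rows = np.nonzero(n_pairs >= MIN_PAIRS)[0]
        for i in rows:
            m = valid[i]
            xi, yi = x[i, m], y[m]
            if np.ptp(xi) == 0 or np.ptp(yi) == 0:
                continue
            out.iloc[i] = stats.spearmanr(xi, yi).statistic
    return out


def per_study_correlation(
    matrix: MethylationMatrix,
    meta: SampleMetadata,
    cpg: str,
    method: CorrelationMethod = "pearson_age",
    log_offset: float = 1.0,
) -> float:
    """Correlation of one CpG's betas with age in one study.

    NaN when fewer than three complete pairs remain or either vector is
    constant (an undefined correlation is never reported as a number).
    """
    if cpg not in matrix.values.index:
        raise KeyError(f"CpG {cpg!r} not in matrix")
    betas = matrix.values.loc[cpg]
    ages = meta.table.loc[betas.index, "age"]
    mask = betas.notna() & ages.notna()
    if mask.sum() < MIN_PAIRS:
        return float("nan")
    x = betas[mask].to_numpy(dtype=float)
    y = ages[mask].to_numpy(dtype=float)
    if method == "pearson_log_age":
        y = np.log(y + log_offset)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "spearman_age":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class SelectionResult:
    """Outcome of the multi-study screen."""

    selected: dict[str, list[str]]           # method -> CpGs passing in every study
    union: list[str]                          # CpGs passing >= 1 method
    venn: dict[frozenset, list[str]]          # exact Venn partition of the methods
    correlations: pd.DataFrame                # (cpg, method, study) -> r, long form
    ineligible: list[str]                     # CpGs absent/unevaluable in some study

    def venn_counts(self) -> dict[str, int]:
        return {"+".join(sorted(k)): len(v) for k, v in self.venn.items()}


def select_candidates(
    collection: StudyCollection,
    criteria: SelectionCriteria = SelectionCriteria(),
    masks: ExclusionMasks | None = None,
) -> SelectionResult:
    """Run the full correlation screen over a study collection.

    A CpG is selected under a method iff in every study it has a defined
    correlation that meets the cutoff *and* all per-study correlations share
    one sign.  CpGs missing from any study are ineligible.  Masks, when
    given, are applied to the common CpG universe first.
    """
    universe = collection.common_cpgs
    if masks is not None:
        universe, _ = apply_exclusion_masks(universe, masks)
    universe_set = set(universe)

    all_ids: set[str] = set()
    for matrix, _ in collection.studies:
        all_ids |= set(matrix.cpg_ids)
    ineligible = sorted(all_ids - universe_set)

    records = []
    per_method: dict[str, pd.DataFrame] = {}
    for method in criteria.methods:
        cols = {}
        for k, (matrix, meta) in enumerate(collection.studies):
            sub = MethylationMatrix(matrix.values.loc[
                [c for c in matrix.cpg_ids if c in universe_set]])
            r = _study_correlations(sub, meta, method, criteria.log_offset)
            cols[k] = r.reindex(universe)
        rmat = pd.DataFrame(cols, index=universe)
        per_method[method] = rmat
        for k in rmat.columns:
            for cpg, r in rmat[k].items():
                records.append((cpg, method, k, r))

    selected: dict[str, list[str]] = {}
    for method, rmat in per_method.items():
        arr = rmat.to_numpy(dtype=float)
        defined = ~np.isnan(arr)
        if criteria.strict:
            meets = defined & (np.abs(arr) > criteria.r_cutoff)
        else:
            meets = defined & (np.abs(arr) >= criteria.r_cutoff)
        all_meet = meets.all(axis=1)
        same_sign = (arr > 0).all(axis=1) | (arr < 0).all(axis=1)
        keep = all_meet & same_sign
        selected[method] = [c for c, k in zip(universe, keep) if k]

    union = [c for c in universe
             if any(c in set(selected[m]) for m in criteria.methods)]

    venn: dict[frozenset, list[str]] = {}
    sets = {m: set(selected[m]) for m in criteria.methods}
    for r in range(1, len(criteria.methods) + 1):
        for combo in combinations(criteria.methods, r):
            inside = set.intersection(*(sets[m] for m in combo))
            outside = set.union(set(), *(sets[m] for m in criteria.methods
                                         if m not in combo))
            exact = inside - outside
            if exact:
                venn[frozenset(combo)] = sorted(exact)

    corr_df = pd.DataFrame(records, columns=["cpg_id", "method", "study_index", "r"])
    return SelectionResult(selected, union, venn, corr_df, ineligible)
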