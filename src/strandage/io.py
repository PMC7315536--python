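"""Tabular input/output for targeted methylation analysis.

The containers here are deliberately thin wrappers around pandas objects and
plain dataclasses.  Everything is read and written as UTF-8, tab-separated
text so that results remain auditable with standard command-line tools.

Conventions
-----------
* Beta matrices are stored with CpGs as rows and samples as columns (the
  layout in which Illumina series matrices are distributed); a flag allows
  the transpose on read.
* Per-read methylation patterns are strings over ``{0, 1, .}`` where ``1``
  is a methylated call, ``0`` unmethylated and ``.`` a missing call.
* Duplex droplet-PCR counts partition every droplet into exactly four
  classes: positive for the methylation probe only, for the unmethylated
  probe only, for both, or for neither.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "SampleMetadata",
    "ReadPatternSet",
    "DropletCounts",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_pattern_table",
    "write_pattern_table",
    "filter_rare_patterns",
    "read_droplet_counts",
    "PATTERN_ALPHABET",
]

PATTERN_ALPHABET = frozenset("01.")


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass
class MethylationMatrix:
    """Methylation fractions (beta values) per CpG and sample.

    ``values`` is a DataFrame indexed by CpG id with one column per sample.
    Entries are fractions in [0, 1]; NaN marks a missing measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate CpG ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise FormatError(
                f"beta value {arr[i, j]!r} outside [0, 1] at "
                f"CpG {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleMetadata:
    """Per-sample annotations: chronological age (years) and study label."""

    table: pd.DataFrame  # index: sample_id; columns: age, study[, tissue]

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = {"age", "study"} - set(t.columns)
        if missing:
            raise FormatError(f"metadata missing required columns: {sorted(missing)}")
        ages = pd.to_numeric(t["age"], errors="raise")
        if (ages < 0).any():
            bad = t.index[ages < 0][0]
            raise FormatError(f"negative age for sample {bad!r}")
        self.table = t.assign(age=ages.astype(float))

    @property
    def ages(self) -> pd.Series:
        return self.table["age"]

    @property
    def studies(self) -> pd.Series:
        return self.table["study"]

    def check_covers(self, matrix: MethylationMatrix) -> None:
        """Require metadata for every sample in ``matrix``."""
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)[:5]}")


@dataclass
class ReadPatternSet:
    """Counted binary methylation patterns for one sample and amplicon.

    One sequenced DNA strand contributes one pattern occurrence.  Pattern
    strings run over the amplicon's CpG sites in order; ``.`` marks a site
    without a usable call on that read.
    """

    sample_id: str
    amplicon_id: str
    n_sites: int
    patterns: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, c in self.patterns.items():
            if len(p) != self.n_sites:
                raise FormatError(
                    f"pattern {p!r} has length {len(p)}, expected {self.n_sites} "
                    f"({self.sample_id}/{self.amplicon_id})"
                )
            if set(p) - PATTERN_ALPHABET:
                raise FormatError(f"pattern {p!r} contains characters outside 0/1/.")
            if not (isinstance(c, (int, np.integer)) and c >= 1):
                raise FormatError(f"count for pattern {p!r} must be a positive integer, got {c!r}")

    @property
    def n_reads(self) -> int:
        return sum(self.patterns.values())

    def site_frequencies(self) -> np.ndarray:
        """Multiplicity-weighted methylation frequency per site.

        Missing calls are excluded from that site's numerator and
        denominator.  Sites with no calls at all yield NaN.
        """
        meth = np.zeros(self.n_sites)
        covered = np.zeros(self.n_sites)
        for p, c in self.patterns.items():
            a = np.frombuffer(p.encode(), dtype=np.uint8)
            is_meth = a == ord("1")
            is_called = a != ord(".")
            meth += c * is_meth
            covered += c * is_called
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(covered > 0, meth / np.maximum(covered, 1), np.nan)


@dataclass
class DropletCounts:
    """Duplex droplet-PCR droplet classification tallies."""

    assay_id: str
    n_total: int
    n_meth_only: int
    n_unmeth_only: int
    n_double: int
    n_negative: int

    def __post_init__(self) -> None:
        counts = (self.n_total, self.n_meth_only, self.n_unmeth_only,
                  self.n_double, self.n_negative)
        if any(c < 0 for c in counts):
            raise FormatError(f"negative droplet count in assay {self.assay_id!r}")
        if self.n_total <= 0:
            raise FormatError(f"assay {self.assay_id!r} has no droplets")
        s = self.n_meth_only + self.n_unmeth_only + self.n_double + self.n_negative
        if s != self.n_total:
            raise FormatError(
                f"assay {self.assay_id!r}: categories sum to {s}, total is {self.n_total}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_methylation_matrix(path: str | Path, samples_as_rows: bool = False) -> MethylationMatrix:
    """Read a TSV beta matrix (first column = CpG id, header = sample ids).

    Set ``samples_as_rows`` if the file stores one sample per row instead.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df = df.apply(pd.to_numeric, errors="raise")
    if samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return MethylationMatrix(df)


def write_methylation_matrix(m: MethylationMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="cpg_id")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_pattern_table(path: str | Path) -> list[ReadPatternSet]:
    """Read counted per-read patterns grouped by (sample, amplicon).

    Expected columns: ``sample_id  amplicon_id  pattern  count``.  Pattern
    length must be consistent within each amplicon across all samples.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "amplicon_id": str,
                                            "pattern": str, "count": int})
    required = {"sample_id", "amplicon_id", "pattern", "count"}
    if missing := required - set(df.columns):
        raise FormatError(f"pattern table missing columns: {sorted(missing)}")

    amp_len: dict[str, int] = {}
    for amp, sub in df.groupby("amplicon_id"):
        lens = sub["pattern"].str.len().unique()
        if len(lens) > 1:
            raise FormatError(
                f"amplicon {amp!r} mixes pattern lengths {sorted(lens.tolist())}"
            )
        amp_len[amp] = int(lens[0])

    out: list[ReadPatternSet] = []
    for (sample, amp), sub in df.groupby(["sample_id", "amplicon_id"], sort=True):
        patterns: dict[str, int] = {}
        for p, c in zip(sub["pattern"], sub["count"]):
            patterns[p] = patterns.get(p, 0) + int(c)
        out.append(ReadPatternSet(sample, amp, amp_len[amp], patterns))
    return out


def write_pattern_table(sets: Iterable[ReadPatternSet], path: str | Path) -> None:
    rows = []
    for rps in sets:
        for p in sorted(rps.patterns):
            rows.append((rps.sample_id, rps.amplicon_id, p, rps.patterns[p]))
    pd.DataFrame(rows, columns=["sample_id", "amplicon_id", "pattern", "count"]) \
        .to_csv(path, sep="\t", index=False)


def filter_rare_patterns(rps: ReadPatternSet, min_count: int = 10) -> ReadPatternSet:
    """Keep only patterns observed at least ``min_count`` times (inclusive).

    Applied per sample and amplicon before any read-level analysis; the
    default of 10 reflects typical amplicon-sequencing noise floors.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = {p: c for p, c in rps.patterns.items() if c >= min_count}
    return ReadPatternSet(rps.sample_id, rps.amplicon_id, rps.n_sites, kept)


def read_droplet_counts(path: str | Path) -> list[DropletCounts]:
    """Read droplet tallies from CSV or TSV.

    Required columns: ``assay_id, n_total, n_meth_only, n_unmeth_only,
    n_double``; ``n_negative`` is derived when absent.
    """
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    required = {"assay_id", "n_total", "n_meth_only", "n_unmeth_only", "n_double"}
    if missing := required - set(df.columns):
        raise FormatError(f"droplet table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        categorized = int(row.n_meth_only) + int(row.n_unmeth_only) + int(row.n_double)
        if "n_negative" in df.columns and not pd.isna(getattr(row, "n_negative")):
            n_neg = int(getattr(row, "n_negative"))
        else:
            n_neg = int(row.n_total) - categorized
            if n_neg < 0:
                raise FormatError(
                    f"assay {row.assay_id!r}: categories sum to {categorized}, "
                    f"exceeding total {row.n_total}"
                )
        out.append(DropletCounts(str(row.assay_id), int(row.n_total),
                                 int(row.n_meth_only), int(row.n_unmeth_only),
                                 int(row.n_double), n_neg))
    return out
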