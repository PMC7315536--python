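"""Multivariable linear epigenetic clocks with an optional age transform.

The transform compresses pediatric ages logarithmically and keeps adult
ages linear, with ``adult_age`` (default 20 years) as the hinge:

    F(a) = ln(a + 1) - ln(adult_age + 1)        for a <= adult_age
    F(a) = (a - adult_age) / (adult_age + 1)    for a >  adult_age

Both branches meet at F(adult_age) = 0 and F is strictly increasing, so a
clock fit on transformed age can be inverted exactly to report predictions
in years.  Methylation changes accumulate much faster in childhood, which
is why fitting on F(age) rather than raw age improves pediatric accuracy.

Clocks are plain ordinary-least-squares fits of (transformed) age on the
beta values of a chosen CpG panel; penalized training is intentionally out
of scope here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .io import MethylationMatrix, SampleMetadata

__all__ = [
    "AgeTransform",
    "LinearClock",
    "ClockEvaluation",
    "transform_age",
    "inverse_transform_age",
    "fit_linear_clock",
    "predict_age",
    "evaluate_predictions",
    "read_clock",
    "write_clock",
]

INTERCEPT_KEY = "(Intercept)"


@dataclass(frozen=True)
class AgeTransform:
    """Piecewise log/linear age transform hinged at ``adult_age`` years."""

    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")

    def forward(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        out = np.where(
            age <= self.adult_age,
            np.log(age + 1.0) - math.log(self.adult_age + 1.0),
            (age - self.adult_age) / (self.adult_age + 1.0),
        )
        return out if out.ndim else float(out)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        out = np.where(
            y < 0,
            (1.0 + self.adult_age) * np.exp(y) - 1.0,
            (1.0 + self.adult_age) * y + self.adult_age,
        )
        return out if out.ndim else float(out)


def transform_age(t: AgeTransform, age):
    """F(age): log branch up to ``adult_age``, linear above (natural log)."""
    return t.forward(age)


def inverse_transform_age(t: AgeTransform, y):
    """inverse-F: maps a model's transformed-age output back to years."""
    return t.inverse(y)


@dataclass
class LinearClock:
    """Intercept plus per-CpG weights; optionally on the transformed-age scale."""

    intercept: float
    coefficients: dict[str, float]
    uses_transform: bool = False
    transform: AgeTransform = field(default_factory=AgeTransform)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("a clock needs at least one CpG coefficient")
        bad = [c for c, w in self.coefficients.items() if not np.isfinite(w)]
        if bad or not np.isfinite(self.intercept):
            raise ValueError(f"non-finite clock coefficients: {bad}")

    @property
    def cpgs(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class ClockEvaluation:
    """Agreement between predicted and chronological age.

    ``r_squared`` is the squared Pearson correlation of predicted versus
    actual age (the scatterplot convention in this literature, not the R²
    of a refit), and ``median_abs_error`` is in years.
    """

    r_squared: float
    median_abs_error: float
    n: int


def _design(matrix: MethylationMatrix, cpgs: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in cpgs if c not in matrix.values.index]
    if missing:
        raise KeyError(f"CpGs absent from matrix: {missing[:5]}")
    return matrix.values.loc[list(cpgs)].T  # samples x cpgs


def fit_linear_clock(
    matrix: MethylationMatrix,
    meta: SampleMetadata,
    cpgs: Sequence[str],
    uses_transform: bool = False,
    transform: AgeTransform = AgeTransform(),
) -> LinearClock:
    """OLS of (transformed) age on the betas of ``cpgs``.

    Samples with a missing beta at any panel CpG, or missing age, are
    dropped (never imputed).  A rank-deficient design raises an error that
    names the collinear CpGs.
    """
    X = _design(matrix, cpgs)
    ages = meta.table.loc[X.index, "age"]
    keep = X.notna().all(axis=1) & ages.notna()
    X, ages = X[keep], ages[keep]
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"{n} usable samples cannot identify {p} coefficients "
                         "plus an intercept")

    y = transform.forward(ages.to_numpy()) if uses_transform else ages.to_numpy(dtype=float)
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        # pivoted QR: trailing pivots with tiny |R_ii| are the dependent columns
        _, R, piv = scipy.linalg.qr(A, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        dependent = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
        names = [cpgs[j - 1] if j > 0 else INTERCEPT_KEY for j in dependent]
        raise ValueError(f"singular design; collinear terms: {names}")

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearClock(
        intercept=float(beta[0]),
        coefficients={c: float(w) for c, w in zip(cpgs, beta[1:])},
        uses_transform=uses_transform,
        transform=transform,
    )


def predict_age(clock: LinearClock, matrix: MethylationMatrix) -> pd.Series:
    """Predicted age in years per sample; NaN where a panel CpG is missing.

    Predictions are not clipped: a very young profile may legitimately map
    below zero, as raw clock outputs do.
    """
    X = _design(matrix, clock.cpgs)
    w = np.array([clock.coefficients[c] for c in clock.cpgs])
    raw = clock.intercept + X.to_numpy(dtype=float) @ w
    pred = pd.Series(raw, index=X.index, name="predicted_age")
    if clock.uses_transform:
        pred = pd.Series(clock.transform.inverse(pred.to_numpy()),
                         index=X.index, name="predicted_age")
    pred[X.isna().any(axis=1)] = np.nan
    return pred


def evaluate_predictions(predicted, actual) -> ClockEvaluation:
    """Squared Pearson correlation and median absolute error, in years.

    Pairs with a missing value on either side are dropped; at least two
    complete pairs are required.
    """
    predicted = pd.Series(predicted, dtype=float)
    actual = pd.Series(actual, dtype=float)
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual must align")
    p = predicted.to_numpy()
    a = actual.to_numpy()
    mask = ~np.isnan(p) & ~np.isnan(a)
    p, a = p[mask], a[mask]
    if p.size < 2:
        raise ValueError("need at least two complete (predicted, actual) pairs")
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(p, a)[0, 1] ** 2)
    return ClockEvaluation(
        r_squared=r2,
        median_abs_error=float(np.median(np.abs(p - a))),
        n=int(p.size),
    )


# ---------------------------------------------------------------------------
# model files: TSV with (cpg_id, weight) rows, a reserved "(Intercept)" row,
# and header comments carrying uses_transform / adult_age.  The layout lets
# published coefficient tables be transcribed directly.
# ---------------------------------------------------------------------------

def write_clock(clock: LinearClock, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# uses_transform={str(clock.uses_transform).lower()}\n")
        fh.write(f"# adult_age={clock.transform.adult_age:g}\n")
        fh.write("cpg_id\tweight\n")
        fh.write(f"{INTERCEPT_KEY}\t{clock.intercept!r}\n")
        for c, w in clock.coefficients.items():
            fh.write(f"{c}\t{w!r}\n")


def read_clock(path: str | Path) -> LinearClock:
    uses_transform = False
    adult_age = 20.0
    rows: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if m := re.match(r"#\s*uses_transform=(\w+)", line):
                    uses_transform = m.group(1).lower() == "true"
                elif m := re.match(r"#\s*adult_age=([\d.eE+-]+)", line):
                    adult_age = float(m.group(1))
                continue
            key, _, val = line.partition("\t")
            if key == "cpg_id":
                continue
            rows[key] = float(val)
    if INTERCEPT_KEY not in rows:
        raise ValueError(f"model file {path} lacks an {INTERCEPT_KEY} row")
    intercept = rows.pop(INTERCEPT_KEY)
    return LinearClock(intercept, rows, uses_transform, AgeTransform(adult_age))
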