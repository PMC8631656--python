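"""Drop-test growth tables: per-strain maximum tolerated sulfite and
promoter-class comparisons.

A drop test scores growth 0–6 at each concentration of potassium
metabisulfite (MBS, g/L): 0 means no spot grew, 6 means even the most
dilute spot grew. A strain's tolerance is summarized as the highest grid
concentration with any growth (score >= 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_quant import WelchResult, compare_expression

__all__ = [
    "DEFAULT_GRID",
    "PROMOTER_CLASSES",
    "DropTestTable",
    "parse_droptest",
    "max_tolerated",
    "tolerance_summary",
    "ClassComparison",
    "class_comparison",
]

DEFAULT_GRID = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
PROMOTER_CLASSES = ("ancestral", "VII^XVI", "XI^XVI")


class DropTestFormatError(ValueError):
    pass


@dataclass
class DropTestTable:
    """Rows of (strain, promoter class, growth score per concentration)."""

    data: pd.DataFrame  # columns: strain, promoter_class, then one per conc
    grid: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if list(self.grid) != sorted(set(self.grid)):
            raise DropTestFormatError("concentration grid must be strictly increasing")
        required = ["strain", "promoter_class"]
        for col in required:
            if col not in self.data.columns:
                raise DropTestFormatError(f"missing column {col!r}")
        bad = set(self.data["promoter_class"]) - set(PROMOTER_CLASSES)
        if bad:
            raise DropTestFormatError(f"unknown promoter class labels {sorted(bad)}")
        for conc in self.grid:
            col = _conc_col(conc)
            if col not in self.data.columns:
                raise DropTestFormatError(f"missing concentration column {col!r}")
            scores = self.data[col]
            if not np.issubdtype(scores.dtype, np.integer):
                if not np.allclose(scores, scores.astype(int)):
                    raise DropTestFormatError(f"non-integer score in column {col}")
            if ((scores < 0) | (scores > 6)).any():
                raise DropTestFormatError(f"score outside 0–6 in column {col}")

    def scores(self, strain: str) -> list[int]:
        row = self.data[self.data["strain"] == strain]
        if row.empty:
            raise KeyError(f"no strain {strain}")
        return [int(row.iloc[0][_conc_col(c)]) for c in self.grid]


def _conc_col(conc: float) -> str:
    return f"{conc:.2f}"


def parse_droptest(path: str | Path) -> DropTestTable:
    """Parse a TSV with header: strain, promoter_class, then one column per
    MBS concentration (g/L, strictly increasing)."""
    df = pd.read_csv(path, sep="\t")
    if "strain" not in df.columns or "promoter_class" not in df.columns:
        raise DropTestFormatError(f"{path}: header must start with strain, promoter_class")
    conc_cols = [c for c in df.columns if c not in ("strain", "promoter_class")]
    try:
        grid = tuple(float(c) for c in conc_cols)
    except ValueError as exc:
        raise DropTestFormatError(f"{path}: non-numeric concentration column") from exc
    if list(grid) != sorted(set(grid)):
        raise DropTestFormatError(f"{path}: concentration grid must be strictly increasing")
    df = df.rename(columns={c: _conc_col(float(c)) for c in conc_cols})
    return DropTestTable(data=df, grid=grid)


def max_tolerated(scores: list[int], grid: tuple[float, ...] = DEFAULT_GRID) -> float | None:
    """Highest grid concentration with score >= 1; None if no growth anywhere."""
    if len(scores) != len(grid):
        raise ValueError("scores and grid lengths differ")
    best = None
    for conc, score in zip(grid, scores):
        if score >= 1:
            best = conc
    return best


def tolerance_summary(table: DropTestTable) -> pd.DataFrame:
    """Per-strain max tolerated MBS (NaN when no growth anywhere)."""
    rows = []
    for _, r in table.data.iterrows():
        scores = [int(r[_conc_col(c)]) for c in table.grid]
        mt = max_tolerated(scores, table.grid)
        rows.append(
            {
                "strain": r["strain"],
                "promoter_class": r["promoter_class"],
                "max_mbs": math.nan if mt is None else mt,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassComparison:
    class_a: str
    class_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float | None
    df: float | None
    p_value: float | None
    n_excluded: int = 0  # strains with no growth anywhere

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def class_comparison(
    table: DropTestTable, class_a: str, class_b: str, welch: bool = True
) -> ClassComparison:
    """Two-sample t-test on per-strain max tolerated MBS between classes.

    Welch (unequal variances) by default; ``welch=False`` uses Student's
    pooled test. A class with fewer than 2 strains (after excluding
    no-growth strains) yields descriptive statistics only (test fields None).
    """
    summary = tolerance_summary(table)
    n_excluded = int(summary["max_mbs"].isna().sum())
    summary = summary.dropna(subset=["max_mbs"])
    a = summary.loc[summary["promoter_class"] == class_a, "max_mbs"].to_numpy()
    b = summary.loc[summary["promoter_class"] == class_b, "max_mbs"].to_numpy()

    def descr(v: np.ndarray) -> tuple[float, float]:
        if len(v) == 0:
            return math.nan, math.nan
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    mean_a, sd_a = descr(a)
    mean_b, sd_b = descr(b)
    t = df = p = None
    if len(a) >= 2 and len(b) >= 2:
        if welch:
            res = compare_expression(a, b)
            t, df, p = res.t, res.df, res.p_value
        else:
            from scipy import stats

            r = stats.ttest_ind(a, b, equal_var=True)
            t, df, p = float(r.statistic), float(len(a) + len(b) - 2), float(r.pvalue)
            if math.isnan(t):  # zero variance in both groups
                t, p = 0.0, 1.0
    return ClassComparison(
        class_a=class_a,
        class_b=class_b,
        mean_a=mean_a,
        sd_a=sd_a,
        n_a=len(a),
        mean_b=mean_b,
        sd_b=sd_b,
        n_b=len(b),
        t=t,
        df=df,
        p_value=p,
        n_excluded=n_excluded,
    )
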