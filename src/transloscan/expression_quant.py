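"""Calibrated relative expression from raw qPCR Ct tables.

Quantities are interpolated from per-gene standard curves (Ct regressed on
log10 dilution; efficiency E = 10^(−1/slope)), the target quantity is
normalized by the average of two constitutive reference genes, and each
(strain, condition, timepoint) cell is expressed as a ratio to a calibrator
strain measured under the same condition and timepoint. Working on
quantities rather than ΔΔCt keeps unequal per-gene efficiencies exact.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "QpcrDataset",
    "read_qpcr_table",
    "read_standard_table",
    "normalize_expression",
    "WelchResult",
    "compare_expression",
]

# slope of a perfectly efficient (doubling) reaction, cycles per log10 quantity
PERFECT_SLOPE = -1.0 / math.log10(2.0)


class CurveFitError(ValueError):
    """Standard curve cannot be fitted or is invalid."""


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct = intercept + slope·log10(quantity)."""

    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    @property
    def valid(self) -> bool:
        return self.slope < 0 and 1.0 < self.efficiency <= 2.2


def default_curve(gene: str) -> StandardCurve:
    """Assumed perfect-efficiency curve (E = 2) when no dilution series exists."""
    return StandardCurve(gene=gene, slope=PERFECT_SLOPE, intercept=20.0, r_squared=1.0)


def fit_standard_curve(
    points: list[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Fit Ct vs log10(dilution) by least squares.

    ``points`` are (dilution factor, Ct) pairs; at least 3 distinct dilutions
    are required. A positive slope is flagged invalid (curve.valid False).
    """
    if len(points) < 3:
        raise CurveFitError(f"{gene}: need >= 3 standard-curve points")
    dil = np.array([p[0] for p in points], dtype=float)
    ct = np.array([p[1] for p in points], dtype=float)
    if np.any(dil <= 0):
        raise CurveFitError(f"{gene}: dilution factors must be positive")
    if len(np.unique(dil)) < 3:
        raise CurveFitError(f"{gene}: need >= 3 distinct dilutions")
    x = np.log10(dil)
    slope, intercept = np.polyfit(x, ct, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((ct - pred) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(gene=gene, slope=float(slope), intercept=float(intercept), r_squared=r2)


def quantify(ct: float, curve: StandardCurve) -> float:
    """Relative quantity from a Ct value: 10^((ct − intercept)/slope).

    Monotone decreasing in Ct for any valid (negative-slope) curve.
    """
    if curve.slope >= 0:
        raise CurveFitError(f"{curve.gene}: invalid curve (slope >= 0)")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass
class QpcrDataset:
    """Raw Ct measurements plus an optional standard-curve dilution series.

    ``measurements`` columns: strain, condition, timepoint, gene, replicate,
    ct. ``standards`` columns: gene, dilution, ct.
    """

    measurements: pd.DataFrame
    standards: pd.DataFrame | None = None
    target_gene: str = "SSU1"
    reference_genes: tuple[str, str] = ("ACT1", "RDN18")

    def __post_init__(self) -> None:
        required = {"strain", "condition", "timepoint", "gene", "replicate", "ct"}
        missing = required - set(self.measurements.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if (self.measurements["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")

    def curves(self) -> dict[str, StandardCurve]:
        """Per-gene standard curves; perfect-efficiency defaults when no
        dilution series is present for a gene."""
        genes = set(self.measurements["gene"])
        out: dict[str, StandardCurve] = {}
        for gene in genes:
            if self.standards is not None:
                sub = self.standards[self.standards["gene"] == gene]
                if len(sub) >= 3:
                    out[gene] = fit_standard_curve(
                        list(zip(sub["dilution"], sub["ct"])), gene=gene
                    )
                    continue
            out[gene] = default_curve(gene)
        return out


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_standard_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def normalize_expression(
    dataset: QpcrDataset,
    curves: dict[str, StandardCurve] | None = None,
    calibrator: str | None = None,
    reference_mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-cell normalized expression and ratios to a calibrator strain.

    Per replicate: normalized = Q_target / mean(Q_ref1, Q_ref2); per
    (strain, condition, timepoint) cell: replicate mean ± sd; the ratio
    divides each cell mean by the calibrator's mean at the same (condition,
    timepoint). Cells missing a reference measurement are flagged
    (ratio NaN) and excluded. ``reference_mean`` may be "arithmetic"
    (default) or "geometric".
    """
    if reference_mean not in ("arithmetic", "geometric"):
        raise ValueError("reference_mean must be 'arithmetic' or 'geometric'")
    curves = curves or dataset.curves()
    df = dataset.measurements.copy()
    df["quantity"] = [
        quantify(ct, curves[gene]) for ct, gene in zip(df["ct"], df["gene"])
    ]
    ref1, ref2 = dataset.reference_genes
    rows = []
    for (strain, cond, tp), cell in df.groupby(
        ["strain", "condition", "timepoint"], sort=True
    ):
        by_gene = {g: sub.set_index("replicate")["quantity"] for g, sub in cell.groupby("gene")}
        if dataset.target_gene not in by_gene or ref1 not in by_gene or ref2 not in by_gene:
            rows.append(
                {"strain": strain, "condition": cond, "timepoint": tp,
                 "normalized_mean": np.nan, "normalized_sd": np.nan,
                 "n": 0, "flagged": True}
            )
            continue
        reps = sorted(
            set(by_gene[dataset.target_gene].index)
            & set(by_gene[ref1].index)
            & set(by_gene[ref2].index)
        )
        values = []
        for rep in reps:
            q_t = by_gene[dataset.target_gene][rep]
            q_1, q_2 = by_gene[ref1][rep], by_gene[ref2][rep]
            denom = (
                (q_1 + q_2) / 2.0
                if reference_mean == "arithmetic"
                else math.sqrt(q_1 * q_2)
            )
            values.append(q_t / denom)
        values = np.asarray(values, dtype=float)
        rows.append(
            {"strain": strain, "condition": cond, "timepoint": tp,
             "normalized_mean": float(values.mean()),
             "normalized_sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
             "n": len(values), "flagged": False}
        )
    table = pd.DataFrame(rows)
    table["ratio"] = np.nan
    if calibrator is not None:
        cal = table[(table["strain"] == calibrator) & ~table["flagged"]]
        cal_means = {
            (r.condition, r.timepoint): r.normalized_mean for r in cal.itertuples()
        }
        ratios = []
        for r in table.itertuples():
            base = cal_means.get((r.condition, r.timepoint))
            if base is None or r.flagged or base == 0:
                ratios.append(np.nan)
            else:
                ratios.append(r.normalized_mean / base)
        table["ratio"] = ratios
    return table


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


def compare_expression(group_a, group_b) -> WelchResult:
    """Welch two-sample t-test (unequal variances, Welch–Satterthwaite df).

    Two identical zero-variance groups give t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(math.inf if a.mean() > b.mean() else -math.inf,
                           float(len(a) + len(b) - 2), 0.0)
    with warnings.catch_warnings():
        # a constant group (e.g. discretized assay maxima) is legitimate;
        # Welch's statistic stays well-defined when the other group varies
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (
        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    )
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_tests(results: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(results, indent=2))
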