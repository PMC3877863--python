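"""Zipf's-law test on rank-ordered expression levels.

Genes are sorted by log2 expression, rank 1 highest, and log2 expression is
regressed on log2 rank by ordinary least squares. Under Zipf's law the
relation is exactly linear with gradient -1; a general power law with
exponent s gives gradient -s. Linearity is judged numerically by R-squared
and by the coefficient of an added quadratic term, evaluated both over the
full rank range and over a central rank window (mirroring distributions
that are linear only over the middle of the curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from fungiflow.quantify import ExpressionVector

DEFAULT_R2_MIN = 0.98
DEFAULT_CURVATURE_MAX = 0.01
DEFAULT_WINDOW = 0.90


@dataclass(frozen=True)
class ZipfFit:
    """OLS fit of log2 expression on log2 rank."""

    gradient: float
    intercept: float
    r_squared: float
    quad_coefficient: float
    n: int

    def to_dict(self) -> dict:
        return {
            "gradient": self.gradient,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "quad_coefficient": self.quad_coefficient,
            "n": self.n,
        }


@dataclass(frozen=True)
class ZipfReport:
    """Full-range and central-window fits plus the consistency verdict.

    ``is_zipf_consistent`` is evaluated on the central window; a series that
    is window-consistent but not full-range-consistent is the distinct
    "linear over the middle part" state.
    """

    full: ZipfFit
    window: ZipfFit
    full_consistent: bool
    window_consistent: bool
    r2_min: float
    curvature_max: float
    window_fraction: float

    @property
    def is_zipf_consistent(self) -> bool:
        return self.window_consistent

    @property
    def middle_only(self) -> bool:
        return self.window_consistent and not self.full_consistent

    def to_dict(self) -> dict:
        return {
            "full": self.full.to_dict(),
            "window": self.window.to_dict(),
            "full_consistent": self.full_consistent,
            "window_consistent": self.window_consistent,
            "is_zipf_consistent": self.is_zipf_consistent,
            "middle_only": self.middle_only,
            "r2_min": self.r2_min,
            "curvature_max": self.curvature_max,
            "window_fraction": self.window_fraction,
        }


def rank_expression(values: ExpressionVector | pd.Series) -> pd.DataFrame:
    """Rank genes by descending log2 expression.

    Rank 1 is the highest expression; ties are broken by locus tag in
    lexicographic order, so ranks are the integers 1..n without gaps.
    Returns a frame with columns rank, log2_rank, log2_value indexed by
    locus tag.
    """
    series = values.values if isinstance(values, ExpressionVector) else values
    if len(series) < 3:
        raise ValueError(f"need at least 3 expressed loci for a rank series, got {len(series)}")
    frame = series.rename("log2_value").to_frame()
    frame.index.name = "locus_tag"
    frame = frame.sort_values(
        by=["log2_value", "locus_tag"], ascending=[False, True], kind="stable"
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["log2_rank"] = np.log2(frame["rank"].to_numpy(dtype=float))
    return frame[["rank", "log2_rank", "log2_value"]]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log2 rank; cannot fit a regression line")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(coef[1]), float(coef[0]), min(r2, 1.0)


def fit_zipf(series: pd.DataFrame) -> ZipfFit:
    """Least-squares line of log2 expression on log2 rank, with curvature.

    The quadratic coefficient comes from a second regression adding a
    squared log2-rank term and diagnoses departure from linearity.
    """
    x = series["log2_rank"].to_numpy(dtype=float)
    y = series["log2_value"].to_numpy(dtype=float)
    gradient, intercept, r2 = _ols(x, y)
    design = np.column_stack([np.ones_like(x), x, x * x])
    quad_coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return ZipfFit(
        gradient=gradient,
        intercept=intercept,
        r_squared=r2,
        quad_coefficient=float(quad_coef[2]),
        n=len(series),
    )


def _central_window(series: pd.DataFrame, fraction: float) -> pd.DataFrame:
    n = len(series)
    margin = (1.0 - fraction) / 2.0
    lo = int(math.ceil(margin * n))
    hi = int(math.floor((1.0 - margin) * n))
    window = series[(series["rank"] > lo) & (series["rank"] <= hi)]
    if len(window) < 3:
        return series
    return window


def assess_linearity(
    series: pd.DataFrame,
    r2_min: float = DEFAULT_R2_MIN,
    curvature_max: float = DEFAULT_CURVATURE_MAX,
    window_fraction: float = DEFAULT_WINDOW,
) -> ZipfReport:
    """Judge Zipf consistency of a rank series.

    Consistency requires R-squared at least ``r2_min`` and an absolute
    quadratic coefficient at most ``curvature_max``; the verdict is taken
    over the central ``window_fraction`` of ranks, with the full-range fit
    reported alongside.
    """
    full = fit_zipf(series)
    window = fit_zipf(_central_window(series, window_fraction))

    def ok(fit: ZipfFit) -> bool:
        return fit.r_squared >= r2_min and abs(fit.quad_coefficient) <= curvature_max

    return ZipfReport(
        full=full,
        window=window,
        full_consistent=ok(full),
        window_consistent=ok(window),
        r2_min=r2_min,
        curvature_max=curvature_max,
        window_fraction=window_fraction,
    )
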