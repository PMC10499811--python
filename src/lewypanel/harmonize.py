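"""Passing-Bablok method-comparison regression and fixed linear transforms.

The slope is the shifted median of all pairwise slopes (the standard 1983
procedure): slopes of exactly -1 are excluded, and the median index is
offset by the number of pairwise slopes below -1.  The intercept is the
median of ``y - slope*x``.  Also ships the study's printed Luminex->Innotest
coefficient table for the AD CSF biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lewypanel.errors import DataError


@dataclass
class PBFit:
    """Passing-Bablok regression line with a rank-based 95% slope CI."""

    slope: float
    intercept: float
    n_pairs: int
    slope_ci: tuple[float, float]

    @property
    def formula(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return f"y = {self.slope:.6g}*x {sign} {abs(self.intercept):.6g}"


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    defined = dx != 0
    slopes = dy[defined] / dx[defined]
    return slopes[slopes != -1.0]


def _shifted_median(sorted_slopes: np.ndarray, K: int) -> float:
    """Median of the sorted slopes with the index shifted by K (1-based)."""
    N = len(sorted_slopes)
    if N % 2 == 1:
        idx = (N + 1) // 2 + K - 1
        if idx >= N:
            raise DataError(
                "shifted median index out of range: methods are not "
                "positively correlated, Passing-Bablok is inapplicable"
            )
        return float(sorted_slopes[idx])
    lo_i, hi_i = N // 2 + K - 1, N // 2 + K
    if hi_i >= N:
        raise DataError(
            "shifted median index out of range: methods are not "
            "positively correlated, Passing-Bablok is inapplicable"
        )
    return float(0.5 * (sorted_slopes[lo_i] + sorted_slopes[hi_i]))


def passing_bablok(x, y, conf: float = 0.95) -> PBFit:
    """Robust method-comparison line from all pairwise slopes.

    Pairs with equal x are omitted (their slope is undefined); slopes of
    exactly -1 are excluded per the standard procedure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise DataError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise DataError("all x equal: every pairwise slope is undefined")
    slopes = np.sort(_pairwise_slopes(x, y))
    N = len(slopes)
    if N == 0:
        raise DataError("no defined pairwise slopes")
    K = int((slopes < -1.0).sum())
    slope = _shifted_median(slopes, K)
    intercept = float(np.median(y - slope * x))

    # rank-based normal-approximation CI for the slope
    z = stats.norm.ppf(0.5 + conf / 2)
    C = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(round((N - C) / 2.0))
    M2 = N - M1 + 1
    lo_i = min(max(M1 + K, 1), N) - 1
    hi_i = min(max(M2 + K, 1), N) - 1
    ci = (float(slopes[lo_i]), float(slopes[hi_i]))

    if slope == 0:
        raise DataError("degenerate fit: zero slope")
    return PBFit(slope=slope, intercept=intercept, n_pairs=n, slope_ci=ci)


def apply_transform(values, coeffs: tuple[float, float]) -> np.ndarray:
    """Elementwise ``slope*x + intercept``."""
    slope, intercept = coeffs
    if not np.isfinite(slope) or not np.isfinite(intercept):
        raise DataError("transform coefficients must be finite")
    return np.asarray(values, dtype=float) * slope + intercept


def invert_transform(values, coeffs: tuple[float, float]) -> np.ndarray:
    slope, intercept = coeffs
    if slope == 0:
        raise DataError("cannot invert a zero-slope transform")
    return (np.asarray(values, dtype=float) - intercept) / slope


# study-reported Luminex -> Innotest-equivalent coefficients
_PAPER_TRANSFORMS = pd.DataFrame(
    [
        {"analyte": "Abeta42", "slope": 4.65, "intercept": -36.23},
        {"analyte": "tTau", "slope": 5.28, "intercept": -2.03},
        {"analyte": "pTau", "slope": 1.88, "intercept": 27.36},
    ]
).set_index("analyte")


def builtin_paper_transforms() -> pd.DataFrame:
    """The shipped (analyte, slope, intercept) coefficient table."""
    return _PAPER_TRANSFORMS.copy()


def paper_transform(analyte: str) -> tuple[float, float]:
    """Look up the shipped coefficients for one analyte."""
    if analyte not in _PAPER_TRANSFORMS.index:
        raise DataError(
            f"unknown analyte {analyte!r}; have "
            f"{_PAPER_TRANSFORMS.index.tolist()}"
        )
    row = _PAPER_TRANSFORMS.loc[analyte]
    return float(row["slope"]), float(row["intercept"])
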