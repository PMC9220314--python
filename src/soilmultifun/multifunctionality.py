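"""Soil multifunctionality (SMF) indices.

Three quantifications of how many functions a plot performs, and how well:

* **averaging** — per plot, the mean of Z-score standardized function
  values; the community-standard composite SMF index;
* **single-threshold** — per plot, the number of functions whose value
  reaches a fixed percentage *t* of that function's "maximum" (the mean of
  its top 5% of observed values);
* **multiple-threshold** — the single-threshold count regressed on
  microbial richness at every threshold of a 5–99% grid, summarized by
  T_min (smallest threshold with a significant positive richness effect),
  T_mde (threshold of maximum effect) and R_mde (the slope realized there,
  in functions per added OTU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import FunctionMatrix, ValidationError

#: Default single-threshold levels.
SINGLE_THRESHOLDS: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90)


def default_grid() -> np.ndarray:
    """The 5%..99% (step 1%) threshold grid as exact hundredths."""
    return np.array([k / 100 for k in range(5, 100)])


@dataclass(frozen=True)
class StandardizedMatrix:
    """Z-scored function matrix with the transform parameters retained."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def inverse(self) -> FunctionMatrix:
        """Undo the standardization (for round-trip checks)."""
        return FunctionMatrix(self.data * self.sds + self.means)


@dataclass(frozen=True)
class ThresholdRegression:
    """OLS fit of threshold counts on richness at one threshold."""

    slope: float
    stderr: float
    pvalue: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ThresholdCurve:
    """Per-threshold regression results plus the derived scalars.

    ``t_min`` and ``t_mde`` are in percent (e.g. 16.0); ``r_mde`` is the
    slope at ``t_mde`` in functions per unit richness.  ``t_min`` is None
    when no threshold shows a significant positive richness effect.
    The literature also spells R_mde as "R_med"; they are the same
    quantity.
    """

    table: pd.DataFrame
    t_min: float | None
    t_mde: float
    r_mde: float
    alpha: float

    def __post_init__(self) -> None:
        thr = self.table["threshold"].to_numpy()
        if not (np.diff(thr) > 0).all():
            raise ValidationError("thresholds must be strictly increasing")


def zscore_standardize(fm: FunctionMatrix, drop_constant: bool = False) -> StandardizedMatrix:
    """Column-wise Z-score transform using the sample (n−1) standard deviation.

    A zero-variance function is an error unless ``drop_constant`` excludes
    it from the output.
    """
    df = fm.data
    sds = df.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()]
    if len(constant):
        if drop_constant:
            df = df.drop(columns=constant.index)
            if df.shape[1] == 0:
                raise ValidationError("all function columns are constant")
            sds = df.std(ddof=1)
        else:
            raise ValidationError(
                f"zero-variance function(s): {', '.join(map(str, constant.index))}; "
                "pass drop_constant=True to exclude them"
            )
    means = df.mean()
    return StandardizedMatrix((df - means) / sds, means=means, sds=sds)


def average_multifunctionality(sm: StandardizedMatrix) -> pd.Series:
    """Averaging SMF index: per plot, the mean of its Z-scores.

    The index has grand mean 0 across plots by construction.
    """
    idx = sm.data.mean(axis=1)
    idx.name = "smf_average"
    return idx


def shift_nonneg(fm: FunctionMatrix) -> FunctionMatrix:
    """Subtract each function's observed minimum so all values are ≥ 0.

    Thresholding against a percentage of the maximum is ill-posed for
    functions that can be negative (net N rates); this explicit shift is
    the documented opt-in remedy.
    """
    return FunctionMatrix(fm.data - fm.data.min())


def function_maxima(fm: FunctionMatrix, top_fraction: float = 0.05) -> pd.Series:
    """Per-function "maximum": the mean of the top ``ceil(top_fraction·n)``
    observed values (at least one).

    Raises if any computed maximum is non-positive — apply
    :func:`shift_nonneg` first for functions that can be negative.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n = fm.shape[0]
    k = max(1, math.ceil(top_fraction * n))
    maxima = fm.data.apply(lambda col: col.nlargest(k).mean())
    bad = maxima[maxima <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive maximum for function(s) {', '.join(map(str, bad.index))}; "
            "apply shift_nonneg() (CLI: --shift-nonneg) before thresholding"
        )
    maxima.name = "maximum"
    return maxima


def single_threshold_counts(fm: FunctionMatrix, maxima: pd.Series, t: float) -> pd.Series:
    """Number of functions per plot with value ≥ t × the function maximum."""
    if not 0 < t < 1:
        raise ValueError("threshold t must be in (0, 1)")
    aligned = maxima.reindex(fm.data.columns)
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()])
        raise ValidationError(f"maxima missing for function(s): {', '.join(map(str, missing))}")
    counts = (fm.data >= t * aligned).sum(axis=1).astype(int)
    counts.name = f"n_functions_ge_{t:g}"
    return counts


def threshold_regression(counts: pd.Series, richness: pd.Series) -> ThresholdRegression:
    """OLS of per-plot function counts on per-plot richness.

    A constant response yields slope 0 with p = 1 (a flat curve is a valid
    observation, not an error); a constant predictor is degenerate.
    """
    x = np.asarray(richness, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(x) != len(y):
        raise ValidationError("counts and richness must be the same length")
    if len(x) < 3:
        raise ValidationError("threshold regression needs at least 3 plots")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate predictor: richness is constant")
    if np.ptp(y) == 0:
        return ThresholdRegression(
            slope=0.0, stderr=0.0, pvalue=1.0, intercept=float(y[0]),
            r_squared=0.0, n=len(x),
        )
    res = sps.linregress(x, y)
    return ThresholdRegression(
        slope=float(res.slope),
        stderr=float(res.stderr),
        pvalue=float(res.pvalue),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def multiple_threshold_analysis(
    fm: FunctionMatrix,
    maxima: pd.Series,
    richness: pd.Series,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ThresholdCurve:
    """Threshold-count regression across the full threshold grid.

    T_min is the smallest grid threshold with slope > 0 and two-sided
    p < ``alpha`` (None when no threshold qualifies); T_mde is the grid
    point of maximum slope (smallest such threshold on ties) and R_mde the
    slope attained there.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("grid must be a non-empty 1-D array of fractions")
    if not ((grid > 0) & (grid < 1)).all():
        raise ValueError("grid thresholds must lie in (0, 1)")
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid thresholds must be strictly increasing")

    rows = []
    for t in grid:
        counts = single_threshold_counts(fm, maxima, float(t))
        reg = threshold_regression(counts, richness)
        rows.append(
            {
                "threshold": float(t),
                "slope": reg.slope,
                "stderr": reg.stderr,
                "pvalue": reg.pvalue,
                "intercept": reg.intercept,
                "n": reg.n,
            }
        )
    table = pd.DataFrame(rows)

    sig = table[(table["slope"] > 0) & (table["pvalue"] < alpha)]
    t_min = float(sig["threshold"].iloc[0]) * 100 if len(sig) else None

    imax = int(table["slope"].idxmax())  # idxmax takes the first (smallest) on ties
    t_mde = float(table.loc[imax, "threshold"]) * 100
    r_mde = float(table.loc[imax, "slope"])
    return ThresholdCurve(table=table, t_min=t_min, t_mde=t_mde, r_mde=r_mde, alpha=alpha)
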