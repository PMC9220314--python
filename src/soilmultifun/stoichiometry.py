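"""Enzymatic-stoichiometry vector length: a plot-level index of microbial
carbon limitation.

The vector-length statistic places each plot in the plane of two ln-ratios
of nutrient-acquisition enzyme activities,

    x = ln βG / ln (NAG + LAP)        (C vs N acquisition)
    y = ln βG / ln ALP                (C vs P acquisition)

and takes the Euclidean norm L = sqrt(x² + y²).  A longer vector means
relatively more investment in carbon-acquiring β-glucosidase, i.e. stronger
microbial C limitation.  Activities must be in nmol g⁻¹ h⁻¹ — ratios of
logarithms are not unit-invariant, so the unit declaration is part of the
interface.

Every logarithm argument must exceed 1 (activities of ~1 nmol g⁻¹ h⁻¹ or
less would make a denominator zero or negative and the ratio meaningless).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PlotMetadata, ValidationError
from .stats import GroupTestResult, gated_t_test

#: Enzymes entering the vector-length statistic.
VECTOR_ENZYMES: tuple[str, ...] = ("bG", "NAG", "LAP", "ALP")

#: The only accepted activity unit declaration.
REQUIRED_UNITS = "nmol_g_h"


def vector_length(
    activities: pd.DataFrame,
    sqrt: bool = True,
    units: str = REQUIRED_UNITS,
) -> pd.Series:
    """Vector length L per plot from a plot × activity table.

    ``activities`` needs columns bG, NAG, LAP, ALP (nmol g⁻¹ h⁻¹).
    ``sqrt=False`` reproduces the bare sum of squares (the vector length
    squared) instead of the Euclidean norm.
    """
    if units != REQUIRED_UNITS:
        raise ValidationError(
            f"activities must be declared in {REQUIRED_UNITS!r} "
            "(nmol per g dry soil per hour); ln-ratios are unit-sensitive"
        )
    missing = [c for c in VECTOR_ENZYMES if c not in activities.columns]
    if missing:
        raise ValidationError(f"missing enzyme column(s): {', '.join(missing)}")

    bg = activities["bG"].astype(float)
    nag_lap = activities["NAG"].astype(float) + activities["LAP"].astype(float)
    alp = activities["ALP"].astype(float)

    nonpos = activities[list(VECTOR_ENZYMES)].le(0).any(axis=1)
    if nonpos.any():
        bad = list(activities.index[nonpos])
        raise ValidationError(f"non-positive enzyme activity in plot(s): {', '.join(map(str, bad))}")
    for label, arg in (("bG", bg), ("NAG+LAP", nag_lap), ("ALP", alp)):
        low = arg <= 1
        if low.any():
            bad = list(activities.index[low])
            raise ValidationError(
                f"log argument {label} <= 1 in plot(s) {', '.join(map(str, bad))}: "
                "the ln-ratio denominator would be non-positive"
            )

    x = np.log(bg) / np.log(nag_lap)
    y = np.log(bg) / np.log(alp)
    sq = x**2 + y**2
    out = np.sqrt(sq) if sqrt else sq
    out.name = "vector_length" if sqrt else "vector_length_squared"
    return out


@dataclass(frozen=True)
class CLimitationContrast:
    """Vector-length contrast between diversity levels (low − high)."""

    mean_low: float
    mean_high: float
    difference: float
    test: GroupTestResult


def compare_c_limitation(L: pd.Series, meta: PlotMetadata, **test_kwargs) -> CLimitationContrast:
    """Compare vector length between low- and high-diversity plots.

    Runs the normality-gated two-sample t-test on L; each level needs at
    least 2 plots.
    """
    low, high = meta.diversity_groups(L)
    if len(low) < 2 or len(high) < 2:
        raise ValidationError(
            f"each diversity level needs >= 2 plots (got low={len(low)}, high={len(high)})"
        )
    test = gated_t_test(low.to_numpy(), high.to_numpy(), **test_kwargs)
    return CLimitationContrast(
        mean_low=float(low.mean()),
        mean_high=float(high.mean()),
        difference=float(low.mean() - high.mean()),
        test=test,
    )
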