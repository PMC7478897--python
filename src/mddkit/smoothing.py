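"""Lowess age curves for feeding indicators.

Implements the classic Cleveland locally weighted running-line smoother
with a nearest-neighbour span: at each evaluation age the nearest
``ceil(bandwidth * n)`` observations (ties at the boundary all included)
receive tricube weights on normalized distance and a weighted
least-squares line is fitted; the curve value is that line evaluated at
the evaluation age.  No robustness iterations are performed, binary
outcomes are smoothed directly as 0/1 microdata (no pre-aggregation to
monthly proportions), and the smoother is unweighted by design weights.
The evaluation grid is the set of distinct observed ages, matching the
monthly granularity of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mddkit.scoring import score_cohort

DEFAULT_BANDWIDTH = 0.7


@dataclass(frozen=True)
class SmoothedCurve:
    """A smoothed prevalence-by-age curve.

    ``x`` is strictly increasing (the distinct observed ages), ``yhat``
    the smoothed value at each age, ``bandwidth`` the span fraction
    actually used, ``indicator`` a tag naming the smoothed outcome, and
    ``n_points`` the number of observations the fit used.
    """

    x: np.ndarray
    yhat: np.ndarray
    bandwidth: float
    indicator: str
    n_points: int

    def __post_init__(self):
        if len(self.x) != len(self.yhat):
            raise ValueError("x and yhat must have equal length")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


def _fit_at(x0: float, x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Tricube-weighted local line through the k nearest points, at x0."""
    dist = np.abs(x - x0)
    d_k = np.partition(dist, k - 1)[k - 1]
    keep = dist <= d_k  # ties at the span boundary all included
    xs, ys, ds = x[keep], y[keep], dist[keep]
    if d_k == 0.0:
        # the whole neighbourhood sits at x0
        return float(ys.mean())
    w = (1.0 - (ds / d_k) ** 3) ** 3
    sw = w.sum()
    if sw <= 0.0:
        return float(ys.mean())
    xbar = (w * xs).sum() / sw
    ybar = (w * ys).sum() / sw
    sxx = (w * (xs - xbar) ** 2).sum()
    if sxx <= 0.0:
        # all positive weight concentrated at one age: local constant fit
        return float(ybar)
    slope = (w * (xs - xbar) * (ys - ybar)).sum() / sxx
    return float(ybar + slope * (x0 - xbar))


def lowess_curve(
    ages,
    y,
    bandwidth: float = DEFAULT_BANDWIDTH,
    indicator: str = "",
) -> SmoothedCurve:
    """Smooth a 0/1 (or real) outcome against age in months.

    Parameters
    ----------
    ages : array-like of ints
        Age in months per record; at least two distinct values.
    y : array-like
        Outcome per record, smoothed directly (no aggregation).
    bandwidth : float in (0, 1]
        Nearest-neighbour span fraction; 0.7 by default.
    indicator : str
        Tag stored on the returned curve.
    """
    x = np.asarray(ages, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(x) != len(yv):
        raise ValueError("ages and y must have equal length")
    if not 0.0 < bandwidth <= 1.0:
        raise ValueError(f"bandwidth must lie in (0, 1], got {bandwidth}")
    grid = np.unique(x)
    if len(grid) < 2:
        raise ValueError("lowess needs at least two distinct ages")
    k = max(2, math.ceil(bandwidth * len(x)))
    yhat = np.array([_fit_at(x0, x, yv, k) for x0 in grid])
    return SmoothedCurve(
        x=grid, yhat=yhat, bandwidth=bandwidth, indicator=indicator,
        n_points=len(x),
    )


def indicator_curves(
    cohort: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> dict[str, SmoothedCurve]:
    """Smoothed breastfeeding, MDD-7 and MDD-8 curves on a common grid.

    Scores are computed from the cohort when not supplied.  Returns a
    dict keyed ``"breastfed"``, ``"mdd7"``, ``"mdd8"``.
    """
    if scores is None:
        scores = score_cohort(cohort)
    ages = cohort["age_months"]
    return {
        "breastfed": lowess_curve(ages, cohort["breastfed"], bandwidth, "breastfed"),
        "mdd7": lowess_curve(ages, scores["mdd7"], bandwidth, "mdd7"),
        "mdd8": lowess_curve(ages, scores["mdd8"], bandwidth, "mdd8"),
    }


def curve_gap(a: SmoothedCurve, b: SmoothedCurve) -> np.ndarray:
    """Element-wise ``a.yhat - b.yhat`` on an identical age grid."""
    if len(a.x) != len(b.x) or not np.array_equal(a.x, b.x):
        raise ValueError("curves are on different age grids")
    return a.yhat - b.yhat
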