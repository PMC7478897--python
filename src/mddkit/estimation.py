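"""Design-based estimation for stratified cluster samples.

Point estimates are Hajek ratio estimators (weighted means).  Standard
errors use first-stage Taylor linearization: the estimator is linearized
to the variate ``z_i = w_i (y_i - estimate) / sum(w)``, cluster (PSU)
totals of ``z`` are formed, and the between-PSU variance of those totals
is accumulated within strata with the usual ``n_h / (n_h - 1)`` factor:

    Var = sum_h  n_h/(n_h - 1) * sum_c (z_hc - zbar_h)^2

This is the standard linearized variance for ratio estimators under
with-replacement first-stage sampling, matching the convention of
mainstream survey software.  Subpopulations (age bands etc.) are handled
as estimation domains: out-of-domain records contribute zeros to the
linearized variate but their PSUs remain in the variance computation, so
domain SEs reflect the random domain sample size.

Confidence intervals for proportions default to the logit-transformed
interval, which respects [0, 1]; a symmetric Wald interval is available.
95% intervals use the normal quantile 1.959964 (PSU counts in the target
surveys are large enough that a t quantile would change nothing at the
reported precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

Z_95 = 1.959964  # normal 97.5% quantile, as used by common survey software


class SingletonStratumError(ValueError):
    """A stratum contains a single PSU, so its variance term is undefined.

    Raised by default rather than silently worked around, because a
    singleton PSU usually signals a mis-specified design.  Pass
    ``singleton="centered"`` to centre singleton strata at the grand
    mean of PSU totals instead.
    """


@dataclass(frozen=True)
class SurveyEstimate:
    """A design-weighted estimate with its uncertainty.

    Attributes
    ----------
    estimate : float
        Weighted proportion (in [0, 1]) or weighted mean.
    se : float
        Taylor-linearized standard error; 0 for a constant outcome.
    ci_low, ci_high : float
        95% confidence limits, ``ci_low <= estimate <= ci_high``.
    n : int
        Number of records contributing to the point estimate (domain
        size for domain estimates).
    n_psu : int
        Number of PSUs in the full design.
    method : str
        CI method tag: ``"logit"`` or ``"wald"``.
    scale : str
        ``"proportion"`` or ``"mean"``.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_psu: int
    method: str
    scale: str

    def as_percent(self) -> "SurveyEstimate":
        """Return the same estimate rescaled from [0, 1] to percent."""
        return SurveyEstimate(
            estimate=100.0 * self.estimate,
            se=100.0 * self.se,
            ci_low=100.0 * self.ci_low,
            ci_high=100.0 * self.ci_high,
            n=self.n,
            n_psu=self.n_psu,
            method=self.method,
            scale=self.scale,
        )


def _as_arrays(y, weights, clusters, strata):
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if strata is None:
        strata = np.zeros(len(y), dtype=int)
    clusters = np.asarray(clusters)
    strata = np.asarray(strata)
    if not (len(y) == len(w) == len(clusters) == len(strata)):
        raise ValueError("y, weights, clusters and strata must have equal length")
    if len(y) == 0:
        raise ValueError("cannot estimate from an empty sample")
    if (w <= 0).any():
        raise ValueError("all weights must be positive")
    return y, w, clusters, strata


def _linearized_variance(z, clusters, strata, singleton: str) -> float:
    """Between-PSU variance of the linearized variate, summed over strata."""
    # PSU totals of z, tracked per (stratum, cluster) pair
    order = np.lexsort((clusters, strata))
    s_sorted = strata[order]
    c_sorted = clusters[order]
    z_sorted = z[order]
    # boundaries where either stratum or cluster changes
    change = np.empty(len(z), dtype=bool)
    change[0] = True
    change[1:] = (s_sorted[1:] != s_sorted[:-1]) | (c_sorted[1:] != c_sorted[:-1])
    group_idx = np.cumsum(change) - 1
    psu_totals = np.bincount(group_idx, weights=z_sorted)
    psu_strata = s_sorted[change]

    variance = 0.0
    grand_mean = psu_totals.mean()
    for h in np.unique(psu_strata):
        totals_h = psu_totals[psu_strata == h]
        n_h = len(totals_h)
        if n_h < 2:
            if singleton == "centered":
                variance += float((totals_h[0] - grand_mean) ** 2)
                continue
            raise SingletonStratumError(
                f"stratum {h!r} has a single PSU; pass singleton='centered' "
                "to centre it at the grand mean of PSU totals"
            )
        dev = totals_h - totals_h.mean()
        variance += n_h / (n_h - 1) * float(dev @ dev)
    return variance


def _count_psus(clusters, strata) -> int:
    pairs = set(zip(np.asarray(strata).tolist(), np.asarray(clusters).tolist()))
    return len(pairs)


def _proportion_ci(p: float, se: float, method: str) -> tuple[float, float]:
    if method == "wald":
        return p - Z_95 * se, p + Z_95 * se
    if method != "logit":
        raise ValueError(f"unknown CI method {method!r}; use 'logit' or 'wald'")
    # logit interval collapses to the point for degenerate or constant outcomes
    if se == 0.0 or p <= 0.0 or p >= 1.0:
        return p, p
    logit = np.log(p / (1.0 - p))
    se_logit = se / (p * (1.0 - p))
    lo, hi = logit - Z_95 * se_logit, logit + Z_95 * se_logit
    return float(1.0 / (1.0 + np.exp(-lo))), float(1.0 / (1.0 + np.exp(-hi)))


def _ratio_estimate(
    y,
    weights,
    clusters,
    strata,
    domain,
    scale: str,
    method: str,
    singleton: str,
) -> SurveyEstimate:
    y, w, clusters, strata = _as_arrays(y, weights, clusters, strata)
    n_psu = _count_psus(clusters, strata)
    if domain is None:
        d = np.ones(len(y))
    else:
        d = np.asarray(domain, dtype=float)
    n_dom = int(d.sum())
    if n_dom == 0:
        return SurveyEstimate(
            estimate=float("nan"), se=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), n=0, n_psu=n_psu, method=method, scale=scale,
        )
    wd = w * d
    estimate = float((wd * y).sum() / wd.sum())
    # linearized variate of the domain ratio estimator; zero outside the domain
    z = wd * (y - estimate) / wd.sum()
    if np.allclose(y[d > 0], y[d > 0][0]):
        se = 0.0
    else:
        se = float(np.sqrt(_linearized_variance(z, clusters, strata, singleton)))
    if scale == "proportion":
        ci_low, ci_high = _proportion_ci(estimate, se, method)
    else:
        ci_low, ci_high = estimate - Z_95 * se, estimate + Z_95 * se
    return SurveyEstimate(
        estimate=estimate, se=se, ci_low=ci_low, ci_high=ci_high,
        n=n_dom, n_psu=n_psu, method=method, scale=scale,
    )


def weighted_proportion(
    y,
    weights,
    clusters,
    strata=None,
    method: str = "logit",
    domain=None,
    singleton: str = "error",
) -> SurveyEstimate:
    """Design-weighted prevalence with Taylor-linearized 95% CI.

    Parameters
    ----------
    y : array-like of 0/1
        Binary outcome per record.
    weights : array-like of positive floats
        Relative sampling weights.
    clusters : array-like
        PSU identifier per record.
    strata : array-like, optional
        Stratum identifier; a single implicit stratum when omitted.
    method : {"logit", "wald"}
        CI construction; the logit interval is the default.
    domain : array-like of 0/1, optional
        Subpopulation indicator; estimation retains the full design.
    singleton : {"error", "centered"}
        Handling of single-PSU strata.
    """
    y_arr = np.asarray(y)
    if not np.isin(y_arr, (0, 1)).all():
        raise ValueError("weighted_proportion requires a binary outcome")
    return _ratio_estimate(
        y, weights, clusters, strata, domain, "proportion", method, singleton
    )


def weighted_mean(
    y,
    weights,
    clusters,
    strata=None,
    domain=None,
    singleton: str = "error",
) -> SurveyEstimate:
    """Design-weighted mean with Taylor-linearized SE and Wald 95% CI."""
    return _ratio_estimate(
        y, weights, clusters, strata, domain, "mean", "wald", singleton
    )


def estimate_by_ageband(
    cohort,
    outcome: str = "breastfed",
    bands: Sequence[tuple[int, int]] = ((6, 11), (12, 23)),
    method: str = "logit",
    singleton: str = "error",
) -> dict[tuple[int, int], SurveyEstimate]:
    """Estimate an outcome's prevalence within age bands as domains.

    Each band ``(lo, hi)`` is inclusive.  Bands are treated as
    estimation domains — out-of-band records stay in the design with a
    zeroed linearized variate — so the SEs account for the random number
    of children per band.  An empty band yields an estimate with
    ``n = 0`` and NaN values.
    """
    ages = np.asarray(cohort["age_months"])
    out: dict[tuple[int, int], SurveyEstimate] = {}
    for lo, hi in bands:
        dom = ((ages >= lo) & (ages <= hi)).astype(float)
        out[(lo, hi)] = weighted_proportion(
            cohort[outcome],
            cohort["weight"],
            cohort["cluster_id"],
            cohort["stratum_id"],
            method=method,
            domain=dom,
            singleton=singleton,
        )
    return out


def ci_overlap(a: SurveyEstimate, b: SurveyEstimate) -> bool:
    """Whether two closed 95% CIs intersect (touching endpoints overlap)."""
    if a.scale != b.scale:
        raise ValueError("cannot compare CIs on different scales")
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
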