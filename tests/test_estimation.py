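"""Design-based estimation against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from mddkit.estimation import (
    Z_95,
    SingletonStratumError,
    SurveyEstimate,
    ci_overlap,
    estimate_by_ageband,
    weighted_mean,
    weighted_proportion,
)
from mddkit.scoring import score_cohort

from conftest import random_cohort


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_taylor_se(y, w, clusters, strata, domain=None):
    """Textbook linearized SE computed with explicit loops over strata/PSUs.

    Kept deliberately naive (lists, per-cluster sums) so it shares no
    code path with the implementation under test.
    """
    y = [float(v) for v in y]
    w = [float(v) for v in w]
    d = [1.0] * len(y) if domain is None else [float(v) for v in domain]
    wd = [wi * di for wi, di in zip(w, d)]
    total_w = sum(wd)
    est = sum(wi * yi for wi, yi in zip(wd, y)) / total_w
    z = [wi * (yi - est) / total_w for wi, yi in zip(wd, y)]
    var = 0.0
    for h in sorted(set(strata)):
        totals = []
        for c in sorted({c for c, s in zip(clusters, strata) if s == h}):
            totals.append(
                sum(zi for zi, ci, si in zip(z, clusters, strata)
                    if ci == c and si == h)
            )
        n_h = len(totals)
        mean_h = sum(totals) / n_h
        var += n_h / (n_h - 1) * sum((t - mean_h) ** 2 for t in totals)
    return est, var**0.5


def jackknife_se(y, w, clusters, strata):
    """Delete-one-PSU jackknife SE for the weighted proportion."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    clusters = np.asarray(clusters)
    strata = np.asarray(strata)
    theta = (w * y).sum() / w.sum()
    var = 0.0
    for h in np.unique(strata):
        psus = np.unique(clusters[strata == h])
        n_h = len(psus)
        for c in psus:
            drop = (strata == h) & (clusters == c)
            wj = w.copy()
            wj[drop] = 0.0
            wj[(strata == h) & ~drop] *= n_h / (n_h - 1)
            theta_j = (wj * y).sum() / wj.sum()
            var += (n_h - 1) / n_h * (theta_j - theta) ** 2
    return var**0.5


def design_fixture(seed=7, n=30, n_clusters=6, n_strata=3):
    """A small unbalanced stratified-cluster sample."""
    rng = np.random.default_rng(seed)
    clusters = np.sort(rng.integers(0, n_clusters, size=n))
    strata = clusters % n_strata
    w = rng.gamma(3.0, 1 / 3.0, size=n)
    y = rng.integers(0, 2, size=n)
    return y, w, clusters, strata


# ---------------------------------------------------------------------------
# point estimates and degenerate cases


def test_equal_weight_proportion_is_plain_mean():
    est = weighted_proportion([1, 0, 1, 0], [1, 1, 1, 1], [1, 2, 3, 4])
    assert est.estimate == pytest.approx(0.5)
    assert est.n == 4 and est.n_psu == 4


def test_constant_outcome_has_zero_se_and_collapsed_ci():
    est = weighted_proportion([1, 1, 1], [1, 2, 3], [1, 2, 3])
    assert est.estimate == 1.0
    assert est.se == 0.0
    assert est.ci_low == est.ci_high == 1.0


def test_constant_mean():
    est = weighted_mean([3, 3, 3], [1, 1, 2], [1, 2, 3])
    assert est.estimate == pytest.approx(3.0)
    assert est.se == 0.0


def test_two_psu_mean_matches_hand_algebra():
    """y = {2, 4}, equal weights, two PSUs, one stratum.

    Estimate 3; z_i = (y_i - 3)/2 gives PSU totals (-1/2, 1/2),
    variance = 2/1 * ((1/2)^2 + (1/2)^2) = 1, SE = 1.
    """
    est = weighted_mean([2, 4], [1, 1], [1, 2])
    assert est.estimate == pytest.approx(3.0)
    assert est.se == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# variance oracles


def test_taylor_se_matches_brute_force_linearization():
    y, w, clusters, strata = design_fixture()
    est = weighted_proportion(y, w, clusters, strata)
    bf_est, bf_se = brute_force_taylor_se(y, w, clusters, strata)
    assert est.estimate == pytest.approx(bf_est, abs=1e-12)
    assert est.se == pytest.approx(bf_se, abs=1e-10)


def test_taylor_se_matches_brute_force_for_means():
    rng = np.random.default_rng(11)
    _, w, clusters, strata = design_fixture(seed=11)
    y = rng.integers(0, 8, size=len(w))
    est = weighted_mean(y, w, clusters, strata)
    bf_est, bf_se = brute_force_taylor_se(y, w, clusters, strata)
    assert est.estimate == pytest.approx(bf_est, abs=1e-12)
    assert est.se == pytest.approx(bf_se, abs=1e-10)


def test_srs_reduction_closed_form():
    """Independent PSUs, equal weights, one stratum: SE = sqrt(p(1-p)/(n-1))."""
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=57)
    n = len(y)
    est = weighted_proportion(y, np.ones(n), np.arange(n))
    p = y.mean()
    assert est.se == pytest.approx(np.sqrt(p * (1 - p) / (n - 1)), abs=1e-12)


def test_taylor_close_to_delete_one_jackknife():
    y, w, clusters, strata = design_fixture(seed=19, n=120, n_clusters=12)
    est = weighted_proportion(y, w, clusters, strata)
    jk = jackknife_se(y, w, clusters, strata)
    assert est.se == pytest.approx(jk, rel=0.15)


def test_weight_scale_invariance():
    y, w, clusters, strata = design_fixture(seed=23)
    a = weighted_proportion(y, w, clusters, strata)
    b = weighted_proportion(y, 137.5 * w, clusters, strata)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)
    assert a.ci_low == pytest.approx(b.ci_low, abs=1e-12)
    assert a.ci_high == pytest.approx(b.ci_high, abs=1e-12)


# ---------------------------------------------------------------------------
# confidence intervals


def test_logit_ci_respects_unit_interval():
    rng = np.random.default_rng(5)
    y = (rng.random(40) < 0.05).astype(int)
    y[0] = 1  # ensure non-degenerate
    est = weighted_proportion(y, rng.gamma(2, 0.5, 40), np.arange(40) // 4)
    assert 0.0 <= est.ci_low <= est.estimate <= est.ci_high <= 1.0


def test_wald_ci_is_symmetric():
    y, w, clusters, strata = design_fixture(seed=31)
    est = weighted_proportion(y, w, clusters, strata, method="wald")
    assert est.ci_high - est.estimate == pytest.approx(
        est.estimate - est.ci_low, abs=1e-12
    )
    assert est.ci_high - est.estimate == pytest.approx(Z_95 * est.se, abs=1e-12)


# ---------------------------------------------------------------------------
# singleton strata, domains, age bands


def test_singleton_stratum_raises_unless_centered():
    y = [1, 0, 1, 0]
    w = [1, 1, 1, 1]
    clusters = [1, 1, 2, 2]
    strata = [1, 1, 2, 2]  # each stratum has a single PSU
    with pytest.raises(SingletonStratumError):
        weighted_proportion(y, w, clusters, strata)
    est = weighted_proportion(y, w, clusters, strata, singleton="centered")
    assert np.isfinite(est.se)


def test_domain_point_estimate_equals_naive_subset(rng):
    cohort = random_cohort(rng, n=400)
    dom = (cohort["age_months"] >= 12).astype(float).to_numpy()
    full = weighted_proportion(
        cohort["breastfed"], cohort["weight"], cohort["cluster_id"],
        domain=dom,
    )
    sub = cohort[cohort["age_months"] >= 12]
    naive = (sub["weight"] * sub["breastfed"]).sum() / sub["weight"].sum()
    assert full.estimate == pytest.approx(naive, abs=1e-12)
    assert full.n == len(sub)


def test_domain_se_matches_brute_force(rng):
    cohort = random_cohort(rng, n=300)
    dom = (cohort["age_months"] <= 11).astype(float).to_numpy()
    est = weighted_proportion(
        cohort["breastfed"], cohort["weight"], cohort["cluster_id"],
        cohort["stratum_id"], domain=dom,
    )
    _, bf_se = brute_force_taylor_se(
        cohort["breastfed"], cohort["weight"], list(cohort["cluster_id"]),
        list(cohort["stratum_id"]), domain=dom,
    )
    assert est.se == pytest.approx(bf_se, abs=1e-10)


def test_ageband_extremes():
    n = 40
    cohort = pd.DataFrame(
        {
            "cluster_id": np.arange(n) // 4,
            "stratum_id": 1,
            "weight": np.ones(n),
            "age_months": np.concatenate([np.full(20, 8), np.full(20, 18)]),
            "breastfed": np.concatenate([np.ones(20, int), np.zeros(20, int)]),
        }
    )
    bands = estimate_by_ageband(cohort)
    assert bands[(6, 11)].estimate == pytest.approx(1.0)
    assert bands[(12, 23)].estimate == pytest.approx(0.0)


def test_empty_band_is_flagged():
    cohort = pd.DataFrame(
        {
            "cluster_id": [1, 1, 2, 2],
            "stratum_id": 1,
            "weight": 1.0,
            "age_months": [7, 8, 9, 10],
            "breastfed": [1, 0, 1, 1],
        }
    )
    bands = estimate_by_ageband(cohort)
    assert bands[(12, 23)].n == 0
    assert np.isnan(bands[(12, 23)].estimate)


def test_mean_difference_equals_breastfed_prevalence(rng):
    """weighted mean8 - mean7 = weighted breastfed prevalence, exactly."""
    cohort = random_cohort(rng, n=800)
    scores = score_cohort(cohort)
    args = (cohort["weight"], cohort["cluster_id"], cohort["stratum_id"])
    m7 = weighted_mean(scores["score7"], *args)
    m8 = weighted_mean(scores["score8"], *args)
    bf = weighted_proportion(cohort["breastfed"], *args)
    assert m8.estimate - m7.estimate == pytest.approx(bf.estimate, abs=1e-10)


# ---------------------------------------------------------------------------
# CI overlap


def _interval(lo, hi):
    return SurveyEstimate(
        estimate=(lo + hi) / 2, se=1.0, ci_low=lo, ci_high=hi,
        n=10, n_psu=5, method="logit", scale="proportion",
    )


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((43.4, 51.2), (35.0, 42.1), False),  # clearly separated intervals
        ((11.1, 15.7), (9.8, 14.2), True),
        ((10.0, 20.0), (20.0, 30.0), True),   # touching endpoints: closed rule
        ((10.0, 20.0), (10.0, 20.0), True),
    ],
)
def test_ci_overlap_cases(a, b, expected):
    assert ci_overlap(_interval(*a), _interval(*b)) is expected
    assert ci_overlap(_interval(*b), _interval(*a)) is expected
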