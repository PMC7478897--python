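"""Country-level comparison of the MDD-7 and MDD-8 definitions.

Assembles one summary row per survey: breastmilk consumption by age
band, both MDD prevalences with 95% CIs, mean group counts with SEs,
and the arithmetic difference between the two indicator definitions in
percentage points.  Because every child meeting MDD-8 also meets MDD-7,
the difference (MDD-8 minus MDD-7) is never positive; its magnitude
grows with the share of older, weaned children in settings where
diversity is otherwise high.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from mddkit.estimation import (
    SurveyEstimate,
    ci_overlap,
    estimate_by_ageband,
    weighted_mean,
    weighted_proportion,
)
from mddkit.scoring import score_cohort


@dataclass(frozen=True)
class CountryComparison:
    """One survey's summary row.

    Prevalence estimates (``bf_6_11``, ``bf_12_23``, ``mdd7``, ``mdd8``)
    are on the percent scale for reporting; means are on the group-count
    scale.  ``difference_pp`` is MDD-8 minus MDD-7 in percentage points,
    computed from unrounded estimates; ``ci_nonoverlap`` flags surveys
    whose MDD-7 and MDD-8 95% CIs do not intersect.
    """

    country_label: str
    survey_year: str
    n: int
    bf_6_11: SurveyEstimate
    bf_12_23: SurveyEstimate
    mdd7: SurveyEstimate
    mdd8: SurveyEstimate
    mean7: SurveyEstimate
    mean8: SurveyEstimate
    difference_pp: float
    ci_nonoverlap: bool


def difference_pp(mdd8_pct: float, mdd7_pct: float) -> float:
    """Arithmetic difference MDD-8 minus MDD-7, in percentage points.

    Inputs are prevalences on the percent scale; the result is reported
    to one decimal by convention (rounding is left to display code).
    """
    if not (0.0 <= mdd8_pct <= 100.0 and 0.0 <= mdd7_pct <= 100.0):
        raise ValueError("prevalences must be on the percent scale [0, 100]")
    return mdd8_pct - mdd7_pct


def compare_country(
    cohort: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    label: str = "",
    year: str = "",
    method: str = "logit",
    singleton: str = "error",
) -> CountryComparison:
    """Assemble the full comparison row for one survey cohort."""
    if scores is None:
        scores = score_cohort(cohort)
    w = cohort["weight"]
    cl = cohort["cluster_id"]
    st = cohort["stratum_id"]

    bands = estimate_by_ageband(
        cohort, outcome="breastfed", method=method, singleton=singleton
    )
    mdd7 = weighted_proportion(scores["mdd7"], w, cl, st, method=method,
                               singleton=singleton)
    mdd8 = weighted_proportion(scores["mdd8"], w, cl, st, method=method,
                               singleton=singleton)
    mean7 = weighted_mean(scores["score7"], w, cl, st, singleton=singleton)
    mean8 = weighted_mean(scores["score8"], w, cl, st, singleton=singleton)

    return CountryComparison(
        country_label=label or str(cohort.get("country_label", pd.Series([""])).iloc[0]),
        survey_year=year,
        n=len(cohort),
        bf_6_11=bands[(6, 11)].as_percent(),
        bf_12_23=bands[(12, 23)].as_percent(),
        mdd7=mdd7.as_percent(),
        mdd8=mdd8.as_percent(),
        mean7=mean7,
        mean8=mean8,
        difference_pp=difference_pp(100.0 * mdd8.estimate, 100.0 * mdd7.estimate),
        ci_nonoverlap=not ci_overlap(mdd7, mdd8),
    )


def rank_differences(
    rows: list[CountryComparison],
) -> tuple[CountryComparison, CountryComparison, int]:
    """Rank surveys by the magnitude of the MDD-8 minus MDD-7 gap.

    Returns ``(largest_gap_row, smallest_gap_row, n_gap_gt5)`` where the
    count applies a strict ``|gap| > 5`` percentage-point threshold.
    """
    if not rows:
        raise ValueError("rank_differences requires at least one row")
    by_gap = sorted(rows, key=lambda r: abs(r.difference_pp))
    n_gt5 = sum(1 for r in rows if abs(r.difference_pp) > 5.0)
    return by_gap[-1], by_gap[0], n_gt5


def _fmt_pct_ci(e: SurveyEstimate) -> str:
    return f"{e.estimate:.1f} ({e.ci_low:.1f}, {e.ci_high:.1f})"


def _fmt_mean_se(e: SurveyEstimate) -> str:
    return f"{e.estimate:.1f} ({e.se:.2f})"


TABLE_COLUMNS = [
    "country",
    "survey_year",
    "n",
    "bf_6_11",
    "bf_12_23",
    "mdd7",
    "mean7",
    "mdd8",
    "mean8",
    "difference_pp",
    "ci_nonoverlap",
]


def write_comparison_table(rows: list[CountryComparison], path) -> None:
    """Write a publication-style CSV: ``x.x (lo, hi)`` prevalences,
    ``m (se)`` means, difference to one decimal."""
    table = pd.DataFrame(
        [
            {
                "country": r.country_label,
                "survey_year": r.survey_year,
                "n": r.n,
                "bf_6_11": _fmt_pct_ci(r.bf_6_11),
                "bf_12_23": _fmt_pct_ci(r.bf_12_23),
                "mdd7": _fmt_pct_ci(r.mdd7),
                "mean7": _fmt_mean_se(r.mean7),
                "mdd8": _fmt_pct_ci(r.mdd8),
                "mean8": _fmt_mean_se(r.mean8),
                "difference_pp": f"{r.difference_pp:.1f}",
                "ci_nonoverlap": int(r.ci_nonoverlap),
            }
            for r in rows
        ],
        columns=TABLE_COLUMNS,
    )
    table.to_csv(path, index=False)


_CI_RE = re.compile(r"^\s*([-\d.]+)\s*\(\s*([-\d.]+)\s*,\s*([-\d.]+)\s*\)\s*$")


def read_comparison_table(path) -> pd.DataFrame:
    """Read back a comparison table at printed precision.

    Formatted cells are split into numeric columns (``mdd7``,
    ``mdd7_lo``, ``mdd7_hi``; ``mean7``, ``mean7_se``; ...).
    """
    raw = pd.read_csv(path, dtype=object, keep_default_na=False)
    out = pd.DataFrame()
    out["country"] = raw["country"]
    out["survey_year"] = raw["survey_year"]
    if len(raw):
        out["n"] = raw["n"].astype(int)
        out["difference_pp"] = raw["difference_pp"].astype(float)
        out["ci_nonoverlap"] = raw["ci_nonoverlap"].astype(int).astype(bool)
    else:
        out["n"] = pd.Series(dtype=int)
        out["difference_pp"] = pd.Series(dtype=float)
        out["ci_nonoverlap"] = pd.Series(dtype=bool)
    for col in ("bf_6_11", "bf_12_23", "mdd7", "mdd8"):
        est, lo, hi = [], [], []
        for cell in raw.get(col, []):
            m = _CI_RE.match(cell)
            if not m:
                raise ValueError(f"unparseable cell in {col!r}: {cell!r}")
            est.append(float(m.group(1)))
            lo.append(float(m.group(2)))
            hi.append(float(m.group(3)))
        out[col], out[f"{col}_lo"], out[f"{col}_hi"] = est, lo, hi
    for col in ("mean7", "mean8"):
        est, se = [], []
        for cell in raw.get(col, []):
            parts = re.match(r"^\s*([-\d.]+)\s*\(\s*([-\d.]+)\s*\)\s*$", cell)
            if not parts:
                raise ValueError(f"unparseable cell in {col!r}: {cell!r}")
            est.append(float(parts.group(1)))
            se.append(float(parts.group(2)))
        out[col], out[f"{col}_se"] = est, se
    return out
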