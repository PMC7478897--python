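"""Published national estimates used as worked-example inputs.

Design-weighted estimates of breastmilk consumption and dietary
diversity in children aged 6-23 months, from the most recent (2011-2017)
Demographic and Health Surveys of 14 countries in Eastern and Southern
Africa, as printed in the published comparison of the MDD-7 and MDD-8
definitions.  These are inputs for the table-level operations
(:func:`mddkit.comparison.difference_pp`,
:func:`mddkit.comparison.rank_differences`,
:func:`mddkit.estimation.ci_overlap`) — reproducing the underlying
child-level estimates requires registered survey microdata and is out of
scope; the full estimation pipeline is instead exercised on synthetic
cohorts with known truth.

Prevalences are percentages; CIs are 95%; means are group counts with
SEs in parentheses in the source, stored here as separate fields.
"""

from __future__ import annotations

import pandas as pd

#: Columns: country, survey_year, n, breastmilk prevalence by age band
#: (% and 95% CI), MDD-7 and MDD-8 prevalence (% and 95% CI), mean
#: 7- and 8-group counts (and SEs), published difference (MDD-8 − MDD-7)
#: in percentage points.
_ROWS = [
    # country, year, n, bf611, lo, hi, bf1223, lo, hi,
    #   mdd7, lo, hi, mean7, se7, mdd8, lo, hi, mean8, se8, diff_pp
    ("Angola", "2015-16", 4259, 91.8, 89.5, 93.6, 63.7, 58.9, 64.2,
     31.5, 28.7, 34.5, 2.7, 0.06, 27.8, 25.2, 30.6, 3.5, 0.06, -3.7),
    ("Burundi", "2016-17", 4054, 96.4, 94.9, 97.5, 85.3, 83.7, 86.7,
     18.4, 17.0, 20.0, 2.4, 0.03, 16.6, 15.1, 18.1, 3.3, 0.03, -1.8),
    ("Congo-DRC", "2013-14", 5221, 96.0, 94.2, 97.3, 75.4, 73.1, 77.5,
     19.4, 16.7, 22.1, 2.3, 0.05, 16.5, 14.2, 19.1, 3.1, 0.05, -2.9),
    ("Ethiopia", "2016", 2965, 93.4, 89.3, 96.1, 79.3, 76.3, 82.1,
     13.4, 11.1, 15.7, 1.8, 0.05, 12.0, 9.8, 14.2, 2.7, 0.06, -1.4),
    ("Kenya", "2014", 2906, 97.3, 95.3, 98.5, 70.9, 68.0, 73.6,
     40.1, 37.3, 42.9, 3.1, 0.05, 35.4, 32.7, 38.1, 3.9, 0.05, -4.7),
    ("Lesotho", "2014", 957, 83.9, 78.2, 88.3, 52.7, 48.1, 57.2,
     23.2, 19.7, 26.8, 2.5, 0.01, 17.0, 14.1, 20.0, 3.2, 0.01, -6.2),
    ("Malawi", "2015-16", 4879, 91.9, 89.9, 93.5, 80.5, 78.6, 82.2,
     24.7, 22.8, 26.5, 2.5, 0.03, 22.2, 20.5, 24.0, 3.3, 0.03, -2.5),
    ("Mozambique", "2011", 3339, 93.5, 91.6, 95.0, 73.3, 70.9, 75.6,
     29.9, 28.0, 32.3, 2.8, 0.05, 27.4, 25.7, 30.0, 3.6, 0.05, -2.5),
    ("Rwanda", "2014-15", 2430, 97.0, 95.5, 98.0, 86.7, 84.7, 88.5,
     29.5, 26.7, 32.2, 2.7, 0.04, 27.4, 24.3, 29.9, 3.6, 0.04, -2.1),
    ("South Africa", "2016", 872, 61.1, 52.1, 69.3, 34.7, 30.0, 39.6,
     47.4, 43.4, 51.2, 3.5, 0.08, 38.5, 35.0, 42.1, 4.0, 0.07, -8.9),
    ("Tanzania", "2015-16", 3170, 96.5, 94.6, 97.7, 68.2, 65.8, 70.5,
     25.6, 23.4, 27.9, 2.7, 0.04, 20.7, 18.7, 22.7, 3.5, 0.04, -4.9),
    ("Uganda", "2016", 4418, 94.8, 93.2, 96.0, 61.3, 59.1, 63.5,
     28.6, 26.7, 30.5, 2.7, 0.04, 24.0, 22.2, 25.7, 3.5, 0.04, -4.6),
    ("Zambia", "2013-14", 3776, 96.6, 95.1, 97.7, 72.5, 70.2, 74.7,
     21.8, 19.8, 23.7, 2.5, 0.03, 18.2, 16.4, 19.9, 3.3, 0.03, -3.6),
    ("Zimbabwe", "2015", 1656, 96.1, 93.8, 97.6, 57.0, 53.6, 60.4,
     28.2, 25.6, 30.9, 2.7, 0.05, 21.5, 19.0, 23.9, 3.4, 0.05, -6.7),
]

_COLUMNS = [
    "country", "survey_year", "n",
    "bf_6_11", "bf_6_11_lo", "bf_6_11_hi",
    "bf_12_23", "bf_12_23_lo", "bf_12_23_hi",
    "mdd7", "mdd7_lo", "mdd7_hi", "mean7", "mean7_se",
    "mdd8", "mdd8_lo", "mdd8_hi", "mean8", "mean8_se",
    "difference_pp",
]


def published_estimates() -> pd.DataFrame:
    """The 14 published survey rows as a DataFrame (percent scale)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def published_comparison_rows() -> list:
    """The published rows as :class:`~mddkit.comparison.CountryComparison`.

    SEs are back-calculated from the printed 95% CI half-widths (a Wald
    approximation, adequate at printed precision); differences use the
    printed values.  PSU counts are not published and are set to 0.
    """
    from mddkit.comparison import CountryComparison, difference_pp
    from mddkit.estimation import Z_95, SurveyEstimate, ci_overlap

    def pct(e, lo, hi, n):
        return SurveyEstimate(
            estimate=e, se=(hi - lo) / (2 * Z_95), ci_low=lo, ci_high=hi,
            n=n, n_psu=0, method="logit", scale="proportion",
        )

    def mean(e, se, n):
        return SurveyEstimate(
            estimate=e, se=se, ci_low=e - Z_95 * se, ci_high=e + Z_95 * se,
            n=n, n_psu=0, method="wald", scale="mean",
        )

    rows = []
    for r in published_estimates().itertuples(index=False):
        mdd7 = pct(r.mdd7, r.mdd7_lo, r.mdd7_hi, r.n)
        mdd8 = pct(r.mdd8, r.mdd8_lo, r.mdd8_hi, r.n)
        rows.append(
            CountryComparison(
                country_label=r.country,
                survey_year=r.survey_year,
                n=r.n,
                bf_6_11=pct(r.bf_6_11, r.bf_6_11_lo, r.bf_6_11_hi, r.n),
                bf_12_23=pct(r.bf_12_23, r.bf_12_23_lo, r.bf_12_23_hi, r.n),
                mdd7=mdd7,
                mdd8=mdd8,
                mean7=mean(r.mean7, r.mean7_se, r.n),
                mean8=mean(r.mean8, r.mean8_se, r.n),
                difference_pp=difference_pp(r.mdd8, r.mdd7),
                ci_nonoverlap=not ci_overlap(mdd7, mdd8),
            )
        )
    return rows
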