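"""Canonical child-level cohort representation.

A cohort is a pandas DataFrame with one row per eligible child aged
6-23 months.  The required columns are the survey-design variables
(cluster, stratum, weight), age in completed months, a breastmilk
indicator for the previous 24 h, and seven binary food-group
consumption indicators for the same recall window.
"""

from __future__ import annotations

import pandas as pd

#: The seven complementary-food groups of the 7-group diversity score,
#: in the conventional IYCF order.  Breastmilk is tracked separately
#: (column ``breastfed``) and enters only the 8-group score.
FOOD_GROUPS: tuple[str, ...] = (
    "grains_roots_tubers",
    "legumes_nuts",
    "dairy",
    "flesh_foods",
    "eggs",
    "vita_fruits_vegetables",
    "other_fruits_vegetables",
)

#: Columns every cohort frame must carry.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "child_id",
    "cluster_id",
    "stratum_id",
    "weight",
    "age_months",
    "breastfed",
    *FOOD_GROUPS,
)

AGE_MIN = 6
AGE_MAX = 23


class CohortSchemaError(ValueError):
    """A cohort frame violates the required schema or an invariant."""


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants, returning the frame unchanged.

    Raises
    ------
    CohortSchemaError
        If a required column is missing, a weight is non-positive, an
        age lies outside 6-23 completed months, or an indicator is not
        0/1.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"cohort is missing required columns: {missing}")
    if len(cohort) == 0:
        return cohort
    if (cohort["weight"] <= 0).any():
        raise CohortSchemaError("cohort contains non-positive sampling weights")
    ages = cohort["age_months"]
    if ((ages < AGE_MIN) | (ages > AGE_MAX)).any():
        raise CohortSchemaError(
            f"cohort contains ages outside [{AGE_MIN}, {AGE_MAX}] months"
        )
    for col in ("breastfed", *FOOD_GROUPS):
        if not cohort[col].isin((0, 1)).all():
            raise CohortSchemaError(f"column {col!r} contains values other than 0/1")
    return cohort
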