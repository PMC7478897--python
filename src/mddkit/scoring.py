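"""Per-child dietary diversity scores and MDD classifications.

The 7-group score counts the complementary-food groups consumed in the
previous 24 h; the 8-group score adds breastmilk as an eighth group.
The minimum-dietary-diversity indicators apply inclusive thresholds:
MDD-7 is ``score7 >= 4`` and MDD-8 is ``score8 >= 5``.  Because
``score8 = score7 + breastfed`` with breastfed in {0, 1}, a child
meeting MDD-8 always meets MDD-7, so MDD-8 prevalence can never exceed
MDD-7 prevalence.  The thresholds are deliberately not configurable:
the two fixed definitions are the object of comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from mddkit.cohort import FOOD_GROUPS

MDD7_THRESHOLD = 4
MDD8_THRESHOLD = 5


@dataclass(frozen=True)
class DiversityScore:
    """Diversity scores and MDD classifications for one child."""

    score7: int
    score8: int
    mdd7: bool
    mdd8: bool


def score_child(record: Mapping) -> DiversityScore:
    """Score a single child record (any mapping with the cohort columns).

    ``score7`` sums the seven food-group indicators, ``score8`` adds the
    breastmilk indicator, and the MDD flags apply the inclusive >=4 / >=5
    thresholds.
    """
    score7 = int(sum(int(record[g]) for g in FOOD_GROUPS))
    score8 = score7 + int(record["breastfed"])
    return DiversityScore(
        score7=score7,
        score8=score8,
        mdd7=score7 >= MDD7_THRESHOLD,
        mdd8=score8 >= MDD8_THRESHOLD,
    )


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score every child, returning a frame aligned to the input index.

    Returns a DataFrame with integer columns ``score7`` and ``score8``
    and 0/1 columns ``mdd7`` and ``mdd8``, one row per input row in the
    same order.
    """
    score7 = cohort[list(FOOD_GROUPS)].astype(int).sum(axis=1)
    score8 = score7 + cohort["breastfed"].astype(int)
    return pd.DataFrame(
        {
            "score7": score7,
            "score8": score8,
            "mdd7": (score7 >= MDD7_THRESHOLD).astype(int),
            "mdd8": (score8 >= MDD8_THRESHOLD).astype(int),
        },
        index=cohort.index,
    )
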