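"""Reading child-level microdata from delimited files.

Survey datasets arrive with survey-specific column names and often with
item-level diet questions (e.g. separate milk / yogurt / cheese items)
rather than ready-made group indicators.  A :class:`ColumnMapping`
declares where each design variable lives and which item columns feed
each of the seven food groups; item responses are OR-aggregated, so a
group is counted as consumed when any of its items is.

Missing-data convention: a missing single diet item is treated as "not
consumed"; a record is dropped (and counted) only when every diet item,
breastmilk included, is missing.  This is the usual convention in
large-survey indicator work, where item-level missingness is rare and
non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from mddkit.cohort import AGE_MAX, AGE_MIN, FOOD_GROUPS

DEFAULT_TRUTHY = ("1", "yes")


class SchemaError(ValueError):
    """The input file does not match the column mapping."""


@dataclass
class ColumnMapping:
    """Mapping from source columns to the canonical cohort schema.

    ``groups`` maps each canonical food-group name to one or more source
    item columns (OR-aggregated).  ``truthy`` lists the values counted
    as consumption after lowercasing/stripping; everything else,
    including ``missing_codes``, is falsy.  ``stratum`` may be omitted
    (single implicit stratum); ``household_id`` enables
    youngest-child-per-household de-duplication downstream.
    """

    cluster: str
    weight: str
    age: str
    breastmilk: str
    groups: dict[str, list[str]]
    stratum: str | None = None
    household_id: str | None = None
    child_id: str | None = None
    truthy: tuple[str, ...] = DEFAULT_TRUTHY
    missing_codes: tuple[str, ...] = ("", ".", "na", "nan", "9", "99")

    def validate(self) -> "ColumnMapping":
        missing = [g for g in FOOD_GROUPS if not self.groups.get(g)]
        if missing:
            raise SchemaError(f"groups without a mapped source column: {missing}")
        seen: dict[str, str] = {}
        for g, cols in self.groups.items():
            for c in cols:
                if c in seen:
                    raise SchemaError(
                        f"source column {c!r} mapped to both {seen[c]!r} and {g!r}"
                    )
                seen[c] = g
        return self

    @property
    def item_columns(self) -> list[str]:
        return [c for g in FOOD_GROUPS for c in self.groups[g]]

    def all_columns(self) -> list[str]:
        cols = [self.cluster, self.weight, self.age, self.breastmilk]
        cols += self.item_columns
        for opt in (self.stratum, self.household_id, self.child_id):
            if opt is not None:
                cols.append(opt)
        return cols

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw = dict(raw)
        if "truthy" in raw:
            raw["truthy"] = tuple(str(v) for v in raw["truthy"])
        if "missing_codes" in raw:
            raw["missing_codes"] = tuple(str(v) for v in raw["missing_codes"])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        data = {
            "cluster": self.cluster,
            "weight": self.weight,
            "age": self.age,
            "breastmilk": self.breastmilk,
            "groups": {g: list(c) for g, c in self.groups.items()},
        }
        for opt in ("stratum", "household_id", "child_id"):
            if getattr(self, opt) is not None:
                data[opt] = getattr(self, opt)
        data["truthy"] = list(self.truthy)
        data["missing_codes"] = list(self.missing_codes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_mapping() -> ColumnMapping:
    """Identity mapping for files in the canonical cohort schema
    (as written by the synthetic generator)."""
    return ColumnMapping(
        cluster="cluster_id",
        stratum="stratum_id",
        weight="weight",
        age="age_months",
        breastmilk="breastfed",
        child_id="child_id",
        groups={g: [g] for g in FOOD_GROUPS},
    ).validate()


@dataclass
class IngestReport:
    """Accounting of rows read, kept and excluded (with reasons)."""

    n_rows_read: int = 0
    n_records: int = 0
    excluded_age: int = 0
    excluded_weight: int = 0
    excluded_all_items_missing: int = 0
    row_errors: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_rows_read - self.n_records

    def summary(self) -> str:
        lines = [
            f"rows read: {self.n_rows_read}",
            f"records kept: {self.n_records}",
            f"excluded, age outside {AGE_MIN}-{AGE_MAX} months: {self.excluded_age}",
            f"excluded, non-positive weight: {self.excluded_weight}",
            f"excluded, all diet items missing: {self.excluded_all_items_missing}",
            f"row errors: {len(self.row_errors)}",
        ]
        lines.extend(f"  {e}" for e in self.row_errors)
        return "\n".join(lines)


def _maybe_int_ids(series: pd.Series) -> pd.Series:
    """Convert id-like columns to integers when possible, else keep strings."""
    try:
        return series.astype(int)
    except (ValueError, TypeError):
        return series.astype(str)


def read_child_records(
    path, mapping: ColumnMapping, delimiter: str = ","
) -> tuple[pd.DataFrame, IngestReport]:
    """Read, validate and aggregate a delimited microdata file.

    Returns a cohort DataFrame in the canonical schema (plus a
    ``household_id`` column when mapped) together with an
    :class:`IngestReport` counting exclusions by reason.

    Raises
    ------
    SchemaError
        If the header lacks a mapped column.
    """
    mapping.validate()
    path = Path(path)
    raw = pd.read_csv(
        path, sep=delimiter, dtype=object, keep_default_na=False, encoding="utf-8"
    )
    missing_cols = [c for c in mapping.all_columns() if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"input file lacks mapped columns: {missing_cols}")

    report = IngestReport(n_rows_read=len(raw))
    truthy = {t.strip().lower() for t in mapping.truthy}
    missing = {m.strip().lower() for m in mapping.missing_codes}

    def norm(col: str) -> pd.Series:
        return raw[col].astype(str).str.strip().str.lower()

    weight = pd.to_numeric(raw[mapping.weight], errors="coerce")
    age = pd.to_numeric(raw[mapping.age], errors="coerce")

    bad_weight_parse = weight.isna()
    bad_age_parse = age.isna() | (age != age.round())
    parse_bad = bad_weight_parse | bad_age_parse
    for idx in raw.index[parse_bad]:
        which = mapping.weight if bad_weight_parse[idx] else mapping.age
        report.row_errors.append(
            f"row {idx}: unparseable value in column {which!r}"
        )

    diet_cols = [mapping.breastmilk, *mapping.item_columns]
    diet_norm = pd.concat([norm(c) for c in diet_cols], axis=1)
    all_items_missing = diet_norm.isin(missing).all(axis=1)

    keep = ~parse_bad
    age_bad = keep & ((age < AGE_MIN) | (age > AGE_MAX))
    report.excluded_age = int(age_bad.sum())
    keep &= ~age_bad
    weight_bad = keep & (weight <= 0)
    report.excluded_weight = int(weight_bad.sum())
    keep &= ~weight_bad
    missing_bad = keep & all_items_missing
    report.excluded_all_items_missing = int(missing_bad.sum())
    keep &= ~missing_bad

    kept = raw.index[keep]
    cohort = pd.DataFrame(index=pd.RangeIndex(len(kept)))
    if mapping.child_id is not None:
        cohort["child_id"] = _maybe_int_ids(raw.loc[kept, mapping.child_id]).to_numpy()
    else:
        cohort["child_id"] = (kept + 1).to_numpy()
    cohort["cluster_id"] = _maybe_int_ids(raw.loc[kept, mapping.cluster]).to_numpy()
    if mapping.stratum is not None:
        cohort["stratum_id"] = _maybe_int_ids(raw.loc[kept, mapping.stratum]).to_numpy()
    else:
        cohort["stratum_id"] = 1
    cohort["weight"] = weight[kept].to_numpy()
    cohort["age_months"] = age[kept].astype(int).to_numpy()
    cohort["breastfed"] = norm(mapping.breastmilk)[kept].isin(truthy).astype(int).to_numpy()
    for g in FOOD_GROUPS:
        consumed = pd.Series(False, index=raw.index)
        for c in mapping.groups[g]:
            consumed |= norm(c).isin(truthy)
        cohort[g] = consumed[kept].astype(int).to_numpy()
    if mapping.household_id is not None:
        cohort["household_id"] = _maybe_int_ids(
            raw.loc[kept, mapping.household_id]
        ).to_numpy()

    report.n_records = len(cohort)
    return cohort, report


def dedupe_youngest(
    records: pd.DataFrame, household_col: str = "household_id"
) -> pd.DataFrame:
    """Keep one record per household: the youngest child.

    Mirrors the survey convention of asking the diet module about the
    youngest 6-23-month-old child in each household.  Age ties are
    broken by the smallest ``child_id`` (deterministic).
    """
    if household_col not in records.columns:
        raise SchemaError(f"records lack household column {household_col!r}")
    ordered = records.sort_values(
        ["age_months", "child_id"], kind="stable"
    ).drop_duplicates(subset=household_col, keep="first")
    return ordered.sort_index().reset_index(drop=True)
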