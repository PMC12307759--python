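"""Missing-data audit, categorization into analysis groups, and exclusions.

The raw food-loss sources label observations with fine-grained commodity
and activity names (hundreds of distinct strings). Analysis happens at the
level of 11 commodity groups and 8 supply-chain stages; the raw → group
maps are data files, not code, so users can audit and extend them. The
screening stage then (a) summarizes missingness across fields, years and
countries, (b) drops whole groups with insufficient temporal/geographic
coverage, and (c) applies listwise deletion of records missing any
modelling variable. No imputation is ever performed: the missingness in
these sources is structural (reporting gaps), not random loss.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

COMMODITY_GROUPS = (
    "grains",
    "roots and tubers",
    "vegetables",
    "fruits",
    "pulses",
    "meat products",
    "dairy and eggs",
    "oilseeds",
    "sugar products",
    "beverages",
    "others",
)

ACTIVITY_GROUPS = (
    "harvest and on-farm operations",
    "processing",
    "transport and distribution",
    "storage",
    "marketing and retail",
    "consumption",
    "packaging",
    "others",
)


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryMap:
    """Raw-label → group maps for commodities and activities.

    Group vocabularies are closed sets; a raw label maps to exactly one
    group. The shipped default covers the synthetic label vocabulary plus a
    starter set of common FAO-style names — a stand-in, since no canonical
    public mapping exists.
    """

    commodity: dict[str, str] = field(default_factory=dict)
    activity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad_c = set(self.commodity.values()) - set(COMMODITY_GROUPS)
        bad_a = set(self.activity.values()) - set(ACTIVITY_GROUPS)
        if bad_c:
            raise ScreeningError(f"unknown commodity groups in map: {sorted(bad_c)}")
        if bad_a:
            raise ScreeningError(f"unknown activity groups in map: {sorted(bad_a)}")

    @staticmethod
    def _read(path) -> dict[str, str]:
        df = pd.read_csv(path, dtype=str)
        if list(df.columns[:2]) != ["raw_label", "group"]:
            raise ScreeningError("category map CSV needs columns raw_label,group")
        dup = df.duplicated(subset="raw_label", keep=False)
        if dup.any():
            conflicts = df.loc[dup].groupby("raw_label")["group"].nunique()
            if (conflicts > 1).any():
                raise ScreeningError(
                    f"raw labels mapped to multiple groups: "
                    f"{list(conflicts[conflicts > 1].index)}"
                )
        return dict(zip(df["raw_label"], df["group"]))

    @classmethod
    def from_csvs(cls, commodity_path, activity_path) -> "CategoryMap":
        return cls(
            commodity=cls._read(commodity_path), activity=cls._read(activity_path)
        )

    @classmethod
    def default(cls) -> "CategoryMap":
        pkg = resources.files("foodloss.data")
        with pkg.joinpath("commodity_map.csv").open("rb") as fc:
            commodity = cls._read(io.BytesIO(fc.read()))
        with pkg.joinpath("activity_map.csv").open("rb") as fa:
            activity = cls._read(io.BytesIO(fa.read()))
        return cls(commodity=commodity, activity=activity)

    def raw_labels_by_group(self, kind: str) -> dict[str, list[str]]:
        mapping = self.commodity if kind == "commodity" else self.activity
        out: dict[str, list[str]] = {}
        for raw, group in mapping.items():
            out.setdefault(group, []).append(raw)
        return {g: sorted(v) for g, v in out.items()}


@dataclass
class CategorizationReport:
    n_records: int
    n_distinct_commodities: int
    n_distinct_activities: int
    unmapped_commodities: list[str]
    unmapped_activities: list[str]


def categorize(
    records: pd.DataFrame, category_map: CategoryMap | None = None
) -> tuple[pd.DataFrame, CategorizationReport]:
    """Assign commodity_group / activity_group from the raw labels.

    Every record is either grouped or its raw label listed in the report;
    records with unmapped labels are retained with the group field absent —
    never silently dropped. Input is not mutated.
    """
    cmap = category_map if category_map is not None else CategoryMap.default()
    out = records.copy()
    out["commodity_group"] = out["commodity_raw"].map(cmap.commodity)
    out["activity_group"] = out["activity_raw"].map(cmap.activity)

    raw_c = out["commodity_raw"].dropna().unique()
    raw_a = out["activity_raw"].dropna().unique()
    report = CategorizationReport(
        n_records=len(out),
        n_distinct_commodities=len(raw_c),
        n_distinct_activities=len(raw_a),
        unmapped_commodities=sorted(set(raw_c) - set(cmap.commodity)),
        unmapped_activities=sorted(set(raw_a) - set(cmap.activity)),
    )
    return out, report


# ---------------------------------------------------------------------------
# missingness audit


@dataclass
class MissingnessReport:
    """Deterministic audit of missingness across fields, years, countries."""

    n_total: int
    n_analyzable: int
    field_missing_frac: dict[str, float]
    per_year: pd.DataFrame
    per_country: pd.DataFrame
    group_crosstab: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_analyzable": self.n_analyzable,
            "field_missing_frac": self.field_missing_frac,
            "per_year": self.per_year.to_dict(orient="list"),
            "per_country": self.per_country.to_dict(orient="list"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = [
            f"records: {self.n_total} total, {self.n_analyzable} analyzable",
            "missing fractions:",
        ]
        for fld, frac in sorted(self.field_missing_frac.items()):
            lines.append(f"  {fld:<15s} {frac:6.1%}")
        lines.append("observations per commodity group x activity group:")
        lines.append(self.group_crosstab.to_string())
        return "\n".join(lines)


def missingness_report(records: pd.DataFrame) -> MissingnessReport:
    """Summarize missingness in the key fields, by year and by country.

    A record is *analyzable* when commodity label, activity label and FLP
    are all present — the variables listwise deletion conditions on.
    """
    fields = ["commodity_raw", "activity_raw", "flp"]
    n = len(records)
    frac = {
        f: (float(records[f].isna().mean()) if n else 0.0) for f in fields
    }
    complete = records[fields].notna().all(axis=1)

    per_year = (
        records.assign(complete=complete)
        .groupby("year")
        .agg(n_records=("year", "size"), n_complete=("complete", "sum"))
        .reset_index()
    )
    per_country = (
        records.assign(complete=complete)
        .groupby("country")
        .agg(n_records=("country", "size"), n_complete=("complete", "sum"))
        .reset_index()
    )
    if {"commodity_group", "activity_group"}.issubset(records.columns):
        crosstab = pd.crosstab(
            records["commodity_group"], records["activity_group"], dropna=True
        )
    else:
        crosstab = pd.DataFrame()

    return MissingnessReport(
        n_total=n,
        n_analyzable=int(complete.sum()),
        field_missing_frac=frac,
        per_year=per_year,
        per_country=per_country,
        group_crosstab=crosstab,
    )


# ---------------------------------------------------------------------------
# exclusions


@dataclass(frozen=True)
class ExclusionRule:
    """Coverage thresholds a group must meet to stay in the analysis.

    The defaults (30 observations, 3 countries, 3 years) make "insufficient
    temporal and geographic coverage" an explicit, reported choice.
    """

    min_obs: int = 30
    min_countries: int = 3
    min_years: int = 3

    def __post_init__(self) -> None:
        if min(self.min_obs, self.min_countries, self.min_years) < 1:
            raise ScreeningError("all exclusion thresholds must be >= 1")


@dataclass
class ExclusionLog:
    n_input: int
    n_retained: int
    n_group_dropped: int
    n_listwise_dropped: int
    excluded_groups: dict[str, list[str]]

    def check_conservation(self) -> None:
        if self.n_input != (
            self.n_retained + self.n_group_dropped + self.n_listwise_dropped
        ):
            raise ScreeningError("exclusion counts do not reconcile")


def apply_exclusions(
    records: pd.DataFrame,
    rule: ExclusionRule | None = None,
    axes: tuple[str, ...] = ("commodity_group", "activity_group"),
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop under-covered groups wholesale, then listwise-delete.

    Group coverage is computed on records with FLP present. After group
    drops, listwise deletion removes records missing flp or any group field
    named in *axes* (the modelling variables). Retained + dropped always
    sums to the input count.
    """
    rule = rule if rule is not None else ExclusionRule()
    n_input = len(records)
    out = records.copy()

    excluded: dict[str, list[str]] = {}
    for axis in axes:
        usable = out[out["flp"].notna() & out[axis].notna()]
        stats = usable.groupby(axis).agg(
            n_obs=("flp", "size"),
            n_countries=("country", "nunique"),
            n_years=("year", "nunique"),
        )
        bad = stats[
            (stats["n_obs"] < rule.min_obs)
            | (stats["n_countries"] < rule.min_countries)
            | (stats["n_years"] < rule.min_years)
        ].index.tolist()
        # groups present in the data but with zero usable observations fail too
        present = set(out[axis].dropna().unique())
        bad = sorted(set(bad) | (present - set(stats.index)))
        excluded[axis] = bad
        if bad and set(bad) == present:
            raise ScreeningError(f"all {axis} groups excluded by rule {rule}")

    group_mask = pd.Series(False, index=out.index)
    for axis in axes:
        group_mask |= out[axis].isin(excluded[axis])
    n_group_dropped = int(group_mask.sum())
    out = out[~group_mask]

    listwise_fields = ["flp", *axes]
    listwise_mask = out[listwise_fields].isna().any(axis=1)
    n_listwise = int(listwise_mask.sum())
    out = out[~listwise_mask].reset_index(drop=True)

    log = ExclusionLog(
        n_input=n_input,
        n_retained=len(out),
        n_group_dropped=n_group_dropped,
        n_listwise_dropped=n_listwise,
        excluded_groups=excluded,
    )
    log.check_conservation()
    return out, log
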