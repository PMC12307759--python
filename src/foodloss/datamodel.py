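"""Shared data model and I/O for the indicator panel and food-loss records.

Two tabular containers flow through the package, both plain pandas
DataFrames validated by the functions here:

* the **indicator panel** — one row per (country, year) with the three
  socioeconomic indicators used to build the development typology:
  GDP per capita (``gdp_pc``, USD), GDP growth rate (``growth``, percent,
  may be negative) and health expenditure per capita (``health_pc``, USD);
* **food-loss records** — one row per observed (country, year, commodity,
  supply-chain activity) cell with the food-loss percentage ``flp`` on the
  0–100 scale, raw source labels kept for audit, and (after screening)
  the analytical ``commodity_group`` / ``activity_group`` assignments.

Missing values are carried end to end as NaN sentinels; no imputation is
ever performed. Years are stored as plain integers — the (year − 2000)
covariate transform belongs to the modelling layer, never to ingest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INDICATORS = ("gdp_pc", "growth", "health_pc")

PANEL_COLUMNS = ("country", "year") + INDICATORS

FLP_COLUMNS = (
    "country",
    "year",
    "commodity_raw",
    "activity_raw",
    "flp",
    "commodity_group",
    "activity_group",
)

#: strings treated as explicit missing markers in source CSVs
NA_VALUES = ["", "n/a", "N/A", "NA", "na", "..", "...", "null", "NULL"]


class DataModelError(ValueError):
    """Raised on contract violations in the shared data model."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataModelError(f"{what} is missing required columns: {missing}")


def validate_indicator_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate panel invariants; returns the (unmodified) frame.

    Enforces unique (country, year) keys, integer years, and non-negative
    gdp_pc / health_pc where present. Growth may be negative.
    """
    _check_columns(panel, ["country", "year"], "indicator panel")
    dup = panel.duplicated(subset=["country", "year"], keep=False)
    if dup.any():
        keys = (
            panel.loc[dup, ["country", "year"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise DataModelError(f"duplicate (country, year) keys: {sorted(keys)}")
    if not np.issubdtype(panel["year"].dtype, np.integer):
        raise DataModelError("year column must be integer-typed")
    for col in ("gdp_pc", "health_pc"):
        if col in panel.columns and (panel[col].dropna() < 0).any():
            raise DataModelError(f"{col} contains negative values")
    return panel


def validate_flp_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate food-loss record invariants; returns the frame."""
    _check_columns(records, ["country", "year", "flp"], "FLP records")
    flp = records["flp"].dropna()
    if ((flp < 0) | (flp > 100)).any():
        bad = flp[(flp < 0) | (flp > 100)]
        raise DataModelError(
            f"flp outside [0, 100] in {len(bad)} records (e.g. {bad.iloc[0]!r})"
        )
    return records


# ---------------------------------------------------------------------------
# indicator panel I/O


def read_indicator_panel(path, dialect: str = "long") -> pd.DataFrame:
    """Read an indicator panel CSV in ``long`` or ``wide`` dialect.

    ``long`` expects columns country, year, gdp_pc, growth, health_pc.
    ``wide`` (World-Bank style) expects country, indicator, then one column
    per year; it is melted and pivoted to one row per (country, year).
    Unparseable numerics become explicit NaN, never zero.
    """
    if dialect == "long":
        df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=True)
        _check_columns(df, PANEL_COLUMNS, "long indicator CSV")
        df = df.loc[:, list(PANEL_COLUMNS)]
    elif dialect == "wide":
        raw = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=True)
        _check_columns(raw, ["country", "indicator"], "wide indicator CSV")
        year_cols = [c for c in raw.columns if c not in ("country", "indicator")]
        if not year_cols:
            raise DataModelError("wide indicator CSV has no year columns")
        long = raw.melt(
            id_vars=["country", "indicator"],
            value_vars=year_cols,
            var_name="year",
            value_name="value",
        )
        long["year"] = long["year"].astype(int)
        df = (
            long.pivot_table(
                index=["country", "year"],
                columns="indicator",
                values="value",
                aggfunc="first",
                dropna=False,
            )
            .reset_index()
            .rename_axis(columns=None)
        )
        for ind in INDICATORS:
            if ind not in df.columns:
                df[ind] = np.nan
        df = df.loc[:, list(PANEL_COLUMNS)]
        # drop (country, year) rows where every indicator is absent: artefacts
        # of rectangular wide layouts, not observations
        df = df.dropna(subset=list(INDICATORS), how="all").reset_index(drop=True)
    else:
        raise DataModelError(f"unknown indicator dialect: {dialect!r}")

    for ind in INDICATORS:
        df[ind] = pd.to_numeric(df[ind], errors="coerce")
    df["year"] = df["year"].astype(int)
    df = df.sort_values(["country", "year"], kind="mergesort").reset_index(drop=True)
    return validate_indicator_panel(df)


def write_indicator_panel(panel: pd.DataFrame, path) -> None:
    validate_indicator_panel(panel)
    panel.loc[:, list(PANEL_COLUMNS)].to_csv(path, index=False)


def read_flp_records(path) -> pd.DataFrame:
    """Read long-format food-loss records; group columns optional on disk."""
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=True)
    _check_columns(df, ["country", "year", "flp"], "FLP CSV")
    for col in FLP_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(np.nan, index=df.index, dtype=object)
    df["year"] = df["year"].astype(int)
    df["flp"] = pd.to_numeric(df["flp"], errors="coerce")
    df = df.loc[:, list(FLP_COLUMNS)].reset_index(drop=True)
    return validate_flp_records(df)


def write_flp_records(records: pd.DataFrame, path) -> None:
    validate_flp_records(records)
    cols = [c for c in FLP_COLUMNS if c in records.columns]
    records.loc[:, cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# country-name harmonization


@dataclass(frozen=True)
class HarmonizationTable:
    """Functional source-name → canonical-name mapping with provenance.

    The table is data, not code: entries live in an editable CSV so a user
    can audit and extend the cross-source name reconciliation. Names absent
    from the table pass through unchanged (and are reported), mirroring a
    manual cross-checking workflow where unmatched names need review rather
    than silent mutation.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path) -> "HarmonizationTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        _check_columns(df, ["source_name", "canonical_name"], "harmonization CSV")
        dup = df.duplicated(subset="source_name", keep=False)
        if dup.any():
            conflicting = df.loc[dup].groupby("source_name")["canonical_name"].nunique()
            if (conflicting > 1).any():
                raise DataModelError(
                    "harmonization table maps a source name to multiple "
                    f"canonical names: {list(conflicting[conflicting > 1].index)}"
                )
        prov = df["provenance"] if "provenance" in df.columns else ""
        return cls(
            mapping=dict(zip(df["source_name"], df["canonical_name"])),
            provenance=dict(zip(df["source_name"], prov))
            if "provenance" in df.columns
            else {},
        )

    @classmethod
    def default(cls) -> "HarmonizationTable":
        """Shipped best-effort table for common World-Bank/FAO dialect gaps.

        A synthetic stand-in for the (unpublished) manual reconciliation an
        analyst would perform; clearly incomplete by construction.
        """
        ref = resources.files("foodloss.data").joinpath("country_harmonization.csv")
        with ref.open("rb") as fh:
            return cls.from_csv(io.BytesIO(fh.read()))


def harmonize_countries(
    names: Iterable[str], table: HarmonizationTable
) -> tuple[list[str], list[str]]:
    """Map source country names to canonical names.

    Returns ``(canonical, unmatched)`` where *canonical* preserves input
    order (names without a table entry pass through unchanged) and
    *unmatched* lists, in first-appearance order, the distinct names that
    had no entry. Unmatched is a report, not an error.
    """
    canonical: list[str] = []
    unmatched: list[str] = []
    seen: set[str] = set()
    known_canonical = set(table.mapping.values())
    for name in names:
        if name in table.mapping:
            canonical.append(table.mapping[name])
        else:
            canonical.append(name)
            if name not in seen and name not in known_canonical:
                unmatched.append(name)
                seen.add(name)
    return canonical, unmatched


def harmonize_frame(
    df: pd.DataFrame, table: HarmonizationTable, column: str = "country"
) -> tuple[pd.DataFrame, list[str]]:
    """Return a copy of *df* with *column* harmonized, plus unmatched names."""
    out = df.copy()
    canonical, unmatched = harmonize_countries(out[column].tolist(), table)
    out[column] = canonical
    return out, unmatched


# ---------------------------------------------------------------------------
# unified dataset


@dataclass
class UnifiedDataset:
    """Indicator panel and FLP records restricted to their common countries."""

    panel: pd.DataFrame
    records: pd.DataFrame
    countries: list[str]
    dropped_from_panel: list[str]
    dropped_from_flp: list[str]

    @property
    def n_common(self) -> int:
        return len(self.countries)


def build_unified_dataset(
    panel: pd.DataFrame, records: pd.DataFrame
) -> UnifiedDataset:
    """Intersect the two sources on country and record what was dropped.

    Inputs are not mutated; output row order is deterministic (sorted by
    country then year) so the operation is order-invariant in its inputs.
    Raises if the intersection is empty.
    """
    validate_indicator_panel(panel)
    validate_flp_records(records)
    panel_countries = set(panel["country"])
    flp_countries = set(records["country"])
    common = sorted(panel_countries & flp_countries)
    if not common:
        raise DataModelError("no countries common to the indicator and FLP sources")
    keep = set(common)
    out_panel = (
        panel[panel["country"].isin(keep)]
        .sort_values(["country", "year"], kind="mergesort")
        .reset_index(drop=True)
    )
    out_records = (
        records[records["country"].isin(keep)]
        .sort_values(["country", "year"], kind="mergesort")
        .reset_index(drop=True)
    )
    return UnifiedDataset(
        panel=out_panel,
        records=out_records,
        countries=common,
        dropped_from_panel=sorted(panel_countries - flp_countries),
        dropped_from_flp=sorted(flp_countries - panel_countries),
    )


def write_unified_dataset(unified: UnifiedDataset, path) -> None:
    """Export one long CSV merging indicators onto every FLP record."""
    merged = unified.records.merge(
        unified.panel, on=["country", "year"], how="left"
    )
    cols = [
        "country",
        "year",
        "gdp_pc",
        "growth",
        "health_pc",
        "commodity_group",
        "activity_group",
        "flp",
    ]
    merged.loc[:, cols].to_csv(path, index=False)
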