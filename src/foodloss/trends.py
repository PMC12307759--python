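"""Descriptive surfaces: group-mean FLP cells and per-group linear trends.

Complements the mixed models with two simpler views of the screened
records: cross-sectional mean food-loss percentages per stratum
(commodity group or supply-chain stage) and development group, and
independent ordinary-least-squares time trends per (stratum x group) cell.
Borderline countries — those whose typology label flips across the λ
grid — are reported as their own columns alongside the two main groups,
since their sparse, temporally skewed records deserve separate reading.

Aggregation level for the means is configurable: the default averages over
observations; ``level="country"`` first averages within country, then
across countries, which weights countries equally instead of by their
reporting volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["group_means", "trend_ols", "trend_table", "borderline_profiles", "TrendFit"]


class TrendsError(ValueError):
    pass


def _with_display_group(
    records: pd.DataFrame, development: pd.Series, borderline: tuple[str, ...]
) -> pd.DataFrame:
    data = records.merge(
        development.rename("development"),
        left_on="country",
        right_index=True,
        how="inner",
    )
    data["display_group"] = np.where(
        data["country"].isin(borderline), data["country"], data["development"]
    )
    return data


def group_means(
    records: pd.DataFrame,
    development: pd.Series,
    by: str = "commodity_group",
    borderline: tuple[str, ...] = (),
    level: str = "observation",
) -> pd.DataFrame:
    """Mean FLP per stratum x development group, with n and year span.

    Borderline countries named in *borderline* appear as their own groups
    (and are excluded from the developed/developing aggregates they would
    otherwise blur). ``level`` picks observation-weighted (default) or
    country-first averaging.
    """
    if level not in ("observation", "country"):
        raise TrendsError(f"unknown aggregation level {level!r}")
    data = _with_display_group(records, development, borderline)
    data = data[data["flp"].notna() & data[by].notna()]

    if level == "country":
        per_country = (
            data.groupby([by, "display_group", "country"])
            .agg(mean_flp=("flp", "mean"), n=("flp", "size"))
            .reset_index()
        )
        out = (
            per_country.groupby([by, "display_group"])
            .agg(mean_flp=("mean_flp", "mean"), n=("n", "sum"))
            .reset_index()
        )
        spans = (
            data.groupby([by, "display_group"])["year"]
            .agg(year_min="min", year_max="max")
            .reset_index()
        )
        out = out.merge(spans, on=[by, "display_group"])
    else:
        out = (
            data.groupby([by, "display_group"])
            .agg(
                mean_flp=("flp", "mean"),
                n=("flp", "size"),
                year_min=("year", "min"),
                year_max=("year", "max"),
            )
            .reset_index()
        )
    return out.rename(columns={by: "stratum", "display_group": "group"})


@dataclass
class TrendFit:
    """OLS slope of FLP on (year - 2000) for one stratum x group cell."""

    stratum: str
    group: str
    slope: float
    se: float
    pvalue: float
    intercept: float
    n: int
    year_min: int
    year_max: int
    flag: str = ""


def trend_ols(
    cell: pd.DataFrame, stratum: str = "", group: str = "", centering: int = 2000
) -> TrendFit:
    """OLS of FLP on centered year for one cell; needs >= 3 distinct years.

    Cells with fewer distinct years come back flagged "insufficient years"
    with NaN estimates — sparse borderline countries land here — rather
    than raising.
    """
    cell = cell[cell["flp"].notna()]
    years = cell["year"].to_numpy(dtype=float)
    n = len(cell)
    base = dict(
        stratum=stratum,
        group=group,
        n=n,
        year_min=int(years.min()) if n else 0,
        year_max=int(years.max()) if n else 0,
    )
    if len(np.unique(years)) < 3:
        return TrendFit(
            slope=np.nan,
            se=np.nan,
            pvalue=np.nan,
            intercept=np.nan,
            flag="insufficient years",
            **base,
        )
    X = sm.add_constant(years - centering)
    res = sm.OLS(cell["flp"].to_numpy(dtype=float), X).fit()
    return TrendFit(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        pvalue=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        **base,
    )


def trend_table(
    records: pd.DataFrame,
    development: pd.Series,
    by: str = "commodity_group",
    borderline: tuple[str, ...] = (),
    centering: int = 2000,
) -> pd.DataFrame:
    """Independent trend fits for every stratum x development-group cell."""
    data = _with_display_group(records, development, borderline)
    data = data[data["flp"].notna() & data[by].notna()]
    rows = []
    for (stratum, group), cell in data.groupby([by, "display_group"], sort=True):
        fit = trend_ols(cell, stratum=str(stratum), group=str(group), centering=centering)
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def borderline_profiles(
    records: pd.DataFrame,
    countries: list[str],
    by: str = "commodity_group",
    window: tuple[int, int] = (2000, 2022),
) -> pd.DataFrame:
    """Descriptive coverage profile per borderline country.

    Reports observation count, year span, coverage fraction of the study
    window, and per-stratum mean FLP. Countries absent from the records get
    an empty row (n = 0) so the caller sees them flagged rather than
    silently missing.
    """
    y0, y1 = window
    span = y1 - y0 + 1
    rows = []
    for country in countries:
        sub = records[records["country"] == country]
        obs = sub[sub["flp"].notna()]
        row: dict = {"country": country, "n_obs": len(obs)}
        if obs.empty:
            row.update(
                year_min=np.nan, year_max=np.nan, coverage_fraction=0.0, note="absent"
            )
        else:
            years = obs["year"]
            row.update(
                year_min=int(years.min()),
                year_max=int(years.max()),
                coverage_fraction=years.nunique() / span,
                note="",
            )
            for stratum, cell in obs.dropna(subset=[by]).groupby(by):
                row[f"mean_flp[{stratum}]"] = cell["flp"].mean()
        rows.append(row)
    base_cols = ["country", "n_obs", "year_min", "year_max", "coverage_fraction", "note"]
    out = pd.DataFrame(rows)
    for col in base_cols:
        if col not in out.columns:
            out[col] = pd.Series(dtype=float)
    ordered = base_cols + [c for c in out.columns if c not in base_cols]
    return out.loc[:, ordered]
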