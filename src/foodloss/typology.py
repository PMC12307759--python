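"""Development typology: temporal weighting, K-means, and λ-sensitivity.

Countries are summarized into one profile each by exponentially
time-weighted averages of the three indicators, then partitioned by
K-means. The weight on a country's observation in year t is

    w_t = exp(lam * (t - min(t))) / sum_s exp(lam * (s - min(t))),

normalized over that country's *observed* years, so recent years dominate
as the decay parameter lam grows; lam = 0 is the exact uniform limit. The
decay parameter is a hyperparameter, selected by scanning a grid
(default 0.00–0.50 in steps of 0.05) and scoring each candidate's
clustering by mean silhouette width, with the within-cluster sum of
squares (WCSS) elbow as complementary evidence for the cluster count.

Cluster labels are aligned across configurations by a fixed rule — the
cluster with the highest GDP-per-capita centroid is always "developed" —
which makes agreement rates between λ settings well defined without any
combinatorial matching. Countries whose label flips somewhere on the λ
grid are flagged as borderline (transitional/hybrid economies).

Features are z-standardized across countries before clustering by default
(raw USD scales would otherwise dominate the Euclidean metric); the flag
is exposed because results can be reported under either convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .datamodel import INDICATORS

__all__ = [
    "temporal_weights",
    "weighted_profile",
    "country_profiles",
    "kmeans_fit",
    "silhouette_mean",
    "elbow_curve",
    "suggest_k",
    "sensitivity_analysis",
    "select_configuration",
    "borderline_report",
    "TypologyResult",
    "SensitivityGrid",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.5001, 0.05), 2))
DEFAULT_K_CANDIDATES = (2, 3, 4, 5, 6)


class TypologyError(ValueError):
    pass


def temporal_weights(years, lam: float) -> np.ndarray:
    """Normalized exponential time weights over an observed year set.

    Weights are returned aligned to the input order and sum to one. lam = 0
    is implemented as the exact uniform limit. Exponentials are computed
    relative to the latest year for overflow safety (the normalization
    cancels the shift).
    """
    years = np.asarray(list(years), dtype=float)
    if years.size == 0:
        raise TypologyError("empty year set")
    if lam < 0:
        raise TypologyError("lam must be >= 0")
    if lam == 0:
        return np.full(years.size, 1.0 / years.size)
    raw = np.exp(lam * (years - years.max()))
    return raw / raw.sum()


def weighted_profile(country_rows: pd.DataFrame, lam: float) -> dict[str, float]:
    """Time-weighted indicator means for one country.

    Weights are renormalized per indicator over that indicator's
    non-missing years, so each weighted mean is a convex combination of the
    observed values (and lies within their range). An indicator with no
    usable years comes back as NaN.
    """
    out: dict[str, float] = {"n_years": float(country_rows["year"].nunique())}
    for ind in INDICATORS:
        obs = country_rows.loc[country_rows[ind].notna(), ["year", ind]]
        if obs.empty:
            out[ind] = np.nan
            continue
        w = temporal_weights(obs["year"].to_numpy(), lam)
        out[ind] = float(np.dot(w, obs[ind].to_numpy()))
    return out


def country_profiles(
    panel: pd.DataFrame, lam: float
) -> tuple[pd.DataFrame, list[str]]:
    """Weighted profiles for every country; drop (and report) unusable ones.

    A country missing an entire indicator cannot be placed in the
    three-dimensional feature space and is excluded from clustering rather
    than imputed. Returns ``(profiles, dropped)`` with profiles indexed by
    country in sorted order.
    """
    rows = {}
    dropped = []
    for country, sub in panel.groupby("country", sort=True):
        prof = weighted_profile(sub, lam)
        if any(np.isnan(prof[ind]) for ind in INDICATORS):
            dropped.append(country)
        else:
            rows[country] = prof
    if not rows:
        raise TypologyError("no country has complete indicator coverage")
    profiles = pd.DataFrame.from_dict(rows, orient="index").loc[
        :, [*INDICATORS, "n_years"]
    ]
    profiles.index.name = "country"
    return profiles, dropped


def _standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mu = features.mean()
    sd = features.std(ddof=0).replace(0.0, 1.0)
    return (features - mu) / sd, mu, sd


def _cluster_names(k: int) -> list[str]:
    names = ["developed", "developing"]
    names += [f"cluster_{i}" for i in range(3, k + 1)]
    return names[:k]


@dataclass
class TypologyResult:
    """One (λ, k) clustering: labels, centroids, quality metrics."""

    lam: float
    k: int
    labels: pd.Series  # country -> cluster name
    centroids: pd.DataFrame  # original units, indexed by cluster name
    centroids_std: pd.DataFrame  # standardized units (identical if not standardized)
    silhouette: float
    wcss: float
    sizes: dict[str, int]
    standardized: bool
    dropped_countries: list[str] = field(default_factory=list)
    #: the weighted country profiles (original units) the fit was run on
    profiles: pd.DataFrame | None = None

    @property
    def n_developed(self) -> int:
        return self.sizes.get("developed", 0)

    @property
    def n_developing(self) -> int:
        return self.sizes.get("developing", 0)


def _best_kmeans(
    X: np.ndarray, k: int, restarts: int, seed: int, max_iter: int = 300
) -> KMeans:
    """Best-of-restarts Lloyd's algorithm, robust on tiny instances.

    k-means++ initializes centers at data points, and on very small inputs
    no data-point seeding may lie in the basin of the global WCSS optimum
    even though that optimum is Voronoi-consistent. A second batch of
    restarts from uniform draws inside the data bounding box closes that
    gap; the overall best model is returned. Fully deterministic per seed.
    """
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, max_iter=max_iter)
    km.fit(X)
    best = km
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    for _ in range(max(restarts // 2, 10)):
        init = rng.uniform(lo, hi, size=(k, X.shape[1]))
        cand = KMeans(n_clusters=k, init=init, n_init=1, max_iter=max_iter)
        cand.fit(X)
        if cand.inertia_ < best.inertia_ - 1e-12:
            best = cand
    return best


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b) over all points.

    Points in singleton clusters contribute s = 0. Requires at least two
    non-empty clusters.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise TypologyError("silhouette needs at least two clusters")
    return float(np.mean(silhouette_samples(np.asarray(X, dtype=float), labels)))


def kmeans_fit(
    profiles: pd.DataFrame,
    k: int,
    lam: float = np.nan,
    restarts: int = 50,
    seed: int = 0,
    standardize: bool = True,
    dropped: list[str] | None = None,
) -> TypologyResult:
    """K-means on country profiles with k-means++ restarts and fixed seed.

    *profiles* is indexed by country with the three indicator columns (the
    output of :func:`country_profiles`; any ``n_years`` column is ignored).
    WCSS is the sum of squared distances to assigned centroids in the
    clustering feature space. Clusters are named by descending
    GDP-per-capita centroid: "developed", "developing", then "cluster_3"…
    """
    features = profiles.loc[:, list(INDICATORS)].sort_index()
    n = len(features)
    if k > n:
        raise TypologyError(f"k={k} exceeds the {n} available countries")
    if features.drop_duplicates().shape[0] < k:
        raise TypologyError(f"fewer than k={k} distinct profiles")

    if standardize:
        X_df, mu, sd = _standardize(features)
    else:
        X_df, mu, sd = features.copy(), features.mean() * 0.0, features.mean() * 0 + 1.0
    X = X_df.to_numpy(dtype=float)

    km = _best_kmeans(X, k, restarts, seed)
    raw_labels = km.labels_

    centroids_std = pd.DataFrame(km.cluster_centers_, columns=list(INDICATORS))
    centroids_orig = centroids_std * sd.to_numpy() + mu.to_numpy()
    order = np.argsort(-centroids_orig["gdp_pc"].to_numpy(), kind="stable")
    names = _cluster_names(k)
    rename = {int(cluster): names[rank] for rank, cluster in enumerate(order)}

    labels = pd.Series(
        [rename[int(c)] for c in raw_labels], index=features.index, name="label"
    )
    centroids_orig = centroids_orig.iloc[order].set_axis(names, axis=0)
    centroids_std = centroids_std.iloc[order].set_axis(names, axis=0)

    sil = silhouette_mean(X, raw_labels) if 2 <= k < n else np.nan
    sizes = labels.value_counts().to_dict()
    return TypologyResult(
        lam=lam,
        k=k,
        labels=labels,
        centroids=centroids_orig,
        centroids_std=centroids_std,
        silhouette=sil,
        wcss=float(km.inertia_),
        sizes={name: int(sizes.get(name, 0)) for name in names},
        standardized=standardize,
        dropped_countries=list(dropped or []),
        profiles=features,
    )


def elbow_curve(
    profiles: pd.DataFrame,
    k_range=(1, 2, 3, 4, 5, 6),
    restarts: int = 50,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """WCSS per k and the per-step reduction ΔWCSS.

    WCSS must be non-increasing in k; a violation (a poor local optimum) is
    retried with quadrupled restarts and warned about if it persists.
    """
    ks = sorted(k_range)
    wcss: dict[int, float] = {}
    features = profiles.loc[:, list(INDICATORS)].sort_index()
    X = (_standardize(features)[0] if standardize else features).to_numpy(dtype=float)
    for k in ks:
        if k == 1:
            wcss[k] = float(((X - X.mean(axis=0)) ** 2).sum())
            continue
        wcss[k] = float(_best_kmeans(X, k, restarts, seed).inertia_)

    for prev, k in zip(ks, ks[1:]):
        if wcss[k] > wcss[prev] + 1e-9:
            km = _best_kmeans(X, k, restarts * 4, seed + 1, max_iter=500)
            wcss[k] = min(wcss[k], float(km.inertia_))
            if wcss[k] > wcss[prev] + 1e-9:
                warnings.warn(f"WCSS increased from k={prev} to k={k}", stacklevel=2)

    out = pd.DataFrame({"k": ks, "wcss": [wcss[k] for k in ks]})
    out["delta_wcss"] = -out["wcss"].diff()
    return out


def suggest_k(
    profiles: pd.DataFrame,
    k_candidates=DEFAULT_K_CANDIDATES,
    restarts: int = 50,
    seed: int = 0,
    standardize: bool = True,
    lam: float = np.nan,
) -> tuple[int, dict[int, float]]:
    """Suggested cluster count: argmax of mean silhouette over candidates."""
    sils: dict[int, float] = {}
    for k in k_candidates:
        res = kmeans_fit(
            profiles, k, lam=lam, restarts=restarts, seed=seed, standardize=standardize
        )
        sils[k] = res.silhouette
    best = max(sils, key=lambda k: (sils[k], -k))
    return best, sils


@dataclass
class SensitivityGrid:
    """Per-λ clustering diagnostics and stability vs a reference λ."""

    reference_lam: float
    table: pd.DataFrame
    results: dict[float, TypologyResult]
    changes: dict[float, pd.DataFrame]

    @property
    def changed_countries(self) -> list[str]:
        names: set[str] = set()
        for df in self.changes.values():
            names.update(df["country"])
        return sorted(names)

    @property
    def stability(self) -> float:
        """Fraction of countries keeping their reference label across the grid."""
        ref = self.results[self.reference_lam].labels
        return 1.0 - len(self.changed_countries) / len(ref)


def sensitivity_analysis(
    panel: pd.DataFrame,
    lam_grid=DEFAULT_LAMBDA_GRID,
    reference_lam: float = 0.20,
    k: int = 2,
    k_candidates=DEFAULT_K_CANDIDATES,
    restarts: int = 50,
    seed: int = 0,
    standardize: bool = True,
) -> SensitivityGrid:
    """Re-weight, re-standardize and re-cluster the panel at every λ.

    For each λ the grid row records the suggested cluster count (silhouette
    argmax over *k_candidates*), the silhouette at k and at the suggested
    count, the k-cluster group sizes, and the label agreement rate against
    the reference-λ solution (labels aligned by the GDP-centroid rule).
    Per-country label changes are kept with their direction.
    """
    lam_grid = [float(l) for l in lam_grid]
    if not lam_grid:
        raise TypologyError("empty lambda grid")
    if float(reference_lam) not in lam_grid:
        raise TypologyError("reference lambda must be in the grid")

    results: dict[float, TypologyResult] = {}
    suggested: dict[float, tuple[int, dict[int, float]]] = {}
    for lam in lam_grid:
        profiles, dropped = country_profiles(panel, lam)
        results[lam] = kmeans_fit(
            profiles,
            k,
            lam=lam,
            restarts=restarts,
            seed=seed,
            standardize=standardize,
            dropped=dropped,
        )
        suggested[lam] = suggest_k(
            profiles,
            k_candidates,
            restarts=restarts,
            seed=seed,
            standardize=standardize,
            lam=lam,
        )

    ref_labels = results[float(reference_lam)].labels
    rows = []
    changes: dict[float, pd.DataFrame] = {}
    for lam in lam_grid:
        res = results[lam]
        best_k, sils = suggested[lam]
        agree = float((res.labels == ref_labels).mean())
        moved = res.labels[res.labels != ref_labels]
        changes[lam] = pd.DataFrame(
            {
                "country": moved.index,
                "from_label": ref_labels.loc[moved.index].to_numpy(),
                "to_label": moved.to_numpy(),
            }
        ).reset_index(drop=True)
        rows.append(
            {
                "lam": lam,
                "silhouette_k2": res.silhouette,
                "suggested_k": best_k,
                "silhouette_suggested_k": sils[best_k],
                "n_developed": res.n_developed,
                "n_developing": res.n_developing,
                "agreement": agree,
                "n_changed": len(moved),
            }
        )
    table = pd.DataFrame(rows)
    return SensitivityGrid(
        reference_lam=float(reference_lam),
        table=table,
        results=results,
        changes=changes,
    )


def select_configuration(grid: SensitivityGrid, k: int = 2) -> float:
    """λ maximizing silhouette among rows whose suggested k matches *k*.

    Ties break toward the smaller λ; stable under grid-row reordering.
    """
    rows = grid.table[grid.table["suggested_k"] == k]
    if rows.empty:
        raise TypologyError(f"no lambda on the grid suggests k={k}")
    rows = rows.sort_values(["silhouette_k2", "lam"], ascending=[False, True])
    best = rows.iloc[0]
    ties = rows[np.isclose(rows["silhouette_k2"], best["silhouette_k2"])]
    return float(ties["lam"].min())


def borderline_report(grid: SensitivityGrid) -> pd.DataFrame:
    """Narrative table for countries whose label varies across the λ grid.

    One row per changer: the λ values at which its label differs from the
    reference solution, the direction of the shift, and its indicator
    profile at the reference λ next to both cluster centroids.
    """
    ref = grid.results[grid.reference_lam]
    rows = []
    for country in grid.changed_countries:
        lams = sorted(
            lam
            for lam, df in grid.changes.items()
            if country in set(df["country"])
        )
        directions = {
            f"{row.from_label}->{row.to_label}"
            for lam in lams
            for row in grid.changes[lam].itertuples()
            if row.country == country
        }
        prof = ref.profiles.loc[country]
        row = {
            "country": country,
            "reference_label": ref.labels[country],
            "lambdas_changed": lams,
            "direction": "; ".join(sorted(directions)),
        }
        for ind in INDICATORS:
            row[ind] = prof[ind]
            row[f"developed_centroid_{ind}"] = ref.centroids.loc["developed", ind]
            row[f"developing_centroid_{ind}"] = ref.centroids.loc["developing", ind]
        rows.append(row)
    columns = [
        "country",
        "reference_label",
        "lambdas_changed",
        "direction",
        *INDICATORS,
        *[f"developed_centroid_{i}" for i in INDICATORS],
        *[f"developing_centroid_{i}" for i in INDICATORS],
    ]
    return pd.DataFrame(rows, columns=columns)
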