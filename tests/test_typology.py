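import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from foodloss import simulate, typology
from foodloss.typology import (
    SensitivityGrid,
    TypologyError,
    borderline_report,
    country_profiles,
    elbow_curve,
    kmeans_fit,
    select_configuration,
    sensitivity_analysis,
    silhouette_mean,
    temporal_weights,
    weighted_profile,
)
from oracles import brute_force_min_wcss, brute_force_silhouette


def profiles_from_points(X):
    """Wrap an (n, 3) point set as a country-profile frame."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 1:
        X = np.hstack([X, np.zeros((len(X), 2))])
    return pd.DataFrame(
        X,
        columns=["gdp_pc", "health_pc", "growth"],
        index=[f"P{i:02d}" for i in range(len(X))],
    )


class TestTemporalWeights:
    def test_lambda_zero_is_exact_uniform(self):
        w = temporal_weights([2000, 2001, 2002], 0.0)
        assert np.array_equal(w, np.full(3, 1 / 3))

    def test_consecutive_ratio_is_exp_lambda(self):
        w = temporal_weights([2000, 2001, 2002], 0.2)
        # direct evaluation oracle: weights proportional to (e^0, e^.2, e^.4)
        raw = np.exp(0.2 * np.array([0.0, 1.0, 2.0]))
        assert np.allclose(w, raw / raw.sum(), atol=1e-15)
        assert np.allclose(w[1] / w[0], np.exp(0.2))
        assert np.allclose(w[2] / w[1], np.exp(0.2))

    def test_singleton_year(self):
        assert temporal_weights([2014], 0.0) == [1.0]
        assert temporal_weights([2014], 3.7) == [1.0]

    @given(
        years=st.lists(
            st.integers(min_value=1990, max_value=2030), min_size=1, max_size=30, unique=True
        ),
        lam=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_weights_normalize_and_increase_with_year(self, years, lam):
        w = temporal_weights(sorted(years), lam)
        assert abs(w.sum() - 1.0) < 1e-12
        assert (w > 0).all()
        if lam > 0:
            assert (np.diff(w) > -1e-15).all()

    def test_empty_year_set_and_negative_lambda_rejected(self):
        with pytest.raises(TypologyError):
            temporal_weights([], 0.1)
        with pytest.raises(TypologyError):
            temporal_weights([2000], -0.1)

    def test_huge_lambda_concentrates_on_latest_year(self):
        rows = pd.DataFrame(
            {"year": [2000, 2001, 2002], "gdp_pc": [1.0, 2.0, 3.0],
             "growth": [0.0, 0.0, 0.0], "health_pc": [9.0, 9.0, 9.0]}
        )
        prof = weighted_profile(rows, 50.0)
        assert abs(prof["gdp_pc"] - 3.0) < 1e-6


class TestWeightedProfile:
    def test_constant_series_fixed_point(self):
        rows = pd.DataFrame(
            {"year": [2001, 2005, 2019], "gdp_pc": [7.0] * 3,
             "growth": [2.0] * 3, "health_pc": [1.0] * 3}
        )
        for lam in (0.0, 0.2, 5.0):
            prof = weighted_profile(rows, lam)
            assert prof["gdp_pc"] == pytest.approx(7.0)

    def test_direct_evaluation_oracle(self):
        # two-line oracle computed independently of the implementation
        w = np.exp(0.2 * np.array([0.0, 1.0, 2.0]))
        expected = float((w / w.sum()) @ np.array([1.0, 2.0, 3.0]))
        rows = pd.DataFrame(
            {"year": [2000, 2001, 2002], "gdp_pc": [1.0, 2.0, 3.0],
             "growth": [0.0, 0.0, 0.0], "health_pc": [0.0, 0.0, 0.0]}
        )
        assert weighted_profile(rows, 0.2)["gdp_pc"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_years_renormalized_per_indicator(self):
        rows = pd.DataFrame(
            {"year": [2000, 2001, 2002], "gdp_pc": [1.0, np.nan, 3.0],
             "growth": [1.0, 2.0, 3.0], "health_pc": [np.nan] * 3}
        )
        prof = weighted_profile(rows, 0.0)
        assert prof["gdp_pc"] == pytest.approx(2.0)  # mean of observed years only
        assert np.isnan(prof["health_pc"])

    def test_convex_combination_bound(self, study_panel):
        panel, _ = study_panel
        for lam in (0.0, 0.25, 0.5):
            profiles, _ = country_profiles(panel, lam)
            for country, sub in panel.groupby("country"):
                for ind in ("gdp_pc", "growth"):
                    lo, hi = sub[ind].min(), sub[ind].max()
                    assert lo - 1e-9 <= profiles.loc[country, ind] <= hi + 1e-9

    def test_country_missing_whole_indicator_dropped_with_log(self, study_panel):
        panel, _ = study_panel
        panel = panel.copy()
        victim = panel["country"].iloc[0]
        panel.loc[panel["country"] == victim, "health_pc"] = np.nan
        profiles, dropped = country_profiles(panel, 0.2)
        assert dropped == [victim]
        assert victim not in profiles.index


class TestKMeans:
    def test_k_equals_n_gives_zero_wcss(self):
        profiles = profiles_from_points(np.arange(12.0).reshape(4, 3))
        res = kmeans_fit(profiles, k=4, standardize=False)
        assert res.wcss == pytest.approx(0.0, abs=1e-12)

    def test_textbook_1d_partition_matches_exhaustive_oracle(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        profiles = profiles_from_points(X)
        res = kmeans_fit(profiles, k=2, standardize=False)
        best_wcss, _ = brute_force_min_wcss(profiles.to_numpy(), 2)
        assert best_wcss == pytest.approx(1.0)
        assert res.wcss == pytest.approx(best_wcss, abs=1e-9)
        labels = res.labels.to_numpy()
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    @pytest.mark.parametrize("k,n", [(2, 10), (3, 8)])
    def test_restart_kmeans_attains_exhaustive_minimum(self, k, n):
        rng = np.random.default_rng(100 + k)
        for _ in range(5):
            X = rng.normal(size=(n, 3))
            profiles = profiles_from_points(X)
            res = kmeans_fit(profiles, k=k, standardize=False)
            best_wcss, _ = brute_force_min_wcss(X, k)
            assert res.wcss == pytest.approx(best_wcss, abs=1e-9)

    def test_developed_cluster_has_highest_gdp_centroid(self, study_panel):
        panel, _ = study_panel
        profiles, _ = country_profiles(panel, 0.2)
        res = kmeans_fit(profiles, k=2)
        assert (
            res.centroids.loc["developed", "gdp_pc"]
            > res.centroids.loc["developing", "gdp_pc"]
        )
        assert sum(res.sizes.values()) == len(res.labels)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(TypologyError):
            kmeans_fit(profiles_from_points(np.eye(3)), k=5)

    def test_row_order_permutation_invariance(self, study_panel):
        panel, _ = study_panel
        shuffled = panel.sample(frac=1, random_state=3).reset_index(drop=True)
        r1 = kmeans_fit(country_profiles(panel, 0.2)[0], 2, seed=0)
        r2 = kmeans_fit(country_profiles(shuffled, 0.2)[0], 2, seed=0)
        pd.testing.assert_series_equal(r1.labels, r2.labels)


class TestSilhouette:
    def test_perfectly_separated_pairs_score_one(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert silhouette_mean(X, np.array([0, 0, 1, 1])) == pytest.approx(1.0)

    def test_matches_brute_force_pairwise_oracle(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        ours = silhouette_mean(X, labels)
        oracle = brute_force_silhouette(X, labels)
        # hand-derivable: mean of (9/11, 7/9, 7/9, 9/11)
        assert oracle == pytest.approx((9 / 11 + 7 / 9) / 2, abs=1e-12)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_random_labelings_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X = rng.normal(size=(12, 3))
            labels = rng.integers(0, 3, size=12)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette_mean(X, labels) == pytest.approx(
                brute_force_silhouette(X, labels), abs=1e-10
            )

    def test_single_cluster_rejected(self):
        with pytest.raises(TypologyError):
            silhouette_mean(np.eye(3), np.zeros(3, dtype=int))


class TestElbow:
    def test_k1_is_total_sum_of_squares(self):
        X = np.arange(15.0).reshape(5, 3)
        curve = elbow_curve(profiles_from_points(X), k_range=(1, 2), standardize=False)
        tss = ((X - X.mean(axis=0)) ** 2).sum()
        assert curve.loc[curve["k"] == 1, "wcss"].iloc[0] == pytest.approx(tss)

    def test_two_cluster_data_elbows_at_two(self, study_panel):
        panel, _ = study_panel
        profiles, _ = country_profiles(panel, 0.2)
        curve = elbow_curve(profiles)
        deltas = curve.dropna(subset=["delta_wcss"]).set_index("k")["delta_wcss"]
        assert deltas.idxmax() == 2
        assert (curve["wcss"].diff().dropna() <= 1e-9).all()  # non-increasing


def _fabricated_grid(rows):
    table = pd.DataFrame(rows)
    return SensitivityGrid(
        reference_lam=0.2, table=table, results={}, changes={}
    )


class TestSelection:
    def test_unique_argmax(self):
        grid = _fabricated_grid(
            [
                {"lam": 0.1, "suggested_k": 2, "silhouette_k2": 0.60},
                {"lam": 0.2, "suggested_k": 2, "silhouette_k2": 0.70},
                {"lam": 0.3, "suggested_k": 3, "silhouette_k2": 0.99},
            ]
        )
        assert select_configuration(grid, k=2) == 0.2

    def test_tie_breaks_toward_smaller_lambda(self):
        grid = _fabricated_grid(
            [
                {"lam": 0.20, "suggested_k": 2, "silhouette_k2": 0.70},
                {"lam": 0.15, "suggested_k": 2, "silhouette_k2": 0.70},
            ]
        )
        assert select_configuration(grid, k=2) == 0.15

    def test_stable_under_row_reordering(self):
        rows = [
            {"lam": l, "suggested_k": 2, "silhouette_k2": s}
            for l, s in [(0.0, 0.6), (0.1, 0.65), (0.2, 0.64)]
        ]
        a = select_configuration(_fabricated_grid(rows))
        b = select_configuration(_fabricated_grid(rows[::-1]))
        assert a == b == 0.1

    def test_no_matching_k_errors(self):
        grid = _fabricated_grid(
            [{"lam": 0.1, "suggested_k": 3, "silhouette_k2": 0.6}]
        )
        with pytest.raises(TypologyError):
            select_configuration(grid, k=2)


def _borderline_panel():
    """20 stable countries plus one whose late years look developed."""
    rows = []
    for i in range(10):
        for year in range(2000, 2023):
            rows.append((f"R{i}", year, 50000 + 100 * i, 1.5, 5000 + 10 * i))
    for i in range(10):
        for year in range(2000, 2023):
            rows.append((f"P{i}", year, 3000 + 100 * i, 3.0, 200 + 10 * i))
    for year in range(2000, 2023):
        gdp, health = (3000, 200) if year < 2016 else (60000, 6000)
        rows.append(("T", year, gdp, 2.2, health))
    return pd.DataFrame(
        rows, columns=["country", "year", "gdp_pc", "growth", "health_pc"]
    )


class TestSensitivity:
    def test_identical_labelings_have_agreement_one(self, study_panel):
        panel, truth = study_panel
        grid = sensitivity_analysis(
            panel, lam_grid=[0.1, 0.2], reference_lam=0.2, restarts=20
        )
        assert (grid.table["agreement"] == 1.0).all()
        assert grid.stability == 1.0
        assert borderline_report(grid).empty

    def test_constructed_borderline_country_flips_with_lambda(self):
        panel = _borderline_panel()
        grid = sensitivity_analysis(
            panel,
            lam_grid=[0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
            reference_lam=0.0,
            restarts=20,
        )
        assert grid.changed_countries == ["T"]
        flipped = [lam for lam, df in grid.changes.items() if len(df)]
        assert flipped  # there is a lambda threshold where T changes group
        change = grid.changes[max(flipped)]
        assert change.loc[0, "from_label"] == "developing"
        assert change.loc[0, "to_label"] == "developed"
        # agreement mirrors the single flip out of 21 countries
        n = 21
        assert grid.table["agreement"].min() == pytest.approx(1 - 1 / n)
        report = borderline_report(grid)
        assert list(report["country"]) == ["T"]
        assert report.loc[0, "direction"] == "developing->developed"

    def test_reference_lambda_must_be_on_grid(self, study_panel):
        panel, _ = study_panel
        with pytest.raises(TypologyError):
            sensitivity_analysis(panel, lam_grid=[0.1], reference_lam=0.2)


class TestRecovery:
    def test_well_separated_panel_recovers_truth_across_grid(self):
        """>= 98% label agreement with generative truth for every lambda."""
        cfg = simulate.IndicatorSimConfig(n_developed=8, n_developing=40, seed=23)
        panel, truth = simulate.generate_indicator_panel(cfg)
        for lam in (0.0, 0.25, 0.5):
            profiles, _ = country_profiles(panel, lam)
            res = kmeans_fit(profiles, 2, lam=lam, restarts=20)
            agreement = (res.labels == truth.loc[res.labels.index]).mean()
            assert agreement >= 0.98
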