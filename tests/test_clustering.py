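"""Clinical clustering: preparation, k-means, stability, profiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations

from metabotyper import clustering
from metabotyper.clustering import (
    CLUSTERING_VARS,
    derive_vldl,
    exclude_extreme,
    impute_median,
    kmeans,
    permutation_stability,
    permute_columns,
    profile_clusters,
    select_k,
    silhouette,
    zscore_scale,
)


def _clinical_frame(values: dict) -> pd.DataFrame:
    """Minimal clinical table: the requested columns, rest filled with 1.0."""
    n = len(next(iter(values.values())))
    data = {"subject_id": [f"S{i}" for i in range(n)]}
    rng = np.random.default_rng(0)
    for var in CLUSTERING_VARS:
        data[var] = values.get(var, 1.0 + 0.01 * rng.standard_normal(n))
    return pd.DataFrame(data)


class TestImputeMedian:
    def test_even_count_median_fills_gap(self):
        tab = _clinical_frame({"alt": [1.0, 2.0, np.nan, 4.0]})
        out = impute_median(tab)
        assert out.loc[2, "alt"] == 2.0

    def test_odd_count_median_fills_gap(self):
        tab = _clinical_frame({"alt": [1.0, np.nan, 3.0, 4.0]})
        out = impute_median(tab)
        assert out.loc[1, "alt"] == 3.0

    def test_complete_table_unchanged(self):
        tab = _clinical_frame({"alt": [1.0, 2.0, 3.0, 4.0]})
        pd.testing.assert_frame_equal(impute_median(tab), tab)

    def test_fully_missing_column_is_an_error(self):
        tab = _clinical_frame({"alt": [np.nan] * 4})
        with pytest.raises(ValueError, match="alt"):
            impute_median(tab)


class TestExcludeExtreme:
    def test_six_sd_outlier_excluded(self):
        vals = np.concatenate([np.random.default_rng(1).normal(50, 5, 60), [50 + 6 * 5]])
        tab = _clinical_frame({"alt": vals})
        kept, excluded = exclude_extreme(tab)
        assert excluded == ["S60"]
        assert len(kept) == 60

    def test_everyone_within_two_sd_retained(self):
        rng = np.random.default_rng(2)
        tab = _clinical_frame({"alt": np.clip(rng.normal(50, 5, 50), 40, 60)})
        kept, excluded = exclude_extreme(tab)
        assert excluded == [] and len(kept) == 50

    def test_boundary_is_strict(self):
        """A subject sitting exactly at the threshold (threshold_sd = its own
        |z|) is retained, because the rule uses a strict inequality."""
        vals = np.array([10.0, 11.0, 9.0, 10.0, 10.5, 9.5, 30.0])
        tab = _clinical_frame({"alt": vals})
        z = np.abs(vals - vals.mean()) / vals.std(ddof=1)
        kept, excluded = exclude_extreme(tab, threshold_sd=float(z.max()))
        assert excluded == []
        kept2, excluded2 = exclude_extreme(tab, threshold_sd=float(z.max()) - 1e-9)
        assert excluded2 == ["S6"]

    def test_zero_variance_variable_flagged_and_skipped(self):
        tab = _clinical_frame({"alt": [1.0, 1.0, 1.0, 1.0]})
        tab["ast"] = [1.0, 2.0, 3.0, 4.0]
        with pytest.warns(UserWarning, match="zero-variance"):
            kept, excluded = exclude_extreme(tab)
        assert len(kept) == 4


class TestScaling:
    def test_simple_column(self):
        X, params = zscore_scale(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(X[:, 0], [-1, 0, 1])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(3)
        X0 = rng.standard_normal((40, 4))
        X1, _ = zscore_scale(X0)
        X2, _ = zscore_scale(X1)
        assert np.allclose(X1, X2, atol=1e-12)

    def test_output_columns_centered_unit_sd(self, rng):
        X, _ = zscore_scale(rng.normal(7, 3, size=(30, 5)))
        assert np.abs(X.mean(0)).max() < 1e-10
        assert np.allclose(X.std(0, ddof=1), 1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_scale(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))


class TestKMeans:
    def test_separable_pairs(self):
        X = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], dtype=float)
        model = kmeans(X, 2, seed=0)
        assert model.assignments[0] == model.assignments[1]
        assert model.assignments[2] == model.assignments[3]
        assert model.wss == pytest.approx(1.0)
        got = sorted(model.centroids.tolist())
        assert np.allclose(got, [[0, 0.5], [10, 10.5]])

    def test_k1_gives_column_means_and_total_ss(self, rng):
        X = rng.normal(size=(25, 3))
        model = kmeans(X, 1, seed=0)
        assert np.allclose(model.centroids[0], X.mean(0))
        assert model.wss == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_matches_exhaustive_bipartition_minimum(self, rng):
        """On 8 points, k-means with restarts finds the globally WSS-optimal
        2-partition (verified against enumeration of all bipartitions)."""
        X = rng.normal(size=(8, 2))
        best = np.inf
        for mask_bits in range(1, 2**7):  # fix point 0 in group A; skip empty B
            mask = np.array([False] + [(mask_bits >> i) & 1 == 1 for i in range(7)])
            wss = 0.0
            for m in (mask, ~mask):
                block = X[m]
                wss += ((block - block.mean(0)) ** 2).sum()
            best = min(best, wss)
        model = kmeans(X, 2, n_start=50, seed=1)
        assert model.wss == pytest.approx(best, abs=1e-9)

    def test_affine_rescaling_of_raw_columns_preserves_assignments(self, rng):
        raw = rng.normal(size=(60, 4)) * np.array([1, 10, 100, 0.1]) + np.array([0, 5, -3, 2])
        rescaled = raw * np.array([3.0, 0.2, 7.0, 40.0]) + np.array([1, 2, 3, 4])
        Xa, _ = zscore_scale(raw)
        Xb, _ = zscore_scale(rescaled)
        ma = kmeans(Xa, 3, seed=5)
        mb = kmeans(Xb, 3, seed=5)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(ma.assignments, mb.assignments) == pytest.approx(1.0)


class TestSilhouette:
    def test_hand_computed_three_points(self):
        X = np.array([[0.0], [1.0], [10.0]])
        s, mean_s = silhouette(X, [0, 0, 1])
        assert np.allclose(s, [0.9, 8 / 9, 0.0])
        assert mean_s == pytest.approx((0.9 + 8 / 9) / 3)

    def test_coincident_clusters_score_one(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        s, _ = silhouette(X, [0, 0, 1, 1])
        assert np.allclose(s, 1.0)

    def test_bounded_and_matches_brute_force(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        s, _ = silhouette(X, labels)
        assert (np.abs(s) <= 1.0 + 1e-12).all()
        # independent double-loop oracle
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        expected = np.zeros(30)
        for i in range(30):
            own = labels == labels[i]
            if own.sum() == 1:
                continue
            a = D[i, own & (np.arange(30) != i)].mean()
            b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
            expected[i] = (b - a) / max(a, b)
        assert np.allclose(s, expected, atol=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), [0] * 5)


class TestSelectK:
    @pytest.mark.parametrize("n_blobs", [2, 3])
    def test_well_separated_blobs_recovered(self, n_blobs):
        rng = np.random.default_rng(20 + n_blobs)
        centers = np.array([[0, 0], [15, 0], [0, 15]])[:n_blobs]
        X = np.vstack([rng.normal(c, 1.0, size=(60, 2)) for c in centers])
        report = select_k(X, k_grid=range(2, 7), seed=0, n_start=10, n_gap_refs=25)
        assert report.recommendation == n_blobs

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_k(np.ones((50, 3)), k_grid=range(2, 4), seed=0)


class TestPermutationStability:
    def test_column_permutation_preserves_marginals(self, rng):
        X = rng.normal(size=(40, 3))
        Xp = permute_columns(X, rng)
        for j in range(3):
            assert np.array_equal(np.sort(X[:, j]), np.sort(Xp[:, j]))

    def test_planted_structure_beats_every_permutation(self):
        rng = np.random.default_rng(31)
        centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]])
        X = np.vstack([rng.normal(c, 1.0, size=(50, 3)) for c in centers])
        report = permutation_stability(X, B=20, k_grid=(2, 3, 4), seed=0, n_start=5)
        assert report.empirical_p[3] == pytest.approx(1 / 21)
        assert report.permuted_silhouettes.shape == (20, 3)

    def test_pure_noise_not_declared_stable(self):
        hits = 0
        for rep in range(5):
            X = np.random.default_rng(100 + rep).standard_normal((80, 8))
            report = permutation_stability(X, B=19, k_grid=(3,), seed=rep, n_start=5)
            if report.empirical_p[3] > 0.05:
                hits += 1
        assert hits >= 4

    def test_single_column_marginal_preserved(self, rng):
        X = rng.normal(size=(30, 1))
        Xp = permute_columns(X, rng)
        assert np.array_equal(np.sort(X[:, 0]), np.sort(Xp[:, 0]))


class TestProfileClusters:
    def test_mann_whitney_exact_small_groups(self):
        tab = _clinical_frame({"alt": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        labels = [0, 0, 0, 1, 1, 1]
        report = profile_clusters(tab, labels, continuous=["alt"], categorical=[])
        row = report.continuous_pairwise.iloc[0]
        assert row["u"] == 0.0
        assert row["p"] == pytest.approx(0.1)  # exact 2/20

    def test_percentages_sum_to_hundred(self, small_cohort):
        _, clinical, truth = small_cohort
        labels = np.array([truth.subject_cluster[s] for s in clinical["subject_id"]])
        report = profile_clusters(clinical, labels, continuous=["alt"],
                                  categorical=["mash_category"])
        sums = report.categorical_summary.groupby("cluster")["percent"].sum()
        assert np.allclose(sums, 100.0)

    def test_kruskal_wallis_type_one_error_calibrated(self):
        """Identical distributions in every cluster: omnibus rejection rate at
        alpha=0.05 stays within binomial tolerance of 0.05."""
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 2000
        labels = np.repeat([0, 1, 2], 10)
        from scipy import stats as sps
        for _ in range(reps):
            x = rng.standard_normal(30)
            groups = [x[labels == c] for c in range(3)]
            _, p = sps.kruskal(*groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_profile_uses_tie_corrected_kruskal(self):
        tab = _clinical_frame({"alt": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 9.0, 9.0, 10.0]})
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        report = profile_clusters(tab, labels, continuous=["alt"], categorical=[])
        from scipy import stats as sps
        h, p = sps.kruskal(*[np.asarray(tab["alt"])[np.asarray(labels) == c] for c in range(3)])
        row = report.continuous_tests.iloc[0]
        assert row["kw_h"] == pytest.approx(h)
        assert row["p"] == pytest.approx(p)

    def test_empty_cluster_rejected(self):
        tab = _clinical_frame({"alt": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            profile_clusters(tab, [0, 0, 1], continuous=["alt"], categorical=[])


class TestDeriveVldl:
    @pytest.mark.parametrize("tg, expected", [(110.0, 22.0), (170.0, 34.0), (0.0, 0.0)])
    def test_published_median_identities(self, tg, expected):
        assert derive_vldl(tg) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            derive_vldl(-1.0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=5, max_size=30),
    st.integers(0, 2**31 - 1),
)
def test_permutation_preserves_each_column_multiset(values, seed):
    X = np.array(values)[:, None]
    Xp = permute_columns(X, np.random.default_rng(seed))
    assert sorted(X[:, 0]) == sorted(Xp[:, 0])
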