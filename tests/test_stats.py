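import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from nestmicro import stats


def euclidean_dm(points, ids=None):
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    ids = ids or [f"S{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


def random_jaccard_dm(n, seed, p=0.4, m=20):
    rng = np.random.default_rng(seed)
    presence = rng.random((n, m)) < p
    d = squareform(pdist(presence, metric="jaccard"))
    return DistanceMatrix(d, ids=[f"S{i}" for i in range(n)])


def mantel_r(a, b):
    ta = a[np.tril_indices(len(a), k=-1)]
    tb = b[np.tril_indices(len(b), k=-1)]
    return np.corrcoef(ta, tb)[0, 1]


class TestMantel:
    def test_self_correlation_is_one(self):
        dm = euclidean_dm(np.random.default_rng(0).random((6, 2)))
        res = stats.mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_label_mismatch_rejected(self):
        d1 = euclidean_dm(np.eye(4), ids=list("abcd"))
        d2 = euclidean_dm(np.eye(4), ids=list("abce"))
        with pytest.raises(ValueError, match="labels"):
            stats.mantel(d1, d2)

    def test_zero_variance_rejected(self):
        flat = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        dm = euclidean_dm(np.random.default_rng(0).random((4, 2)), ids=list("abcd"))
        with pytest.raises(ValueError, match="zero-variance"):
            stats.mantel(dm, flat)

    def test_statistic_matches_skbio(self):
        d1 = random_jaccard_dm(10, seed=1)
        d2 = random_jaccard_dm(10, seed=2)
        mine = stats.mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0, alternative="greater")
        assert mine.statistic == pytest.approx(float(r_ref), abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5])
    def test_p_value_matches_exhaustive_enumeration(self, n):
        """Permutation p agrees with the exact null over all n! relabelings."""
        rng = np.random.default_rng(42 + n)
        d1 = euclidean_dm(rng.random((n, 2)))
        d2_pts = rng.random((n, 2))
        d2 = euclidean_dm(d2_pts)
        observed = mantel_r(d1.data, d2.data)
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = mantel_r(d1.data, d2.data[np.ix_(perm, perm)])
            hits += r >= observed - 1e-12
            total += 1
        p_exact = hits / total
        n_perm = 1000
        res = stats.mantel(d1, d2, n_perm=n_perm, seed=7)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_value - p_exact) <= 2 * mc_se + 2 / n_perm

    def test_invariant_to_simultaneous_relabeling(self):
        d1 = random_jaccard_dm(8, seed=3)
        d2 = random_jaccard_dm(8, seed=4)
        perm = np.random.default_rng(0).permutation(8)
        ids = [d1.ids[i] for i in perm]
        d1p = DistanceMatrix(d1.data[np.ix_(perm, perm)], ids=ids)
        d2p = DistanceMatrix(d2.data[np.ix_(perm, perm)], ids=ids)
        a = stats.mantel(d1, d2, n_perm=49, seed=0)
        b = stats.mantel(d1p, d2p, n_perm=49, seed=0)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


class TestPermanova:
    def test_equals_classical_anova_f_on_univariate_euclidean(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=16)
        groups = np.repeat(["a", "b"], 8)
        dm = euclidean_dm(y)
        design = pd.DataFrame({"g": groups}, index=dm.ids)
        table = stats.permanova(dm, design, ["g"], n_perm=9, seed=0)
        f_ref = f_oneway(y[groups == "a"], y[groups == "b"]).statistic
        assert table.loc["g", "pseudo_F"] == pytest.approx(f_ref, abs=1e-8)

    def test_statistic_matches_skbio_on_jaccard_data(self):
        dm = random_jaccard_dm(15, seed=5)
        groups = ["x"] * 5 + ["y"] * 5 + ["z"] * 5
        design = pd.DataFrame({"g": groups}, index=dm.ids)
        mine = stats.permanova(dm, design, ["g"], n_perm=9, seed=0)
        ref = skbio_permanova(dm, grouping=groups, permutations=0)
        assert mine.loc["g", "pseudo_F"] == pytest.approx(float(ref["test statistic"]), abs=1e-8)

    def test_perfect_separation_has_maximal_f_and_exact_p(self):
        """Within-group distance 0, between 1: F is maximal for the true
        labelling and its exact permutation p over C(6,3) splits is 2/20."""
        d = np.ones((6, 6)) - np.eye(6)
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[f"S{i}" for i in range(6)])
        f_obs = None
        f_all = []
        for members in itertools.combinations(range(6), 3):
            labels = np.array(["b"] * 6, dtype=object)
            labels[list(members)] = "a"
            design = pd.DataFrame({"g": labels}, index=dm.ids)
            f = stats.permanova(dm, design, ["g"], n_perm=0, seed=0).loc["g", "pseudo_F"]
            f_all.append(f)
            if members == (0, 1, 2):
                f_obs = f
        assert f_obs == pytest.approx(max(f_all))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])  # = 2/20 (complement ties)
        assert p_exact == pytest.approx(0.1)
        design = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=dm.ids)
        res = stats.permanova(dm, design, ["g"], n_perm=999, seed=3)
        assert abs(res.loc["g", "p_value"] - p_exact) <= 2 * np.sqrt(0.1 * 0.9 / 999) + 2 / 999

    def test_single_term_r2_identity(self):
        dm = random_jaccard_dm(12, seed=9)
        design = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=dm.ids)
        table = stats.permanova(dm, design, ["g"], n_perm=9, seed=0)
        assert table.loc["g", "R2"] + table.loc["Residual", "R2"] == pytest.approx(1.0, abs=1e-10)

    def test_margin_mode_adjusts_each_term_for_the_other(self):
        rng = np.random.default_rng(21)
        n = 24
        g1 = np.repeat(["a", "b"], n // 2)
        g2 = np.tile(["x", "y"], n // 2)
        y = (g1 == "b") * 1.0 + rng.normal(scale=0.5, size=n)
        dm = euclidean_dm(y)
        design = pd.DataFrame({"g1": g1, "g2": g2}, index=dm.ids)
        table = stats.permanova(dm, design, ["g1", "g2"], n_perm=99, seed=0)
        assert table.loc["g1", "pseudo_F"] > table.loc["g2", "pseudo_F"]
        # marginal SS of orthogonal balanced terms sum to the model SS
        ss_model = table.loc["Total", "sum_sq"] - table.loc["Residual", "sum_sq"]
        assert table.loc["g1", "sum_sq"] + table.loc["g2", "sum_sq"] == pytest.approx(ss_model)

    def test_singleton_level_rejected(self):
        dm = random_jaccard_dm(5, seed=2)
        design = pd.DataFrame({"g": ["a", "a", "b", "b", "c"]}, index=dm.ids)
        with pytest.raises(ValueError, match="singleton.*'c'"):
            stats.permanova(dm, design, ["g"])

    def test_aliased_terms_rejected(self):
        dm = random_jaccard_dm(8, seed=2)
        g = ["a"] * 4 + ["b"] * 4
        design = pd.DataFrame({"g1": g, "g2": g}, index=dm.ids)
        with pytest.raises(ValueError, match="aliased"):
            stats.permanova(dm, design, ["g1", "g2"])


class TestPcoa:
    def test_plane_points_reconstructed(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        dm = euclidean_dm(pts)
        ordn = stats.pcoa(dm)
        assert (ordn.eigenvalues > 0).sum() == 2
        assert ordn.imaginary.shape[1] == 0
        np.testing.assert_allclose(ordn.reconstructed_distances(), dm.data, atol=1e-8)

    def test_jaccard_matrix_reconstruction_with_negative_eigenvalues(self):
        dm = random_jaccard_dm(10, seed=13)
        ordn = stats.pcoa(dm, eig_tol=0.0)
        np.testing.assert_allclose(ordn.reconstructed_distances(), dm.data, atol=1e-8)

    def test_equidistant_simplex(self):
        dm = DistanceMatrix(1 - np.eye(5), ids=list("abcde"))
        ordn = stats.pcoa(dm)
        # n equidistant points embed exactly with one repeated positive eigenvalue
        pos = ordn.eigenvalues[ordn.eigenvalues > 1e-10]
        np.testing.assert_allclose(pos, pos[0], atol=1e-10)
        np.testing.assert_allclose(ordn.reconstructed_distances(), dm.data, atol=1e-8)

    def test_positive_eigenvalues_match_skbio(self):
        pts = np.random.default_rng(3).random((8, 3))
        dm = euclidean_dm(pts)
        ordn = stats.pcoa(dm)
        import skbio

        ref = skbio.stats.ordination.pcoa(dm, method="eigh")
        mine = np.sort(ordn.eigenvalues[ordn.eigenvalues > 1e-9])[::-1]
        theirs = np.sort(ref.eigvals[ref.eigvals > 1e-9].to_numpy())[::-1]
        np.testing.assert_allclose(mine, theirs, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            stats.pcoa(bad)


class TestDispersion:
    def test_equidistant_configuration_gives_equal_centroid_distances(self):
        dm = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        dists, _ = stats.dispersion_to_centroid(dm, ["g"] * 4, n_perm=9, seed=0)
        np.testing.assert_allclose(dists, dists.iloc[0], atol=1e-10)

    def test_matches_direct_coordinate_computation(self):
        rng = np.random.default_rng(8)
        pts = rng.random((9, 2))
        groups = ["a"] * 4 + ["b"] * 5
        dm = euclidean_dm(pts)
        dists, _ = stats.dispersion_to_centroid(dm, groups, n_perm=9, seed=0)
        expected = np.empty(9)
        for g in ("a", "b"):
            idx = [i for i, x in enumerate(groups) if x == g]
            centroid = pts[idx].mean(axis=0)
            expected[idx] = np.linalg.norm(pts[idx] - centroid, axis=1)
        np.testing.assert_allclose(dists.to_numpy(), expected, atol=1e-8)

    def test_translated_copy_groups_have_null_f(self):
        rng = np.random.default_rng(9)
        pts_a = rng.random((5, 2))
        pts_b = pts_a + np.array([10.0, 0.0])  # congruent group: same dispersion
        dm = euclidean_dm(np.vstack([pts_a, pts_b]))
        groups = ["a"] * 5 + ["b"] * 5
        _, res = stats.dispersion_to_centroid(dm, groups, n_perm=199, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.9

    def test_singleton_group_distance_zero_and_excluded(self):
        pts = np.random.default_rng(1).random((5, 2))
        dm = euclidean_dm(pts)
        dists, res = stats.dispersion_to_centroid(dm, ["a", "a", "a", "a", "solo"], n_perm=9, seed=0)
        assert dists["S4"] == 0.0
        assert np.isnan(res.statistic)  # only one testable group left


class TestWelchBH:
    def test_identical_groups_are_null(self):
        features = pd.DataFrame(np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 1)))
        res = stats.welch_bh(features, ["a", "a", "a", "b", "b", "b"])
        assert (res["t"] == 0).all()
        assert (res["p_value"] == 1).all()
        assert (res["q_value"] == 1).all()

    def test_single_feature_q_equals_p(self):
        rng = np.random.default_rng(2)
        features = pd.DataFrame(rng.normal(size=(1, 10)))
        res = stats.welch_bh(features, ["a"] * 5 + ["b"] * 5)
        assert res["q_value"].iloc[0] == pytest.approx(res["p_value"].iloc[0])

    def test_welch_statistic_against_hand_formula(self):
        a = np.array([3.1, 2.9, 3.4, 3.0])
        b = np.array([2.1, 2.0, 2.6])
        features = pd.DataFrame([np.concatenate([a, b])])
        res = stats.welch_bh(features, ["a"] * 4 + ["b"] * 3)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert res["t"].iloc[0] == pytest.approx((a.mean() - b.mean()) / se)


class TestSmaSlope:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r = stats.sma_slope(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_equals_ols_slope_over_abs_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(scale=0.8, size=50)
        slope, _, r = stats.sma_slope(x, y)
        ols = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(ols / abs(r))

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(scale=0.3, size=30)
        s_xy, _, _ = stats.sma_slope(x, y)
        s_yx, _, _ = stats.sma_slope(y, x)
        assert s_xy == pytest.approx(1 / s_yx)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.sma_slope(np.ones(5), np.arange(5.0))
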