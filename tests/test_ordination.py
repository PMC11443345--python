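"""PCoA geometry, PERMANOVA oracles, regression and the test battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from statsmodels.stats.multitest import multipletests

from swabshade.ordination import (
    bh_adjust,
    kruskal_wallis,
    mean_distance_to_reference,
    pairwise_wilcoxon_fdr,
    pcoa,
    permanova,
    regress_on_axes,
    spearman,
)


def euclidean_dm(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"S{i}" for i in range(len(pts))]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


# ---------------------------------------------------------------------------
# PCoA


class TestPcoa:
    def test_collinear_points_recover_spacings(self):
        dm = euclidean_dm([[0.0], [1.0], [3.0]])
        res = pcoa(dm)
        axis1 = res.coordinates["PC1"].to_numpy()
        gaps = np.abs(np.diff(np.sort(axis1)))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0], atol=1e-10)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_reconstructs_random_2d_cloud(self, rng):
        pts = rng.normal(size=(12, 2))
        res = pcoa(euclidean_dm(pts), n_axes=2)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, squareform(pdist(pts)), atol=1e-8)

    def test_procrustes_recovery_of_configuration(self, rng):
        pts = rng.normal(size=(10, 3))
        pts -= pts.mean(axis=0)
        res = pcoa(euclidean_dm(pts), n_axes=3)
        coords = res.coordinates.to_numpy()
        r, _ = orthogonal_procrustes(coords, pts)
        assert np.abs(coords @ r - pts).max() < 1e-8

    def test_duplicated_sample_coincident(self):
        dm = euclidean_dm([[0, 0], [1, 1], [1, 1]])
        res = pcoa(dm)
        c = res.coordinates.to_numpy()
        np.testing.assert_allclose(c[1], c[2], atol=1e-10)

    def test_axis_sign_convention(self, rng):
        res = pcoa(euclidean_dm(rng.normal(size=(8, 2))))
        for col in res.coordinates:
            v = res.coordinates[col].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0

    def test_proportion_explained_sums_to_at_most_one(self, rng):
        res = pcoa(euclidean_dm(rng.normal(size=(9, 4))))
        assert res.proportion_explained.sum() <= 1 + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_n_axes_bound(self):
        dm = euclidean_dm([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="n_axes"):
            pcoa(dm, n_axes=5)


# ---------------------------------------------------------------------------
# PERMANOVA


def oracle_pseudo_f(d, labels):
    """Naive pseudo-F from the definition (independent of the package)."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    groups = list(dict.fromkeys(labels.tolist()))
    ss_total = sum(d[i, j] ** 2 for i in range(n)
                   for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx
                         if i < j) / len(idx)
    a = len(groups)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_two_separated_clusters_minimal_p(self, rng):
        """Maximal separation puts p at the permutation floor.

        The observed F is the maximum over all labelings, so the only
        permutations counted are those recreating the observed bipartition
        (expected ~2 of 999 draws for n=6+6); p sits within a few counts
        of 1/(999+1).
        """
        pts = np.vstack([rng.normal(0, 0.01, size=(6, 2)),
                         rng.normal(10, 0.01, size=(6, 2))])
        labels = ["a"] * 6 + ["b"] * 6
        dm = euclidean_dm(pts)
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.p_value >= 0.001  # add-one rule: never 0
        assert res.p_value <= 0.01
        # and the observed F really is the maximum over all bipartitions
        f_obs = oracle_pseudo_f(dm.data, labels)
        f_max = 0.0
        for combo in itertools.combinations(range(12), 6):
            perm = np.array(["b"] * 12)
            perm[list(combo)] = "a"
            f_max = max(f_max, oracle_pseudo_f(dm.data, perm))
        assert f_obs == pytest.approx(f_max, abs=1e-9)

    def test_exact_matches_bruteforce_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = euclidean_dm(pts)
        res = permanova(dm, labels, exact=True)
        f_obs = oracle_pseudo_f(dm.data, labels)
        assert res.statistic == pytest.approx(f_obs, abs=1e-10)
        # enumerate all 20 distinct labelings
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            perm = np.array(["b"] * 6)
            perm[list(combo)] = "a"
            total += 1
            if oracle_pseudo_f(dm.data, perm) >= f_obs - 1e-12:
                count += 1
        assert total == 20
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_f_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        dm = euclidean_dm(pts)
        mine = permanova(dm, labels, n_perm=99, seed=1)
        theirs = skbio_permanova(dm, labels, permutations=99)
        assert mine.statistic == pytest.approx(theirs["test statistic"],
                                               abs=1e-10)

    def test_identical_samples_degenerate(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = permanova(dm, ["x", "x", "y", "y"], n_perm=99, seed=0)
        assert res.p_value == 1.0
        assert res.extras.get("degenerate")

    def test_small_group_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a", "a", "a", "a", "b"])

    def test_seeded_p_reproducible(self, rng):
        pts = rng.normal(size=(12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        dm = euclidean_dm(pts)
        p1 = permanova(dm, labels, n_perm=199, seed=7).p_value
        p2 = permanova(dm, labels, n_perm=199, seed=7).p_value
        assert p1 == p2


# ---------------------------------------------------------------------------
# regression on axes


class TestAxisRegression:
    def _ordination(self, coords):
        from swabshade.ordination import OrdinationResult

        df = pd.DataFrame(coords, columns=["PC1", "PC2"],
                          index=[f"S{i}" for i in range(len(coords))])
        return OrdinationResult(df, np.array([2.0, 1.0]), np.array([0.6, 0.3]))

    def test_exact_linear_fit_on_axis1(self, rng):
        coords = rng.normal(size=(20, 2))
        ordn = self._ordination(coords)
        darkness = pd.Series(0.2 + 0.5 * coords[:, 0],
                             index=ordn.coordinates.index)
        res = regress_on_axes(darkness, ordn)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.params["PC1"] == pytest.approx(0.5, abs=1e-10)
        assert abs(res.params["PC2"]) < 1e-10
        assert res.p_values["PC1"] < 1e-12

    def test_three_point_normal_equations(self):
        # darkness ~ b0 + b1*x1 + b2*x2 with 3 points: exact interpolation
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ordn = self._ordination(coords)
        darkness = pd.Series([0.3, 0.7, 0.5], index=ordn.coordinates.index)
        res = regress_on_axes(darkness, ordn)
        x = np.column_stack([np.ones(3), coords])
        beta = np.linalg.solve(x, darkness.to_numpy())
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_constant_darkness_rejected(self, rng):
        ordn = self._ordination(rng.normal(size=(5, 2)))
        darkness = pd.Series(0.5, index=ordn.coordinates.index)
        with pytest.raises(ValueError, match="constant"):
            regress_on_axes(darkness, ordn)

    def test_null_p_values_roughly_uniform(self):
        """With independent darkness the axis-1 p-value is U(0,1)."""
        pvals = []
        rng = np.random.default_rng(0)
        for _ in range(400):
            coords = rng.normal(size=(60, 2))
            ordn = self._ordination(coords)
            darkness = pd.Series(rng.uniform(0, 1, 60),
                                 index=ordn.coordinates.index)
            pvals.append(regress_on_axes(darkness, ordn).p_values["PC1"])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestMeanDistance:
    def _ordination(self, coords, ids):
        from swabshade.ordination import OrdinationResult

        df = pd.DataFrame(coords, columns=["PC1", "PC2"], index=ids)
        return OrdinationResult(df, np.ones(2), np.ones(2) / 2)

    def test_coincident_reference_zero(self):
        ordn = self._ordination([[1, 1], [1, 1]], ["swab", "ref"])
        out = mean_distance_to_reference(ordn, ["swab"], ["ref"])
        assert out["swab"] == 0.0

    def test_symmetric_references(self):
        ordn = self._ordination([[0, 0], [1, 0], [-1, 0]],
                                ["swab", "r1", "r2"])
        out = mean_distance_to_reference(ordn, ["swab"], ["r1", "r2"])
        assert out["swab"] == pytest.approx(1.0)

    def test_hand_computed_means(self):
        coords = [[0, 0], [3, 4], [6, 8], [0, 5], [5, 0]]
        ids = ["w1", "w2", "w3", "r1", "r2"]
        ordn = self._ordination(coords, ids)
        out = mean_distance_to_reference(ordn, ["w1", "w2", "w3"],
                                         ["r1", "r2"])
        d = lambda a, b: math.dist(a, b)
        for sid, pt in zip(["w1", "w2", "w3"], coords[:3]):
            expected = (d(pt, [0, 5]) + d(pt, [5, 0])) / 2
            assert out[sid] == pytest.approx(expected, abs=1e-12)

    def test_empty_reference_rejected(self):
        ordn = self._ordination([[0, 0]], ["swab"])
        with pytest.raises(ValueError, match="empty"):
            mean_distance_to_reference(ordn, ["swab"], [])


# ---------------------------------------------------------------------------
# nonparametric battery


class TestBattery:
    def test_kruskal_all_equal(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_kruskal_matches_scipy(self, rng):
        vals = rng.normal(size=30)
        groups = rng.choice(["a", "b", "c"], size=30)
        res = kruskal_wallis(vals, groups)
        h, p = stats.kruskal(*[vals[groups == g] for g in "abc"])
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_spearman_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == 1.0
        res = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert res.statistic == -1.0

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_pairwise_wilcoxon_all_pairs_bh(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15),
                               rng.normal(0, 1, 15)])
        groups = np.repeat(["a", "b", "c"], 15)
        out = pairwise_wilcoxon_fdr(vals, groups)
        assert len(out) == 3
        np.testing.assert_allclose(out["q"], bh_adjust(out["p"].to_numpy()))

    def test_kruskal_consistent_with_wilcoxon_two_groups(self):
        """KW on 2 groups agrees with the rank-sum decision at alpha=0.05."""
        rng = np.random.default_rng(3)
        agree = 0
        n_sim = 300
        for _ in range(n_sim):
            shift = rng.choice([0.0, 1.0])
            a = rng.normal(0, 1, 12)
            b = rng.normal(shift, 1, 12)
            vals = np.concatenate([a, b])
            groups = np.repeat(["a", "b"], 12)
            kw = kruskal_wallis(vals, groups).p_value < 0.05
            # exact-free comparison: same asymptotic family
            _, wp = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic",
                                       use_continuity=False)
            agree += (kw == (wp < 0.05))
        assert agree / n_sim > 0.99


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            mine = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]),
                                   atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 20)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
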