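"""Generalized UniFrac, NMDS, PERMANOVA, and dysbiosis trajectories."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as skbio_beta
from skbio.stats.distance import permanova as skbio_permanova

from dsslong.beta_diversity import adonis, baseline_distance, gunifrac, nmds
from dsslong.cohort_io import CohortValidationError, FeatureTable
from dsslong.synthetic_cohort import random_tree


def _brute_force_gunifrac(tree, taxa, ra_a, ra_b, alpha):
    """Naive per-branch traversal, re-deriving clade sums leaf by leaf."""
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        leaves = [t.name for t in node.tips()] or [node.name]
        p = sum(ra_a[taxa.index(n)] for n in leaves if n in taxa)
        q = sum(ra_b[taxa.index(n)] for n in leaves if n in taxa)
        if p + q == 0:
            continue
        w = node.length * (p + q) ** alpha
        num += w * abs(p - q) / (p + q)
        den += w
    return num / den if den else 0.0


def _random_instance(seed, n_leaves=8, n_samples=4):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_leaves)]
    tree = random_tree(n_leaves, seed=seed, leaf_names=taxa)
    counts = rng.integers(0, 50, size=(n_samples, n_leaves))
    counts[:, 0] += 1  # keep every sample non-empty
    return tree, taxa, counts


class TestGUniFrac:
    def test_identical_samples_distance_zero(self):
        tree, taxa, counts = _random_instance(0)
        t = FeatureTable(["a", "b"], taxa, np.vstack([counts[0], counts[0]]))
        dm = gunifrac(t, tree, alpha=0.5)
        assert dm[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_distance_one(self):
        taxa = ["A", "B", "C", "D"]
        tree = TreeNode.read(io.StringIO("((A:1,B:2):0.5,(C:1.5,D:0.7):0.3);"))
        t = FeatureTable(["x", "y"], taxa, np.array([[3, 5, 0, 0], [0, 0, 2, 9]]))
        for alpha in (0.0, 0.5, 1.0):
            assert gunifrac(t, tree, alpha=alpha)[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_brute_force_oracle(self, alpha):
        for seed in range(10):
            tree, taxa, counts = _random_instance(seed)
            t = FeatureTable([f"s{i}" for i in range(len(counts))], taxa, counts)
            dm = gunifrac(t, tree, alpha=alpha)
            ra = counts / counts.sum(axis=1, keepdims=True)
            for i in range(len(counts)):
                for j in range(i + 1, len(counts)):
                    expected = _brute_force_gunifrac(tree, taxa, ra[i], ra[j], alpha)
                    assert dm[i, j] == pytest.approx(expected, abs=1e-12)

    def test_alpha_one_equals_normalized_weighted_unifrac(self):
        # independent library implementation as a second oracle
        for seed in range(5):
            tree, taxa, counts = _random_instance(seed + 100)
            t = FeatureTable([f"s{i}" for i in range(len(counts))], taxa, counts)
            ours = gunifrac(t, tree, alpha=1.0)
            ref = skbio_beta("weighted_unifrac", counts,
                             ids=list(ours.ids), taxa=taxa, tree=tree,
                             normalized=True)
            assert np.allclose(ours.data, ref.data, atol=1e-10)

    def test_continuity_in_alpha(self):
        tree, taxa, counts = _random_instance(7)
        t = FeatureTable([f"s{i}" for i in range(len(counts))], taxa, counts)
        d1 = gunifrac(t, tree, alpha=0.5).data
        d2 = gunifrac(t, tree, alpha=0.5 + 1e-6).data
        assert np.abs(d1 - d2).max() < 1e-4

    def test_missing_tree_feature_is_error(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1);"))
        t = FeatureTable(["s1", "s2"], ["A", "Z"], np.array([[1, 1], [2, 1]]))
        with pytest.raises(CohortValidationError, match="missing from tree"):
            gunifrac(t, tree)

    def test_bounds_symmetry_diagonal(self, small_cohort):
        from dsslong.community_metrics import rarefy
        rare = rarefy(small_cohort.table, 10000, seed=0)
        sub = rare.select_samples(rare.sample_ids[:12])
        dm = gunifrac(sub, small_cohort.tree)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T, atol=1e-12)
        assert np.allclose(np.diag(dm.data), 0)


class TestNMDS:
    def test_three_points_embed_exactly(self):
        D = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]]),
                           ids=["a", "b", "c"])
        res = nmds(D, k=2, seed=0, restarts=4)
        assert res.stress <= 1e-6

    def test_recovers_rank_order_of_known_configuration(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 2))
        from scipy.spatial.distance import pdist, squareform
        D = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(9)])
        res = nmds(D, k=2, seed=1, restarts=8)
        assert res.stress < 1e-3
        got = pdist(res.coordinates)
        want = pdist(X)
        from scipy.stats import spearmanr
        assert spearmanr(got, want).statistic >= 0.99

    def test_coordinates_centered_and_deterministic(self):
        tree, taxa, counts = _random_instance(3, n_samples=6)
        t = FeatureTable([f"s{i}" for i in range(6)], taxa, counts)
        dm = gunifrac(t, tree)
        a = nmds(dm, seed=9, restarts=3)
        b = nmds(dm, seed=9, restarts=3)
        assert np.allclose(a.coordinates, b.coordinates)
        assert np.allclose(a.coordinates.mean(axis=0), 0, atol=1e-12)

    def test_k_must_be_small(self):
        D = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            nmds(D, k=3)


class TestAdonis:
    @staticmethod
    def _two_clusters(sep, n=8, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, size=(n, 3)),
                         rng.normal(sep, 1, size=(n, 3))])
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        labels = ["a"] * n + ["b"] * n
        return DistanceMatrix(D, ids=[str(i) for i in range(2 * n)]), labels

    def test_separated_clusters_detected(self):
        dm, labels = self._two_clusters(sep=25.0)
        res = adonis(dm, labels, n_perm=999, seed=1)
        assert res.r2 > 0.9
        assert res.p == pytest.approx(1 / 1000)

    def test_pseudo_f_matches_skbio_permanova(self):
        dm, labels = self._two_clusters(sep=2.0, seed=3)
        ours = adonis(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=0)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_reproducible_under_seed_and_reorder_invariant_r2(self):
        dm, labels = self._two_clusters(sep=1.0, seed=5)
        a = adonis(dm, labels, n_perm=199, seed=7)
        b = adonis(dm, labels, n_perm=199, seed=7)
        assert (a.r2, a.pseudo_f, a.p) == (b.r2, b.pseudo_f, b.p)
        perm = np.random.default_rng(0).permutation(len(labels))
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                             ids=[dm.ids[i] for i in perm])
        c = adonis(dm2, [labels[i] for i in perm], n_perm=199, seed=7)
        assert c.r2 == pytest.approx(a.r2, rel=1e-9)

    def test_single_group_rejected(self):
        dm, _ = self._two_clusters(sep=1.0)
        with pytest.raises(ValueError):
            adonis(dm, ["x"] * len(dm.ids))


class TestBaselineDistance:
    def test_constant_distances(self):
        n = 5
        D = np.full((n, n), 0.3)
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(D, ids=[f"s{i}" for i in range(n)])
        out = baseline_distance(dm, ["s0", "s1"])
        assert out["s4"] == pytest.approx(0.3)

    def test_baseline_member_excludes_self(self):
        D = np.array([
            [0.0, 0.1, 0.2, 0.3],
            [0.1, 0.0, 0.5, 0.5],
            [0.2, 0.5, 0.0, 0.5],
            [0.3, 0.5, 0.5, 0.0],
        ])
        dm = DistanceMatrix(D, ids=list("abcd"))
        out = baseline_distance(dm, list("bcd"))
        assert out["a"] == pytest.approx(0.2)
        assert out["b"] == pytest.approx(0.5)  # own zero excluded

    def test_dysbiosis_grows_with_day_at_top_dose(self, default_cohort):
        from dsslong.community_metrics import rarefy
        c = default_cohort
        rare = rarefy(c.table, 10000, seed=2)
        dm = gunifrac(rare, c.tree)
        baseline = [s for s in dm.ids if c.metadata.group_of(s) == (0, 0)]
        bd = baseline_distance(dm, baseline)
        means = {}
        for day in c.config.days:
            ids = [s for s in dm.ids if c.metadata.group_of(s) == (3, day)]
            means[day] = float(bd[ids].mean())
        assert means[max(c.config.days)] > means[0]
        # broadly non-decreasing: late-course mean exceeds early-course mean
        days = sorted(means)
        early = np.mean([means[d] for d in days[:3]])
        late = np.mean([means[d] for d in days[-3:]])
        assert late > early
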