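import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

import gutlinks as gl


def table_from(rows, samples=None, otus=None):
    rows = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    otus = otus or [f"o{j}" for j in range(rows.shape[1])]
    return gl.OtuTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestAlphaDiversity:
    def test_chao1_bias_corrected_hand_value(self):
        # 10 observed OTUs, F1=4 singletons, F2=2 doubletons:
        # classic 10 + 16/4 = 14; bias-corrected 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5, 0]
        t = table_from([counts])
        res = gl.alpha_diversity(t)
        assert res.loc["s0", "chao1"] == pytest.approx(12.0)
        classic = gl.alpha_diversity(t, bias_corrected=False)
        assert classic.loc["s0", "chao1"] == pytest.approx(14.0)

    def test_shannon_uniform_closed_form(self):
        t = table_from([[5] * 8])
        res = gl.alpha_diversity(t)
        assert res.loc["s0", "shannon"] == pytest.approx(np.log(8))

    def test_faith_pd_star_tree(self):
        tree = TreeNode.read(io.StringIO(
            "(" + ",".join(f"o{j}:1" for j in range(9)) + ");"))
        counts = [[1] * 5 + [0] * 4]
        t = table_from(counts)
        res = gl.alpha_diversity(t, tree=tree)
        assert res.loc["s0", "pd"] == pytest.approx(5.0)

    def test_chao1_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(0, 4, size=(10, 30)))
        res = gl.alpha_diversity(t)
        observed = (t.counts > 0).sum(axis=1)
        assert (res["chao1"].to_numpy() >= observed - 1e-9).all()

    def test_faith_pd_matches_skbio_on_bifurcating_trees(self):
        """Independent oracle: scikit-bio's faith_pd on random coalescents."""
        from skbio.diversity.alpha import faith_pd as skbio_faith_pd
        cfg = gl.SimulationConfig(n_samples_per_cell=2, n_otus=12, depth=300,
                                  n_blocks=0, block_size=0, n_stage_otus=0,
                                  n_group_otus=0, seed=6)
        table, _, tree, _, _ = gl.simulate_dataset(cfg)
        mine = gl.alpha_diversity(table, tree=tree)["pd"]
        for i, sid in enumerate(table.sample_ids):
            ref = skbio_faith_pd(table.counts[i], taxa=table.otu_ids,
                                 tree=tree)
            assert mine[sid] == pytest.approx(ref)

    def test_missing_leaf_error_lists_otus(self):
        tree = TreeNode.read(io.StringIO("(o0:1,o1:1);"))
        t = table_from([[1, 1, 1]])
        with pytest.raises(ValueError, match="o2"):
            gl.alpha_diversity(t, tree=tree)


def brute_force_unifrac(tree, presence_a, presence_b):
    """Independent oracle: classify every branch as shared or unique by
    enumerating the leaves it subtends."""
    unique = 0.0
    union = 0.0
    for node in tree.traverse(include_self=False):
        if node.length in (None, 0):
            length = node.length or 0.0
        else:
            length = node.length
        leaves = {t.name for t in node.tips()} or {node.name}
        in_a = bool(leaves & presence_a)
        in_b = bool(leaves & presence_b)
        if in_a or in_b:
            union += length
            if in_a != in_b:
                unique += length
    return unique / union if union else 0.0


class TestUnweightedUnifrac:
    def test_identical_profiles_zero(self):
        tree = TreeNode.read(io.StringIO("((o0:1,o1:2):1,(o2:1,o3:1):2);"))
        t = table_from([[1, 0, 3, 0], [5, 0, 1, 0]])
        d = gl.unweighted_unifrac(t, tree)
        assert d["s0", "s1"] == pytest.approx(0.0)

    def test_disjoint_root_clades_distance_one(self):
        tree = TreeNode.read(io.StringIO("((o0:1,o1:2):1,(o2:1,o3:1):2);"))
        t = table_from([[1, 1, 0, 0], [0, 0, 1, 1]])
        d = gl.unweighted_unifrac(t, tree)
        assert d["s0", "s1"] == pytest.approx(1.0)

    def test_matches_branch_enumeration_oracle_exhaustively(self):
        """All non-empty presence patterns on a random 6-leaf tree."""
        rng = np.random.default_rng(4)
        cfg = gl.SimulationConfig(n_samples_per_cell=1, n_otus=6, depth=100,
                                  n_blocks=0, block_size=0, n_stage_otus=0,
                                  n_group_otus=0, seed=8)
        _, _, tree, _, _ = gl.simulate_dataset(cfg)
        otus = sorted(t.name for t in tree.tips())
        patterns = [p for p in itertools.product([0, 1], repeat=6) if any(p)]
        counts = np.array(patterns)
        t = table_from(counts, otus=otus)
        d = gl.unweighted_unifrac(t, tree)
        for i, j in itertools.combinations(range(len(patterns)), 2):
            pa = {otus[k] for k in range(6) if patterns[i][k]}
            pb = {otus[k] for k in range(6) if patterns[j][k]}
            expected = brute_force_unifrac(tree, pa, pb)
            assert d[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-10)

    def test_empty_sample_raises(self):
        tree = TreeNode.read(io.StringIO("(o0:1,o1:1);"))
        t = table_from([[1, 1], [0, 0]])
        with pytest.raises(ValueError):
            gl.unweighted_unifrac(t, tree)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = gl.bray_curtis(table_from([[2, 3], [2, 3]]))
        assert d["s0", "s1"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = gl.bray_curtis(table_from([[2, 0], [0, 7]]))
        assert d["s0", "s1"] == pytest.approx(1.0)

    def test_hand_computed_on_counts(self):
        # (2,2) vs (2,0): sum|a-b| = 2, sum(a+b) = 6 -> 1/3
        d = gl.bray_curtis(table_from([[2, 2], [2, 0]]), on="counts")
        assert d["s0", "s1"] == pytest.approx(2 / 6)

    def test_symmetric_bounded(self):
        rng = np.random.default_rng(1)
        t = table_from(rng.integers(0, 20, size=(8, 12)) + 1)
        d = gl.bray_curtis(t).data
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = DistanceMatrix(np.array([[0., 1, 2], [1, 0, 1], [2, 1, 0]]),
                           ids=list("abc"))
        res = gl.pcoa(d)
        coords = res.coordinates.to_numpy()
        # first axis reproduces the line (spacing 1), higher eigenvalues ~ 0
        gaps = np.diff(np.sort(coords[:, 0]))
        assert np.allclose(gaps, 1.0, atol=1e-9)
        assert np.all(res.eigenvalues[1:] < 1e-9)

    def test_euclidean_distances_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"s{i}" for i in range(10)])
        res = gl.pcoa(d)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d.data, atol=1e-9)

    def test_equilateral_simplex_equal_eigenvalues(self):
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = gl.pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"s{i}" for i in range(6)])
        a = gl.pcoa(d).coordinates
        b = gl.pcoa(d).coordinates
        pd.testing.assert_frame_equal(a, b)
        first_nonzero = a.to_numpy()[np.abs(a.to_numpy()[:, 0]) > 1e-12, 0][0]
        assert first_nonzero > 0


class TestPermanova:
    @pytest.fixture
    def euclid(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 4))
        ids = [f"s{i}" for i in range(30)]
        meta = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                             "h": (["x", "y", "z"] * 10)},
                            index=ids)
        return DistanceMatrix(squareform(pdist(pts)), ids=ids), meta

    def test_single_factor_partition_identity(self, euclid):
        dm, meta = euclid
        res = gl.permanova(dm, meta, ["g"], n_perm=99, seed=0)
        assert res["R2"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_skbio_pseudo_f(self, euclid):
        """Independent oracle: scikit-bio's single-factor PERMANOVA."""
        dm, meta = euclid
        res = gl.permanova(dm, meta, ["g"], n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=meta["g"].tolist(), permutations=99)
        assert res.loc["g", "F"] == pytest.approx(ref["test statistic"],
                                                  rel=1e-10)

    def test_two_separated_clusters(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.1, (15, 2)),
                         rng.normal(100, 0.1, (15, 2))])
        ids = [f"s{i}" for i in range(30)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        meta = pd.DataFrame({"g": ["a"] * 15 + ["b"] * 15}, index=ids)
        res = gl.permanova(dm, meta, ["g"], n_perm=999, seed=1)
        assert res.loc["g", "R2"] > 0.99
        assert res.loc["g", "p"] == pytest.approx(1 / 1000)

    def test_sequential_r2_sums_to_one_multi_factor(self, euclid):
        dm, meta = euclid
        res = gl.permanova(dm, meta, ["g", "h"], n_perm=99, seed=0)
        assert res["R2"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_level_factor_rejected(self, euclid):
        dm, meta = euclid
        meta = meta.assign(const="same")
        with pytest.raises(ValueError, match="single level"):
            gl.permanova(dm, meta, ["const"], n_perm=99, seed=0)

    def test_aliased_factor_rejected(self, euclid):
        dm, meta = euclid
        meta = meta.assign(g2=meta["g"])
        with pytest.raises(ValueError, match="aliased"):
            gl.permanova(dm, meta, ["g", "g2"], n_perm=99, seed=0)

    def test_marginal_mode_matches_single_factor_fits(self, euclid):
        dm, meta = euclid
        marg = gl.permanova(dm, meta, ["g", "h"], n_perm=99, seed=0,
                            mode="marginal")
        solo = gl.permanova(dm, meta, ["h"], n_perm=99, seed=0)
        assert marg.loc["h", "F"] == pytest.approx(solo.loc["h", "F"])


class TestKruskalWallis:
    def test_all_identical_values(self):
        h, p = gl.kruskal_wallis_by_group([1.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert h == 0.0 and p == 1.0

    def test_separated_ranks_hand_formula(self):
        # groups {1..5} and {6..10}: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        values = list(range(1, 11))
        groups = ["a"] * 5 + ["b"] * 5
        h, p = gl.kruskal_wallis_by_group(values, groups)
        expected = 12 / (10 * 11) * (5 * (3 - 5.5) ** 2 + 5 * (8 - 5.5) ** 2)
        assert h == pytest.approx(expected)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=12)
        groups = np.array(["a", "b", "c"] * 4)
        h1, _ = gl.kruskal_wallis_by_group(values, groups)
        perm = rng.permutation(12)
        h2, _ = gl.kruskal_wallis_by_group(values[perm], groups[perm])
        assert h1 == pytest.approx(h2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gl.kruskal_wallis_by_group([1, 2, 3], ["a", "a", "a"])
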