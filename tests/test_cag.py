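import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import gutlinks as gl
from conftest import make_corr


class TestBuildCags:
    def test_planted_partition_recovered_exactly(self, two_blocks_dataset,
                                                 two_blocks_sparcc):
        table, *_, truth = two_blocks_dataset
        cags = gl.build_cags(table, two_blocks_sparcc, n_cags=2)
        truth_labels = [truth.block_membership.get(o, -1)
                        for o in cags.assignment.index]
        assert adjusted_rand_score(truth_labels,
                                   cags.assignment.to_numpy()) == 1.0

    def test_retention_rule_keeps_partnered_otus_only(self):
        m = np.eye(5)
        m[0, 1] = m[1, 0] = 0.8     # o0, o1 partnered
        m[2, 3] = m[3, 2] = 0.4     # below threshold
        corr = make_corr(m)
        df = pd.DataFrame(np.ones((4, 5), dtype=int),
                          index=[f"s{i}" for i in range(4)],
                          columns=corr.otu_ids)
        cags = gl.build_cags(gl.OtuTable(df), corr, n_cags=1)
        assert sorted(cags.assignment.index) == ["o0", "o1"]

    def test_otu_order_invariance(self, two_blocks_dataset, two_blocks_sparcc):
        table, *_ = two_blocks_dataset
        cags = gl.build_cags(table, two_blocks_sparcc, n_cags=2)
        perm = list(np.random.default_rng(0).permutation(table.otu_ids))
        corr_perm = gl.CorrelationMatrix(
            rho=two_blocks_sparcc.rho.loc[perm, perm])
        table_perm = gl.OtuTable(table.df[perm])
        cags2 = gl.build_cags(table_perm, corr_perm, n_cags=2)
        assert adjusted_rand_score(
            cags.assignment.loc[cags2.assignment.index].to_numpy(),
            cags2.assignment.to_numpy()) == 1.0

    def test_singleton_cut_skips_validation(self, two_blocks_dataset,
                                            two_blocks_sparcc):
        table, *_ = two_blocks_dataset
        retained = len(gl.build_cags(table, two_blocks_sparcc, n_cags=2)
                       .assignment)
        cags = gl.build_cags(table, two_blocks_sparcc, n_cags=retained)
        validated = gl.validate_cags(cags, table, n_perm=199, seed=0)
        assert validated.pvalues == {}

    def test_n_cags_exceeding_retained_rejected(self, two_blocks_dataset,
                                                two_blocks_sparcc):
        table, *_ = two_blocks_dataset
        with pytest.raises(ValueError, match="exceeds"):
            gl.build_cags(table, two_blocks_sparcc, n_cags=10_000)

    def test_no_partner_raises(self):
        corr = make_corr(np.eye(4))
        df = pd.DataFrame(np.ones((3, 4), dtype=int),
                          index=["s0", "s1", "s2"], columns=corr.otu_ids)
        with pytest.raises(ValueError, match="partner"):
            gl.build_cags(gl.OtuTable(df), corr, n_cags=2)

    def test_abundance_conservation(self, two_blocks_dataset, two_blocks_sparcc):
        """CAG abundances sum to the total retained-OTU relative abundance."""
        table, *_ = two_blocks_dataset
        cags = gl.build_cags(table, two_blocks_sparcc, n_cags=2)
        rel = gl.relative_abundance(table).df
        expected = rel[list(cags.assignment.index)].sum(axis=1)
        assert np.allclose(cags.abundance.sum(axis=1), expected)

    def test_ward_merge_heights_monotone(self, two_blocks_sparcc):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        retained = gl.cag._retained_otus(two_blocks_sparcc, 0.5)
        d = 1 - two_blocks_sparcc.rho.loc[retained, retained].to_numpy()
        np.fill_diagonal(d, 0)
        z = linkage(squareform((d + d.T) / 2, checks=False), method="ward")
        assert (np.diff(z[:, 2]) >= -1e-9).all()


class TestValidateCags:
    def test_planted_block_vs_null_otus_gets_minimal_p(self, two_blocks_dataset):
        """A planted block tested against unstructured OTUs: p = 1/(n_perm+1)."""
        table, *_, truth = two_blocks_dataset
        block = sorted(o for o, b in truth.block_membership.items() if b == 0)
        nulls = [o for o in table.otu_ids
                 if o not in truth.block_membership][:20]
        labels = [1] * len(block) + [2] * len(nulls)
        assignment = pd.Series(labels,
                               index=pd.Index(block + nulls, name="otu_id"))
        rel = gl.relative_abundance(table).df
        abund = pd.DataFrame({c: rel[assignment.index[assignment == c]]
                              .sum(axis=1) for c in (1, 2)})
        cags = gl.CagSet(assignment=assignment, abundance=abund)
        validated = gl.validate_cags(cags, table, n_perm=999, seed=1)
        assert validated.pvalues[1] == pytest.approx(1 / 1000)
        assert validated.acceptable[1]

    def test_both_blocks_validated_in_two_way_cut(self, two_blocks_dataset,
                                                  two_blocks_sparcc):
        table, *_ = two_blocks_dataset
        cags = gl.build_cags(table, two_blocks_sparcc, n_cags=2)
        validated = gl.validate_cags(cags, table, n_perm=999, seed=1)
        assert all(validated.acceptable.values())
        assert max(validated.pvalues.values()) <= 0.004

    def test_null_acceptance_rate_calibrated(self):
        """Random CAGs over i.i.d. OTUs are accepted at ~ the nominal level.

        p < 0.005 with 999 permutations accepts when at most 3 of 999
        permuted statistics exceed the observed one, i.e. with probability
        4/1000 under the null.
        """
        rng = np.random.default_rng(0)
        accepted = 0
        n_rep = 400
        for rep in range(n_rep):
            x = np.exp(rng.normal(0, 1, size=(20, 30)))
            counts = np.floor(1000 * x / x.sum(1, keepdims=True)).astype(int) + 1
            table = gl.OtuTable(pd.DataFrame(
                counts, index=[f"s{i}" for i in range(20)],
                columns=[f"o{j}" for j in range(30)]))
            labels = np.ones(30, dtype=int)
            labels[rng.choice(30, size=5, replace=False)] = 2
            assignment = pd.Series(labels, index=table.otu_ids, name="cag")
            rel = gl.relative_abundance(table).df
            abund = pd.DataFrame({c: rel[assignment.index[assignment == c]]
                                  .sum(axis=1) for c in (1, 2)})
            cags = gl.CagSet(assignment=assignment, abundance=abund)
            validated = gl.validate_cags(cags, table, n_perm=999,
                                         seed=1000 + rep)
            accepted += sum(validated.acceptable.values())
        rate = accepted / (2 * n_rep)
        assert rate <= 0.02

    def test_insufficient_permutations_rejected(self, two_blocks_dataset,
                                                two_blocks_sparcc):
        table, *_ = two_blocks_dataset
        cags = gl.build_cags(table, two_blocks_sparcc, n_cags=2)
        with pytest.raises(ValueError):
            gl.validate_cags(cags, table, n_perm=99)


class TestCompareCagGroups:
    def _cagset(self, abund, samples):
        assignment = pd.Series([1], index=pd.Index(["o0"], name="otu_id"))
        return gl.CagSet(assignment=assignment,
                         abundance=pd.DataFrame({1: abund}, index=samples))

    def test_shifted_abundance_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        for rep in range(40):
            a = rng.lognormal(0, 0.5, 40)
            b = rng.lognormal(np.log(1.5), 0.5, 40)   # +50 % shift
            samples = [f"s{i}" for i in range(80)]
            cags = self._cagset(np.r_[a, b], samples)
            meta = pd.DataFrame({"group": ["NA"] * 40 + ["NO"] * 40},
                                index=samples)
            res = gl.compare_cag_groups(cags, meta)
            detected += res.loc[1, "p"] < 0.05
        assert detected / 40 >= 0.8

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(200):
            abund = rng.lognormal(0, 0.5, 30)
            samples = [f"s{i}" for i in range(30)]
            cags = self._cagset(abund, samples)
            meta = pd.DataFrame({"group": ["NA"] * 15 + ["NO"] * 15},
                                index=samples)
            ps.append(gl.compare_cag_groups(cags, meta).loc[1, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        abund = rng.lognormal(0, 1, 20)
        samples = [f"s{i}" for i in range(20)]
        cags = self._cagset(abund, samples)
        meta = pd.DataFrame({"group": ["NA"] * 10 + ["NO"] * 10},
                            index=samples)
        swapped = meta.replace({"NA": "NO", "NO": "NA"})
        r1 = gl.compare_cag_groups(cags, meta)
        r2 = gl.compare_cag_groups(cags, swapped)
        assert r1.loc[1, "p"] == pytest.approx(r2.loc[1, "p"])
        assert r1.loc[1, "direction"] != r2.loc[1, "direction"]

    def test_small_level_rejected(self):
        samples = [f"s{i}" for i in range(5)]
        cags = self._cagset(np.arange(5.0), samples)
        meta = pd.DataFrame({"group": ["NA"] * 3 + ["NO"] * 2}, index=samples)
        with pytest.raises(ValueError, match="fewer than 3"):
            gl.compare_cag_groups(cags, meta)
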