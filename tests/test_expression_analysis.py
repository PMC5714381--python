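"""Probe collapse, scaling, clustering, differential expression, set tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

import peaklink as pl
from peaklink.expression_analysis import ExpressionError


@pytest.fixture
def probe_matrix():
    return pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0, 7.0],
            "s2": [2.0, 5.2, 2.0, 7.0],
            "s3": [9.0, 5.4, 2.0, 7.0],
        },
        index=["pA1", "pA2", "pB1", "pX"],
    )


class TestCollapseProbes:
    def test_largest_iqr_retained(self, probe_matrix):
        out = pl.collapse_probes(
            probe_matrix, {"pA1": "geneA", "pA2": "geneA", "pB1": "geneB"}
        )
        # pA1 (IQR 3.5) beats pA2 (IQR 0.2); unmapped pX dropped
        assert list(out.index) == ["geneA", "geneB"]
        assert out.loc["geneA", "s3"] == 9.0

    def test_single_probe_gene_unchanged(self, probe_matrix):
        out = pl.collapse_probes(probe_matrix, {"pB1": "geneB"})
        assert out.loc["geneB"].tolist() == [2.0, 2.0, 2.0]

    def test_equal_iqr_breaks_lexicographically(self):
        m = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 2.0], "s3": [3.0, 3.0]},
            index=["pZ", "pA"],
        )
        out = pl.collapse_probes(m, {"pZ": "g", "pA": "g"})
        assert out.shape[0] == 1  # pA kept: lexicographically smaller

    def test_empty_mapping_rejected(self, probe_matrix):
        with pytest.raises(ExpressionError, match="mapping"):
            pl.collapse_probes(probe_matrix, {})


class TestZScale:
    def test_row_scaling_and_degenerate(self):
        m = pd.DataFrame({"a": [1.0, 5.0], "b": [2.0, 5.0], "c": [3.0, 5.0]},
                         index=["g1", "g2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = pl.zscale_genes(m)
        assert out.loc["g1"].tolist() == [-1.0, 0.0, 1.0]
        assert out.loc["g2"].tolist() == [0.0, 0.0, 0.0]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(5, 2, size=(30, 8)))
        once = pl.zscale_genes(m)
        twice = pl.zscale_genes(once)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12
        assert np.abs(once.mean(axis=1)).max() < 1e-12
        assert np.abs(once.std(axis=1, ddof=1) - 1).max() < 1e-12


class TestPairwiseCorrelation:
    def test_duplicate_and_negated_rows(self):
        base = np.arange(10.0)
        m = pd.DataFrame([base, base, -base], index=["g1", "g2", "g3"])
        r = pl.pairwise_correlation(m)
        assert r.loc["g1", "g2"] == pytest.approx(1.0)
        assert r.loc["g1", "g3"] == pytest.approx(-1.0)
        assert np.allclose(r, r.T) and np.allclose(np.diag(r), 1.0)

    def test_independent_rows_near_zero(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.standard_normal((2, 1000)), index=["a", "b"])
        assert abs(pl.pairwise_correlation(m).loc["a", "b"]) < 0.1

    def test_missing_gene_listed(self):
        m = pd.DataFrame(np.ones((2, 4)), index=["a", "b"])
        with pytest.raises(ExpressionError, match="ghost"):
            pl.pairwise_correlation(m, ["a", "ghost"])


class TestHierCluster:
    def test_line_points_split_by_complete_linkage(self):
        """Points 0,1,10,11 on a line split {0,1} vs {10,11} at k=2;
        the full linkage sequence is hand-checkable (merge heights
        1, 1, 11)."""
        m = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]},
                         index=["p0", "p1", "p10", "p11"])
        Z = hierarchy.linkage(m.to_numpy(), method="complete")
        res = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        assert res[0] == res[1] and res[2] == res[3] and res[0] != res[2]
        assert sorted(Z[:, 2].round(6).tolist()) == [1.0, 1.0, 11.0]

    def test_identical_rows_cluster_together(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=6)
        m = pd.DataFrame([a, a + 1e-9, a + 50], index=["r1", "r2", "far"])
        res = pl.hier_cluster(m, input_type="correlation" if False else "expression",
                              k=2)
        assert res.flat["r1"] == res.flat["r2"] != res.flat["far"]

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(12, 6)),
                         index=[f"g{i}" for i in range(12)])
        res1 = pl.hier_cluster(m, k=3)
        perm = m.sample(frac=1, random_state=5)
        res2 = pl.hier_cluster(perm, k=3)
        l1 = [res1.flat[g] for g in m.index]
        l2 = [res2.flat[g] for g in m.index]
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_correlation_input_distance(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, -0.8], [0.9, 1.0, -0.7], [-0.8, -0.7, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        res = pl.hier_cluster(corr, input_type="correlation", k=2)
        assert res.flat["a"] == res.flat["b"] != res.flat["c"]

    def test_block_partition_recovered_exactly(self):
        """Two anti-correlated blocks (within r=+0.8, between r=-0.8,
        200 samples) are recovered with adjusted Rand index 1.0."""
        expr, truth = pl.generate_expression(
            pl.ExprSimParams(n_samples=200, block_sizes=(30, 30),
                             n_null_genes=0, seed=17)
        )
        members = truth.block_members
        genes = members["A"] + members["B"]
        res = pl.hier_cluster(expr.loc[genes], k=2)
        want = [0] * len(members["A"]) + [1] * len(members["B"])
        got = [res.flat[g] for g in genes]
        assert adjusted_rand_score(want, got) == 1.0


class TestDifferentialExpression:
    def test_log2fc_is_group_mean_difference(self):
        m = pd.DataFrame(
            [[1.0, 1.2, 0.8, 4.0, 4.2, 3.8]],
            index=["g"], columns=list("abcdef"),
        )
        de = pl.differential_expression(m, ["a", "b", "c"], ["d", "e", "f"])
        assert de.loc["g", "log2fc"] == pytest.approx(3.0)

    def test_null_gene_not_flagged(self):
        m = pd.DataFrame(
            [[5.0, 5.1, 4.9, 5.05, 4.95, 5.0]],
            index=["g"], columns=list("abcdef"),
        )
        de = pl.differential_expression(m, list("abc"), list("def"))
        assert not de.loc["g", "significant"]

    def test_small_group_rejected(self):
        m = pd.DataFrame(np.ones((2, 3)), columns=list("abc"))
        with pytest.raises(ExpressionError, match="group"):
            pl.differential_expression(m, ["a"], ["b", "c"])

    def test_bh_monotone(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=list("abcdef"),
                         index=[f"g{i}" for i in range(200)])
        de = pl.differential_expression(m, list("abc"), list("def"))
        srt = de.sort_values("pvalue")
        assert srt["padj"].is_monotonic_increasing
        assert (de["padj"] >= de["pvalue"] - 1e-15).all()

    def test_planted_effects_recovered(self):
        """Delta=2, sigma=0.25, 3v3: >=18/20 planted genes flagged and at
        most one of 500 null genes flagged under the 0.05 / 1.5 rules."""
        expr, truth = pl.generate_expression(
            pl.ExprSimParams(
                n_samples=6, block_sizes=(0, 0), n_null_genes=500,
                n_de_genes=20, delta=2.0, sigma=0.25, group_sizes=(3, 3),
                seed=23,
            )
        )
        g = truth.group_samples
        de = pl.differential_expression(expr, g["group1"], g["group2"])
        planted = set(truth.de_genes)
        flagged = set(de.index[de["significant"]])
        assert len(flagged & planted) >= 18
        assert len(flagged - planted) <= 1


class TestModeratedTOracle:
    def test_matches_limma_reference(self, tmp_path):
        """The moderated t (empirical-Bayes variance shrinkage) agrees
        with the Bioconductor limma implementation on a small matrix."""
        import shutil
        import subprocess

        rng = np.random.default_rng(44)
        X = rng.normal(8, 1, size=(60, 6)) * np.sqrt(
            rng.chisquare(6, size=(60, 1)) / 6
        )
        X[:5, 3:] += 2.0
        genes = [f"g{i}" for i in range(60)]
        m = pd.DataFrame(X, index=genes, columns=list("abcdef"))
        de = pl.differential_expression(m, list("abc"), list("def"))
        csv = tmp_path / "m.csv"
        m.to_csv(csv)
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.csv("{csv}", row.names=1))\n'
            'design <- cbind(1, c(0,0,0,1,1,1))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2]),'
            f' "{tmp_path}/out.csv")\n'
        )
        subprocess.run(
            [shutil.which("Rscript") or "Rscript", str(script)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(de["t"].to_numpy(), ref["t"].to_numpy(),
                                   rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(de["pvalue"].to_numpy(), ref["p"].to_numpy(),
                                   rtol=1e-4, atol=1e-8)


class TestGeneSetPerturbation:
    def _de_from_stats(self, values):
        return pd.DataFrame({"log2fc": values},
                            index=[f"g{i}" for i in range(len(values))])

    def test_null_set_centers_at_half(self):
        """A set whose statistics all equal the background mean gives
        t ~ 0 and p ~ 0.5 under the one-sided test."""
        rng = np.random.default_rng(31)
        vals = rng.normal(0, 1, size=500)
        vals[:20] = vals[20:].mean()
        de = self._de_from_stats(vals)
        gs = pl.GeneSet("s", tuple(f"g{i}" for i in range(20)))
        r = pl.geneset_perturbation_test(de, gs, mode="directed")
        assert abs(r.t) < 0.5
        assert r.pvalue == pytest.approx(0.5, abs=0.2)

    def test_extreme_set_significant(self):
        vals = np.zeros(100)
        vals[:10] = 5.0
        de = self._de_from_stats(vals)
        gs = pl.GeneSet("top", tuple(f"g{i}" for i in range(10)))
        r = pl.geneset_perturbation_test(de, gs, mode="directed")
        assert r.pvalue < 0.05

    def test_directed_antisymmetric_under_sign_flip(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0.3, 1, size=300)
        de = self._de_from_stats(vals)
        flipped = self._de_from_stats(-vals)
        gs = pl.GeneSet("s", tuple(f"g{i}" for i in range(40)))
        p1 = pl.geneset_perturbation_test(de, gs).pvalue
        p2 = pl.geneset_perturbation_test(flipped, gs).pvalue
        assert p1 + p2 == pytest.approx(1.0, abs=1e-6)

    def test_undirected_uses_absolute_statistics(self):
        vals = np.concatenate([np.full(20, -4.0), np.zeros(480)])
        de = self._de_from_stats(vals)
        gs = pl.GeneSet("down", tuple(f"g{i}" for i in range(20)))
        directed = pl.geneset_perturbation_test(de, gs, mode="directed")
        undirected = pl.geneset_perturbation_test(de, gs, mode="undirected")
        assert directed.pvalue > 0.5  # downregulated: not 'greater'
        assert undirected.pvalue < 0.01

    def test_size_bounds_enforced(self):
        de = self._de_from_stats(np.zeros(600))
        small = pl.GeneSet("small", tuple(f"g{i}" for i in range(5)))
        big = pl.GeneSet("big", tuple(f"g{i}" for i in range(500)))
        for gs in (small, big):
            with pytest.raises(ExpressionError, match="size"):
                pl.geneset_perturbation_test(de, gs)

    def test_shifted_set_detected_with_high_power(self):
        """A +1.0-shifted 40-gene set on a 2000-gene background is detected
        at p<0.01 in >=95 of 100 replicate simulations."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            vals = rng.normal(0, 0.5, size=2040)
            vals[:40] += 1.0
            de = self._de_from_stats(vals)
            gs = pl.GeneSet("s", tuple(f"g{i}" for i in range(40)))
            if pl.geneset_perturbation_test(de, gs).pvalue < 0.01:
                hits += 1
        assert hits >= 95
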