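"""Consensus signature derivation, weighted z-score, Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet

import nersig as ns
from nersig.containers import NersigError
from nersig.diffexpr import signed_linear_fc


def _de(genes, log2fc, q, comparison="lineA"):
    log2fc = np.asarray(log2fc, dtype=float)
    return pd.DataFrame(
        {
            "comparison": comparison,
            "log2fc": log2fc,
            "fold_change": signed_linear_fc(log2fc),
            "q_value": np.asarray(q, dtype=float),
        },
        index=pd.Index(genes, name="gene"),
    )


class TestConsensusSelection:
    def test_gene_failing_one_line_excluded(self):
        genes = ["a", "b"]
        results = {
            f"L{i}": _de(genes, [1.0, 1.0], [0.01, 0.01], f"L{i}") for i in range(4)
        }
        results["L4"] = _de(genes, [1.0, 0.1], [0.01, 0.5], "L4")  # b fails in L4
        assert ns.select_consensus_genes(results) == {"a"}

    def test_gene_passing_everywhere_included(self):
        genes = ["up18"]
        results = {f"L{i}": _de(genes, [np.log2(1.8)], [0.005], f"L{i}") for i in range(5)}
        assert ns.select_consensus_genes(results) == {"up18"}

    def test_discordant_sign_excluded(self):
        results = {
            "L0": _de(["a"], [1.0], [0.001], "L0"),
            "L1": _de(["a"], [-1.0], [0.001], "L1"),
        }
        assert ns.select_consensus_genes(results) == set()
        assert ns.select_consensus_genes(results, require_consistent_sign=False) == {"a"}

    def test_toy_panel_matches_enumeration_oracle(self):
        genes = [f"g{i}" for i in range(6)]
        fc = {
            "L0": [2.0, 1.4, -1.8, 1.7, 1.6, 1.2],
            "L1": [1.9, 1.6, -2.1, 1.8, 1.5, 1.1],
            "L2": [2.2, 1.7, -1.6, 1.9, 1.7, 1.3],
        }
        q = {
            "L0": [0.01, 0.02, 0.001, 0.2, 0.01, 0.001],
            "L1": [0.02, 0.03, 0.002, 0.01, 0.02, 0.002],
            "L2": [0.01, 0.01, 0.04, 0.02, 0.03, 0.003],
        }
        results = {
            line: _de(genes, np.log2(np.abs(fc[line])) * np.sign(fc[line]), q[line], line)
            for line in fc
        }
        # brute-force enumeration over genes and lines
        expected = {
            g
            for i, g in enumerate(genes)
            if all(abs(fc[line][i]) > 1.5 and q[line][i] < 0.05 for line in fc)
            and len({np.sign(fc[line][i]) for line in fc}) == 1
        }
        assert ns.select_consensus_genes(results) == expected
        assert expected == {"g0", "g2"}  # sanity on the hand-constructed table

    def test_fewer_than_two_comparisons_rejected(self):
        with pytest.raises(NersigError, match="at least 2"):
            ns.select_consensus_genes({"L0": _de(["a"], [1.0], [0.01])})

    def test_empty_consensus_warns_not_raises(self):
        results = {
            "L0": _de(["a"], [0.1], [0.9], "L0"),
            "L1": _de(["a"], [0.1], [0.9], "L1"),
        }
        with pytest.warns(UserWarning, match="empty"):
            assert ns.select_consensus_genes(results) == set()


class TestBuildSignature:
    def test_coefficient_is_mean_log2fc(self):
        results = {
            "L0": _de(["a"], [1.0], [0.01], "L0"),
            "L1": _de(["a"], [2.0], [0.01], "L1"),
            "L2": _de(["a"], [3.0], [0.01], "L2"),
        }
        sig = ns.build_signature(results, {"a"})
        assert sig.coefficients["a"] == pytest.approx(2.0)
        assert sig.provenance["comparisons"] == ["L0", "L1", "L2"]

    def test_constant_fc_gives_that_coefficient(self):
        results = {f"L{i}": _de(["a"], [1.0], [0.01], f"L{i}") for i in range(5)}
        assert ns.build_signature(results, {"a"}).coefficients["a"] == 1.0

    def test_linear_scale_option(self):
        results = {
            "L0": _de(["a"], [1.0], [0.01], "L0"),
            "L1": _de(["a"], [2.0], [0.01], "L1"),
        }
        sig = ns.build_signature(results, {"a"}, scale="linear")
        assert sig.coefficients["a"] == pytest.approx((2.0 + 4.0) / 2)

    def test_missing_gene_names_gene_and_comparison(self):
        results = {
            "L0": _de(["a"], [1.0], [0.01], "L0"),
            "L1": _de(["b"], [1.0], [0.01], "L1"),
        }
        with pytest.raises(NersigError, match="'a'.*'L1'"):
            ns.build_signature(results, {"a"})

    def test_recovers_planted_coefficients(self, panel_signature):
        results, sig, truth = panel_signature
        planted = truth.planted_log2fc.loc[sig.genes].mean(axis=1)
        r = np.corrcoef(sig.coefficients, planted)[0, 1]
        assert r > 0.95


class TestScoreSamples:
    def _mat(self, values, genes, samples):
        return ns.ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=samples), log_scale=True
        )

    def test_identical_samples_error_zero_variance(self):
        mat = self._mat(np.ones((2, 3)), ["a", "b"], ["s1", "s2", "s3"])
        sig = ns.GeneSignature(pd.Series({"a": 1.0, "b": 2.0}))
        with pytest.raises(NersigError, match="dropped|retained"):
            ns.score_samples(mat, sig)  # all genes zero-variance -> all dropped

    def test_single_gene_normalization_cancels(self):
        # one gene, coefficient +2: score must equal the gene's z exactly
        vals = np.array([[1.0, 2.0, 3.0, 4.0]])
        mat = self._mat(vals, ["a"], list("wxyz"))
        sig = ns.GeneSignature(pd.Series({"a": 2.0}))
        sv = ns.score_samples(mat, sig)
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        np.testing.assert_allclose(sv.scores.to_numpy(), z, atol=1e-12)

    def test_hand_computed_worked_example(self):
        # 3 genes x 4 samples with c = (2, -1, 0.5); expected values frozen
        # from an independent spreadsheet-style computation.
        mat = self._mat(
            np.array([[1, 2, 3, 4], [0, 0, 1, 1], [5, 5, 5, 7]], dtype=float),
            ["g1", "g2", "g3"],
            ["s1", "s2", "s3", "s4"],
        )
        sig = ns.GeneSignature(pd.Series({"g1": 2.0, "g2": -1.0, "g3": 0.5}))
        sv = ns.score_samples(mat, sig)
        expected = [
            -0.4879327439828604,
            -0.04530607584486991,
            -0.09755106701227294,
            0.6307898868400033,
        ]
        np.testing.assert_allclose(sv.scores.to_numpy(), expected, atol=1e-12)
        assert sv.n_genes_used == 3 and sv.dropped_genes == []

    def test_missing_genes_dropped_and_renormalized(self):
        mat = self._mat(np.array([[1.0, 2.0, 3.0]]), ["a"], ["s1", "s2", "s3"])
        sig = ns.GeneSignature(pd.Series({"a": 1.0, "b": 1.0}), provenance={})
        sv = ns.score_samples(mat, sig, max_dropped_frac=0.6)
        assert sv.dropped_genes == ["b"]
        z = (np.array([1.0, 2.0, 3.0]) - 2.0) / 1.0
        np.testing.assert_allclose(sv.scores.to_numpy(), z, atol=1e-12)

    def test_excess_dropped_fraction_errors(self):
        mat = self._mat(np.array([[1.0, 2.0, 3.0]]), ["a"], ["s1", "s2", "s3"])
        sig = ns.GeneSignature(pd.Series({"a": 1.0, "b": 1.0}))
        with pytest.raises(NersigError, match="max_dropped_frac"):
            ns.score_samples(mat, sig)

    def test_frozen_reference_mode(self):
        vals = np.array([[1.0, 3.0]])
        mat = self._mat(vals, ["a"], ["s1", "s2"])
        sig = ns.GeneSignature(pd.Series({"a": 1.0}))
        ref = (pd.Series({"a": 0.0}), pd.Series({"a": 2.0}))
        sv = ns.score_samples(mat, sig, reference=ref)
        np.testing.assert_allclose(sv.scores.to_numpy(), [0.5, 1.5])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_affine_invariance_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(5, 6))
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{j}" for j in range(6)]
        coef = pd.Series(rng.normal(size=5) + 0.1, index=genes)
        sig = ns.GeneSignature(coef)
        base = ns.score_samples(self._mat(vals, genes, samples), sig)
        # positive affine map on one gene row leaves scores unchanged
        scaled = vals.copy()
        scaled[2] = 3.5 * scaled[2] - 7.0
        after = ns.score_samples(self._mat(scaled, genes, samples), sig)
        np.testing.assert_allclose(after.scores, base.scores, atol=1e-10)
        # negating all coefficients negates all scores
        neg = ns.score_samples(self._mat(vals, genes, samples), ns.GeneSignature(-coef))
        np.testing.assert_allclose(neg.scores, -base.scores, atol=1e-10)
        # cohort mean of scores is 0; |score| bounded by max |z|
        assert base.scores.mean() == pytest.approx(0.0, abs=1e-10)
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        assert np.all(np.abs(base.scores.to_numpy()) <= np.abs(z).max() + 1e-10)


class TestWardCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=4)
        vals = np.column_stack([col, col, col + 5.0])
        mat = ns.ExpressionMatrix(
            pd.DataFrame(vals, index=list("abcd"), columns=["s1", "s2", "s3"]),
            log_scale=True,
        )
        res = ns.ward_cluster(mat, list("abcd"))
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_top_split_separates_control_from_knockdowns(self, small_panel, panel_signature):
        mat, design, _ = small_panel
        _, sig, _ = panel_signature
        res = ns.ward_cluster(mat, sig.genes)
        # cut into two clusters at the top: controls must be alone on one side
        from scipy.cluster.hierarchy import fcluster

        assign = fcluster(res.linkage, 2, criterion="maxclust")
        ctrl_clusters = {assign[i] for i, s in enumerate(res.sample_ids)
                         if design.groups[s] == design.control}
        kd_clusters = {assign[i] for i, s in enumerate(res.sample_ids)
                       if design.groups[s] != design.control}
        assert len(ctrl_clusters) == 1 and ctrl_clusters.isdisjoint(kd_clusters)

    def test_sample_order_invariance(self, toy_matrix):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 8))
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{j}" for j in range(8)]
        mat = ns.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), log_scale=True)
        perm = rng.permutation(8)
        mat_p = ns.ExpressionMatrix(mat.data.iloc[:, perm], log_scale=True)
        r1 = ns.ward_cluster(mat, genes)
        r2 = ns.ward_cluster(mat_p, genes)
        # identical topology <=> identical cophenetic distances between samples
        d1 = pd.DataFrame(
            _square(cophenet(r1.linkage)), index=r1.sample_ids, columns=r1.sample_ids
        )
        d2 = pd.DataFrame(
            _square(cophenet(r2.linkage)), index=r2.sample_ids, columns=r2.sample_ids
        )
        np.testing.assert_allclose(
            d1.loc[samples, samples], d2.loc[samples, samples], atol=1e-8
        )

    def test_empty_gene_set_rejected(self, toy_matrix):
        with pytest.raises(NersigError, match="empty"):
            ns.ward_cluster(toy_matrix, [])


def _square(condensed):
    from scipy.spatial.distance import squareform

    return squareform(condensed)
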