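"""Expression statistics against enumeration, scipy, and scanpy oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse, stats as sps

from synotreg.datatypes import DataError, ExpressionMatrix
from synotreg.expression import (
    asymptotic_rank_p,
    cluster_compartment_test,
    exact_rank_p,
    module_score,
    normalize,
    report_filter,
    spearman_pairs,
    wilcoxon_de,
)


def _matrix(counts, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = [f"c{i}" for i in range(counts.shape[1])]
    return ExpressionMatrix(sparse.csr_matrix(counts), genes, barcodes)


class TestNormalize:
    def test_hand_computed_values(self):
        m = _matrix(np.array([[1], [1], [2]]))
        norm = normalize(m, scale_total=10_000)
        dense = np.asarray(norm.values.todense()).ravel()
        assert dense == pytest.approx(
            [math.log(2501), math.log(2501), math.log(5001)]
        )

    def test_scale_invariance_and_zero_preservation(self):
        counts = np.array([[1, 2], [0, 0], [3, 4]])
        doubled = counts * 2
        a = np.asarray(normalize(_matrix(counts)).values.todense())
        b = np.asarray(normalize(_matrix(doubled)).values.todense())
        assert np.allclose(a, b)
        assert (a[1] == 0).all()

    def test_zero_total_cell_raises(self):
        with pytest.raises(DataError, match="QC"):
            normalize(_matrix(np.array([[1, 0], [2, 0]])))

    def test_matches_scanpy_normalize_total_log1p(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata as ad

        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(50, 30))
        counts[:, 0] += 1  # avoid empty cells
        ours = np.asarray(normalize(_matrix(counts)).values.todense())
        adata = ad.AnnData(sparse.csr_matrix(counts.T.astype(np.float32)))
        scanpy.pp.normalize_total(adata, target_sum=10_000)
        scanpy.pp.log1p(adata)
        theirs = np.asarray(adata.X.todense()).T
        assert np.allclose(ours, theirs, atol=1e-5)


def exact_oracle(a, b):
    """Independent pure-python enumeration of the rank-sum permutation p."""
    pooled = list(a) + list(b)
    ranks = sps.rankdata(pooled)
    na, n = len(a), len(pooled)
    mu = na * (n + 1) / 2
    obs = abs(sum(ranks[:na]) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxon:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(3, 8), st.integers(3, 8), st.randoms(use_true_random=False))
    def test_exact_mode_equals_enumeration(self, na, nb, rnd):
        vals = [rnd.choice([0.0, 0.5, 1.0, 1.7, 2.2]) for _ in range(na + nb)]
        a, b = np.array(vals[:na]), np.array(vals[na:])
        assert exact_rank_p(a, b) == pytest.approx(exact_oracle(a, b), abs=1e-12)

    def test_asymptotic_close_to_scipy_at_n50(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0.3, 1, 50)
            ours = asymptotic_rank_p(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=0.01)

    def test_identical_groups_give_null_results(self):
        counts = np.vstack([np.arange(1, 9)] * 5)
        norm = normalize(_matrix(counts))
        out = wilcoxon_de(norm, [0, 1, 2, 3], [4, 5, 6, 7])
        assert np.allclose(out["log_fc"], 0.0, atol=1e-12)
        assert np.allclose(out["p"], 1.0)

    def test_detection_floor_excludes_rare_genes(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, size=(4, 60))
        counts[0] = 0
        counts[0, 1] = 5  # detected in ~2% of one group only
        counts[3] += 1
        norm = normalize(_matrix(counts))
        out = wilcoxon_de(norm, np.arange(30), np.arange(30, 60), min_pct=0.10)
        assert "G0" not in set(out["gene"])

    def test_label_swap_negates_logfc_and_preserves_p(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(4.0, size=(6, 40)) + 1
        norm = normalize(_matrix(counts))
        ga, gb = np.arange(20), np.arange(20, 40)
        ab = wilcoxon_de(norm, ga, gb)
        ba = wilcoxon_de(norm, gb, ga)
        assert np.allclose(ab["log_fc"], -ba["log_fc"], atol=1e-12)
        assert np.allclose(ab["p"], ba["p"], atol=1e-12)

    def test_overlapping_groups_rejected(self):
        norm = normalize(_matrix(np.ones((3, 10))))
        with pytest.raises(DataError, match="overlap"):
            wilcoxon_de(norm, [0, 1, 2], [2, 3, 4])

    def test_bonferroni_uses_total_gene_count(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5.0, size=(20, 30)) + 1
        norm = normalize(_matrix(counts))
        out = wilcoxon_de(norm, np.arange(15), np.arange(15, 30))
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p"] * 20))


class TestReportFilter:
    def _results(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "TRBV9", "C"],
                "log_fc": [0.25, 0.6, 0.9, -0.5],
                "pct_a": 0.5, "pct_b": 0.5,
                "p": [0.1, 1e-5, 1e-6, 0.2],
                "p_adj": [1.0, 1e-3, 1e-4, 1.0],
            }
        )

    def test_logfc_cut_is_strict(self):
        out = report_filter(self._results())
        assert "A" not in set(out["gene"])  # |0.25| is not > 0.25
        assert {"B", "TRBV9", "C"} <= set(out["gene"])

    def test_tcr_variable_genes_removable(self):
        out = report_filter(self._results(), drop_tcr_genes=True)
        assert "TRBV9" not in set(out["gene"])

    def test_empty_input_gives_empty_output(self):
        out = report_filter(self._results().iloc[:0])
        assert out.empty


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        m = _matrix(np.full((40, 10), 3))
        norm = normalize(m)
        ms = module_score(norm, ["G0", "G1", "G2"], seed=0)
        assert np.allclose(ms.scores, 0.0, atol=1e-12)

    def test_same_seed_reproducible_different_seed_not_required(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.poisson(3.0, size=(60, 25)) + 1)
        norm = normalize(m)
        a = module_score(norm, ["G0", "G5", "G9"], seed=3)
        b = module_score(norm, ["G0", "G5", "G9"], seed=3)
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_missing_genes_warn_and_empty_module_errors(self):
        m = _matrix(np.ones((5, 6)))
        norm = normalize(m)
        with pytest.warns(UserWarning, match="absent"):
            module_score(norm, ["G0", "NOPE"], seed=0)
        with pytest.raises(DataError, match="empty"):
            module_score(norm, ["NOPE"], seed=0)

    def test_elevated_cluster_ranks_first(self, small_dataset):
        norm = normalize(small_dataset.expression)
        ms = module_score(norm, small_dataset.truth.module_genes, seed=0)
        means = ms.scores.groupby(small_dataset.meta["cluster"]).mean()
        assert means.idxmax() == small_dataset.truth.module_cluster


class TestClusterCompartmentTest:
    def _meta(self, clusters, compartments):
        barcodes = [f"c{i}" for i in range(len(clusters))]
        return pd.DataFrame(
            {"barcode": barcodes, "compartment": compartments,
             "cluster": clusters},
            index=pd.Index(barcodes, name="barcode"),
        )

    def test_equal_proportions_give_z_zero(self):
        meta = self._meta(["A"] * 4 + ["B"] * 4, ["PB", "SF"] * 4)
        out = cluster_compartment_test(meta).set_index("cluster")
        assert out.loc["A", "z"] == pytest.approx(0.0)
        assert out.loc["A", "p"] == pytest.approx(1.0)

    def test_z_squared_equals_chi2_without_correction(self):
        clusters = ["A"] * 30 + ["B"] * 50
        comps = (["PB"] * 20 + ["SF"] * 10) + (["PB"] * 15 + ["SF"] * 35)
        out = cluster_compartment_test(self._meta(clusters, comps))
        row = out.set_index("cluster").loc["A"]
        table = np.array([[20, 15], [10, 35]])
        chi2 = sps.chi2_contingency(table, correction=False)[0]
        assert row["z"] ** 2 == pytest.approx(chi2, rel=1e-9)

    def test_p_matches_normal_tail_oracle(self):
        clusters = ["A"] * 25 + ["B"] * 55
        comps = (["PB"] * 18 + ["SF"] * 7) + (["PB"] * 22 + ["SF"] * 33)
        out = cluster_compartment_test(self._meta(clusters, comps))
        row = out.set_index("cluster").loc["A"]
        x1, n1, x2, n2 = 18, 40, 7, 40
        p_hat = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / math.sqrt(
            p_hat * (1 - p_hat) * (1 / n1 + 1 / n2)
        )
        assert row["p"] == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-9)


class TestSpearman:
    def test_self_and_monotone_pairs(self):
        counts = np.array([[1, 2, 3, 4, 5],
                           [2, 4, 6, 8, 10],
                           [5, 4, 3, 2, 1]])
        norm = normalize(_matrix(counts))
        rho = spearman_pairs(norm, ["G0", "G1", "G2"])
        assert rho.loc["G0", "G0"] == 1.0
        assert rho.loc["G0", "G1"] == pytest.approx(1.0)
        assert rho.loc["G0", "G2"] == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(2.0, size=(4, 30)) + 1
        norm = normalize(_matrix(counts))
        rho = spearman_pairs(norm, ["G0", "G1"])
        dense = np.asarray(norm.values.todense())
        ref = sps.spearmanr(dense[0], dense[1]).statistic
        assert rho.loc["G0", "G1"] == pytest.approx(float(ref), abs=1e-12)

    def test_zero_variance_gene_reported_missing(self):
        from synotreg.expression import NormalizedMatrix

        vals = sparse.csr_matrix(np.array([[1.0, 1.0, 1.0, 1.0],
                                           [0.1, 0.2, 0.3, 0.4]]))
        nm = NormalizedMatrix(vals, np.array(["GC", "GV"], dtype=object),
                              np.array([f"c{i}" for i in range(4)], dtype=object),
                              10_000)
        rho = spearman_pairs(nm, ["GC", "GV"])
        assert math.isnan(rho.loc["GC", "GV"])
        assert math.isnan(rho.loc["GC", "GC"])
        assert rho.loc["GV", "GV"] == 1.0
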