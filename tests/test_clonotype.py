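"""Clonotype calling and enrichment statistics against independent oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from synotreg import clonotype as ct
from synotreg.clonotype import (
    bh_adjust,
    call_clonotypes,
    clone_cluster_distribution,
    clone_key,
    clone_table,
    collapse_chains,
    classify_lineage,
    fisher_two_sided,
)
from synotreg.datatypes import CellChains, ContigRecord, DataError


def fisher_oracle(table):
    """Exact-rational enumeration of the point-probability two-sided rule."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    total = comb(n, c1)
    # integer-exact version of pmf(x) <= pmf(a) * (1 + 1e-7)
    acc = sum(v for v in nums.values() if v * 10**7 <= obs * (10**7 + 1))
    return float(min(Fraction(acc, total), 1))


def _contig(bc, chain, nt, productive=True):
    return ContigRecord(bc, chain, nt, "X", "V", "J", productive, 2)


class TestCollapseAndCall:
    def test_duplicate_and_nonproductive_contigs_collapse(self):
        contigs = [
            _contig("c1", "TRB", "TGTGCC"),
            _contig("c1", "TRB", "TGTGCC"),
            _contig("c1", "TRA", "TGTAAA"),
            _contig("c1", "TRA", "TGTCCC", productive=False),
        ]
        cells = collapse_chains(contigs)
        assert cells["c1"].betas == ("TGTGCC",)
        assert cells["c1"].alphas == ("TGTAAA",)

    def test_identical_chain_pairs_share_a_clone(self):
        cells = {
            "c1": CellChains("c1", ("TGTAAA",), ("TGTGCC",)),
            "c2": CellChains("c2", ("TGTAAA",), ("TGTGCC",)),
            "c3": CellChains("c3", ("TGTAAA",), ("TGTGGG",)),
        }
        out = call_clonotypes(cells, mode="joint_gex")
        ids = out.set_index("barcode")["clone_id"]
        assert ids["c1"] == ids["c2"] != ids["c3"]

    def test_joint_mode_excludes_multiplets_but_keeps_dual_alpha(self):
        cells = {
            "two_beta": CellChains("two_beta", ("TGTAAA",), ("TGTGCC", "TGTGGG")),
            "dual_alpha": CellChains("dual_alpha", ("TGTAAA", "TGTCCC"), ("TGTGCC",)),
            "no_beta": CellChains("no_beta", ("TGTAAA",), ()),
        }
        out = call_clonotypes(cells, mode="joint_gex")
        assert list(out["barcode"]) == ["dual_alpha"]
        assert out["clone_id"].iloc[0] == clone_key(("TGTAAA", "TGTCCC"), ("TGTGCC",))

    def test_clonality_table_mode_keeps_multibeta_as_own_clone(self):
        cells = {
            "m1": CellChains("m1", ("TGTAAA",), ("TGTGCC", "TGTGGG")),
            "m2": CellChains("m2", ("TGTAAA",), ("TGTGCC", "TGTGGG")),
            "s1": CellChains("s1", ("TGTAAA",), ("TGTGCC",)),
        }
        out = call_clonotypes(cells, mode="clonality_table")
        ids = out.set_index("barcode")["clone_id"]
        assert ids["m1"] == ids["m2"] != ids["s1"]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_contig_order_never_changes_clone_assignments(self, rnd):
        contigs = []
        for i in range(20):
            contigs.append(_contig(f"c{i % 7}", "TRA", "TGT" + "AAA" * (1 + i % 3)))
            contigs.append(_contig(f"c{i % 7}", "TRB", "TGT" + "CCC" * (1 + i % 2)))
        shuffled = contigs[:]
        rnd.shuffle(shuffled)
        a = call_clonotypes(collapse_chains(contigs))
        b = call_clonotypes(collapse_chains(shuffled))
        pd.testing.assert_frame_equal(a, b)


class TestFisher:
    def test_balanced_three_by_three_table(self):
        # margins (3,3)/(3,3): masses {1,9,9,1}/20 -> two-sided p = 2/20
        assert fisher_two_sided([[3, 0], [0, 3]]) == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_margins_give_one(self):
        assert fisher_two_sided([[0, 0], [0, 0]]) == 1.0
        assert fisher_two_sided([[5, 0], [3, 0]]) == 1.0

    def test_example_from_enumeration(self):
        # [[3,3],[0,3]]: 3 SF-only clone cells among 6 SF and 3 PB cells
        assert fisher_two_sided([[3, 3], [0, 3]]) == pytest.approx(
            fisher_oracle([[3, 3], [0, 3]]), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    def test_matches_exact_rational_oracle(self, a, b, c, d):
        ours = fisher_two_sided([[a, b], [c, d]])
        assert ours == pytest.approx(fisher_oracle([[a, b], [c, d]]), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_agrees_with_scipy_two_sided(self, a, b, c, d):
        ours = fisher_two_sided([[a, b], [c, d]])
        scipy_p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(float(scipy_p), abs=1e-9)


class TestBH:
    def test_hand_computed_step_up(self):
        # m=4: min over j>=i of p_(j)*4/j -> all 0.04
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=120))
    def test_matches_statsmodels_and_dominates_raw(self, pvals):
        ours = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_readjusting_never_decreases(self, pvals):
        once = bh_adjust(pvals)
        twice = bh_adjust(once)
        assert np.all(twice >= once - 1e-15)


def _meta(n_pb, n_sf, clusters=None):
    barcodes = [f"p{i}" for i in range(n_pb)] + [f"s{i}" for i in range(n_sf)]
    meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": "AS01",
            "compartment": ["PB"] * n_pb + ["SF"] * n_sf,
            "patient": "AS01",
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    if clusters is not None:
        meta["cluster"] = clusters
    return meta


class TestEnrichment:
    def _clones(self, members):
        """members: dict clone_id -> list of barcodes."""
        rows = [
            {"barcode": bc, "clone_id": cid}
            for cid, bcs in members.items()
            for bc in bcs
        ]
        return pd.DataFrame(rows)

    def test_small_clone_not_tested(self):
        meta = _meta(100, 100)
        assignments = self._clones(
            {"small": ["p0", "p1", "s0", "s1"],
             "big": [f"s{i}" for i in range(2, 8)]}
        )
        # remaining cells are singletons so totals are realistic
        table = clone_table(assignments, meta)
        enr = ct.test_enrichment(table, meta)
        assert "small" not in set(enr["clone_id"])  # max(2,2) < 3
        assert "big" in set(enr["clone_id"])

    def test_balanced_clone_has_p_one(self):
        meta = _meta(100, 100)
        assignments = self._clones(
            {"bal": [f"p{i}" for i in range(3)] + [f"s{i}" for i in range(3)]}
        )
        extra = self._clones(
            {f"bg{i}": [f"p{i+3}"] for i in range(97)}
            | {f"bgs{i}": [f"s{i+3}"] for i in range(97)}
        )
        table = clone_table(pd.concat([assignments, extra]), meta)
        enr = ct.test_enrichment(table, meta).set_index("clone_id")
        assert enr.loc["bal", "p"] == pytest.approx(1.0, abs=1e-9)

    def test_contingency_table_and_p_match_oracle(self):
        # 3 SF-only clone cells among 6 SF and 3 PB clonotyped cells
        meta = _meta(3, 6)
        assignments = self._clones(
            {"clone": ["s0", "s1", "s2"],
             "x0": ["s3"], "x1": ["s4"], "x2": ["s5"],
             "y0": ["p0"], "y1": ["p1"], "y2": ["p2"]}
        )
        table = clone_table(assignments, meta)
        enr = ct.test_enrichment(table, meta).set_index("clone_id")
        assert enr.loc["clone", "p"] == pytest.approx(
            fisher_oracle([[3, 3], [0, 3]]), abs=1e-12
        )
        assert enr.loc["clone", "enriched_in"] == "SF"
        assert enr.loc["clone", "total_sf"] == 6
        assert enr.loc["clone", "total_pb"] == 3

    def test_member_without_compartment_label_is_an_error(self):
        meta = _meta(3, 3)
        assignments = self._clones({"c": ["p0", "p1", "ghost"]})
        with pytest.raises(DataError, match="ghost"):
            clone_table(assignments, meta)

    def test_significance_threshold_is_adjusted_p(self, small_dataset):
        from synotreg.clonotype import collapse_chains

        chains = collapse_chains(small_dataset.contigs)
        table = clone_table(call_clonotypes(chains), small_dataset.meta)
        enr = ct.test_enrichment(table, small_dataset.meta)
        assert (enr["significant"] == (enr["p_adj"] <= 0.05)).all()
        assert (enr["p_adj"] >= enr["p"] - 1e-15).all()


class TestCloneClusterDistribution:
    def test_fractions_and_unlabelled(self):
        meta = _meta(0, 12, clusters=["A"] * 6 + ["B"] * 6)
        members = [f"s{i}" for i in range(10)]
        dist = clone_cluster_distribution(members, meta).set_index("cluster")
        assert dist.loc["A", "n"] == 6 and dist.loc["B", "n"] == 4
        assert dist.loc["A", "fraction"] == pytest.approx(0.6)
        # hypergeometric scores present and in [0, 1]
        assert 0 <= dist.loc["A", "p_over"] <= 1

    def test_single_cluster_has_mass_one(self):
        meta = _meta(0, 5, clusters=["A"] * 5)
        dist = clone_cluster_distribution([f"s{i}" for i in range(3)], meta)
        assert dist["fraction"].tolist() == [1.0]


class TestLineage:
    def _norm(self, genes, values):
        return np.asarray(values), np.array(genes, dtype=object)

    def test_majority_vote(self):
        values = np.array(
            [  # genes x cells: CD4, CD8A, CD8B
                [2.0, 2.0, 2.0, 0.0],
                [0.0, 0.0, 0.0, 3.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        lineage = classify_lineage(
            ["c0", "c1", "c2", "c3"], values, ["CD4", "CD8A", "CD8B"],
            ["c0", "c1", "c2", "c3"],
        )
        assert lineage == "CD4"

    def test_all_zero_expression_unassigned(self):
        values = np.zeros((3, 2))
        assert classify_lineage(
            ["c0", "c1"], values, ["CD4", "CD8A", "CD8B"], ["c0", "c1"]
        ) == "unassigned"
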