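"""Validation experiments: independent oracles and simulation studies.

Each function here re-derives an expected answer through a route independent
of the implementation it checks (exact rational enumeration, reference
step-up loops, scipy distributions) or measures operating characteristics
(false-discovery proportion, recovery, classification accuracy) on
truth-labelled synthetic data.  Both the test suite and the reproduction
script call into this module so the numbers they report are computed the
same way, from scratch, at run time.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb, inf
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps

from . import clonotype as ct
from .datatypes import CellChains, ExpressionMatrix
from .expression import asymptotic_rank_p, exact_rank_p, module_score, normalize
from .hto_demux import demux, nb_quantile
from .datatypes import NBParams
from .qc import apply_filters, compute_metrics
from .simulate import SimConfig, generate_dataset, generate_null_replicates


# --------------------------------------------------------------------------
# exact-test oracles


def fisher_enumeration_oracle(table) -> float:
    """Point-probability two-sided Fisher p by exact integer enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    acc = sum(v for v in nums if v * 10**7 <= obs * (10**7 + 1))
    return min(acc / comb(n, c1), 1.0)


def fisher_vs_enumeration(max_total: int = 40) -> Tuple[float, int]:
    """Max |p - oracle| over every 2x2 table with grand total <= max_total."""
    worst = 0.0
    n_tables = 0
    for n in range(max_total + 1):
        for r1 in range(n + 1):
            r2 = n - r1
            for c1 in range(n + 1):
                lo, hi = max(0, c1 - r2), min(r1, c1)
                if lo > hi:
                    continue
                for a in range(lo, hi + 1):
                    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    err = abs(ct.fisher_two_sided(table)
                              - fisher_enumeration_oracle(table))
                    worst = max(worst, err)
                    n_tables += 1
    return worst, n_tables


def bh_reference(pvals) -> np.ndarray:
    """Plain-loop reference implementation of the BH step-up adjustment."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return np.array(adjusted)


def bh_vs_reference(n_vectors: int = 1000, seed: int = 0) -> Tuple[float, int]:
    """Max |adjusted - reference| over random p-vectors of length 1-500."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        length = int(rng.integers(1, 501))
        pvals = rng.random(length)
        if rng.random() < 0.3:  # inject ties
            pvals = np.round(pvals, 2)
        worst = max(worst, float(np.max(np.abs(
            ct.bh_adjust(pvals) - bh_reference(pvals)
        ))))
    return worst, n_vectors


def wilcoxon_exact_vs_enumeration(n_datasets: int = 100,
                                  seed: int = 0) -> Tuple[float, int]:
    """Max |exact p - full labeling enumeration| for group sizes <= 8."""

    def enumeration(a, b):
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        na, n = len(a), len(pooled)
        mu = na * (n + 1) / 2
        obs = abs(ranks[:na].sum() - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), na):
            total += 1
            if abs(sum(ranks[i] for i in combo) - mu) >= obs - 1e-9:
                hits += 1
        return hits / total

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        values = rng.choice([0.0, 0.0, 0.4, 1.1, 2.0, 3.5], size=na + nb)
        a, b = values[:na], values[na:]
        worst = max(worst, abs(exact_rank_p(a, b) - enumeration(a, b)))
    return worst, n_datasets


def wilcoxon_approx_vs_exact(n_datasets: int = 100, n_per_group: int = 50,
                             seed: int = 0) -> Tuple[float, int]:
    """Max |asymptotic p - exact p| on tie-free draws at n cells per group.

    The exact reference is the rank-sum null distribution computed by
    scipy's exact method (valid without ties).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(rng.uniform(-0.5, 0.5), 1.0, n_per_group)
        approx = asymptotic_rank_p(a, b)
        ref = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue)
        worst = max(worst, abs(approx - ref))
    return worst, n_datasets


# --------------------------------------------------------------------------
# simulation studies


def _null_config(seed: int) -> SimConfig:
    # ~100 eligible clones per replicate; expression kept minimal because
    # only the repertoire enters the enrichment test
    return SimConfig(
        n_cells_pb=1360, n_cells_sf=1360, n_genes=60, n_clusters=2,
        markers_per_cluster=2, n_module_genes=3, mito_gene_count=2,
        n_expanded_clones=135, expanded_size_mean=6.0, sf_bias=0.5,
        n_hashtags=2, seed=seed,
    )


def null_fdr_study(n_reps: int = 200, seed: int = 0) -> Dict[str, float]:
    """False-discovery behaviour of the enrichment test under the null.

    With sf_bias = 0.5 every discovery is false, so the per-replicate FDP is
    1 if anything is flagged significant (0 when nothing is).  Also counts,
    exactly, whether any clone below the three-cell rule was ever tested.
    """
    fdps: List[float] = []
    eligible: List[int] = []
    ineligible_tested = 0
    for ds in generate_null_replicates(_null_config(seed), n_reps):
        chains = ct.collapse_chains(ds.contigs)
        clones = ct.clone_table(ct.call_clonotypes(chains, mode="joint_gex"),
                                ds.meta)
        enr = ct.test_enrichment(clones, ds.meta, min_cells=3, alpha=0.05)
        eligible.append(len(enr))
        n_sig = int(enr["significant"].sum())
        fdps.append(1.0 if n_sig > 0 else 0.0)  # V/max(R,1): all null
        tested = clones.merge(enr[["clone_id"]], on="clone_id")
        ineligible_tested += int(
            (tested[["n_pb", "n_sf"]].max(axis=1) < 3).sum()
        )
    fdps_arr = np.asarray(fdps)
    return {
        "mean_fdp": float(fdps_arr.mean()),
        "mcse": float(fdps_arr.std(ddof=1) / np.sqrt(n_reps)),
        "mean_eligible": float(np.mean(eligible)),
        "ineligible_tested": ineligible_tested,
        "n_reps": n_reps,
    }


def _recovery_config(seed: int) -> SimConfig:
    # 10 planted clones, geometric-law sizes with mean 20, 0.9 SF bias,
    # >= 2000 singleton background cells
    return SimConfig(
        n_cells_pb=1150, n_cells_sf=1150, n_genes=60, n_clusters=2,
        markers_per_cluster=2, n_module_genes=3, mito_gene_count=2,
        n_expanded_clones=10, expanded_size_mean=20.0, sf_bias=0.9,
        n_hashtags=2, seed=seed,
    )


def clone_recovery_study(n_seeds: int = 50, seed: int = 0) -> Dict[str, float]:
    """Fraction of planted compartment-biased clones flagged significant."""
    recoveries: List[float] = []
    for s in range(n_seeds):
        ds = generate_dataset(_recovery_config(seed + s))
        chains = ct.collapse_chains(ds.contigs)
        clones = ct.clone_table(ct.call_clonotypes(chains, mode="joint_gex"),
                                ds.meta)
        enr = ct.test_enrichment(clones, ds.meta, min_cells=3, alpha=0.05)
        sig = set(enr.loc[enr["significant"], "clone_id"])
        recoveries.append(float(ds.truth.clones["clone_id"].isin(sig).mean()))
    return {
        "mean_recovery": float(np.mean(recoveries)),
        "n_planted": 10,
        "n_seeds": n_seeds,
    }


def demux_accuracy_study(n_seeds: int = 20, seed: int = 0) -> Dict[str, float]:
    """Singlet accuracy and doublet recall at 50x signal-to-background."""
    singlet_accs: List[float] = []
    doublet_recalls: List[float] = []
    for s in range(n_seeds):
        cfg = SimConfig(
            n_cells_pb=500, n_cells_sf=500, n_genes=60, n_clusters=2,
            markers_per_cluster=2, n_module_genes=3, mito_gene_count=2,
            n_expanded_clones=0, sf_bias=0.5, n_hashtags=2,
            hto_signal_mean=200.0, hto_background_mean=4.0,
            doublet_rate=0.05, seed=seed + s,
        )
        ds = generate_dataset(cfg)
        calls, _ = demux(ds.hto, q=0.99, random_state=seed + s)
        truth = ds.truth.hashtag
        singlets = truth.index[truth["true_class"] == "singlet"]
        correct = (
            (calls.loc[singlets, "hto_class"] == "singlet")
            & (calls.loc[singlets, "assigned_tag"]
               == truth.loc[singlets, "true_tag"])
        )
        singlet_accs.append(float(correct.mean()))
        doublets = truth.index[truth["true_class"] == "doublet"]
        if len(doublets):
            doublet_recalls.append(
                float((calls.loc[doublets, "hto_class"] == "doublet").mean())
            )
    return {
        "singlet_accuracy": float(np.mean(singlet_accs)),
        "doublet_recall": float(np.mean(doublet_recalls)),
        "n_seeds": n_seeds,
    }


def nb_quantile_grid_mismatches(q: float = 0.99) -> Tuple[int, int]:
    """Disagreements with the scipy CDF inversion over the (mu, size) grid."""
    mismatches = checked = 0
    for mu in (1.0, 10.0, 100.0):
        for size in (0.5, 2.0, 10.0, inf):
            ours = nb_quantile(NBParams(mu=mu, size=size), q)
            if np.isinf(size):
                ref = int(sps.poisson.ppf(q, mu))
            else:
                ref = int(sps.nbinom.ppf(q, size, size / (size + mu)))
            mismatches += int(ours != ref)
            checked += 1
    return mismatches, checked


def _module_config(seed: int, fold: float) -> SimConfig:
    return SimConfig(
        n_cells_pb=500, n_cells_sf=500, n_genes=800, n_clusters=8,
        n_module_genes=25, module_fold=fold, n_expanded_clones=0,
        sf_bias=0.5, n_hashtags=2, seed=seed,
    )


def module_score_study(n_seeds: int = 50, seed: int = 0) -> Dict[str, float]:
    """How often the module-elevated cluster ranks first by mean score."""
    wins = 0
    for s in range(n_seeds):
        ds = generate_dataset(_module_config(seed + s, fold=2.0))
        norm = normalize(ds.expression)
        ms = module_score(norm, ds.truth.module_genes, seed=seed + s)
        means = ms.scores.groupby(ds.meta["cluster"]).mean()
        wins += int(means.idxmax() == ds.truth.module_cluster)
    return {"top_rank_wins": wins, "n_seeds": n_seeds,
            "top_rank_rate": wins / n_seeds}


def module_null_study(n_seeds: int = 20, seed: int = 0) -> Dict[str, float]:
    """Module-score bias when module genes are exchangeable with controls.

    The expectation of the per-dataset mean score is 0 under exchangeability;
    ``abs_mean_score`` is its Monte-Carlo estimate across replicates (the
    systematic-bias check), ``max_abs_mean_score`` the worst single replicate
    (which also carries per-replicate sampling noise).
    """
    means: List[float] = []
    for s in range(n_seeds):
        ds = generate_dataset(_module_config(seed + s, fold=1.0))
        norm = normalize(ds.expression)
        ms = module_score(norm, ds.truth.module_genes, seed=seed + s)
        means.append(float(ms.scores.mean()))
    return {
        "abs_mean_score": float(abs(np.mean(means))),
        "max_abs_mean_score": float(np.max(np.abs(means))),
        "n_seeds": n_seeds,
    }


def qc_fixture_study() -> Dict[str, int]:
    """Crafted 12-cell matrix: one violation per rule plus boundary cells."""
    from .testing import crafted_qc_fixture

    matrix, chains, expected_kept, expected_rule = crafted_qc_fixture()
    metrics = compute_metrics(matrix, chains)
    keep, counts = apply_filters(metrics)
    kept = set(keep.index[keep])
    return {
        "n_cells": len(metrics),
        "n_kept": len(kept),
        "kept_matches_design": int(kept == expected_kept),
        "boundary_cells_kept": int(
            {"bound_genes", "bound_mito", "bound_umi"} <= kept
        ),
    }


def determinism_study(workdir, seed: int = 0) -> Dict[str, int]:
    """Two pipeline runs with one config: is the output bundle byte-identical?"""
    import yaml

    from . import pipeline

    workdir = __import__("pathlib").Path(workdir)
    cfg_path = workdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump({
        "seed": seed,
        "simulate": {
            "n_cells_pb": 300, "n_cells_sf": 300, "n_genes": 500,
            "n_clusters": 5, "n_module_genes": 15, "mito_gene_count": 5,
            "n_expanded_clones": 5, "expanded_size_mean": 12.0,
            "sf_bias": 0.9,
        },
        "qc": {"overrides": {"min_genes": 50}},
    }))
    pipeline.run_all(cfg_path, out_dir=workdir / "a")
    pipeline.run_all(cfg_path, out_dir=workdir / "b")
    names = sorted(p.name for p in (workdir / "a").iterdir())
    identical = all(
        (workdir / "a" / n).read_bytes() == (workdir / "b" / n).read_bytes()
        for n in names
    )
    return {"identical": int(identical), "n_files": len(names)}
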