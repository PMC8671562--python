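"""Expression statistics: normalization, differential expression, module
scoring, co-expression, and the per-cluster compartment composition test.

Normalization is library-size scaling to ``scale_total`` counts per cell
followed by natural log1p ("log(UMI + 1)" on depth-corrected counts).
Differential expression uses the Wilcoxon rank-sum test (exact enumeration
for small groups, tie-corrected normal approximation otherwise) with
Bonferroni correction, a 10% detection floor, and the Seurat-style natural-log
fold change ln(mean(expm1) + 1) ratio.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .datatypes import DataError, ExpressionMatrix

TCR_VARIABLE_PREFIXES = ("TRAV", "TRBV", "TRAJ", "TRBJ")


@dataclass
class NormalizedMatrix:
    """log1p of depth-scaled counts; zeros map to zeros (sparse-preserving)."""

    values: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray
    scale_total: float


def normalize(matrix: ExpressionMatrix, scale_total: float = 10_000) -> NormalizedMatrix:
    """Per-cell library-size scaling to ``scale_total`` then natural log1p."""
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = matrix.cell_barcodes[np.argmax(totals == 0)]
        raise DataError(
            f"cell {bad} has zero total counts; run QC before normalization"
        )
    scaled = matrix.counts.astype(float) @ sparse.diags(scale_total / totals)
    values = scaled.tocsr()
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=values,
        gene_ids=matrix.gene_ids,
        cell_barcodes=matrix.cell_barcodes,
        scale_total=scale_total,
    )


def _columns_for(norm: NormalizedMatrix, group: Sequence) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        return np.flatnonzero(group)
    if np.issubdtype(group.dtype, np.integer):
        return group
    pos = {b: i for i, b in enumerate(norm.cell_barcodes)}
    try:
        return np.array([pos[b] for b in group], dtype=int)
    except KeyError as exc:
        raise DataError(f"barcode not in matrix: {exc.args[0]}") from exc


def exact_rank_p(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group labelings.

    p is the fraction of the C(n_a + n_b, n_a) relabelings whose rank sum
    deviates from its null mean at least as much as the observed one.
    Average ranks are used for ties, so the enumeration is valid with ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    mu = na * (n + 1) / 2.0
    obs = abs(ranks[:na].sum() - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            count += 1
    return count / total


def asymptotic_rank_p(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided rank-sum p: normal approximation with tie-corrected variance."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = len(a), len(b)
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:na].sum()
    mu = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_de(
    norm: NormalizedMatrix,
    group_a: Sequence,
    group_b: Sequence,
    min_pct: float = 0.10,
    m_total: Optional[int] = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Group A vs group B differential expression.

    Genes are tested iff detected (count > 0) in at least ``min_pct`` of
    cells of either group.  ``mode`` selects the p-value route: ``"exact"``
    (full enumeration), ``"asymptotic"``, or ``"auto"`` (exact when both
    groups have <= 8 cells).  Bonferroni multiplies by ``m_total`` (default:
    all genes in the matrix).

    Returns columns gene, log_fc (natural log, A vs B), pct_a, pct_b, p, p_adj.
    """
    cols_a = _columns_for(norm, group_a)
    cols_b = _columns_for(norm, group_b)
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise DataError("each group needs at least 3 cells")
    if set(cols_a) & set(cols_b):
        raise DataError("groups overlap")
    m = m_total if m_total is not None else len(norm.gene_ids)
    if mode not in ("auto", "exact", "asymptotic"):
        raise DataError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and len(cols_a) <= 8 and len(cols_b) <= 8
    )

    sub_a = np.asarray(norm.values[:, cols_a].todense())
    sub_b = np.asarray(norm.values[:, cols_b].todense())
    pct_a = (sub_a > 0).mean(axis=1)
    pct_b = (sub_b > 0).mean(axis=1)
    tested = np.flatnonzero(np.maximum(pct_a, pct_b) >= min_pct)

    mean_a = np.expm1(sub_a).mean(axis=1)
    mean_b = np.expm1(sub_b).mean(axis=1)
    log_fc = np.log(mean_a + 1.0) - np.log(mean_b + 1.0)

    rows = []
    for g in tested:
        a, b = sub_a[g], sub_b[g]
        p = exact_rank_p(a, b) if use_exact else asymptotic_rank_p(a, b)
        rows.append(
            {
                "gene": norm.gene_ids[g],
                "log_fc": float(log_fc[g]),
                "pct_a": float(pct_a[g]),
                "pct_b": float(pct_b[g]),
                "p": p,
                "p_adj": min(1.0, p * m),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "log_fc", "pct_a", "pct_b", "p", "p_adj"]
    )


def report_filter(
    results: pd.DataFrame,
    log_fc_cut: float = 0.25,
    alpha: float = 0.05,
    drop_tcr_genes: bool = False,
) -> pd.DataFrame:
    """Reporting filter: keep |log_fc| strictly above the cutoff.

    Adds a ``significant`` flag (adjusted p strictly below ``alpha``); with
    ``drop_tcr_genes`` the TCR variable-chain genes (TRAV/TRBV/TRAJ/TRBJ
    prefixes) are removed, as conventional for clonotype-vs-clonotype
    comparisons where those segments are clone identity, not biology.
    """
    if results.empty:
        out = results.copy()
        out["significant"] = pd.Series(dtype=bool)
        return out
    keep = results["log_fc"].abs() > log_fc_cut
    if drop_tcr_genes:
        keep &= ~results["gene"].str.startswith(TCR_VARIABLE_PREFIXES)
    out = results.loc[keep].copy().reset_index(drop=True)
    out["significant"] = out["p_adj"] < alpha
    return out


@dataclass
class ModuleScore:
    """Per-cell gene-module score with its control configuration."""

    scores: pd.Series
    module_genes: List[str]
    n_bins: int
    n_ctrl: int
    seed: int


def module_score(
    norm: NormalizedMatrix,
    module_genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScore:
    """Module score with expression-matched controls.

    All genes are binned into ``n_bins`` equal-count bins of average
    normalized expression; for each module gene, ``n_ctrl`` control genes are
    drawn with replacement from its bin.  The per-cell score is the mean over
    module genes minus the mean over all control draws, so a random gene set
    scores ~0 regardless of expression level.
    """
    gene_ids = np.asarray(norm.gene_ids, dtype=object)
    present = [g for g in dict.fromkeys(module_genes) if g in set(gene_ids)]
    dropped = [g for g in dict.fromkeys(module_genes) if g not in set(gene_ids)]
    if dropped:
        warnings.warn(f"module genes absent from matrix, dropped: {dropped}")
    if not present:
        raise DataError("module is empty after dropping missing genes")

    dense = np.asarray(norm.values.todense())
    gene_means = dense.mean(axis=1)
    order = stats.rankdata(gene_means, method="ordinal") - 1  # 0-based ranks
    bins = (order * n_bins // len(gene_means)).astype(int)

    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(gene_ids)}
    module_idx = np.array([idx[g] for g in present])
    ctrl_draws = []
    for gi in module_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_draws.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_draws)

    scores = dense[module_idx].mean(axis=0) - dense[ctrl_idx].mean(axis=0)
    return ModuleScore(
        scores=pd.Series(scores, index=pd.Index(norm.cell_barcodes, name="barcode"),
                         name="module_score"),
        module_genes=present,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def cluster_compartment_test(meta: pd.DataFrame) -> pd.DataFrame:
    """Two-proportion z-test of cluster composition between compartments.

    For each cluster c, compares the fraction of PB cells in c with the
    fraction of SF cells in c using the pooled-proportion z statistic without
    continuity correction; two-sided p, no multiplicity correction.
    """
    if "cluster" not in meta.columns or meta["cluster"].isna().any():
        raise DataError("every cell needs a cluster label for this test")
    n1 = int((meta["compartment"] == "PB").sum())
    n2 = int((meta["compartment"] == "SF").sum())
    rows = []
    for cluster in sorted(meta["cluster"].astype(str).unique()):
        in_c = meta["cluster"].astype(str) == cluster
        x1 = int((in_c & (meta["compartment"] == "PB")).sum())
        x2 = int((in_c & (meta["compartment"] == "SF")).sum())
        if x1 + x2 == 0:
            warnings.warn(f"cluster {cluster} empty in both compartments; skipped")
            continue
        p_hat = (x1 + x2) / (n1 + n2)
        denom = np.sqrt(p_hat * (1 - p_hat) * (1 / n1 + 1 / n2))
        z = (x1 / n1 - x2 / n2) / denom if denom > 0 else 0.0
        rows.append(
            {
                "cluster": cluster,
                "n_pb": x1,
                "n_sf": x2,
                "prop_pb": x1 / n1,
                "prop_sf": x2 / n2,
                "z": z,
                "p": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster", "n_pb", "n_sf", "prop_pb", "prop_sf", "z", "p"]
    )


def spearman_pairs(norm: NormalizedMatrix, gene_list: Sequence[str]) -> pd.DataFrame:
    """Pairwise Spearman rho across cells for the given genes.

    Average ranks handle ties; a zero-variance gene has undefined rho and is
    reported as NaN (including against itself).
    """
    if len(norm.cell_barcodes) < 3:
        raise DataError("Spearman correlation needs at least 3 cells")
    idx = []
    for g in gene_list:
        hits = np.flatnonzero(np.asarray(norm.gene_ids, dtype=object) == g)
        if hits.size == 0:
            raise DataError(f"gene not in matrix: {g}")
        idx.append(int(hits[0]))
    dense = np.asarray(norm.values[idx, :].todense())
    ranks = np.vstack([stats.rankdata(row) for row in dense])
    sd = ranks.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(rho)
    degenerate = sd == 0
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(rho, index=list(gene_list), columns=list(gene_list))
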