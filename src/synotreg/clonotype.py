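"""Clonotype calling and compartment-enrichment testing.

T cells are assigned to the same clonotype when they carry identical CDR3
nucleotide sequences for both the alpha and beta chains.  Per clone, the
proportion of cells found in synovial fluid versus peripheral blood is
compared with a two-sided Fisher's exact test (point-probability rule) over
all clones with three or more cells in either compartment, with
Benjamini-Hochberg correction across the tested clones.

Two calling modes mirror the two uses of the repertoire:

``clonality_table``
    Multi-beta partitions are retained; each distinct chain multiset keys its
    own clone (a droplet whose beta pairing cannot be resolved is treated as
    a single clone).
``joint_gex``
    For joint analysis with gene expression, partitions with more than one
    beta chain or more than two alpha chains are treated as multiplets and
    excluded before keying.

Cells lacking a productive beta chain are excluded from clonotyping in both
modes.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CellChains, ContigRecord, DataError, ExpressionMatrix


def collapse_chains(contigs: Iterable[ContigRecord]) -> Dict[str, CellChains]:
    """Collapse contigs to per-cell distinct productive chain sets.

    Non-productive contigs are ignored; duplicate contigs of the same chain
    and CDR3 nucleotide sequence collapse to one entry (assembly redundancy,
    not extra chains).
    """
    alphas: Dict[str, set] = {}
    betas: Dict[str, set] = {}
    for rec in contigs:
        if not rec.productive:
            continue
        store = alphas if rec.chain == "TRA" else betas
        store.setdefault(rec.barcode, set()).add(rec.cdr3_nt)
    cells = {}
    for bc in sorted(set(alphas) | set(betas)):
        cells[bc] = CellChains(
            barcode=bc,
            alphas=tuple(alphas.get(bc, ())),
            betas=tuple(betas.get(bc, ())),
        )
    return cells


def clone_key(alphas: Sequence[str], betas: Sequence[str]) -> str:
    """Canonical clone id: sorted alpha CDR3s + '|' + sorted beta CDR3s."""
    return ";".join(sorted(alphas)) + "|" + ";".join(sorted(betas))


def call_clonotypes(
    cells: Mapping[str, CellChains], mode: str = "joint_gex"
) -> pd.DataFrame:
    """Assign cells to clonotypes; returns columns ``barcode``, ``clone_id``.

    Cells without a beta chain are never clonotyped.  Alpha-less cells are
    likewise excluded (the clone definition keys on both chains).
    """
    if mode not in ("clonality_table", "joint_gex"):
        raise DataError(f"unknown clonotype mode {mode!r}")
    rows = []
    for bc in sorted(cells):
        cc = cells[bc]
        if cc.n_beta == 0 or cc.n_alpha == 0:
            continue
        if mode == "joint_gex" and (cc.n_beta > 1 or cc.n_alpha > 2):
            continue
        rows.append({"barcode": bc, "clone_id": clone_key(cc.alphas, cc.betas)})
    return pd.DataFrame(rows, columns=["barcode", "clone_id"])


def clone_table(assignments: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Summarise clone membership per compartment.

    Returns one row per clone with ``clone_id``, ``size``, ``n_pb``, ``n_sf``,
    sorted by descending size then clone_id.  Every member barcode must carry
    a compartment label in ``meta`` (indexed by barcode).
    """
    missing = [b for b in assignments["barcode"] if b not in meta.index]
    if missing:
        raise DataError(f"clone member without compartment label: {missing[0]}")
    comp = meta.loc[assignments["barcode"], "compartment"].to_numpy()
    df = assignments.assign(compartment=comp)
    grouped = (
        df.groupby("clone_id")["compartment"]
        .agg(
            size="count",
            n_pb=lambda s: int((s == "PB").sum()),
            n_sf=lambda s: int((s == "SF").sum()),
        )
        .reset_index()
    )
    return grouped.sort_values(
        ["size", "clone_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, point-probability rule.

    p is the sum of hypergeometric point probabilities, over all tables with
    the observed margins, that do not exceed the observed table's probability
    by more than a 1e-7 relative tolerance.  Degenerate margins give p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise DataError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = _log_binom(n, c1)
    xs = np.arange(lo, hi + 1)
    logpmf = np.array(
        [_log_binom(r1, x) + _log_binom(r2, c1 - x) - denom for x in xs]
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(1.0, max(0.0, p))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_enrichment(
    clones: pd.DataFrame,
    meta: pd.DataFrame,
    min_cells: int = 3,
    alpha: float = 0.05,
    eligibility: str = "either",
) -> pd.DataFrame:
    """Per-clone compartment-enrichment test.

    Eligibility (default ``"either"``): a clone is tested iff it has at least
    ``min_cells`` cells in either compartment, i.e. max(n_pb, n_sf) >=
    min_cells; ``"total"`` instead requires size >= min_cells.  For each
    eligible clone the 2x2 table [[n_sf, total_sf - n_sf], [n_pb, total_pb -
    n_pb]] is tested, where the totals are all clonotyped cells per
    compartment.  BH correction runs across eligible clones only; a clone is
    significant iff its adjusted p <= alpha.
    """
    if eligibility not in ("either", "total"):
        raise DataError(f"unknown eligibility rule {eligibility!r}")
    total_pb = int(clones["n_pb"].sum())
    total_sf = int(clones["n_sf"].sum())
    if eligibility == "either":
        eligible = clones[["n_pb", "n_sf"]].max(axis=1) >= min_cells
    else:
        eligible = clones["size"] >= min_cells
    tested = clones.loc[eligible].reset_index(drop=True)
    rows = []
    for rec in tested.itertuples(index=False):
        a, c = rec.n_sf, rec.n_pb
        b, d = total_sf - a, total_pb - c
        p = fisher_two_sided([[a, b], [c, d]])
        odds = (a * d) / (b * c) if b * c > 0 else math.inf
        frac_sf = a / total_sf if total_sf else 0.0
        frac_pb = c / total_pb if total_pb else 0.0
        rows.append(
            {
                "clone_id": rec.clone_id,
                "n_pb": c,
                "n_sf": a,
                "total_pb": total_pb,
                "total_sf": total_sf,
                "odds_ratio": odds,
                "p": p,
                "enriched_in": "SF" if frac_sf >= frac_pb else "PB",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "clone_id", "n_pb", "n_sf", "total_pb", "total_sf",
            "odds_ratio", "p", "enriched_in",
        ],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    out["significant"] = out["p_adj"] <= alpha if len(out) else np.array([], dtype=bool)
    return out


def clone_cluster_distribution(
    member_barcodes: Sequence[str], meta: pd.DataFrame
) -> pd.DataFrame:
    """Distribution of one clone's members over transcriptional clusters.

    Returns per-cluster member counts and fractions plus descriptive
    hypergeometric over/under-representation p-values (``p_over`` =
    P(X >= observed), ``p_under`` = P(X <= observed) for X hypergeometric on
    cluster size, clone size and total labelled cells).  Members without a
    cluster label are counted under ``"unlabelled"``.
    """
    clusters = []
    for bc in member_barcodes:
        label = meta.loc[bc, "cluster"] if (
            bc in meta.index and "cluster" in meta.columns
        ) else None
        if label is None or (isinstance(label, float) and math.isnan(label)):
            label = "unlabelled"
        clusters.append(str(label))
    counts = pd.Series(clusters).value_counts().sort_index()
    n_members = len(member_barcodes)
    if "cluster" in meta.columns:
        universe = meta["cluster"].fillna("unlabelled").astype(str).value_counts()
    else:
        universe = pd.Series(dtype=int)
    total = int(universe.sum())
    rows = []
    for cluster, k in counts.items():
        row = {"cluster": cluster, "n": int(k), "fraction": k / n_members}
        if total and cluster in universe.index:
            K = int(universe[cluster])
            hg = stats.hypergeom(total, K, n_members)
            row["p_over"] = float(hg.sf(k - 1))
            row["p_under"] = float(hg.cdf(k))
        else:
            row["p_over"] = math.nan
            row["p_under"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["cluster", "n", "fraction", "p_over", "p_under"])


def classify_lineage(
    member_barcodes: Sequence[str],
    norm_values,
    gene_ids: Sequence[str],
    cell_barcodes: Sequence[str],
) -> str:
    """CD4/CD8 lineage of a clone by majority vote over member cells.

    A member is CD8-like when its normalized CD8A + CD8B expression exceeds
    CD4, CD4-like for the reverse, and abstains on a tie; the clone lineage
    is the majority of non-abstaining members, with ties ``"unassigned"``.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {b: i for i, b in enumerate(cell_barcodes)}

    def expr(gene: str, col: int) -> float:
        idx = np.flatnonzero(gene_ids == gene)
        return float(norm_values[int(idx[0]), col]) if idx.size else 0.0

    cd4_votes = cd8_votes = 0
    for bc in member_barcodes:
        col = pos.get(bc)
        if col is None:
            continue
        cd4 = expr("CD4", col)
        cd8 = expr("CD8A", col) + expr("CD8B", col)
        if cd8 > cd4:
            cd8_votes += 1
        elif cd4 > cd8:
            cd4_votes += 1
    if cd4_votes > cd8_votes:
        return "CD4"
    if cd8_votes > cd4_votes:
        return "CD8"
    return "unassigned"
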