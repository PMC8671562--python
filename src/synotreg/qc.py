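"""Cell-level quality control.

Removal criteria follow the study design for sorted memory Tregs: cells with
>10% mitochondrial transcripts, <250 or >4000 expressed genes, >25,000 UMIs,
no transcript from the CD3 complex (CD3E/CD3D/CD3G), or a TCR chain multiplet
(>1 beta chain or >2 alpha chains) are excluded.  A variant preset for the
psoriatic-arthritis dataset uses 500/3500 gene bounds, skips the CD3 gate
(those libraries were sorted on CD3 protein) and additionally removes
CD4/CD8 co-expressing cells.

Boundary semantics: every removal condition is a strict inequality, so cells
at exactly 250 genes, 10.0% mitochondrial fraction or 25,000 UMIs are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import CellChains, ExpressionMatrix

#: fixed order in which rules are attributed when a cell fails several
RULE_ORDER = (
    "high_mito",
    "low_genes",
    "high_genes",
    "high_umi",
    "cd3_negative",
    "tcr_multiplet",
    "cd4_cd8_coexpression",
    "cd14_positive",
)


@dataclass
class QCThresholds:
    max_mito_frac: float = 0.10
    min_genes: int = 250
    max_genes: int = 4000
    max_umi: int = 25000
    cd3_genes: Tuple[str, ...] = ("CD3E", "CD3D", "CD3G")
    require_cd3: bool = True
    max_beta_chains: int = 1
    max_alpha_chains: int = 2
    exclude_cd4_cd8: bool = False
    drop_cd14: bool = False

    def __post_init__(self) -> None:
        if not (self.min_genes < self.max_genes):
            raise ValueError("min_genes must be < max_genes")
        if not (0 <= self.max_mito_frac <= 1):
            raise ValueError("max_mito_frac must lie in [0, 1]")

    @classmethod
    def preset(cls, name: str, **overrides) -> "QCThresholds":
        """Named presets: ``AS`` (default bounds) and ``PsA``."""
        if name == "AS":
            base = cls()
        elif name == "PsA":
            base = cls(min_genes=500, max_genes=3500, require_cd3=False,
                       exclude_cd4_cd8=True)
        else:
            raise ValueError(f"unknown QC preset {name!r}")
        return replace(base, **overrides) if overrides else base


def _gene_positive(matrix: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Boolean per cell: any of ``genes`` present in the matrix has count > 0."""
    rows = [matrix.gene_index(g) for g in genes if matrix.has_gene(g)]
    if not rows:
        return np.zeros(matrix.n_cells, dtype=bool)
    sub = matrix.counts[rows, :]
    return np.asarray((sub > 0).sum(axis=0)).ravel() > 0


def compute_metrics(
    matrix: ExpressionMatrix,
    chains: Optional[Mapping[str, CellChains]] = None,
    mito_prefix: str = "MT-",
    cd3_genes: Sequence[str] = ("CD3E", "CD3D", "CD3G"),
) -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a DataFrame indexed by barcode with columns ``mito_frac``
    (mitochondrial UMIs / total UMIs, 0 for empty cells), ``n_genes``
    (genes with count > 0), ``n_umi``, ``cd3_positive``, ``n_alpha``/``n_beta``
    (distinct productive chains, 0 for cells without TCR evidence) and the
    positivity flags used by the PsA and CD14 rules.
    """
    counts = matrix.counts.tocsc()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()

    mito_mask = np.array([g.startswith(mito_prefix) for g in matrix.gene_ids])
    if not mito_mask.any():
        warnings.warn(
            f"no gene id matches mitochondrial prefix {mito_prefix!r}; "
            "mito_frac set to 0 for all cells"
        )
        mito_umi = np.zeros_like(n_umi)
    else:
        mito_umi = np.asarray(counts[np.flatnonzero(mito_mask), :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)

    cd8_pos = _gene_positive(matrix, ("CD8A", "CD8B"))
    cd4_pos = _gene_positive(matrix, ("CD4",))

    metrics = pd.DataFrame(
        {
            "mito_frac": mito_frac,
            "n_genes": n_genes.astype(int),
            "n_umi": n_umi.astype(int),
            "cd3_positive": _gene_positive(matrix, cd3_genes),
            "cd4_cd8_coexpression": cd4_pos & cd8_pos,
            "cd14_positive": _gene_positive(matrix, ("CD14",)),
        },
        index=pd.Index(matrix.cell_barcodes, name="barcode"),
    )

    n_alpha = np.zeros(matrix.n_cells, dtype=int)
    n_beta = np.zeros(matrix.n_cells, dtype=int)
    if chains:
        pos = {b: i for i, b in enumerate(matrix.cell_barcodes)}
        for bc, cc in chains.items():
            i = pos.get(bc)
            if i is not None:
                n_alpha[i] = cc.n_alpha
                n_beta[i] = cc.n_beta
    metrics["n_alpha"] = n_alpha
    metrics["n_beta"] = n_beta
    return metrics


def _violations(metrics: pd.DataFrame, th: QCThresholds) -> Dict[str, np.ndarray]:
    """Per-rule violation masks, in RULE_ORDER; removal criteria are strict."""
    v = {
        "high_mito": metrics["mito_frac"].to_numpy() > th.max_mito_frac,
        "low_genes": metrics["n_genes"].to_numpy() < th.min_genes,
        "high_genes": metrics["n_genes"].to_numpy() > th.max_genes,
        "high_umi": metrics["n_umi"].to_numpy() > th.max_umi,
        "cd3_negative": (
            ~metrics["cd3_positive"].to_numpy()
            if th.require_cd3
            else np.zeros(len(metrics), dtype=bool)
        ),
        "tcr_multiplet": (
            (metrics["n_beta"].to_numpy() > th.max_beta_chains)
            | (metrics["n_alpha"].to_numpy() > th.max_alpha_chains)
        ),
        "cd4_cd8_coexpression": (
            metrics["cd4_cd8_coexpression"].to_numpy()
            if th.exclude_cd4_cd8
            else np.zeros(len(metrics), dtype=bool)
        ),
        "cd14_positive": (
            metrics["cd14_positive"].to_numpy()
            if th.drop_cd14
            else np.zeros(len(metrics), dtype=bool)
        ),
    }
    return v


def apply_filters(
    metrics: pd.DataFrame, thresholds: Optional[QCThresholds] = None
) -> Tuple[pd.Series, Dict[str, int]]:
    """Apply all removal rules; returns (keep mask, first-failing-rule counts).

    A cell is kept iff it violates no rule; each removed cell is attributed to
    the first rule it fails in :data:`RULE_ORDER`, so the per-rule counts plus
    the kept count always total the number of cells.
    """
    th = thresholds or QCThresholds()
    v = _violations(metrics, th)
    keep = np.ones(len(metrics), dtype=bool)
    attributed = np.zeros(len(metrics), dtype=bool)
    counts: Dict[str, int] = {}
    for rule in RULE_ORDER:
        first_fail = v[rule] & ~attributed
        counts[rule] = int(first_fail.sum())
        attributed |= v[rule]
        keep &= ~v[rule]
    return pd.Series(keep, index=metrics.index, name="keep"), counts


def apply_psa_variant(
    matrix: ExpressionMatrix,
    metrics: pd.DataFrame,
    thresholds: Optional[QCThresholds] = None,
) -> Tuple[pd.Series, Dict[str, int]]:
    """PsA-dataset filters: 500/3500 gene bounds plus CD4/CD8 co-expression."""
    for g in ("CD4", "CD8A", "CD8B"):
        if not matrix.has_gene(g):
            warnings.warn(f"gene {g} absent; CD4/CD8 co-expression rule weakened")
    th = thresholds or QCThresholds.preset("PsA")
    return apply_filters(metrics, th)
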