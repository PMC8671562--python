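"""Hand-crafted miniature inputs with known answers (synthetic, not patient
data), shared by the test suite and the validation experiments."""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .datatypes import CellChains, ExpressionMatrix


def _qc_cell(n_genes_total: int, *, n_expressed: int, n_umi: int,
             mito_umi: int, cd3: bool = True) -> np.ndarray:
    """Count column with exact expressed-gene, UMI and mito composition.

    Gene layout: 0-2 CD3E/CD3D/CD3G, 3-12 MT- genes, the rest generic.
    """
    col = np.zeros(n_genes_total, dtype=np.int64)
    used = 0
    if cd3:
        col[0] = 1
        used += 1
    if mito_umi > 0:
        col[3] = mito_umi
        used += 1
    n_generic = n_expressed - used
    assert n_generic >= 1
    col[13: 13 + n_generic] = 1
    remaining = n_umi - int(col.sum())
    assert remaining >= 0
    col[13] += remaining
    assert int(col.sum()) == n_umi and int((col > 0).sum()) == n_expressed
    return col


def crafted_qc_fixture():
    """12 cells: one violation per filtering rule, boundary cells, clean cells.

    Returns (matrix, chains, expected_kept, expected_rule_of_removed).  The
    boundary cells sit exactly at 250 genes, 10.0% mitochondrial fraction and
    25,000 UMIs and must survive (removal criteria are strict inequalities).
    """
    n_genes = 4100
    gene_ids = (
        ["CD3E", "CD3D", "CD3G"]
        + [f"MT-G{i}" for i in range(10)]
        + [f"G{i:05d}" for i in range(n_genes - 13)]
    )
    cells = {
        "clean1": _qc_cell(n_genes, n_expressed=1000, n_umi=8000, mito_umi=400),
        "high_mito": _qc_cell(n_genes, n_expressed=1000, n_umi=8000, mito_umi=960),
        "low_genes": _qc_cell(n_genes, n_expressed=249, n_umi=5000, mito_umi=100),
        "high_genes": _qc_cell(n_genes, n_expressed=4001, n_umi=8000, mito_umi=100),
        "high_umi": _qc_cell(n_genes, n_expressed=1000, n_umi=25001, mito_umi=500),
        "cd3_null": _qc_cell(n_genes, n_expressed=1000, n_umi=8000, mito_umi=400,
                             cd3=False),
        "two_beta": _qc_cell(n_genes, n_expressed=1000, n_umi=8000, mito_umi=400),
        "bound_genes": _qc_cell(n_genes, n_expressed=250, n_umi=5000, mito_umi=100),
        "bound_mito": _qc_cell(n_genes, n_expressed=1000, n_umi=8000, mito_umi=800),
        "bound_umi": _qc_cell(n_genes, n_expressed=1000, n_umi=25000, mito_umi=500),
        "clean2": _qc_cell(n_genes, n_expressed=600, n_umi=4000, mito_umi=100),
        "three_alpha": _qc_cell(n_genes, n_expressed=1000, n_umi=8000, mito_umi=400),
    }
    barcodes = list(cells)
    counts = sparse.csr_matrix(np.column_stack([cells[b] for b in barcodes]))
    matrix = ExpressionMatrix(counts, np.array(gene_ids, dtype=object),
                              np.array(barcodes, dtype=object))
    chains = {
        b: CellChains(barcode=b, alphas=("AAACCC",), betas=("GGGTTT",))
        for b in barcodes
    }
    chains["two_beta"] = CellChains("two_beta", alphas=("AAACCC",),
                                    betas=("GGGTTT", "CCCAAA"))
    chains["three_alpha"] = CellChains(
        "three_alpha", alphas=("AAACCC", "CCCGGG", "TTTAAA"), betas=("GGGTTT",)
    )
    expected_kept = {"clean1", "clean2", "bound_genes", "bound_mito", "bound_umi"}
    expected_rule = {
        "high_mito": "high_mito",
        "low_genes": "low_genes",
        "high_genes": "high_genes",
        "high_umi": "high_umi",
        "cd3_null": "cd3_negative",
        "two_beta": "tcr_multiplet",
        "three_alpha": "tcr_multiplet",
    }
    return matrix, chains, expected_kept, expected_rule
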