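"""Readers and writers for the standard on-disk formats.

CellRanger-style layout: a Matrix Market triplet file with ``features.tsv``
and ``barcodes.tsv`` sidecars (1-based MTX indices are converted to the
package's 0-based convention at this boundary), a TCR contig table in the 10x
``filtered_contig_annotations.csv`` dialect, and TSV for every output table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import (
    ContigRecord,
    ExpressionMatrix,
    FormatError,
    HTOCounts,
    VALID_CHAINS,
    validate_meta,
)

logger = logging.getLogger(__name__)

CONTIG_COLUMNS = (
    "barcode",
    "chain",
    "cdr3",
    "cdr3_nt",
    "v_gene",
    "j_gene",
    "productive",
    "umis",
)


def _read_id_file(path, n_expected: int, what: str) -> np.ndarray:
    """Read a one-id-per-line (optionally multi-column TSV) sidecar file."""
    lines = Path(path).read_text().splitlines()
    ids = [ln.split("\t")[0] for ln in lines if ln.strip()]
    if len(ids) != n_expected:
        raise FormatError(
            f"{what} file {path} has {len(ids)} entries but the matrix "
            f"declares {n_expected}"
        )
    return np.asarray(ids, dtype=object)


def _read_mtx(mtx_path) -> sparse.csr_matrix:
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # malformed header / body
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"negative entry in {mtx_path}")
    return mat


def read_expression(mtx_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read a genes x cells UMI matrix with its feature/barcode sidecars."""
    mat = _read_mtx(mtx_path)
    genes = _read_id_file(features_path, mat.shape[0], "features")
    barcodes = _read_id_file(barcodes_path, mat.shape[1], "barcodes")
    return ExpressionMatrix(mat, genes, barcodes)


def write_expression(matrix: ExpressionMatrix, mtx_path, features_path, barcodes_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(matrix.counts), field="integer")
    Path(features_path).write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.gene_ids)
    )
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.cell_barcodes))


def read_hto(mtx_path, tags_path, barcodes_path) -> HTOCounts:
    mat = _read_mtx(mtx_path)
    tags = _read_id_file(tags_path, mat.shape[0], "hashtag ids")
    barcodes = _read_id_file(barcodes_path, mat.shape[1], "barcodes")
    return HTOCounts(mat, tags, barcodes)


def write_hto(hto: HTOCounts, mtx_path, tags_path, barcodes_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(hto.counts), field="integer")
    Path(tags_path).write_text("".join(f"{t}\n" for t in hto.hashtag_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in hto.cell_barcodes))


def read_contigs(csv_path) -> List[ContigRecord]:
    """Parse a 10x-dialect contig annotation CSV into :class:`ContigRecord` rows.

    Rows whose ``chain`` is outside {TRA, TRB} (e.g. "Multi", IG loci) are
    dropped with a logged count; ``productive`` is truthy only for the literal
    strings True/true/TRUE.
    """
    df = pd.read_csv(csv_path, dtype=str)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig file {csv_path} missing columns: {missing}")
    keep = df["chain"].isin(VALID_CHAINS)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_contigs: dropped %d rows with chain outside %s",
                    n_dropped, VALID_CHAINS)
    records = []
    for row in df.loc[keep].itertuples(index=False):
        records.append(
            ContigRecord(
                barcode=row.barcode,
                chain=row.chain,
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3 if isinstance(row.cdr3, str) else "",
                v_gene=row.v_gene if isinstance(row.v_gene, str) else "",
                j_gene=row.j_gene if isinstance(row.j_gene, str) else "",
                productive=str(row.productive) in ("True", "true", "TRUE"),
                umis=int(row.umis),
            )
        )
    return records


def write_contigs(records: Iterable[ContigRecord], csv_path) -> None:
    rows = [
        {
            "barcode": r.barcode,
            "chain": r.chain,
            "cdr3": r.cdr3_aa,
            "cdr3_nt": r.cdr3_nt,
            "v_gene": r.v_gene,
            "j_gene": r.j_gene,
            "productive": "True" if r.productive else "False",
            "umis": r.umis,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(CONTIG_COLUMNS)).to_csv(csv_path, index=False)


def write_table(records, path, comments: Optional[Sequence[str]] = None) -> None:
    """Write a table as TSV with >= 12 significant digits so reruns are diffable.

    ``records`` may be a DataFrame or a list of dicts sharing a schema;
    ``comments`` are emitted as leading ``#``-prefixed header lines.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    with open(path, "w") as fh:
        for line in comments or ():
            fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_meta(path) -> pd.DataFrame:
    """Read a per-cell metadata TSV and validate/index it by barcode."""
    return validate_meta(pd.read_csv(path, sep="\t", comment="#", dtype=str))


def write_meta(meta: pd.DataFrame, path, comments: Optional[Sequence[str]] = None) -> None:
    write_table(meta.reset_index(drop=True), path, comments=comments)
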