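"""Core in-memory containers and error types shared across the pipeline.

Tabular results (QC metrics, demultiplexing calls, clone tables, differential
expression) are plain :class:`pandas.DataFrame` objects with documented column
schemas; the matrix-shaped containers below carry their own invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class FormatError(ValueError):
    """An on-disk file violates its format contract."""


class DataError(ValueError):
    """Input data violate a precondition of an operation."""


class ConfigError(ValueError):
    """A configuration value is invalid or infeasible."""


COMPARTMENTS = ("PB", "SF")

#: required columns of a cell-metadata table
META_COLUMNS = ("barcode", "sample_id", "compartment", "patient")


def _as_str_array(values: Sequence[str]) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise DataError("identifier list must be one-dimensional")
    return arr


@dataclass
class ExpressionMatrix:
    """Sparse nonnegative UMI count matrix, genes x cells.

    Attributes
    ----------
    counts
        ``scipy.sparse.csr_matrix`` of shape ``(n_genes, n_cells)`` holding
        nonnegative integer UMI counts.
    gene_ids, cell_barcodes
        Unique identifiers for the rows and columns, in matrix order.
    """

    counts: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_barcodes = _as_str_array(self.cell_barcodes)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids and "
                f"{len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise FormatError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count entry")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(gene_id)
        return int(idx[0])

    def has_gene(self, gene_id: str) -> bool:
        return bool(np.any(self.gene_ids == gene_id))

    def subset_cells(self, keep) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``keep`` (mask or column indices)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            self.counts[:, keep], self.gene_ids, self.cell_barcodes[keep]
        )


@dataclass
class HTOCounts:
    """Hashtag-oligo count matrix, hashtags x cells."""

    counts: sparse.csr_matrix
    hashtag_ids: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.hashtag_ids = _as_str_array(self.hashtag_ids)
        self.cell_barcodes = _as_str_array(self.cell_barcodes)
        if self.counts.shape != (len(self.hashtag_ids), len(self.cell_barcodes)):
            raise FormatError("HTO matrix shape inconsistent with id lists")
        if len(set(self.hashtag_ids)) != len(self.hashtag_ids):
            raise FormatError("duplicate hashtag ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative HTO count")

    @property
    def n_tags(self) -> int:
        return self.counts.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


VALID_CHAINS = ("TRA", "TRB")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled TCR contig for one cell."""

    barcode: str
    chain: str
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    productive: bool
    umis: int

    def __post_init__(self) -> None:
        if self.chain not in VALID_CHAINS:
            raise DataError(f"chain must be one of {VALID_CHAINS}, got {self.chain!r}")
        if not self.cdr3_nt or set(self.cdr3_nt) - set("ACGT"):
            raise DataError(f"cdr3_nt must be non-empty over ACGT: {self.cdr3_nt!r}")
        if self.umis < 0:
            raise DataError("umis must be nonnegative")


@dataclass(frozen=True)
class CellChains:
    """Collapsed per-cell chain evidence: distinct productive CDR3 nt per locus."""

    barcode: str
    alphas: tuple
    betas: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(sorted(set(self.alphas))))
        object.__setattr__(self, "betas", tuple(sorted(set(self.betas))))

    @property
    def n_alpha(self) -> int:
        return len(self.alphas)

    @property
    def n_beta(self) -> int:
        return len(self.betas)


@dataclass
class NBParams:
    """Negative binomial parameters; ``size = inf`` denotes the Poisson limit.

    The parameterisation is mean/size: variance = mu + mu**2 / size.
    """

    mu: float
    size: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise DataError("NB mean must be >= 0")
        if not (self.size > 0):
            raise DataError("NB size must be > 0 (use inf for Poisson)")


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a cell-metadata table and return it indexed by barcode."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    bad = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise DataError(f"unknown compartment labels: {sorted(bad)}")
    if meta["barcode"].duplicated().any():
        dup = meta.loc[meta["barcode"].duplicated(), "barcode"].iloc[0]
        raise DataError(f"duplicate barcode in metadata: {dup}")
    out = meta.copy()
    out.index = pd.Index(meta["barcode"], name="barcode")
    return out
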