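"""Truth-labelled synthetic datasets for a two-compartment Treg study.

The generator emulates the statistical structure the downstream analysis
assumes, not transcriptome realism: clustered negative-binomial expression
(gamma-Poisson draws; baseline gene means log-normal, cluster marker genes
multiplied by a fold factor, one cluster with an elevated gene module),
mitochondrial genes with an ``MT-`` prefix, a TCR repertoire of singleton
background clones plus planted expanded clones whose members land in
synovial fluid with a configurable bias, hashtag counts with signal/background
means and doublets carrying two signals, and optional controlled QC
violations.

Planted clone sizes are 2 + Geometric(p = 1/(mean - 2)): a geometric-shaped
heavy tail with support >= 3 (smaller groups are not expansions under the
analysis' own three-cell rule) and exact mean ``expanded_size_mean``.

All randomness flows from one seed through named substreams, so adding a
component never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Dict, Iterator, List, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import sparse

from . import io as sio
from .clonotype import clone_key
from .datatypes import ConfigError, ContigRecord, ExpressionMatrix, HTOCounts

# the 13 protein-coding mitochondrial genes
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

QC_RULES = ("high_mito", "low_genes", "high_genes", "high_umi", "multi_beta")

# fixed substream salts: new components get new salts, existing draws never move
_SALT = {"genes": 11, "cells": 23, "expression": 37, "tcr": 53, "hto": 71, "qc": 89}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset (see module docstring)."""

    n_cells_pb: int = 1000
    n_cells_sf: int = 1000
    n_genes: int = 1200
    n_clusters: int = 10
    markers_per_cluster: int = 10
    marker_fold: float = 4.0
    module_genes: Optional[List[str]] = None
    n_module_genes: int = 25
    module_fold: float = 2.0
    mito_gene_count: int = 13
    nb_dispersion: float = 2.0
    gene_mean_log_mean: float = 0.0
    gene_mean_log_sd: float = 1.0
    cell_size_log_sd: float = 0.25
    cd8_cell_frac: float = 0.10
    n_expanded_clones: int = 10
    expanded_size_mean: float = 20.0
    sf_bias: float = 0.9
    background_clone_size: int = 1
    dual_alpha_rate: float = 0.10
    nonproductive_rate: float = 0.05
    contig_umi_mean: float = 8.0
    n_hashtags: int = 2
    hto_signal_mean: float = 200.0
    hto_background_mean: float = 4.0
    hto_nb_size: float = 10.0
    doublet_rate: float = 0.05
    qc_violation_rates: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "sf_bias": self.sf_bias,
            "cd8_cell_frac": self.cd8_cell_frac,
            "dual_alpha_rate": self.dual_alpha_rate,
            "nonproductive_rate": self.nonproductive_rate,
            "doublet_rate": self.doublet_rate,
            **{f"qc_violation_rates[{k}]": v for k, v in self.qc_violation_rates.items()},
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} = {v} must lie in [0, 1]")
        for name in ("n_cells_pb", "n_cells_sf", "n_genes", "n_clusters",
                     "n_hashtags", "mito_gene_count"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_expanded_clones < 0:
            raise ConfigError("n_expanded_clones must be >= 0")
        if self.n_expanded_clones and self.expanded_size_mean < 3:
            raise ConfigError("expanded_size_mean must be >= 3")
        if self.background_clone_size != 1:
            raise ConfigError("only singleton background clones are supported")
        if self.nb_dispersion <= 0 or self.hto_nb_size <= 0:
            raise ConfigError("NB dispersion parameters must be positive")
        bad = set(self.qc_violation_rates) - set(QC_RULES)
        if bad:
            raise ConfigError(f"unknown QC violation rules: {sorted(bad)}")
        reserved = (
            len(MITO_GENES[: self.mito_gene_count])
            + max(0, self.mito_gene_count - len(MITO_GENES))
            + len(_SPECIAL_GENES)
            + self.n_clusters * self.markers_per_cluster
            + (0 if self.module_genes else self.n_module_genes)
        )
        if self.n_genes < reserved + 10:
            raise ConfigError(
                f"n_genes = {self.n_genes} too small for {reserved} reserved genes"
            )


# special genes and their baseline NB means; CD3 means are high so that the
# CD3 gate passes for essentially every genuine T cell
_SPECIAL_GENES = {
    "CD3E": 8.0, "CD3D": 4.0, "CD3G": 2.0,
    "CD4": 2.0, "CD8A": 0.02, "CD8B": 0.02,
    "FOXP3": 3.0, "IL2RA": 3.0,
    "TRBV9": 1.0, "TRAV12": 1.0,
}


@dataclass
class TruthTable:
    """Ground truth for one generated dataset."""

    clones: pd.DataFrame          # clone_id, size, n_pb, n_sf, biased
    hashtag: pd.DataFrame         # barcode-indexed: true_class, true_tag(s)
    module_genes: List[str]
    module_cluster: str
    qc_violations: pd.DataFrame   # barcode-indexed boolean flags per rule
    seed: int


@dataclass
class SimDataset:
    expression: ExpressionMatrix
    meta: pd.DataFrame            # barcode-indexed
    contigs: List[ContigRecord]
    hto: HTOCounts
    truth: TruthTable


def _rng(config: SimConfig, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_SALT[name],))
    )


def _draw_cdr3(rng: np.random.Generator) -> str:
    n_codons = int(rng.integers(10, 21))  # 30-60 nt, in frame, no stops
    codons = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in codons)


def _unique_cdr3(rng: np.random.Generator, seen: set) -> str:
    while True:
        s = _draw_cdr3(rng)
        if s not in seen:
            seen.add(s)
            return s


def _barcodes(rng: np.random.Generator, n: int) -> np.ndarray:
    alphabet = np.array(list("ACGT"))
    out: List[str] = []
    seen: set = set()
    while len(out) < n:
        for row in rng.integers(0, 4, size=(n - len(out), 16)):
            bc = "".join(alphabet[row]) + "-1"
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return np.asarray(out, dtype=object)


def _clone_sizes(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    if mean == 3.0:
        return np.full(n, 3, dtype=int)
    return 2 + rng.geometric(1.0 / (mean - 2.0), size=n)


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate one truth-labelled dataset; identical config => identical output."""
    config.validate()
    n_cells = config.n_cells_pb + config.n_cells_sf

    # --- genes ---------------------------------------------------------
    rng_genes = _rng(config, "genes")
    mito = list(MITO_GENES[: config.mito_gene_count])
    mito += [f"MT-EXT{i}" for i in range(len(mito), config.mito_gene_count)]
    special = list(_SPECIAL_GENES)
    n_generic = config.n_genes - len(mito) - len(special)
    generic = [f"GENE{i:05d}" for i in range(n_generic)]
    gene_ids = np.asarray(special + mito + generic, dtype=object)

    base_mean = rng_genes.lognormal(
        config.gene_mean_log_mean, config.gene_mean_log_sd, size=config.n_genes
    )
    for i, g in enumerate(special):
        base_mean[i] = _SPECIAL_GENES[g]

    generic_order = rng_genes.permutation(n_generic)
    offset = len(special) + len(mito)
    cursor = 0
    marker_idx: Dict[str, np.ndarray] = {}
    for c in range(config.n_clusters):
        take = generic_order[cursor: cursor + config.markers_per_cluster]
        marker_idx[f"C{c}"] = offset + take
        cursor += config.markers_per_cluster
    if config.module_genes:
        module_genes = list(config.module_genes)
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in module_genes if g not in gene_pos]
        if missing:
            raise ConfigError(f"module genes not among generated genes: {missing}")
        module_idx = np.array([gene_pos[g] for g in module_genes])
    else:
        take = generic_order[cursor: cursor + config.n_module_genes]
        module_idx = offset + take
        module_genes = [str(gene_ids[i]) for i in module_idx]
    module_cluster = "C0"

    # --- cells ---------------------------------------------------------
    rng_cells = _rng(config, "cells")
    barcodes = _barcodes(rng_cells, n_cells)
    compartment = np.array(
        ["PB"] * config.n_cells_pb + ["SF"] * config.n_cells_sf, dtype=object
    )
    cluster = np.array(
        [f"C{c}" for c in rng_cells.integers(0, config.n_clusters, size=n_cells)],
        dtype=object,
    )
    lineage = np.where(
        rng_cells.random(n_cells) < config.cd8_cell_frac, "CD8", "CD4"
    )
    size_factor = rng_cells.lognormal(0.0, config.cell_size_log_sd, size=n_cells)

    # --- QC violation cells -------------------------------------------
    rng_qc = _rng(config, "qc")
    qc_flags = pd.DataFrame(
        False, index=pd.Index(barcodes, name="barcode"), columns=list(QC_RULES)
    )
    available = rng_qc.permutation(n_cells)
    cursor_v = 0
    for rule in QC_RULES:
        rate = config.qc_violation_rates.get(rule, 0.0)
        k = int(round(rate * n_cells))
        if cursor_v + k > n_cells:
            raise ConfigError("QC violation rates exceed the number of cells")
        chosen = available[cursor_v: cursor_v + k]
        qc_flags.iloc[chosen, qc_flags.columns.get_loc(rule)] = True
        cursor_v += k
    if config.qc_violation_rates.get("high_genes", 0.0) > 0 and config.n_genes <= 4000:
        raise ConfigError("high_genes violations need n_genes > 4000")

    # --- expression ----------------------------------------------------
    rng_expr = _rng(config, "expression")
    mu = base_mean[:, None] * size_factor[None, :]
    for c_name, idx in marker_idx.items():
        cols = np.flatnonzero(cluster == c_name)
        if cols.size:
            mu[np.ix_(idx, cols)] *= config.marker_fold
    cols = np.flatnonzero(cluster == module_cluster)
    if cols.size:
        mu[np.ix_(module_idx, cols)] *= config.module_fold
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    cd8_cols = np.flatnonzero(lineage == "CD8")
    if cd8_cols.size:
        mu[gene_pos["CD8A"], cd8_cols] = 3.0
        mu[gene_pos["CD8B"], cd8_cols] = 2.0
        mu[gene_pos["CD4"], cd8_cols] = 0.05

    r = config.nb_dispersion
    lam = rng_expr.gamma(shape=r, scale=mu / r)
    counts = rng_expr.poisson(lam).astype(np.int64)

    # apply expression-level QC violations
    mito_rows = np.array([gene_pos[g] for g in mito])
    for i in np.flatnonzero(qc_flags["high_mito"].to_numpy()):
        total = counts[:, i].sum()
        mito_now = counts[mito_rows, i].sum()
        add = int(np.ceil(max(0.0, (0.30 * total - mito_now) / 0.70)))
        counts[mito_rows[0], i] += add
    keep_always = np.array([gene_pos[g] for g in ("CD3E", "CD3D", "CD3G")])
    for i in np.flatnonzero(qc_flags["low_genes"].to_numpy()):
        nz = np.flatnonzero(counts[:, i])
        keep = set(nz[np.argsort(counts[nz, i])[::-1][:100]]) | set(keep_always)
        drop = np.array([g for g in nz if g not in keep])
        if drop.size:
            counts[drop, i] = 0
    for i in np.flatnonzero(qc_flags["high_genes"].to_numpy()):
        zero = np.flatnonzero(counts[:, i] == 0)[:4001]
        counts[zero, i] = 1
    for i in np.flatnonzero(qc_flags["high_umi"].to_numpy()):
        total = counts[:, i].sum()
        factor = int(np.ceil(30_000 / max(total, 1)))
        counts[:, i] *= max(factor, 2)

    expression = ExpressionMatrix(
        sparse.csr_matrix(counts), gene_ids, barcodes
    )

    # --- TCR repertoire ------------------------------------------------
    rng_tcr = _rng(config, "tcr")
    sizes = _clone_sizes(rng_tcr, config.n_expanded_clones, config.expanded_size_mean)
    multi_beta = qc_flags["multi_beta"].to_numpy()
    pools = {
        "PB": list(rng_tcr.permutation(
            np.flatnonzero((compartment == "PB") & ~multi_beta))),
        "SF": list(rng_tcr.permutation(
            np.flatnonzero((compartment == "SF") & ~multi_beta))),
    }
    seen_cdr3: set = set()
    contigs: List[ContigRecord] = []
    clone_rows = []
    cell_clone = np.full(n_cells, "", dtype=object)

    def add_contig(cell: int, chain: str, cdr3_nt: str, productive: bool = True) -> None:
        umis = 1 + int(rng_tcr.poisson(max(config.contig_umi_mean - 1, 0.0)))
        v_locus = "TRAV" if chain == "TRA" else "TRBV"
        j_locus = "TRAJ" if chain == "TRA" else "TRBJ"
        contigs.append(
            ContigRecord(
                barcode=str(barcodes[cell]),
                chain=chain,
                cdr3_nt=cdr3_nt,
                cdr3_aa=str(Seq(cdr3_nt).translate()),
                v_gene=f"{v_locus}{1 + int(rng_tcr.integers(30))}",
                j_gene=f"{j_locus}{1 + int(rng_tcr.integers(20))}",
                productive=productive,
                umis=umis,
            )
        )

    for k, size in enumerate(sizes):
        n_alpha_chains = 2 if rng_tcr.random() < config.dual_alpha_rate else 1
        alphas = tuple(_unique_cdr3(rng_tcr, seen_cdr3) for _ in range(n_alpha_chains))
        beta = _unique_cdr3(rng_tcr, seen_cdr3)
        cid = clone_key(alphas, (beta,))
        n_sf = int((rng_tcr.random(size) < config.sf_bias).sum())
        n_pb = int(size) - n_sf
        if n_pb > len(pools["PB"]) or n_sf > len(pools["SF"]):
            raise ConfigError(
                f"expanded clone {k} needs {n_pb} PB / {n_sf} SF cells but the "
                "compartment pools are exhausted"
            )
        members = [pools["PB"].pop() for _ in range(n_pb)]
        members += [pools["SF"].pop() for _ in range(n_sf)]
        for cell in members:
            cell_clone[cell] = cid
            for a in alphas:
                add_contig(cell, "TRA", a)
            add_contig(cell, "TRB", beta)
        clone_rows.append(
            {"clone_id": cid, "size": int(size), "n_pb": n_pb, "n_sf": n_sf,
             "biased": config.sf_bias != 0.5}
        )

    # background singleton clones on every remaining cell
    for cell in sorted(pools["PB"] + pools["SF"]) + list(
        np.flatnonzero(multi_beta)
    ):
        if cell_clone[cell]:
            continue
        alpha = _unique_cdr3(rng_tcr, seen_cdr3)
        beta = _unique_cdr3(rng_tcr, seen_cdr3)
        cell_clone[cell] = clone_key((alpha,), (beta,))
        add_contig(cell, "TRA", alpha)
        add_contig(cell, "TRB", beta)
        if multi_beta[cell]:
            add_contig(cell, "TRB", _unique_cdr3(rng_tcr, seen_cdr3))
        if rng_tcr.random() < config.nonproductive_rate:
            add_contig(cell, "TRA", _unique_cdr3(rng_tcr, seen_cdr3),
                       productive=False)

    truth_clones = pd.DataFrame(
        clone_rows, columns=["clone_id", "size", "n_pb", "n_sf", "biased"]
    )

    # --- hashtag counts -------------------------------------------------
    rng_hto = _rng(config, "hto")
    tag_ids = np.asarray([f"HTO{t + 1}" for t in range(config.n_hashtags)],
                         dtype=object)
    is_doublet = rng_hto.random(n_cells) < config.doublet_rate
    first_tag = rng_hto.integers(0, config.n_hashtags, size=n_cells)
    second_tag = np.full(n_cells, -1)
    if config.n_hashtags >= 2:
        shift = 1 + rng_hto.integers(0, config.n_hashtags - 1, size=n_cells)
        second_tag = np.where(
            is_doublet, (first_tag + shift) % config.n_hashtags, -1
        )
    else:
        is_doublet[:] = False
    hto_mu = np.full((config.n_hashtags, n_cells), config.hto_background_mean)
    hto_mu[first_tag, np.arange(n_cells)] = config.hto_signal_mean
    dbl = np.flatnonzero(second_tag >= 0)
    hto_mu[second_tag[dbl], dbl] = config.hto_signal_mean
    hs = config.hto_nb_size
    hto_counts = rng_hto.poisson(rng_hto.gamma(shape=hs, scale=hto_mu / hs))
    hto = HTOCounts(sparse.csr_matrix(hto_counts.astype(np.int64)),
                    tag_ids, barcodes)
    truth_hto = pd.DataFrame(
        {
            "true_class": np.where(is_doublet, "doublet", "singlet"),
            "true_tag": [str(tag_ids[t]) for t in first_tag],
            "true_tag2": [str(tag_ids[t]) if t >= 0 else "" for t in second_tag],
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": np.char.add("AS01_", compartment.astype(str)),
            "compartment": compartment,
            "patient": "AS01",
            "cluster": cluster,
            "lineage": lineage,
            "clone_id": cell_clone,
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    truth = TruthTable(
        clones=truth_clones,
        hashtag=truth_hto,
        module_genes=module_genes,
        module_cluster=module_cluster,
        qc_violations=qc_flags,
        seed=config.seed,
    )
    return SimDataset(expression=expression, meta=meta, contigs=contigs,
                      hto=hto, truth=truth)


def generate_null_replicates(config: SimConfig, n_reps: int) -> Iterator[SimDataset]:
    """Independent null datasets (no compartment bias), seeds base_seed + r."""
    if n_reps <= 0:
        raise ConfigError("n_reps must be positive")
    if config.sf_bias != 0.5:
        raise ConfigError("null replicates require sf_bias = 0.5")
    for rep in range(n_reps):
        yield generate_dataset(replace(config, seed=config.seed + rep))


def write_dataset(ds: SimDataset, outdir) -> Dict[str, str]:
    """Write a dataset in the exact formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "contigs": out / "filtered_contig_annotations.csv",
        "meta": out / "meta.tsv",
        "hto_mtx": out / "hto.mtx",
        "hto_tags": out / "hto_ids.tsv",
        "hto_barcodes": out / "hto_barcodes.tsv",
        "truth_clones": out / "truth_clones.tsv",
        "truth_hashtag": out / "truth_hashtag.tsv",
        "truth_qc": out / "truth_qc.tsv",
        "module_genes": out / "module_genes.txt",
    }
    sio.write_expression(ds.expression, paths["mtx"], paths["features"],
                         paths["barcodes"])
    sio.write_contigs(ds.contigs, paths["contigs"])
    sio.write_meta(ds.meta, paths["meta"])
    sio.write_hto(ds.hto, paths["hto_mtx"], paths["hto_tags"],
                  paths["hto_barcodes"])
    sio.write_table(ds.truth.clones, paths["truth_clones"],
                    comments=[f"seed={ds.truth.seed}"])
    sio.write_table(ds.truth.hashtag.reset_index(), paths["truth_hashtag"],
                    comments=[f"seed={ds.truth.seed}"])
    sio.write_table(ds.truth.qc_violations.reset_index(), paths["truth_qc"],
                    comments=[f"seed={ds.truth.seed}"])
    Path(paths["module_genes"]).write_text(
        "".join(f"{g}\n" for g in ds.truth.module_genes)
    )
    return {k: str(v) for k, v in paths.items()}
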