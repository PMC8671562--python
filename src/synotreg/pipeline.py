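"""End-to-end orchestration: QC -> demultiplexing -> clonotyping ->
enrichment -> differential expression -> module scoring.

A structured YAML config drives the run; every output table carries the seed
and a config hash in a comment header, and a JSON manifest records per-stage
cell counts so the QC funnel is auditable on any dataset.  Identical config +
seed produces a byte-identical output bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import clonotype as ct
from . import hto_demux as dx
from . import expression as ex
from . import io as sio
from . import qc
from .datatypes import ConfigError
from .simulate import SimConfig, generate_dataset


_DEFAULTS = {
    "seed": 0,
    "out_dir": "results",
    "inputs": {},
    "simulate": None,
    "qc": {"preset": "AS", "drop_cd14": False, "overrides": {}},
    "demux": {"enabled": "auto", "quantile": 0.99},
    "clonotype": {"mode": "joint_gex", "min_cells": 3, "alpha": 0.05,
                  "eligibility": "either"},
    "de": {"min_pct": 0.10, "log_fc_cut": 0.25, "drop_tcr_genes": True,
           "mode": "auto", "scale_total": 10000},
    "module": {"genes_file": None, "n_bins": 24, "n_ctrl": 100},
}

_INPUT_KEYS = ("mtx", "features", "barcodes", "contigs", "meta",
               "hto_mtx", "hto_tags", "hto_barcodes")


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, value in raw.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(path) -> List[str]:
    """Return a list of 'field: value violates constraint' strings (empty = ok)."""
    try:
        cfg = load_config(path)
    except (OSError, yaml.YAMLError) as exc:
        return [f"config file unreadable or unparsable: {exc}"]
    errors: List[str] = []

    def check(cond: bool, field: str, value, constraint: str) -> None:
        if not cond:
            errors.append(f"{field} = {value!r} violates: {constraint}")

    check(isinstance(cfg["seed"], int), "seed", cfg["seed"], "must be an integer")
    sim = cfg.get("simulate")
    inputs = cfg.get("inputs") or {}
    if sim is None:
        for key in ("mtx", "features", "barcodes"):
            check(key in inputs, f"inputs.{key}", None, "required without simulate")
        for key, value in inputs.items():
            check(key in _INPUT_KEYS, f"inputs.{key}", value, "unknown input key")
            if key in _INPUT_KEYS and value is not None:
                check(Path(value).exists(), f"inputs.{key}", value, "file must exist")
        if "contigs" not in inputs:
            check(False, "inputs.contigs", None,
                  "required when clonotyping is enabled")
    else:
        try:
            SimConfig(**{**sim, "seed": cfg["seed"]}).validate()
        except (TypeError, ConfigError) as exc:
            errors.append(f"simulate: {exc}")
    alpha = cfg["clonotype"]["alpha"]
    check(0 < alpha <= 1, "clonotype.alpha", alpha, "must lie in (0, 1]")
    check(cfg["clonotype"]["min_cells"] >= 1, "clonotype.min_cells",
          cfg["clonotype"]["min_cells"], "must be >= 1")
    check(cfg["clonotype"]["mode"] in ("joint_gex", "clonality_table"),
          "clonotype.mode", cfg["clonotype"]["mode"],
          "must be joint_gex or clonality_table")
    q = cfg["demux"]["quantile"]
    check(0 < q < 1, "demux.quantile", q, "must lie strictly in (0, 1)")
    check(0 <= cfg["de"]["min_pct"] <= 1, "de.min_pct", cfg["de"]["min_pct"],
          "must lie in [0, 1]")
    check(cfg["qc"]["preset"] in ("AS", "PsA"), "qc.preset", cfg["qc"]["preset"],
          "must be AS or PsA")
    gf = cfg["module"]["genes_file"]
    if gf is not None:
        check(Path(gf).exists(), "module.genes_file", gf, "file must exist")
    return errors


def _config_hash(cfg: dict) -> str:
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]


def _load_inputs(cfg: dict) -> tuple:
    sim = cfg.get("simulate")
    if sim is not None:
        sim_cfg = SimConfig(**{**sim, "seed": cfg["seed"]})
        ds = generate_dataset(sim_cfg)
        return ds.expression, ds.meta, ds.contigs, ds.hto, ds
    inputs = cfg["inputs"]
    matrix = sio.read_expression(inputs["mtx"], inputs["features"],
                                 inputs["barcodes"])
    meta = sio.read_meta(inputs["meta"]) if inputs.get("meta") else None
    contigs = sio.read_contigs(inputs["contigs"]) if inputs.get("contigs") else []
    hto = None
    if inputs.get("hto_mtx"):
        hto = sio.read_hto(inputs["hto_mtx"], inputs["hto_tags"],
                           inputs["hto_barcodes"])
    return matrix, meta, contigs, hto, None


def run_all(config_path, out_dir: Optional[str] = None,
            seed: Optional[int] = None) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    errors = validate_config(config_path)
    if errors:
        raise ConfigError("invalid config:\n" + "\n".join(errors))
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = seed
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    header = [f"seed={cfg['seed']}", f"config_sha256={chash}"]
    manifest: dict = {"seed": cfg["seed"], "config_sha256": chash, "stages": {}}

    matrix, meta, contigs, hto, ds = _load_inputs(cfg)
    if meta is None:
        raise ConfigError("a cell metadata table is required (inputs.meta)")
    manifest["stages"]["input"] = {"n_cells": int(matrix.n_cells),
                                   "n_genes": int(matrix.n_genes)}

    # --- stage 1: expression QC (mito / gene counts / UMI) -------------
    chains = ct.collapse_chains(contigs)
    thresholds = qc.QCThresholds.preset(
        cfg["qc"]["preset"],
        drop_cd14=cfg["qc"]["drop_cd14"],
        **(cfg["qc"].get("overrides") or {}),
    )
    metrics = qc.compute_metrics(matrix, chains, cd3_genes=thresholds.cd3_genes)
    keep, rule_counts = qc.apply_filters(metrics, thresholds)
    sio.write_table(metrics.reset_index(), out / "metrics.tsv", comments=header)
    manifest["stages"]["qc"] = {
        "n_in": int(matrix.n_cells),
        "n_out": int(keep.sum()),
        "removed_by_rule": {k: int(v) for k, v in rule_counts.items()},
    }
    kept_barcodes = keep.index[keep.to_numpy()].to_numpy()

    # --- stage 2: hashtag demultiplexing (keep singlets) ---------------
    if hto is not None and cfg["demux"]["enabled"] in ("auto", True):
        calls, hto_thresholds = dx.demux(hto, q=cfg["demux"]["quantile"],
                                         random_state=cfg["seed"] % (2**31))
        sio.write_table(calls.reset_index(), out / "demux.tsv", comments=header)
        singlets = set(calls.index[calls["hto_class"] == "singlet"])
        n_before = len(kept_barcodes)
        kept_barcodes = np.array([b for b in kept_barcodes if b in singlets],
                                 dtype=object)
        manifest["stages"]["demux"] = {
            "n_in": n_before,
            "n_out": int(len(kept_barcodes)),
            "thresholds": {k: int(v) for k, v in sorted(hto_thresholds.items())},
        }

    kept_set = set(kept_barcodes)
    kept_matrix = matrix.subset_cells(
        np.array([b in kept_set for b in matrix.cell_barcodes])
    )
    kept_meta = meta.loc[[b for b in matrix.cell_barcodes if b in kept_set]]

    # --- stage 3: clonotyping and compartment enrichment ---------------
    kept_chains = {b: c for b, c in chains.items() if b in kept_set}
    assignments = ct.call_clonotypes(kept_chains, mode=cfg["clonotype"]["mode"])
    clones = ct.clone_table(assignments, kept_meta)
    sio.write_table(clones, out / "clones.tsv", comments=header)
    enrichment = ct.test_enrichment(
        clones, kept_meta,
        min_cells=cfg["clonotype"]["min_cells"],
        alpha=cfg["clonotype"]["alpha"],
        eligibility=cfg["clonotype"]["eligibility"],
    )
    sio.write_table(enrichment, out / "enrichment.tsv", comments=header)
    manifest["stages"]["clonotype"] = {
        "n_cells_clonotyped": int(len(assignments)),
        "n_clones": int(len(clones)),
        "n_eligible": int(len(enrichment)),
        "n_significant": int(enrichment["significant"].sum()) if len(enrichment) else 0,
    }

    # --- stage 4: expression statistics --------------------------------
    norm = ex.normalize(kept_matrix, scale_total=cfg["de"]["scale_total"])
    group_sf = kept_meta.index[kept_meta["compartment"] == "SF"].to_numpy()
    group_pb = kept_meta.index[kept_meta["compartment"] == "PB"].to_numpy()
    if len(group_sf) >= 3 and len(group_pb) >= 3:
        de = ex.wilcoxon_de(norm, group_sf, group_pb,
                            min_pct=cfg["de"]["min_pct"], mode=cfg["de"]["mode"])
        de_report = ex.report_filter(
            de, log_fc_cut=cfg["de"]["log_fc_cut"],
            drop_tcr_genes=cfg["de"]["drop_tcr_genes"],
        )
        sio.write_table(de, out / "de_sf_vs_pb.tsv", comments=header)
        sio.write_table(de_report, out / "de_sf_vs_pb_filtered.tsv",
                        comments=header)
        manifest["stages"]["de"] = {
            "n_tested": int(len(de)),
            "n_reported": int(len(de_report)),
            "n_significant": int((de_report["significant"]).sum())
            if len(de_report) else 0,
        }

    module_genes: List[str] = []
    if cfg["module"]["genes_file"]:
        module_genes = [
            ln.strip() for ln in Path(cfg["module"]["genes_file"]).read_text().splitlines()
            if ln.strip()
        ]
    elif ds is not None:
        module_genes = ds.truth.module_genes
    if module_genes:
        score = ex.module_score(
            norm, module_genes,
            n_bins=cfg["module"]["n_bins"], n_ctrl=cfg["module"]["n_ctrl"],
            seed=cfg["seed"],
        )
        sio.write_table(score.scores.reset_index(), out / "scores.tsv",
                        comments=header)
        manifest["stages"]["module_score"] = {
            "n_genes": len(score.module_genes), "n_cells": int(len(score.scores))
        }

    if "cluster" in kept_meta.columns and not kept_meta["cluster"].isna().any():
        ztest = ex.cluster_compartment_test(kept_meta)
        sio.write_table(ztest, out / "cluster_compartment.tsv", comments=header)
        manifest["stages"]["cluster_test"] = {"n_clusters": int(len(ztest))}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest
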