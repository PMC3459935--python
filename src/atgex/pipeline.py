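"""End-to-end orchestration: simulate -> normalize -> screen -> network -> eqtl.

A single YAML config drives all five stages.  Each stage writes its TSV
outputs into the artifact directory; a manifest records inputs, parameters
and the seed so any stage can be re-run in isolation.  Re-running with the
same config and seed reproduces every output byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eqtl as eqtl_mod
from . import ggm, io, phenotypes, qpcr, screening, simulate
from .datatypes import ExpressionSet

log = logging.getLogger("atgex.pipeline")

STAGES = ("simulate", "qpcr", "screen", "network", "eqtl")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "atgex_run",
    "log_level": "INFO",
    "simulate": {"n_subjects": 200, "sim": {}, "plates": {}, "snps": {}},
    "qpcr": {"method": "dct", "reference_gene": "GUSB", "impute_k": 10},
    "screen": {"alpha": 0.05, "design": "S4"},
    "network": {"alpha_mix": 0.5, "target_density": 0.15, "policy": "AND",
                "group_by": "sex"},
    "eqtl": {"alpha": 0.05, "upstream": 10000, "downstream": 15000},
}


def load_config(path: str | Path | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        for key, val in user.items():
            if isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> None:
    for stage in STAGES:
        if stage not in cfg:
            raise ValueError(f"config missing stage block {stage!r}")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    for key in ("genotype_file", "ct_file", "cohort_file"):
        path = cfg.get(key)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"config references missing file: {path}")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path | None = None) -> Path:
    """Run all stages; returns the artifact directory."""
    cfg = config if isinstance(config, dict) else load_config(config)
    validate_config(cfg)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.get("log_level", "INFO"))
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    seed = cfg["seed"]
    manifest = {"seed": seed, "stages": [], "parameters": cfg}

    try:
        # ---- simulate ---------------------------------------------------- #
        log.info("stage simulate")
        sc = cfg["simulate"]
        sim_cfg = simulate.SimConfig(**sc.get("sim", {}))
        plate_cfg = simulate.PlateDesign(**sc.get("plates", {}))
        snp_cfg = simulate.SnpConfig(**sc.get("snps", {}))
        truth, cohort, expr, ct, genotypes, gene_ann = simulate.simulate_study(
            sim_cfg, n_subjects=sc.get("n_subjects", 200),
            seed=_stage_seed(seed, "simulate"), plate_design=plate_cfg,
            snp_config=snp_cfg)
        io.write_ct_tsv(ct, out / "ct.tsv")
        io.write_cohort_tsv(cohort, out / "cohort.tsv")
        io.write_dose_tsv(genotypes, out / "doses.tsv")
        io.write_vcf(genotypes, out / "genotypes.vcf")
        io.write_gene_annotation_tsv(gene_ann, out / "genes.tsv")
        io.write_truth_json(truth, out / "truth.json")
        manifest["stages"].append("simulate")

        # ---- qpcr -------------------------------------------------------- #
        log.info("stage qpcr")
        qc = cfg["qpcr"]
        ct_f, report = qpcr.qc_filter_genes(ct)
        expr_norm = qpcr.normalize(ct_f, method=qc.get("method", "dct"),
                                   reference_gene=qc.get("reference_gene",
                                                         "GUSB"),
                                   impute_k=qc.get("impute_k", 10))
        io.write_expression_tsv(expr_norm, out / "expression.tsv")
        with open(out / "qc_report.json", "w") as f:
            json.dump({"removed": report.removed_genes,
                       "retained": report.retained_genes}, f, indent=1)
        manifest["stages"].append("qpcr")

        # ---- screen ------------------------------------------------------ #
        log.info("stage screen")
        cohort_d = phenotypes.derive_phenotypes(cohort)
        expr_bc = simulate.invert_delta_ct(expr_norm, ct_f)
        spec = screening.DESIGNS[cfg["screen"].get("design", "S4")]
        fits = screening.fit_gene_lmm(expr_bc, cohort_d, spec)
        contrasts = screening.cid_contrasts(fits, expr_bc)
        contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False,
                         float_format="%.6g")
        patterns = screening.classify_diet_patterns(
            contrasts, alpha=cfg["screen"].get("alpha", 0.05))
        patterns.to_csv(out / "diet_patterns.tsv", sep="\t",
                        float_format="%.6g")
        manifest["stages"].append("screen")

        # ---- network ----------------------------------------------------- #
        log.info("stage network")
        nc = cfg["network"]
        base = expr_bc.for_cid(1).T          # observations x genes
        grp = cohort_d[cohort_d["cid"] == 1].set_index("subject_id")["sex"]
        grp = grp.reindex(base.index)
        nets = ggm.infer_group_networks(
            base, grp, alpha_mix=nc.get("alpha_mix", 0.5),
            target_density=nc.get("target_density", 0.15),
            policy=nc.get("policy", "AND"))
        net_summary = {}
        for gname, net in nets.items():
            ggm.export_network(net, str(out / f"network_{gname}.graphml"))
            ggm.export_network(net, str(out / f"network_{gname}_edges.tsv"),
                               fmt="tsv")
            ggm.network_metrics(net).to_csv(out / f"network_{gname}_metrics.tsv",
                                            sep="\t", float_format="%.6g")
            net_summary[gname] = {"edges": net.n_edges,
                                  "density": net.density,
                                  "penalty": net.penalty}
        manifest["stages"].append("network")
        manifest["networks"] = net_summary

        # ---- eqtl -------------------------------------------------------- #
        log.info("stage eqtl")
        ec = cfg["eqtl"]
        genotypes_f, greport = eqtl_mod.genotype_qc(genotypes)
        pairs = eqtl_mod.map_cis_pairs(genotypes_f.annotation, gene_ann,
                                       upstream=ec.get("upstream", 10000),
                                       downstream=ec.get("downstream", 15000))
        results = eqtl_mod.eqtl_screen(expr_bc, genotypes_f, pairs, cohort_d,
                                       cid=1, alpha=ec.get("alpha", 0.05))
        results.to_csv(out / "eqtl.tsv", sep="\t", index=False,
                       float_format="%.6g")
        with open(out / "genotype_qc.json", "w") as f:
            json.dump(greport.as_dict(), f, indent=1)
        manifest["stages"].append("eqtl")
    except Exception as exc:
        manifest["failed"] = str(exc)
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, default=str)
        raise RuntimeError(
            f"pipeline failed after stages {manifest['stages']}: {exc}"
        ) from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, default=str)
    return out


def validate_io(paths: dict[str, str | Path]) -> dict[str, list[str]]:
    """Schema checks for the pipeline's input files.

    ``paths`` maps format names ('ct', 'cohort', 'doses', 'genes') to file
    paths; the report maps each to its violation list (empty = clean).
    """
    report: dict[str, list[str]] = {}
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            report[kind] = [f"file not found: {path}"]
            continue
        try:
            if kind == "ct":
                wells = pd.read_csv(path, sep="\t")
                report[kind] = io.validate_ct_table(wells)
            elif kind == "cohort":
                report[kind] = io.validate_cohort_table(
                    pd.read_csv(path, sep="\t"))
            elif kind == "doses":
                g = io.read_dose_tsv(path)
                vals = g.doses.to_numpy()
                ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
                report[kind] = ([] if ok.all()
                                else ["dose values outside {0, 1, 2, NaN}"])
            elif kind == "genes":
                io.read_gene_annotation_tsv(path)
                report[kind] = []
            else:
                report[kind] = [f"unknown format {kind!r}"]
        except Exception as exc:
            report[kind] = [f"failed to parse: {exc}"]
    return report
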