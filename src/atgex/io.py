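"""Plain-text readers and writers for the pipeline's file formats.

All tables travel as TSV; genotypes additionally as a minimal VCF (GT field
only); ground truth as JSON.  Coordinates are 1-based inclusive throughout
(the VCF convention); BED-like annotation files here carry 1-based
``cds_start``/``cds_end`` columns and are not converted.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CT_MISSING, CtSet, ExpressionSet, GenotypeSet
from .simulate import SimTruth

CT_COLUMNS = ["plate", "set", "well", "sample_id", "cid", "gene", "ct",
              "is_calibrator", "is_water"]


# ---- Ct ------------------------------------------------------------------- #

def write_ct_tsv(ct: CtSet, path: str | Path) -> None:
    ct.wells[CT_COLUMNS].to_csv(path, sep="\t", index=False)
    if ct.gene_baselines is not None:
        base_path = Path(path).with_suffix(".baselines.tsv")
        ct.gene_baselines.rename("baseline_ct").to_csv(base_path, sep="\t")


def read_ct_tsv(path: str | Path) -> CtSet:
    wells = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    wells["is_calibrator"] = wells["is_calibrator"].astype(bool)
    wells["is_water"] = wells["is_water"].astype(bool)
    baselines = None
    base_path = Path(path).with_suffix(".baselines.tsv")
    if base_path.exists():
        baselines = pd.read_csv(base_path, sep="\t", index_col=0)["baseline_ct"]
    return CtSet(wells=wells, gene_baselines=baselines)


# ---- cohort / expression -------------------------------------------------- #

def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("completer", "mets_latent", "mets"):
        if col in df.columns:
            df[col] = df[col].astype("boolean").astype(object)
    return df


def write_expression_tsv(expr: ExpressionSet, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> ExpressionSet:
    values = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionSet(values)


# ---- genotypes ------------------------------------------------------------ #

def write_dose_tsv(genotypes: GenotypeSet, path: str | Path) -> None:
    genotypes.doses.to_csv(path, sep="\t", index_label="snp")
    ann_path = Path(path).with_suffix(".annotation.tsv")
    genotypes.annotation.to_csv(ann_path, sep="\t", index_label="snp")


def read_dose_tsv(path: str | Path) -> GenotypeSet:
    doses = pd.read_csv(path, sep="\t", index_col="snp")
    ann_path = Path(path).with_suffix(".annotation.tsv")
    annotation = (pd.read_csv(ann_path, sep="\t", index_col="snp")
                  if ann_path.exists() else
                  pd.DataFrame(index=doses.index))
    if "chrom" in annotation.columns:
        annotation["chrom"] = annotation["chrom"].astype(str)
    return GenotypeSet(doses=doses, annotation=annotation)


def write_vcf(genotypes: GenotypeSet, path: str | Path) -> None:
    """Minimal VCF 4.2 with a GT field only; missing doses become ./."""
    subjects = list(genotypes.doses.columns)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    ann = genotypes.annotation
    order = ann.sort_values(["chrom", "pos"]).index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        for snp in order:
            row = ann.loc[snp]
            doses = genotypes.doses.loc[snp]
            gts = [gt_map.get(float(d), "./.") if not pd.isna(d) else "./."
                   for d in doses]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                     f"{row.get('major', 'G')}\t{row.get('minor', 'A')}\t.\t"
                     f"PASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str | Path) -> GenotypeSet:
    """Read a GT-only VCF back into a dose matrix (ALT allele dose)."""
    rows, ann_rows, ids = [], [], []
    subjects = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                subjects = fields[9:]
                continue
            chrom, pos, snp, ref, alt = fields[:5]
            doses = []
            for gt in fields[9:]:
                gt = gt.split(":")[0]
                if "." in gt:
                    doses.append(np.nan)
                else:
                    doses.append(float(sum(int(a) for a in
                                           gt.replace("|", "/").split("/"))))
            ids.append(snp)
            rows.append(doses)
            ann_rows.append({"chrom": str(chrom), "pos": int(pos),
                             "minor": alt, "major": ref})
    doses = pd.DataFrame(rows, index=ids, columns=subjects)
    annotation = pd.DataFrame(ann_rows, index=ids)
    return GenotypeSet(doses=doses, annotation=annotation)


# ---- gene annotation ------------------------------------------------------ #

def write_gene_annotation_tsv(gene_ann: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "chrom", "strand", "cds_start", "cds_end"]
    gene_ann[cols].to_csv(path, sep="\t", index=False)


def read_gene_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "chrom", "strand", "cds_start", "cds_end"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    bad = df[df["cds_start"] > df["cds_end"]]
    if len(bad):
        raise ValueError(f"cds_start > cds_end for genes: {bad['gene'].tolist()}")
    return df


# ---- truth ---------------------------------------------------------------- #

def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "genes": truth.genes,
        "groups": truth.groups,
        "precision_by_group": {g: m.tolist()
                               for g, m in truth.precision_by_group.items()},
        "shared_edges": sorted(map(list, truth.shared_edges)),
        "sex_effect": truth.sex_effect,
        "bmi_slope": truth.bmi_slope,
        "diet_pattern": truth.diet_pattern,
        "mets_shift": truth.mets_shift,
        "eqtl_effect": {f"{s}|{g}": b
                        for (s, g), b in truth.eqtl_effect.items()},
        "config": vars(truth.config),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=lambda o: list(o)
                  if isinstance(o, tuple) else o)


# ---- validation ----------------------------------------------------------- #

def validate_ct_table(wells: pd.DataFrame) -> list[str]:
    """Schema violations of a long-format Ct table (empty list = clean)."""
    issues = []
    missing = set(CT_COLUMNS) - set(wells.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    ct = wells["ct"]
    bad = wells[(ct != CT_MISSING) & ((ct <= 0) | (ct > 40))]
    for r in bad.itertuples():
        issues.append(f"Ct out of range (0, 40]: plate {r.plate} well "
                      f"{r.well} gene {r.gene} ct {r.ct}")
    for plate, grp in wells.groupby("plate"):
        if not grp["is_calibrator"].any():
            issues.append(f"plate {plate} has no calibrator well")
        if not grp["is_water"].any():
            issues.append(f"plate {plate} has no water well")
    samples = wells[~wells["is_calibrator"] & ~wells["is_water"]]
    dup = samples.duplicated(subset=["set", "gene", "sample_id", "cid"])
    for r in samples[dup].itertuples():
        issues.append(f"duplicate (gene, sample, cid) in set {r.set}: "
                      f"{r.gene}, {r.sample_id}, cid {r.cid}")
    return issues


def validate_cohort_table(cohort: pd.DataFrame) -> list[str]:
    issues = []
    needed = {"subject_id", "cid", "centre", "sex", "weight", "height"}
    missing = needed - set(cohort.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    if (cohort["weight"] <= 0).any():
        issues.append("non-positive weight values")
    bad_sex = set(cohort["sex"].unique()) - {"M", "F"}
    if bad_sex:
        issues.append(f"unknown sex codes: {sorted(bad_sex)}")
    for sid, sub in cohort.groupby("subject_id"):
        if sub["sex"].nunique() > 1 or sub["centre"].nunique() > 1:
            issues.append(f"subject {sid}: sex/centre vary across visits")
    return issues
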