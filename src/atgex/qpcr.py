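"""Plate QC, Ct normalization and missing-value imputation.

Four normalization routes are supported, mirroring common practice for
microfluidic RT-qPCR panels:

* ``dct`` — the 2^-dCt method against a single reference transcript,
* ``quantile`` — force identical per-sample distributions,
* ``rank_invariant`` — monotone mapping fitted through rank-stable genes,
* ``raw`` — -Ct, sign-flipped so larger means more transcript (baseline).

Reference-gene candidates are ranked with the geNorm stability measure M
(mean standard deviation of pairwise log-ratios; lower is more stable), and
methods are compared by the coefficient of variation of the shared
calibrator sample across plates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .datatypes import CT_MISSING, CtSet, ExpressionSet, sample_key

NORMALIZATION_METHODS = ("raw", "dct", "quantile", "rank_invariant")


@dataclass
class QcReport:
    removed_genes: dict[str, str] = field(default_factory=dict)  # gene -> reason
    retained_genes: list[str] = field(default_factory=list)
    details: dict[str, dict] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": g, "reason": r} for g, r in self.removed_genes.items()])


# --------------------------------------------------------------------------- #
# QC                                                                          #
# --------------------------------------------------------------------------- #

def qc_filter_genes(ct: CtSet, high_ct_threshold: float = 30.0,
                    calibrator_outlier_fraction: float = 0.20,
                    bad_well_majority: float = 0.50,
                    min_calibrator_replicates: int = 5,
                    ) -> tuple[CtSet, QcReport]:
    """Remove genes with unreliable amplification.

    A gene is dropped when (a) more than ``bad_well_majority`` of its sample
    wells read above ``high_ct_threshold`` cycles or the absent sentinel
    (too low or inconsistent expression), or (b) more than
    ``calibrator_outlier_fraction`` of its calibrator replicates across
    plates are outliers, where an outlier lies beyond median +/- 3 MAD
    (the rule needs replication and is skipped below
    ``min_calibrator_replicates`` plates).
    """
    report = QcReport()
    samples = ct.sample_wells()
    calib = ct.calibrator_wells()

    if calib.empty:
        raise ValueError("no calibrator wells present; cannot assess outliers")

    for gene, grp in samples.groupby("gene"):
        vals = grp["ct"].to_numpy()
        bad = (vals == CT_MISSING) | (vals > high_ct_threshold)
        frac_bad = bad.mean() if len(vals) else 1.0
        if frac_bad > bad_well_majority:
            reason = "absent" if (vals == CT_MISSING).all() else "high_or_absent_ct"
            report.removed_genes[gene] = reason
            report.details[gene] = {"fraction_bad_wells": float(frac_bad)}

    for gene, grp in calib.groupby("gene"):
        if gene in report.removed_genes:
            continue
        vals = grp.loc[grp["ct"] != CT_MISSING, "ct"].to_numpy()
        if len(vals) < min_calibrator_replicates:
            continue
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:
            out_frac = float(np.mean(vals != med))
        else:
            out_frac = float(np.mean(np.abs(vals - med) > 3 * mad))
        if out_frac > calibrator_outlier_fraction:
            report.removed_genes[gene] = "calibrator_outliers"
            report.details[gene] = {"calibrator_outlier_fraction": out_frac}

    keep = [g for g in ct.wells["gene"].unique() if g not in report.removed_genes]
    if not keep:
        raise ValueError("QC removed every gene; check input Ct data")
    report.retained_genes = sorted(keep)
    filtered = CtSet(wells=ct.wells[ct.wells["gene"].isin(keep)].copy(),
                     gene_baselines=ct.gene_baselines,
                     meta=dict(ct.meta))
    return filtered, report


# --------------------------------------------------------------------------- #
# normalization                                                               #
# --------------------------------------------------------------------------- #

def _ct_matrix(ct: CtSet) -> pd.DataFrame:
    """Genes x sample-visit matrix of sample-well Ct (sentinel -> NaN)."""
    sw = ct.sample_wells().copy()
    sw["sample"] = [sample_key(s, c) for s, c in zip(sw["sample_id"], sw["cid"])]
    mat = sw.pivot_table(index="gene", columns="sample", values="ct",
                         aggfunc="mean")
    return mat.where(mat != CT_MISSING)


def delta_ct_normalize(ct: CtSet, reference_gene: str) -> ExpressionSet:
    """2^-dCt relative quantification against a single reference gene.

    log2 expression = -(Ct_gene - Ct_reference) per sample-visit.  Any
    per-plate additive Ct shift cancels because it hits the reference and
    target wells of the same sample equally.  Samples whose reference well
    is absent are flagged missing for every gene.
    """
    mat = _ct_matrix(ct)
    if reference_gene not in mat.index:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    ref = mat.loc[reference_gene]
    values = -(mat.drop(index=reference_gene).sub(ref, axis=1))
    ref_missing = ref.isna()
    if ref_missing.any():
        values.loc[:, ref_missing[values.columns].to_numpy()] = np.nan
    return ExpressionSet(values, provenance={"method": "dct",
                                             "reference_gene": reference_gene})


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (row-mean) quantile distribution.

    Missing entries are excluded from rank computation and re-inserted as
    missing afterwards; ties share the average of their target quantiles.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    if m.isna().all(axis=0).any():
        bad = m.columns[m.isna().all(axis=0)].tolist()
        raise ValueError(f"columns entirely missing: {bad}")

    ranks = m.rank(axis=0, method="average", na_option="keep")
    # reference distribution: mean of column-sorted values at each quantile,
    # computed on complete rows' grid via per-column sorted interpolation
    sorted_cols = np.sort(m.to_numpy(), axis=0)
    # rows that are all-NaN across columns contribute nothing
    mean_sorted = np.nanmean(sorted_cols, axis=1)
    n_valid = m.notna().sum(axis=0)

    out = m.copy()
    grid = np.arange(1, m.shape[0] + 1, dtype=float)
    for j, col in enumerate(m.columns):
        nv = n_valid[col]
        if nv == 0:
            continue
        # quantile positions of this column's ranks on the reference grid
        ref = mean_sorted[~np.isnan(mean_sorted)][:]
        # map rank r in [1, nv] -> position on the pooled grid
        pos = (ranks[col] - 1) / max(nv - 1, 1) * (len(ref) - 1)
        vals = np.interp(pos, np.arange(len(ref)), ref)
        out[col] = np.where(ranks[col].isna(), np.nan, vals)
    return out


def rank_invariant_normalize(m: pd.DataFrame,
                             reference_profile: pd.Series | None = None,
                             rank_tolerance: float = 0.05,
                             min_invariant: int = 5,
                             lowess_frac: float = 0.5) -> pd.DataFrame:
    """Normalize each column through its rank-invariant gene set.

    Genes whose rank in a column differs from their rank in the reference
    profile by at most ``rank_tolerance`` x (number of genes) form the
    invariant set; a monotone smooth mapping (LOWESS, isotonicized) fitted
    on (column value -> reference value) over that set is applied to all
    genes of the column.  The reference defaults to the per-gene median
    pseudo-sample.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if reference_profile is None:
        reference_profile = m.median(axis=1)
    ref_rank = reference_profile.rank()
    n = len(m.index)
    tol = rank_tolerance * n

    out = m.copy()
    for col in m.columns:
        colvals = m[col]
        col_rank = colvals.rank()
        invariant = (col_rank - ref_rank).abs() <= tol
        invariant &= colvals.notna() & reference_profile.notna()
        if invariant.sum() < min_invariant:
            raise ValueError(
                f"column {col!r}: invariant set of size {int(invariant.sum())} "
                f"< minimum {min_invariant}")
        x = colvals[invariant].to_numpy()
        y = reference_profile[invariant].to_numpy()
        if np.allclose(x, y):
            continue
        order = np.argsort(x)
        fit = lowess(y[order], x[order], frac=lowess_frac, return_sorted=True)
        fx, fy = fit[:, 0], np.maximum.accumulate(fit[:, 1])  # enforce monotone
        out[col] = np.interp(colvals.to_numpy(), fx, fy,
                             left=fy[0] + (colvals.min() - fx[0]),
                             right=fy[-1] + (colvals.max() - fx[-1]))
        out.loc[colvals.isna(), col] = np.nan
    return out


# --------------------------------------------------------------------------- #
# reference-gene ranking (geNorm)                                             #
# --------------------------------------------------------------------------- #

def genorm_rank(m: pd.DataFrame, candidates: list[str],
                max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Rank candidate reference genes by the geNorm stability value M.

    For candidates j, k the pairwise variation V_jk is the standard
    deviation over samples of their log2 ratio (difference on the log2
    scale); M_j is the mean of V_jk over k != j.  The least stable
    (highest M) candidate is dropped iteratively; the returned table lists
    each candidate with its M at the round it was dropped and the drop
    order (order 1 = dropped first = least stable; the two survivors share
    the final round).
    """
    if len(candidates) < 3:
        raise ValueError("geNorm needs at least 3 candidate genes")
    missing = [g for g in candidates if g not in m.index]
    if missing:
        raise ValueError(f"candidates not in matrix: {missing}")

    usable = []
    for g in candidates:
        if m.loc[g].isna().mean() > max_missing_fraction:
            continue
        usable.append(g)
    if len(usable) < 3:
        raise ValueError("fewer than 3 candidates with sufficient data")

    if m.loc[usable].notna().sum(axis=1).min() < 2:
        raise ValueError("geNorm needs at least 2 samples per candidate")

    remaining = list(usable)
    records = []
    order = 0
    while len(remaining) > 2:
        mvals = _genorm_m(m, remaining)
        worst = max(remaining, key=lambda g: mvals[g])
        order += 1
        records.append({"gene": worst, "M": mvals[worst], "drop_order": order})
        remaining.remove(worst)
    mvals = _genorm_m(m, remaining)
    for g in sorted(remaining, key=lambda g: -mvals[g]):
        order += 1
        records.append({"gene": g, "M": mvals[g], "drop_order": order})
    table = pd.DataFrame(records).set_index("gene")
    table["rank"] = len(table) - table["drop_order"] + 1  # rank 1 = most stable
    return table.sort_values("rank")


def _genorm_m(m: pd.DataFrame, genes: list[str]) -> dict[str, float]:
    vals = {}
    for g in genes:
        vs = []
        for h in genes:
            if h == g:
                continue
            ratio = m.loc[g] - m.loc[h]
            vs.append(float(ratio.std(ddof=1)))
        vals[g] = float(np.mean(vs))
    return vals


# --------------------------------------------------------------------------- #
# calibrator CV method comparison                                             #
# --------------------------------------------------------------------------- #

def _calibrator_matrix(ct: CtSet) -> pd.DataFrame:
    """Genes x plates matrix of calibrator Ct (sentinel -> NaN)."""
    calib = ct.calibrator_wells()
    mat = calib.pivot_table(index="gene", columns="plate", values="ct",
                            aggfunc="mean")
    return mat.where(mat != CT_MISSING)


def calibrator_cv(ct: CtSet, methods: list[str] | None = None,
                  reference_gene: str = "GUSB") -> pd.Series:
    """Mean per-gene coefficient of variation of the calibrator across plates.

    Each method normalizes the calibrator's per-plate profiles; the CV of
    the resulting linear-scale expression (2^log2x) is computed per gene
    across plates and averaged over genes.  Lower CV = better removal of
    inter-plate variation.  ``raw`` (the unnormalized Ct converted to
    linear scale) serves as the baseline.
    """
    methods = methods or list(NORMALIZATION_METHODS)
    unknown = set(methods) - set(NORMALIZATION_METHODS)
    if unknown:
        raise ValueError(f"unknown normalization methods: {sorted(unknown)}")

    cal = _calibrator_matrix(ct)
    if cal.shape[1] < 2:
        raise ValueError("calibrator must be measured on at least 2 plates")

    out = {}
    for method in methods:
        if method == "raw":
            log2x = -cal
        elif method == "dct":
            if reference_gene not in cal.index:
                raise ValueError(f"reference gene {reference_gene!r} missing "
                                 "from calibrator wells")
            log2x = -(cal.drop(index=reference_gene).sub(cal.loc[reference_gene],
                                                         axis=1))
        elif method == "quantile":
            log2x = -quantile_normalize(cal)
        elif method == "rank_invariant":
            log2x = -rank_invariant_normalize(cal)
        lin = np.power(2.0, log2x)
        cv = lin.std(axis=1, ddof=1) / lin.mean(axis=1)
        out[method] = float(cv.mean())
    return pd.Series(out, name="calibrator_cv")


# --------------------------------------------------------------------------- #
# imputation                                                                  #
# --------------------------------------------------------------------------- #

def knn_impute(m: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing entries with the distance-weighted mean of the k nearest
    genes (Euclidean distance over shared samples)."""
    if m.isna().all(axis=1).any():
        bad = m.index[m.isna().all(axis=1)].tolist()
        raise ValueError(f"genes missing everywhere cannot be imputed: {bad}")
    if not m.isna().to_numpy().any():
        return m.copy()
    imputer = KNNImputer(n_neighbors=min(k, max(len(m) - 1, 1)),
                         weights="distance")
    # genes are rows: KNNImputer finds neighbours among rows
    filled = imputer.fit_transform(m.to_numpy())
    return pd.DataFrame(filled, index=m.index, columns=m.columns)


def normalize(ct: CtSet, method: str = "dct",
              reference_gene: str = "GUSB", impute_k: int | None = 10,
              ) -> ExpressionSet:
    """One-stop normalization front-end used by the CLI.

    Runs the chosen method on the sample wells and optionally imputes
    remaining missing values with :func:`knn_impute`.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{NORMALIZATION_METHODS}")
    if method == "dct":
        es = delta_ct_normalize(ct, reference_gene)
    else:
        mat = _ct_matrix(ct)
        if method == "raw":
            vals = -mat
        elif method == "quantile":
            vals = -quantile_normalize(mat)
        else:
            vals = -rank_invariant_normalize(mat)
        es = ExpressionSet(vals, provenance={"method": method})
    all_missing = es.values.columns[es.values.isna().all(axis=0)]
    if len(all_missing):
        # samples with no usable wells (e.g. absent reference gene) cannot
        # be imputed gene-wise; drop them and record it
        es = ExpressionSet(es.values.drop(columns=all_missing),
                           provenance={**es.provenance,
                                       "dropped_samples": list(all_missing)})
    if impute_k and es.values.isna().to_numpy().any():
        es = ExpressionSet(knn_impute(es.values, k=impute_k),
                           provenance={**es.provenance, "imputed_knn_k": impute_k})
    return es
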