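"""cis-eQTL mapping: SNP selection, genotype QC and allele-dose association.

SNPs are mapped to genes through a strand-aware cis window around the
coding sequence (10 kb upstream, 15 kb downstream by default), filtered on
call rate (>= 95%) and Hardy-Weinberg equilibrium (chi-square P > 0.05),
and tested for a linear log-additive allele-dose effect on log2 expression
with sex (and optionally BMI) as fixed covariates and centre as a random
intercept.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionSet, GenotypeSet
from .screening import DesignSpec, bh_adjust, fit_gene_lmm

CALL_RATE_MIN = 0.95
HWE_ALPHA = 0.05
UPSTREAM_DEFAULT = 10_000
DOWNSTREAM_DEFAULT = 15_000


# --------------------------------------------------------------------------- #
# cis windows                                                                 #
# --------------------------------------------------------------------------- #

def cis_window(cds_start: int, cds_end: int, strand: str,
               upstream: int = UPSTREAM_DEFAULT,
               downstream: int = DOWNSTREAM_DEFAULT) -> tuple[int, int]:
    """Closed genomic interval around a coding sequence.

    On the + strand the window runs from ``cds_start - upstream`` to
    ``cds_end + downstream``; on the - strand the up/downstream extensions
    are mirrored.
    """
    if strand == "+":
        return cds_start - upstream, cds_end + downstream
    if strand == "-":
        return cds_start - downstream, cds_end + upstream
    raise ValueError(f"unknown strand {strand!r}")


def map_cis_pairs(snp_annotation: pd.DataFrame, gene_annotation: pd.DataFrame,
                  upstream: int = UPSTREAM_DEFAULT,
                  downstream: int = DOWNSTREAM_DEFAULT) -> pd.DataFrame:
    """SNP-gene pairs whose SNP lies in the gene's cis window.

    ``snp_annotation`` is indexed by SNP id with columns ``chrom, pos``;
    ``gene_annotation`` has columns ``gene, chrom, strand, cds_start,
    cds_end`` (1-based inclusive).  Boundaries are inclusive.
    """
    rows = []
    for g in gene_annotation.itertuples():
        lo, hi = cis_window(g.cds_start, g.cds_end, g.strand,
                            upstream, downstream)
        hits = snp_annotation[
            (snp_annotation["chrom"].astype(str) == str(g.chrom))
            & (snp_annotation["pos"] >= lo) & (snp_annotation["pos"] <= hi)]
        for snp in hits.index:
            rows.append({"snp": snp, "gene": g.gene,
                         "distance": int(hits.loc[snp, "pos"]) - g.cds_start})
    return pd.DataFrame(rows, columns=["snp", "gene", "distance"])


# --------------------------------------------------------------------------- #
# genotype QC                                                                 #
# --------------------------------------------------------------------------- #

def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df) goodness-of-fit test of Hardy-Weinberg equilibrium.

    Expected genotype counts derive from the estimated allele frequency;
    returns NaN for monomorphic SNPs (the test is undefined).
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return float("nan")
    exp = np.array([n * p ** 2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact (Wigginton-style mid-less) Hardy-Weinberg test by enumeration
    of heterozygote counts conditional on the allele counts."""
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    hets = range(rare % 2, rare + 1, 2)

    def log_prob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        from scipy.special import gammaln
        return (gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(h + 1)
                - gammaln(hom_c + 1) + h * np.log(2)
                + gammaln(rare + 1) + gammaln(2 * n - rare + 1)
                - gammaln(2 * n + 1))

    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_ab)]
    return float(probs[probs <= p_obs + 1e-12].sum())


@dataclass
class GenotypeQcReport:
    n_input: int
    n_retained: int
    removed_low_call: list[str]
    removed_hwe: list[str]

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "removed_low_call": self.removed_low_call,
                "removed_hwe": self.removed_hwe}


def genotype_qc(genotypes: GenotypeSet, call_rate_min: float = CALL_RATE_MIN,
                hwe_alpha: float = HWE_ALPHA,
                ) -> tuple[GenotypeSet, GenotypeQcReport]:
    """Retain SNPs with call rate >= 95% and Hardy-Weinberg P > 0.05.

    Both boundaries follow the filter conventions: the call-rate cutoff is
    inclusive, the HWE cutoff is strict (P must exceed alpha).  Monomorphic
    SNPs (HWE undefined) are retained by call rate alone.
    """
    call = genotypes.call_rate()
    low_call = [s for s in genotypes.doses.index if call[s] < call_rate_min]
    removed_hwe = []
    for snp in genotypes.doses.index:
        if snp in low_call:
            continue
        p = hwe_test(*genotypes.genotype_counts(snp))
        if not np.isnan(p) and p <= hwe_alpha:
            removed_hwe.append(snp)
    drop = set(low_call) | set(removed_hwe)
    keep = [s for s in genotypes.doses.index if s not in drop]
    report = GenotypeQcReport(n_input=len(genotypes.doses),
                              n_retained=len(keep),
                              removed_low_call=low_call,
                              removed_hwe=removed_hwe)
    filtered = GenotypeSet(doses=genotypes.doses.loc[keep],
                           annotation=genotypes.annotation.loc[keep])
    return filtered, report


# --------------------------------------------------------------------------- #
# association                                                                 #
# --------------------------------------------------------------------------- #

def fit_eqtl(expr_values: pd.Series, dose: pd.Series, cohort: pd.DataFrame,
             cid: int = 1, include_bmi: bool = False,
             ) -> dict[str, float] | None:
    """Allele-dose association of one gene with one SNP at one visit.

    Log2 expression (indexed by subject) is regressed on the minor-allele
    dose with sex (and optionally BMI) as fixed covariates and centre as a
    random intercept.  Missing doses are dropped.  Returns None (skipped)
    when fewer than two dose levels are observed.
    """
    sub = cohort[cohort["cid"] == cid].set_index("subject_id")
    common = expr_values.index.intersection(dose.index).intersection(sub.index)
    d = dose[common].dropna()
    common = d.index
    if d.nunique() < 2:
        return None

    df = sub.loc[common].rename_axis("subject_id").reset_index()
    df["dose"] = d.to_numpy()
    df["cid"] = cid
    if include_bmi and "bmi" not in df.columns:
        df["bmi"] = df["weight"] / df["height"] ** 2
    fixed = ["dose", "sex"] + (["bmi"] if include_bmi else [])
    spec = DesignSpec(fixed=fixed, random=("centre",), name="eqtl")

    es = ExpressionSet(pd.DataFrame(
        [expr_values[common].to_numpy()], index=["y"],
        columns=[f"{s}:{cid}" for s in common]))
    fit = fit_gene_lmm(es, df, spec)["y"]
    if fit.error:
        return None
    return {"beta": fit.term_estimate("dose"),
            "se": float(fit.bse[fit.term_columns["dose"][0]]),
            "p": fit.term_pvalue("dose"), "n": fit.n_obs}


def eqtl_screen(expr: ExpressionSet, genotypes: GenotypeSet,
                pairs: pd.DataFrame, cohort: pd.DataFrame, cid: int = 1,
                include_bmi: bool = False, alpha: float = 0.05,
                ) -> pd.DataFrame:
    """Run :func:`fit_eqtl` over a SNP-gene pair table and BH-adjust."""
    mat = expr.for_cid(cid)
    rows = []
    for pr in pairs.itertuples():
        if pr.gene not in mat.index or pr.snp not in genotypes.doses.index:
            continue
        res = fit_eqtl(mat.loc[pr.gene], genotypes.doses.loc[pr.snp],
                       cohort, cid=cid, include_bmi=include_bmi)
        if res is None:
            continue
        rows.append({"snp": pr.snp, "gene": pr.gene, "cid": cid, **res})
    table = pd.DataFrame(rows)
    if not table.empty:
        q, rej = bh_adjust(table["p"], alpha)
        table["q"], table["significant"] = q, rej
    return table


def eqtl_persistence(results_by_cid: dict[int, pd.DataFrame],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Pairs BH-significant at baseline that stay significant at both
    follow-up visits."""
    if 1 not in results_by_cid:
        raise ValueError("baseline (cid=1) results required")

    def sig_pairs(t):
        if t.empty:
            return set()
        return set(map(tuple, t.loc[t["significant"], ["snp", "gene"]]
                       .to_numpy()))

    base = results_by_cid[1]
    keep = sig_pairs(base)
    for cid in (2, 3):
        if cid in results_by_cid:
            keep &= sig_pairs(results_by_cid[cid])
    if base.empty:
        return base
    mask = [tuple(x) in keep for x in base[["snp", "gene"]].to_numpy()]
    return base[mask].reset_index(drop=True)


def delta_association(expr: ExpressionSet, genotypes: GenotypeSet,
                      pairs: pd.DataFrame, cohort: pd.DataFrame,
                      cid_from: int = 1, cid_to: int = 2,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Dose association with within-subject diet-induced expression changes.

    The change score log2(expression at cid_to / at cid_from) replaces the
    expression level in the same mixed-model contract as :func:`fit_eqtl`.
    """
    a, b = expr.for_cid(cid_from), expr.for_cid(cid_to)
    common = a.columns.intersection(b.columns)
    delta = b[common] - a[common]
    delta_es = ExpressionSet(
        delta.rename(columns={s: f"{s}:{cid_from}" for s in common}))
    return eqtl_screen(delta_es, genotypes, pairs, cohort, cid=cid_from,
                       alpha=alpha)


def sex_genotype_independence(table: np.ndarray) -> dict[str, float | str]:
    """Test independence of sex and genotype in a 2 x 3 count table.

    Uses the chi-square test; switches to the Fisher-Freeman-Halton exact
    backend when any expected cell count falls below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2 x 3 sex-by-genotype table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("table has a zero margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        return {"p": _fisher_rxc(t), "method": "fisher_exact"}
    chi2, p = _chi2_independence(t, expected)
    return {"p": p, "chi2": chi2, "method": "chi2"}


def _chi2_independence(t: np.ndarray, expected: np.ndarray,
                       ) -> tuple[float, float]:
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df))


def _fisher_rxc(t: np.ndarray) -> float:
    """Exact Freeman-Halton test for a 2 x 3 table by enumeration of all
    tables with the observed margins."""
    from scipy.special import gammaln

    t = t.astype(int)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()

    def log_prob(a, b, cc):
        cells = np.array([a, b, cc, c[0] - a, c[1] - b, c[2] - cc])
        if np.any(cells < 0):
            return None
        return (gammaln(r + 1).sum() + gammaln(c + 1).sum()
                - gammaln(n + 1) - gammaln(cells + 1).sum())

    obs = log_prob(t[0, 0], t[0, 1], t[0, 2])
    total = 0.0
    for a in range(min(r[0], c[0]) + 1):
        for b in range(min(r[0] - a, c[1]) + 1):
            cc = r[0] - a - b
            lp = log_prob(a, b, cc)
            if lp is not None and lp <= obs + 1e-12:
                total += np.exp(lp)
    return float(min(total, 1.0))
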