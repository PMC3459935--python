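"""Gene-by-gene linear mixed-effect screening.

The basic model regresses log2 expression on fixed clinical terms (visit,
sex, metabolic-syndrome status, weight, BMI, diet arm, ...) with centre —
and, for repeated-measure designs, subject — as random intercepts, fitted
by REML.  Visit contrasts use a Tukey (studentized-range) family-wise
adjustment on model-based standard errors; across genes the
Benjamini-Hochberg step-up procedure controls the false discovery rate at
5%.

The module owns design construction, contrast arithmetic and the
screening / classification logic; the REML optimizer is statsmodels'
``MixedLM``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionSet, split_sample_key

#: visit-contrast labels: baseline vs end of LCD, end of LCD vs end of WMD,
#: baseline vs end of WMD
CONTRASTS = ("bas_lcd", "lcd_wmd", "bas_wmd")

# categorical fixed terms: (cohort column, baseline level)
_CATEGORICAL = {
    "cid": ("cid", 1),
    "sex": ("sex", "M"),
    "mets": ("mets", False),
    "diet": ("diet_arm", 1),
    "group": ("weight_change_group", "loss"),
}
_CONTINUOUS = {"weight": "weight", "bmi": "bmi", "fat_mass": "fat_mass",
               "weight_change": "weight_change", "dose": "dose"}


@dataclass
class DesignSpec:
    """One regression equation of the screen.

    ``fixed`` lists model terms in order; categorical terms are dummy-coded
    against a fixed baseline (cid=1, sex=M, mets=False, diet arm 1,
    weight-change group 'loss').  ``random`` may contain 'centre' and
    'subject'.  ``subset`` filters the cohort rows (e.g. one sex, one
    visit) before fitting.  ``log_covariates`` are skewed clinical columns
    entered on the log scale.
    """

    fixed: Sequence[str]
    random: Sequence[str] = ("centre",)
    subset: dict | None = None
    log_covariates: Sequence[str] = ()
    name: str = ""

    def __post_init__(self):
        for t in self.fixed:
            if t not in _CATEGORICAL and t not in _CONTINUOUS:
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random:
            if t not in ("centre", "subject"):
                raise ValueError(f"unknown random term {t!r}")


#: Preconfigured screen equations, named after the analyses they drive.
DESIGNS = {
    # visit effect with repeated measures; weight optionally added
    "S4": DesignSpec(fixed=["cid"], random=("centre", "subject"), name="S4"),
    "S4w": DesignSpec(fixed=["cid", "weight"], random=("centre", "subject"),
                      name="S4w"),
    # end-of-intervention regulation, diet arm as fixed effect
    "S5": DesignSpec(fixed=["cid", "diet"], random=("centre", "subject"),
                     name="S5"),
    # weight-regain/loss markers on CID3/CID2 change scores
    "S6": DesignSpec(fixed=["group", "diet"], random=("centre",), name="S6"),
    # sexual dimorphism at one visit, optionally fat-mass adjusted
    "S7": DesignSpec(fixed=["sex"], random=("centre",), name="S7"),
    "S7f": DesignSpec(fixed=["sex", "fat_mass"], random=("centre",), name="S7f"),
    # metabolic-syndrome contrast within sex
    "S8": DesignSpec(fixed=["mets"], random=("centre",), name="S8"),
    # BMI dependency per visit (diet added at CID3 by the screen itself)
    "S9": DesignSpec(fixed=["bmi"], random=("centre",), name="S9"),
    # model basis: sex + metabolic syndrome, centre random
    "basis": DesignSpec(fixed=["sex", "mets"], random=("centre",), name="basis"),
}


@dataclass
class GeneFit:
    gene: str
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    df_resid: float
    n_obs: int
    converged: bool
    singular: bool
    term_columns: dict[str, list[str]]
    error: str | None = None

    def term_pvalue(self, term: str) -> float:
        """Wald test of a fixed term (t for one column, F for several),
        with residual-based degrees of freedom."""
        cols = self.term_columns.get(term, [])
        if not cols:
            raise KeyError(f"term {term!r} not in the fitted design")
        if len(cols) == 1:
            tval = self.params[cols[0]] / self.bse[cols[0]]
            return float(2 * stats.t.sf(abs(tval), self.df_resid))
        b = self.params[cols].to_numpy()
        v = self.cov.loc[cols, cols].to_numpy()
        w = float(b @ np.linalg.solve(v, b)) / len(cols)
        return float(stats.f.sf(w, len(cols), self.df_resid))

    def term_estimate(self, term: str) -> float:
        cols = self.term_columns[term]
        if len(cols) != 1:
            raise ValueError(f"term {term!r} has {len(cols)} columns")
        return float(self.params[cols[0]])


# --------------------------------------------------------------------------- #
# design construction                                                         #
# --------------------------------------------------------------------------- #

def _assemble(expr: ExpressionSet, cohort: pd.DataFrame,
              spec: DesignSpec) -> pd.DataFrame:
    """Long table of one row per modelled sample-visit with all covariates."""
    df = cohort.copy()
    if "bmi" in [t for t in spec.fixed] and "bmi" not in df.columns:
        df["bmi"] = df["weight"] / df["height"] ** 2
    if spec.subset:
        for col, val in spec.subset.items():
            df = df[df[col] == val]
    for col in spec.log_covariates:
        df[col] = np.log(df[col])
    df = df.set_index(
        df["subject_id"].astype(str) + ":" + df["cid"].astype(str))
    keep = df.index.intersection(expr.samples)
    return df.loc[keep]


def _build_fixed(df: pd.DataFrame, spec: DesignSpec,
                 ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    cols = {"Intercept": np.ones(len(df))}
    term_columns: dict[str, list[str]] = {}
    for term in spec.fixed:
        if term in _CATEGORICAL:
            src, baseline = _CATEGORICAL[term]
            levels = [l for l in sorted(df[src].unique(), key=str)
                      if l != baseline]
            names = []
            for lev in levels:
                name = f"{term}[{lev}]"
                cols[name] = (df[src] == lev).to_numpy(float)
                names.append(name)
            term_columns[term] = names
        else:
            src = _CONTINUOUS[term]
            cols[term] = df[src].to_numpy(float)
            term_columns[term] = [term]
    return pd.DataFrame(cols, index=df.index), term_columns


def _build_vc(df: pd.DataFrame, groups: np.ndarray) -> VCSpec:
    """Variance-component spec for subject random intercepts nested in
    centre groups."""
    labels = np.unique(groups)
    mats, colnames = [], []
    for lab in labels:
        sub = df.loc[groups == lab, "subject_id"]
        dummies = pd.get_dummies(sub).astype(float)
        mats.append(dummies.to_numpy())
        colnames.append(list(dummies.columns))
    return VCSpec(["subject"], [colnames], [mats])


# --------------------------------------------------------------------------- #
# fitting                                                                     #
# --------------------------------------------------------------------------- #

def fit_gene_lmm(expr: ExpressionSet, cohort: pd.DataFrame, spec: DesignSpec,
                 genes: Sequence[str] | None = None) -> dict[str, GeneFit]:
    """REML-fit the spec's model to every gene.

    Returns per-gene fixed-effect estimates, their covariance and
    residual-df Wald tests.  Singular random-effect variances are reported
    (``singular=True``) rather than treated as failures; genes whose fixed
    design is rank-deficient are flagged with an ``error`` and excluded
    from downstream screens.
    """
    df = _assemble(expr, cohort, spec)
    if df.empty:
        raise ValueError("no overlap between expression samples and cohort "
                         "subset")
    exog_full, term_columns = _build_fixed(df, spec)
    genes = list(genes) if genes is not None else list(expr.genes)

    use_centre = "centre" in spec.random
    use_subject = "subject" in spec.random and df["subject_id"].duplicated().any()

    fits: dict[str, GeneFit] = {}
    y_all = expr.values.loc[genes, df.index]
    for gene in genes:
        y = y_all.loc[gene]
        ok = y.notna().to_numpy()
        yv = y.to_numpy(float)[ok]
        exog = exog_full if ok.all() else exog_full.loc[ok]
        sub = df if ok.all() else df.loc[ok]
        fits[gene] = _fit_single(gene, yv, exog, sub, term_columns,
                                 use_centre, use_subject)
    return fits


def _fit_single(gene: str, y: np.ndarray, exog: pd.DataFrame,
                df: pd.DataFrame, term_columns: dict[str, list[str]],
                use_centre: bool, use_subject: bool) -> GeneFit:
    X = exog.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return GeneFit(gene, pd.Series(dtype=float), pd.Series(dtype=float),
                       pd.DataFrame(), 0, len(y), False, False, term_columns,
                       error="rank-deficient fixed design")
    n = len(y)
    df_resid = n - X.shape[1]

    groups = (df["centre"].to_numpy() if use_centre
              else np.zeros(n, dtype=int))
    exog_vc = _build_vc(df, groups) if use_subject else None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups, exog_vc=exog_vc)
        try:
            res = model.fit(reml=True)
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            res, err = None, str(exc)
        if res is not None:
            vcomps = np.concatenate([np.asarray(res.cov_re).ravel(),
                                     np.asarray(res.vcomp).ravel()])
            fully_singular = vcomps.size > 0 and np.all(vcomps < 1e-8)
        else:
            fully_singular = False
        if res is None or fully_singular or \
                not np.all(np.isfinite(res.bse[:X.shape[1]])):
            # non-invertible REML Hessian at the variance boundary (NaN
            # standard errors) or optimizer failure: fall back to the
            # zero-variance (OLS) limit, flagged singular
            import statsmodels.api as sm
            ols = sm.OLS(y, X).fit()
            params = pd.Series(ols.params, index=exog.columns)
            bse = pd.Series(ols.bse, index=exog.columns)
            cov = pd.DataFrame(np.asarray(ols.cov_params()),
                               index=exog.columns, columns=exog.columns)
            return GeneFit(gene, params, bse, cov, df_resid, n, True, True,
                           term_columns)
    names = list(exog.columns)
    k = len(names)
    params = pd.Series(res.params[:k], index=names)
    bse = pd.Series(res.bse[:k], index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                       index=names, columns=names)
    singular = bool(np.any(np.asarray(res.cov_re).diagonal() < 1e-8)) if \
        res.k_re > 0 else False
    return GeneFit(gene, params, bse, cov, df_resid, n,
                   bool(res.converged), singular, term_columns)


# --------------------------------------------------------------------------- #
# multiplicity                                                                #
# --------------------------------------------------------------------------- #

def bh_adjust(pvalues: Sequence[float], alpha: float = 0.05,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection flags).

    q-values are the monotone-enforced adjusted p-values; rejections are
    q <= alpha.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


# --------------------------------------------------------------------------- #
# visit contrasts                                                             #
# --------------------------------------------------------------------------- #

def cid_contrasts(fits: dict[str, GeneFit], expr: ExpressionSet | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """All three pairwise visit contrasts with Tukey family-wise adjustment.

    Per gene and contrast the studentized-range statistic
    q = |estimate| / (SE / sqrt(2)) is referred to the k=3 studentized-range
    distribution on the model's residual df; across genes each contrast's
    Tukey-adjusted p-values are BH-corrected.  When ``expr`` is given the
    per-subject median linear-scale fold change is attached.
    """
    rows = []
    for gene, fit in fits.items():
        if fit.error:
            continue
        cols = fit.term_columns.get("cid")
        if not cols or len(cols) != 2:
            raise ValueError("cid (3 visit levels) must be a fixed term")
        c2, c3 = cols            # cid[2], cid[3] vs baseline cid 1
        b = fit.params
        V = fit.cov
        k_groups = 3
        specs = {
            "bas_lcd": (b[c2], V.loc[c2, c2]),
            "lcd_wmd": (b[c3] - b[c2],
                        V.loc[c3, c3] + V.loc[c2, c2] - 2 * V.loc[c2, c3]),
            "bas_wmd": (b[c3], V.loc[c3, c3]),
        }
        for name, (est, var) in specs.items():
            se = float(np.sqrt(var))
            qstat = abs(est) / (se / np.sqrt(2)) if se > 0 else np.inf
            padj = float(stats.studentized_range.sf(qstat, k_groups,
                                                    max(fit.df_resid, 2)))
            rows.append({"gene": gene, "contrast": name,
                         "estimate": float(est), "se": se,
                         "p_tukey": min(max(padj, 0.0), 1.0)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for name in CONTRASTS:
        mask = table["contrast"] == name
        q, _ = bh_adjust(table.loc[mask, "p_tukey"], alpha)
        table.loc[mask, "q"] = q
    if expr is not None:
        fc = _median_fold_changes(expr)
        table = table.merge(fc, on=["gene", "contrast"], how="left")
    return table


def _median_fold_changes(expr: ExpressionSet) -> pd.DataFrame:
    """Median over subjects of within-subject linear-scale expression ratios."""
    by_cid = {cid: expr.for_cid(cid) for cid in (1, 2, 3)}
    pairs = {"bas_lcd": (1, 2), "lcd_wmd": (2, 3), "bas_wmd": (1, 3)}
    rows = []
    for name, (a, b) in pairs.items():
        A, B = by_cid[a], by_cid[b]
        common = A.columns.intersection(B.columns)
        ratio = np.power(2.0, B[common] - A[common])
        med = ratio.median(axis=1)
        for gene, v in med.items():
            rows.append({"gene": gene, "contrast": name,
                         "median_fold_change": float(v)})
    return pd.DataFrame(rows)


def classify_diet_patterns(contrasts: pd.DataFrame, alpha: float = 0.05,
                           ) -> pd.DataFrame:
    """Label each gene's diet-regulation pattern from the visit contrasts.

    ``opposite_*``: significant opposite-signed changes during the
    low-calorie and weight-maintenance phases; ``end_*``: significant
    baseline-to-end change.  The two labels are recorded independently —
    a gene may carry both.
    """
    wide_q = contrasts.pivot(index="gene", columns="contrast", values="q")
    wide_e = contrasts.pivot(index="gene", columns="contrast",
                             values="estimate")
    out = []
    for gene in wide_q.index:
        q, e = wide_q.loc[gene], wide_e.loc[gene]
        opposite = None
        if q["bas_lcd"] <= alpha and q["lcd_wmd"] <= alpha and \
                e["bas_lcd"] * e["lcd_wmd"] < 0:
            opposite = ("opposite_down_up" if e["bas_lcd"] < 0
                        else "opposite_up_down")
        end = None
        if q["bas_wmd"] <= alpha:
            end = "end_down" if e["bas_wmd"] < 0 else "end_up"
        out.append({"gene": gene, "opposite_pattern": opposite,
                    "end_pattern": end})
    return pd.DataFrame(out).set_index("gene")


# --------------------------------------------------------------------------- #
# screens                                                                     #
# --------------------------------------------------------------------------- #

def term_screen(fits: dict[str, GeneFit], term: str, alpha: float = 0.05,
                ) -> pd.DataFrame:
    """Per-gene table of a fixed term's estimate, p and BH q."""
    rows = []
    for gene, fit in fits.items():
        if fit.error:
            continue
        cols = fit.term_columns[term]
        est = fit.term_estimate(term) if len(cols) == 1 else np.nan
        rows.append({"gene": gene, "estimate": est,
                     "p": fit.term_pvalue(term)})
    table = pd.DataFrame(rows).set_index("gene")
    q, rej = bh_adjust(table["p"], alpha)
    table["q"], table["significant"] = q, rej
    return table


def covariate_robustness(fit_without: dict[str, GeneFit],
                         fit_with: dict[str, GeneFit], term: str,
                         alpha: float = 0.05) -> pd.Series:
    """Flag genes whose focal effect survives adding a covariate.

    True when the term is BH-significant both without and with the
    covariate (e.g. 'weight-independent' or 'fat-mass-independent' genes).
    """
    if set(fit_without) != set(fit_with):
        raise ValueError("the two fit sets cover different genes")
    s_without = term_screen(fit_without, term, alpha)["significant"]
    s_with = term_screen(fit_with, term, alpha)["significant"]
    return (s_without & s_with).rename("robust")


def persistent_signature(result_sets: Sequence[set]) -> set:
    """Genes consistently significant in every provided result set."""
    if len(result_sets) < 2:
        raise ValueError("need at least 2 result sets to intersect")
    out = set(result_sets[0])
    for s in result_sets[1:]:
        out &= set(s)
    return out


def bmi_dependency_screen(expr: ExpressionSet, cohort: pd.DataFrame,
                          sex: str = "F", alpha: float = 0.05,
                          ) -> tuple[set, pd.DataFrame]:
    """Sex-stratified screen for persistent BMI dependence of expression.

    Per visit, log2 expression is regressed on BMI (diet arm added as a
    fixed effect at the weight-maintenance visit) with centre random;
    genes BH-significant at every visit form the persistent set.  The
    reporting ratio divides the mean linear-scale expression of the top
    BMI decile by that of the bottom decile.
    """
    per_cid = {}
    for cid in (1, 2, 3):
        fixed = ["bmi", "diet"] if cid == 3 else ["bmi"]
        spec = DesignSpec(fixed=fixed, random=("centre",),
                          subset={"sex": sex, "cid": cid},
                          name=f"S9_cid{cid}")
        fits = fit_gene_lmm(expr, cohort, spec)
        per_cid[cid] = term_screen(fits, "bmi", alpha)
    persistent = persistent_signature(
        [set(t.index[t["significant"]]) for t in per_cid.values()])

    sub = cohort[cohort["sex"] == sex].copy()
    sub["bmi"] = sub["weight"] / sub["height"] ** 2
    rows = []
    for cid in (1, 2, 3):
        c = sub[sub["cid"] == cid].set_index("subject_id")
        mat = expr.for_cid(cid)
        common = mat.columns.intersection(c.index)
        bmi = c.loc[common, "bmi"]
        n_dec = max(len(common) // 10, 1)
        top = bmi.nlargest(n_dec).index
        bot = bmi.nsmallest(n_dec).index
        lin = np.power(2.0, mat[common])
        if len(top) < 2 or len(bot) < 2:
            ratio = pd.Series(np.nan, index=mat.index)
        else:
            ratio = lin[top].mean(axis=1) / lin[bot].mean(axis=1)
        for gene in mat.index:
            rows.append({"gene": gene, "cid": cid,
                         "p": per_cid[cid].loc[gene, "p"]
                         if gene in per_cid[cid].index else np.nan,
                         "q": per_cid[cid].loc[gene, "q"]
                         if gene in per_cid[cid].index else np.nan,
                         "decile_ratio": float(ratio[gene])})
    return persistent, pd.DataFrame(rows)


def weight_group_markers(expr: ExpressionSet, cohort: pd.DataFrame,
                         sex: str = "F", alpha: float = 0.05) -> pd.DataFrame:
    """Markers separating weight regainers from continued losers.

    The within-subject log2 change from the end of calorie restriction
    (CID2) to the end of weight maintenance (CID3) is modelled with the
    weight-change group and diet arm as fixed effects and centre random.
    The reporting ratio divides the regain group's mean linear-scale fold
    change by the loss group's.
    """
    base = cohort[(cohort["cid"] == 1) & (cohort["sex"] == sex)]
    base = base.set_index("subject_id")
    groups = base["weight_change_group"]
    regain = set(groups.index[groups == "regain"])
    loss = set(groups.index[groups == "loss"])
    if not regain or not loss:
        raise ValueError("both regain and loss groups must be non-empty")

    m2, m3 = expr.for_cid(2), expr.for_cid(3)
    subjects = [s for s in m2.columns.intersection(m3.columns)
                if s in regain | loss]
    delta = m3[subjects] - m2[subjects]

    # wrap the change scores as a one-visit expression set for the fitter
    delta_es = ExpressionSet(
        delta.rename(columns={s: f"{s}:3" for s in subjects}))
    spec = DesignSpec(fixed=["group", "diet"], random=("centre",),
                      subset={"sex": sex, "cid": 3}, name="S6")
    coh = cohort[cohort["subject_id"].isin(subjects)]
    fits = fit_gene_lmm(delta_es, coh, spec)
    table = term_screen(fits, "group", alpha)

    lin = np.power(2.0, delta)
    r_cols = [s for s in subjects if s in regain]
    l_cols = [s for s in subjects if s in loss]
    table["regain_loss_ratio"] = (lin[r_cols].mean(axis=1)
                                  / lin[l_cols].mean(axis=1))
    return table


def expression_changes(expr: ExpressionSet, cid_from: int, cid_to: int,
                       ) -> pd.DataFrame:
    """Within-subject log2 expression changes between two visits."""
    a, b = expr.for_cid(cid_from), expr.for_cid(cid_to)
    common = a.columns.intersection(b.columns)
    return b[common] - a[common]
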