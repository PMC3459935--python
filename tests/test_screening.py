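"""Mixed-model screening: BH oracle, OLS equivalence, contrasts, screens."""
import itertools

import numpy as np
import pandas as pd
import pytest

from atgex import phenotypes
from atgex.datatypes import ExpressionSet
from atgex.screening import (DESIGNS, DesignSpec, bh_adjust, cid_contrasts,
                             classify_diet_patterns, covariate_robustness,
                             fit_gene_lmm, persistent_signature, term_screen,
                             weight_group_markers)
from atgex.simulate import (SimConfig, generate_cohort, generate_expression,
                            generate_truth)


def bh_oracle(p):
    """Brute-force step-up: q_i = min_{j >= rank_i} p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_printed_example(self):
        q, rej = bh_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])
        assert rej.all()

    def test_single_p_unchanged(self):
        q, _ = bh_adjust([0.2])
        assert q[0] == pytest.approx(0.2)

    def test_all_ones_no_rejections(self):
        _, rej = bh_adjust([1.0] * 5)
        assert not rej.any()

    def test_empty(self):
        q, rej = bh_adjust([])
        assert len(q) == 0 and len(rej) == 0

    def test_matches_oracle_exhaustively_up_to_length_8(self):
        grid = [0.001, 0.02, 0.2, 0.7, 1.0]
        for n in range(1, 9):
            for combo in itertools.combinations_with_replacement(grid, n):
                q, _ = bh_adjust(list(combo))
                np.testing.assert_allclose(q, bh_oracle(combo), atol=1e-12,
                                           err_msg=str(combo))

    def test_out_of_range_refused(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _zero_variance_study(n=120, seed=60):
    cfg = SimConfig(noise_sd=0.5, centre_sd=0.0, subject_sd=0.0)
    truth = generate_truth(cfg, seed=seed)
    cohort = generate_cohort(truth, n_subjects=n, seed=seed + 1)
    cohort = cohort[cohort["cid"] == 1].copy()
    expr = generate_expression(truth, cohort, seed=seed + 2)
    return truth, phenotypes.derive_phenotypes(cohort), expr


class TestFitGeneLmm:
    def test_approaches_ols_when_random_variances_zero(self):
        """With no true centre/subject variance the REML variance estimate
        shrinks toward the boundary and GLS fixed effects converge on OLS
        (exactly so for fits flagged singular)."""
        import statsmodels.api as sm
        truth, cohort, expr = _zero_variance_study(n=500)
        genes = truth.genes[:10]
        fits = fit_gene_lmm(expr, cohort, DESIGNS["basis"], genes=genes)
        sub = cohort.set_index(
            cohort["subject_id"].astype(str) + ":1")
        X = pd.DataFrame({
            "Intercept": 1.0,
            "sex[F]": (sub["sex"] == "F").astype(float),
            "mets[True]": (sub["mets"] == True).astype(float),  # noqa: E712
        })
        for gene in genes:
            y = expr.values.loc[gene, X.index]
            ols = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
            tol = 1e-6 if fits[gene].singular else 2e-2
            np.testing.assert_allclose(
                fits[gene].params.to_numpy(), ols.params,
                atol=tol, rtol=0, err_msg=gene)

    def test_rank_deficient_design_flagged(self, small_cohort_derived,
                                           small_expression):
        cohort = small_cohort_derived.copy()
        cohort["fat_mass"] = cohort["weight"]   # collinear with weight
        spec = DesignSpec(fixed=["weight", "fat_mass"], random=("centre",),
                          subset={"cid": 1})
        fits = fit_gene_lmm(small_expression, cohort, spec,
                            genes=[small_expression.genes[0]])
        fit = next(iter(fits.values()))
        assert fit.error is not None

    def test_null_gene_pvalues_roughly_uniform(self):
        # aggregate the sex-term p over null genes from one replicate
        cfg = SimConfig(sex_effect_fraction=0.0, bmi_fraction=0.0,
                        mets_fraction=0.0)
        truth = generate_truth(cfg, seed=70)
        cohort = generate_cohort(truth, n_subjects=150, seed=71)
        cohort = phenotypes.derive_phenotypes(cohort[cohort["cid"] == 1])
        expr = generate_expression(truth, cohort, seed=72)
        fits = fit_gene_lmm(expr, cohort, DESIGNS["basis"])
        pvals = [f.term_pvalue("sex") for f in fits.values()]
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCidContrasts:
    @pytest.fixture(scope="class")
    def contrast_studies(self):
        """Three replicate simulations at n=300 with injected 0.5 shifts."""
        out = []
        for seed in (80, 83, 86):
            cfg = SimConfig(sex_effect_fraction=0.0, bmi_fraction=0.0,
                            mets_fraction=0.0, opposite_fraction=0.4,
                            end_fraction=0.2)
            truth = generate_truth(cfg, seed=seed)
            cohort = generate_cohort(truth, n_subjects=300, seed=seed + 1)
            expr = generate_expression(truth, cohort, seed=seed + 2,
                                       diet_shift=0.5)
            cohort_d = phenotypes.derive_phenotypes(cohort)
            fits = fit_gene_lmm(expr, cohort_d, DESIGNS["S4"])
            out.append((truth, cid_contrasts(fits, expr)))
        return out

    def test_contrast_table_shape_and_invariants(self, contrast_studies):
        truth, table = contrast_studies[0]
        assert set(table["contrast"].unique()) == {"bas_lcd", "lcd_wmd",
                                                   "bas_wmd"}
        # BH q never smaller than the raw (Tukey-adjusted) p
        assert (table["q"] >= table["p_tukey"] - 1e-12).all()
        # fold-change direction agrees with the contrast estimate
        big = table[table["estimate"].abs() > 0.2]
        assert ((big["median_fold_change"] > 1) ==
                (big["estimate"] > 0)).all()

    def test_opposite_patterns_recovered(self, contrast_studies):
        hits = total = 0
        for truth, table in contrast_studies:
            labels = classify_diet_patterns(table)
            true_opp = {g for g, p in truth.diet_pattern.items()
                        if p.startswith("opposite")}
            hits += sum(labels.loc[g, "opposite_pattern"]
                        == truth.diet_pattern[g] for g in true_opp)
            total += len(true_opp)
        assert hits / total >= 0.9

    def test_null_genes_rarely_flagged(self, contrast_studies):
        truth, table = contrast_studies[0]
        labels = classify_diet_patterns(table)
        null = [g for g, p in truth.diet_pattern.items() if p == "null"]
        flagged = sum(labels.loc[g, "opposite_pattern"] is not None
                      for g in null)
        assert flagged / len(null) <= 0.1

    def test_requires_cid_term(self, small_expression, small_cohort_derived):
        fits = fit_gene_lmm(small_expression, small_cohort_derived,
                            DESIGNS["S7"], genes=[small_expression.genes[0]])
        with pytest.raises(ValueError):
            cid_contrasts(fits)


class TestClassifyRules:
    def _table(self, rows):
        return pd.DataFrame(
            [{"gene": "G", "contrast": c, "estimate": e, "q": q}
             for c, e, q in rows])

    def test_down_then_up_is_opposite_down_up(self):
        t = self._table([("bas_lcd", -0.5, 0.01), ("lcd_wmd", 0.5, 0.01),
                         ("bas_wmd", 0.0, 0.9)])
        lab = classify_diet_patterns(t)
        assert lab.loc["G", "opposite_pattern"] == "opposite_down_up"
        assert lab.loc["G", "end_pattern"] is None

    def test_only_end_contrast_significant_negative(self):
        t = self._table([("bas_lcd", -0.1, 0.4), ("lcd_wmd", -0.1, 0.4),
                         ("bas_wmd", -0.4, 0.01)])
        lab = classify_diet_patterns(t)
        assert lab.loc["G", "end_pattern"] == "end_down"
        assert lab.loc["G", "opposite_pattern"] is None


class TestScreens:
    def test_persistent_signature_intersection(self):
        assert persistent_signature([{"A", "B", "C"}, {"B", "C"},
                                     {"B", "C", "D"}]) == {"B", "C"}
        assert persistent_signature([{"A"}, {"B"}]) == set()
        assert persistent_signature([{"A"}, {"A"}]) == {"A"}

    def test_covariate_robustness_mediated_vs_orthogonal(self):
        # gene 0: true sex effect, fat mass pure noise (orthogonal)
        # gene 1: "sex effect" entirely mediated by fat mass
        rng = np.random.default_rng(90)
        n = 400
        sex = np.repeat(["M", "F"], n // 2)
        fat = np.where(sex == "F", 40.0, 30.0) + rng.normal(0, 2, n)
        y0 = 1.0 * (sex == "F") + rng.normal(0, 0.5, n)
        y1 = 0.12 * fat + rng.normal(0, 0.5, n)
        y2 = rng.normal(0, 0.5, n)      # pure null
        subj = [f"S{i:04d}" for i in range(n)]
        cohort = pd.DataFrame({
            "subject_id": subj, "cid": 1, "centre": np.arange(n) % 4 + 1,
            "sex": sex, "weight": 90.0, "height": 1.7, "fat_mass": fat,
        })
        expr = ExpressionSet(pd.DataFrame(
            [y0, y1, y2], index=["ORTHO", "MEDIATED", "NULL"],
            columns=[f"{s}:1" for s in subj]))
        f_without = fit_gene_lmm(expr, cohort, DESIGNS["S7"])
        f_with = fit_gene_lmm(expr, cohort, DESIGNS["S7f"])
        robust = covariate_robustness(f_without, f_with, "sex")
        assert bool(robust["ORTHO"]) is True
        assert bool(robust["MEDIATED"]) is False
        assert bool(robust["NULL"]) is False

    def test_weight_group_marker_recovery_and_symmetry(self):
        # change scores difference out subject effects but keep two visit
        # draws of biological noise; scale it down so a 0.6 log2 shift is
        # detectable at ~30 women per group
        cfg = SimConfig(sex_effect_fraction=0.0, bmi_fraction=0.0,
                        mets_fraction=0.0, opposite_fraction=0.0,
                        end_fraction=0.0, regain_fraction=0.4,
                        loss_fraction=0.4, ggm_scale=0.25, noise_sd=0.2)
        truth = generate_truth(cfg, seed=95)
        cohort = generate_cohort(truth, n_subjects=160, seed=96)
        cohort_d = phenotypes.derive_phenotypes(cohort)
        expr = generate_expression(truth, cohort, seed=97)
        # inject a regain-specific +0.6 log2 shift at CID3 into 8 genes
        marker_genes = truth.genes[:8]
        regain = cohort_d[(cohort_d["weight_change_group"] == "regain")
                          & (cohort_d["cid"] == 1)]["subject_id"]
        for s in regain:
            col = f"{s}:3"
            if col in expr.values.columns:
                expr.values.loc[marker_genes, col] += 0.6
        table = weight_group_markers(expr, cohort_d, sex="F")
        detected = table.loc[marker_genes, "significant"].sum()
        assert detected >= 6
        ratios = table.loc[marker_genes, "regain_loss_ratio"]
        assert ratios.mean() == pytest.approx(2 ** 0.6, rel=0.15)
        null_genes = truth.genes[8:]
        assert table.loc[null_genes, "significant"].sum() <= 3
        # swapping group labels inverts the ratio exactly
        gene = marker_genes[0]
        swapped = cohort_d.copy()
        swap = {"regain": "loss", "loss": "regain"}
        swapped["weight_change_group"] = swapped["weight_change_group"].map(
            lambda g: swap.get(g, g))
        t2 = weight_group_markers(expr, swapped, sex="F")
        assert t2.loc[gene, "regain_loss_ratio"] == pytest.approx(
            1.0 / table.loc[gene, "regain_loss_ratio"])


def test_power_monotone_in_effect_size():
    """Detection rate of the sex screen is non-decreasing in the injected
    effect size on a fixed simulation grid."""
    rates = []
    for effect in (0.0, 0.4, 1.2):
        cfg = SimConfig(sex_effect_fraction=0.0, bmi_fraction=0.0,
                        mets_fraction=0.0, opposite_fraction=0.0,
                        end_fraction=0.0)
        truth = generate_truth(cfg, seed=55)
        hit_genes = truth.genes[:10]
        truth.sex_effect = {g: (effect if g in hit_genes else 0.0)
                            for g in truth.genes}
        cohort = generate_cohort(truth, n_subjects=150, seed=56)
        cohort = phenotypes.derive_phenotypes(cohort[cohort["cid"] == 1])
        expr = generate_expression(truth, cohort, seed=57)
        fits = fit_gene_lmm(expr, cohort, DESIGNS["basis"])
        table = term_screen(fits, "sex")
        rates.append(table.loc[hit_genes, "significant"].mean())
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]


class TestDesignSpecValidation:
    def test_unknown_terms_refused(self):
        with pytest.raises(ValueError):
            DesignSpec(fixed=["nonsense"])
        with pytest.raises(ValueError):
            DesignSpec(fixed=["sex"], random=("batch",))
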