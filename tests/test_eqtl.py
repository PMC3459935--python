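"""cis-eQTL mapping: windows, Hardy-Weinberg, QC, association."""
import numpy as np
import pandas as pd
import pytest

from atgex import phenotypes
from atgex.datatypes import GenotypeSet
from atgex.eqtl import (cis_window, delta_association, eqtl_persistence,
                        eqtl_screen, fit_eqtl, genotype_qc, hwe_exact_test,
                        hwe_test, map_cis_pairs, sex_genotype_independence)
from atgex.simulate import (SimConfig, SnpConfig, apply_eqtl_effects,
                            generate_cohort, generate_expression,
                            generate_genotypes, generate_truth)


class TestCisWindows:
    GENES = pd.DataFrame([
        {"gene": "PLUS", "chrom": "1", "strand": "+",
         "cds_start": 100_000, "cds_end": 101_000},
        {"gene": "MINUS", "chrom": "1", "strand": "-",
         "cds_start": 200_000, "cds_end": 201_000},
    ])

    def _pairs(self, snps):
        ann = pd.DataFrame(snps).set_index("snp")
        return map_cis_pairs(ann, self.GENES)

    def test_midpoint_snp_included(self):
        pairs = self._pairs([{"snp": "s1", "chrom": "1", "pos": 100_500}])
        assert ("s1", "PLUS") in set(map(tuple, pairs[["snp", "gene"]]
                                         .to_numpy()))

    def test_plus_strand_upstream_boundary_closed(self):
        # + strand window starts at cds_start - 10 kb = 90,000 inclusive
        inside = self._pairs([{"snp": "s", "chrom": "1", "pos": 90_000}])
        outside = self._pairs([{"snp": "s", "chrom": "1", "pos": 89_999}])
        assert "PLUS" in inside["gene"].values
        assert "PLUS" not in outside["gene"].values

    def test_plus_strand_downstream_boundary(self):
        # window ends at cds_end + 15 kb = 116,000 inclusive
        inside = self._pairs([{"snp": "s", "chrom": "1", "pos": 116_000}])
        outside = self._pairs([{"snp": "s", "chrom": "1", "pos": 116_001}])
        assert "PLUS" in inside["gene"].values
        assert "PLUS" not in outside["gene"].values

    def test_minus_strand_window_mirrored(self):
        lo, hi = cis_window(200_000, 201_000, "-")
        assert (lo, hi) == (200_000 - 15_000, 201_000 + 10_000)

    def test_other_chromosome_excluded(self):
        pairs = self._pairs([{"snp": "s", "chrom": "2", "pos": 100_500}])
        assert len(pairs) == 0

    def test_unknown_strand_refused(self):
        with pytest.raises(ValueError):
            cis_window(1, 2, "?")


class TestHwe:
    @pytest.mark.parametrize("counts,expected_p", [
        ((25, 50, 25), 1.0),      # perfect equilibrium at MAF 0.5
        ((36, 48, 16), 1.0),      # equilibrium at allele freq 0.6
    ])
    def test_equilibrium_counts(self, counts, expected_p):
        assert hwe_test(*counts) == pytest.approx(expected_p, abs=1e-9)

    def test_heterozygote_excess_chi2_by_hand(self):
        # observed (30, 60, 10) vs expected (36, 48, 16): chi2 = 6.25
        from scipy.stats import chi2
        p = hwe_test(30, 60, 10)
        assert p == pytest.approx(chi2.sf(6.25, 1), abs=1e-10)
        assert p == pytest.approx(0.0124, abs=5e-4)

    def test_monomorphic_flagged_nan(self):
        assert np.isnan(hwe_test(100, 0, 0))

    def test_exact_test_agrees_with_chi2_at_scale(self):
        p_chi = hwe_test(360, 480, 160)
        p_exact = hwe_exact_test(360, 480, 160)
        assert p_exact == pytest.approx(p_chi, abs=0.1)


def _genoset(doses: dict[str, list[float]]) -> GenotypeSet:
    subj = [f"S{i}" for i in range(len(next(iter(doses.values()))))]
    d = pd.DataFrame(doses, index=subj).T
    ann = pd.DataFrame({"chrom": "1", "pos": 1000, "minor": "A",
                        "major": "G"}, index=d.index)
    return GenotypeSet(doses=d, annotation=ann)


class TestGenotypeQc:
    def test_call_rate_boundary_inclusive(self):
        # 19/20 = 0.95 called: retained; 18/20 = 0.90: removed
        base = [0, 1, 2, 1] * 5
        at_boundary = base.copy()
        at_boundary[0] = np.nan
        below = base.copy()
        below[0] = below[1] = np.nan
        g = _genoset({"ok": base, "boundary": at_boundary, "low": below})
        filtered, report = genotype_qc(g)
        assert "boundary" in filtered.doses.index
        assert "low" in report.removed_low_call

    def test_heterozygote_deficit_removed(self):
        rng = np.random.default_rng(1)
        n = 400
        hwe = rng.binomial(2, 0.3, n).astype(float)
        deficit = rng.choice([0.0, 2.0], size=n, p=[0.7, 0.3])  # no hets
        g = _genoset({"hwe": list(hwe), "violator": list(deficit)})
        filtered, report = genotype_qc(g)
        assert "violator" in report.removed_hwe
        assert "hwe" in filtered.doses.index

    def test_clean_panel_mostly_retained(self, small_truth, small_cohort):
        cfg = SnpConfig(hwe_violator_fraction=0.0, low_call_fraction=0.0)
        big = generate_cohort(small_truth, n_subjects=300, seed=5)
        geno, _ = generate_genotypes(small_truth, big, cfg, seed=6)
        _, report = genotype_qc(geno)
        # HWE chi-square falsely removes ~5% of true-equilibrium SNPs
        assert report.n_retained / report.n_input > 0.88


@pytest.fixture(scope="module")
def eqtl_study():
    cfg = SimConfig(sex_effect_fraction=0.0, bmi_fraction=0.0,
                    mets_fraction=0.0, opposite_fraction=0.0,
                    end_fraction=0.0)
    truth = generate_truth(cfg, seed=100)
    cohort = generate_cohort(truth, n_subjects=250, seed=101)
    geno, gene_ann = generate_genotypes(
        truth, cohort, SnpConfig(hwe_violator_fraction=0.0,
                                 low_call_fraction=0.0,
                                 outside_window_fraction=0.0),
        seed=102, eqtl_fraction=0.5, eqtl_beta_range=(0.4, 0.6))
    expr = generate_expression(truth, cohort, seed=103)
    expr = apply_eqtl_effects(expr, geno, truth)
    cohort_d = phenotypes.derive_phenotypes(cohort)
    return truth, cohort_d, expr, geno, gene_ann


class TestFitEqtl:
    def test_beta_matches_ols_with_zero_centre_variance(self):
        rng = np.random.default_rng(20)
        n = 300
        dose = pd.Series(rng.binomial(2, 0.3, n).astype(float),
                         index=[f"S{i:04d}" for i in range(n)])
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        y = 0.5 * dose.to_numpy() + 0.3 * (sex == "F") + rng.normal(0, 0.4, n)
        cohort = pd.DataFrame({"subject_id": dose.index, "cid": 1,
                               "centre": np.arange(n) % 6 + 1, "sex": sex,
                               "weight": 90.0, "height": 1.7})
        expr = pd.Series(y, index=dose.index)
        res = fit_eqtl(expr, dose, cohort)
        import statsmodels.api as sm
        X = np.column_stack([np.ones(n), dose.to_numpy(), (sex == "F")])
        ols = sm.OLS(y, X).fit()
        assert res["beta"] == pytest.approx(ols.params[1], abs=0.01)
        assert res["beta"] == pytest.approx(0.5, abs=0.15)

    def test_dose_recoding_negates_beta(self):
        rng = np.random.default_rng(21)
        n = 200
        dose = pd.Series(rng.binomial(2, 0.4, n).astype(float),
                         index=[f"S{i:04d}" for i in range(n)])
        y = pd.Series(0.4 * dose.to_numpy() + rng.normal(0, 0.5, n),
                      index=dose.index)
        cohort = pd.DataFrame({"subject_id": dose.index, "cid": 1,
                               "centre": np.arange(n) % 4 + 1,
                               "sex": np.where(np.arange(n) % 2 == 0,
                                               "M", "F"),
                               "weight": 90.0, "height": 1.7})
        a = fit_eqtl(y, dose, cohort)
        b = fit_eqtl(y, 2.0 - dose, cohort)
        assert b["beta"] == pytest.approx(-a["beta"], abs=1e-6)

    def test_monomorphic_dose_skipped(self):
        dose = pd.Series([1.0] * 10, index=[f"S{i}" for i in range(10)])
        y = pd.Series(np.arange(10.0), index=dose.index)
        cohort = pd.DataFrame({"subject_id": dose.index, "cid": 1,
                               "centre": 1, "sex": "F", "weight": 90.0,
                               "height": 1.7})
        assert fit_eqtl(y, dose, cohort) is None

    def test_true_effects_recovered_in_screen(self, eqtl_study):
        truth, cohort_d, expr, geno, gene_ann = eqtl_study
        pairs = map_cis_pairs(geno.annotation, gene_ann)
        res = eqtl_screen(expr, geno, pairs, cohort_d, cid=1)
        true_pairs = set(truth.eqtl_effect)
        hits = res[[tuple(x) in true_pairs
                    for x in res[["snp", "gene"]].to_numpy()]]
        assert (hits["significant"]).mean() > 0.7
        merged_beta = {(r.snp, r.gene): r.beta for r in hits.itertuples()}
        errs = [merged_beta[p] - truth.eqtl_effect[p]
                for p in merged_beta]
        assert abs(np.mean(errs)) < 0.1


class TestPersistenceAndDelta:
    def test_static_eqtl_persists_and_artifact_dropped(self, eqtl_study):
        truth, cohort_d, expr, geno, gene_ann = eqtl_study
        pairs = map_cis_pairs(geno.annotation, gene_ann)
        by_cid = {cid: eqtl_screen(expr, geno, pairs, cohort_d, cid=cid)
                  for cid in (1, 2, 3)}
        persistent = eqtl_persistence(by_cid)
        true_pairs = set(truth.eqtl_effect)
        kept = set(map(tuple, persistent[["snp", "gene"]].to_numpy()))
        # a majority of the injected static eQTL survive all three visits
        assert len(kept & true_pairs) >= 0.5 * len(true_pairs)

    def test_visit_specific_artifact_dropped(self):
        base = pd.DataFrame({"snp": ["s1"], "gene": ["g1"], "p": [1e-6],
                             "significant": [True]})
        null = pd.DataFrame({"snp": ["s1"], "gene": ["g1"], "p": [0.8],
                             "significant": [False]})
        out = eqtl_persistence({1: base, 2: null, 3: null})
        assert len(out) == 0

    def test_empty_baseline_gives_empty(self):
        empty = pd.DataFrame(columns=["snp", "gene", "significant"])
        assert len(eqtl_persistence({1: empty})) == 0

    def test_static_effects_null_on_change_scores(self, eqtl_study):
        """Level-only eQTL effects cancel in within-subject changes."""
        truth, cohort_d, expr, geno, gene_ann = eqtl_study
        pairs = map_cis_pairs(geno.annotation, gene_ann)
        res = delta_association(expr, geno, pairs, cohort_d,
                                cid_from=1, cid_to=2)
        true_pairs = set(truth.eqtl_effect)
        hits = res[[tuple(x) in true_pairs
                    for x in res[["snp", "gene"]].to_numpy()]]
        assert not hits["significant"].any()

    def test_injected_dose_by_visit_interaction_detected(self, eqtl_study):
        truth, cohort_d, expr, geno, gene_ann = eqtl_study
        (snp, gene) = next(iter(truth.eqtl_effect))
        expr2 = expr.copy()
        dose = geno.doses.loc[snp]
        for s, d in dose.items():          # effect grows by 0.5/allele at CID2
            col = f"{s}:2"
            if col in expr2.values.columns and not np.isnan(d):
                expr2.values.loc[gene, col] += 0.5 * d
        pairs = pd.DataFrame({"snp": [snp], "gene": [gene]})
        res = delta_association(expr2, geno, pairs, cohort_d,
                                cid_from=1, cid_to=2)
        # the change-score estimator's own SE is ~0.18 here; check the
        # interaction is detected with a positive beta of the right size
        assert res.iloc[0]["p"] < 0.01
        assert res.iloc[0]["beta"] == pytest.approx(0.5, abs=3 * res.iloc[0]["se"])


class TestSexGenotypeIndependence:
    def test_identical_rows_chi2_zero(self):
        out = sex_genotype_independence([[100, 200, 100], [100, 200, 100]])
        assert out["chi2"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_strong_dependence_tiny_p(self):
        out = sex_genotype_independence([[50, 50, 0], [0, 50, 50]])
        assert out["p"] < 1e-10

    def test_small_expected_cells_route_to_exact(self):
        out = sex_genotype_independence([[3, 2, 1], [2, 3, 1]])
        assert out["method"] == "fisher_exact"
        assert 0 < out["p"] <= 1

    def test_exact_p_matches_enumeration_sanity(self):
        # balanced table: exact p should be large
        out = sex_genotype_independence([[2, 2, 2], [2, 2, 2]])
        assert out["p"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_margin_refused(self):
        with pytest.raises(ValueError):
            sex_genotype_independence([[0, 0, 0], [1, 2, 3]])
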