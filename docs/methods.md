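# Methods

This note documents the statistical models implemented in `atgex`, the
synthetic-data generator that exercises them, the numerical choices made
where the design was open, and the limits of what the test suite can
show about real data.

## Study design being modelled

The package targets multi-centre dietary-intervention cohorts with three
clinical investigation days (CID1 baseline, CID2 after an 8-week
low-calorie diet with a ≥8% weight-loss objective, CID3 after a 26-week
ad libitum weight-maintenance diet in one of five arms), subjects
recruited at 8 centres, adipose-tissue expression of a few dozen to a few
hundred genes measured by plate-structured RT-qPCR with a shared
calibrator sample, and biallelic cis SNPs genotyped per subject.

## Synthetic cohort generator

Every generator is a pure function of (config, seed); identical inputs
give bit-identical outputs.

**Dependence structure.** Gene–gene dependence is a sparse Gaussian
graphical model per sex group. Supports are drawn Erdős–Rényi at a target
density (default 15% of node pairs, the network-construction density used
downstream) with an exactly controlled fraction of edges shared between
groups (default 75%). Off-diagonal precision entries get magnitudes
uniform in [0.15, 0.35] with random sign (shared edges share weights
across groups); positive definiteness is enforced by diagonal loading —
shifting the spectrum so the smallest eigenvalue is +0.1 — which is
simple, reproducible, and leaves marginal variances near 1.

**Fixed effects.** A configurable fraction of genes receives each effect:
sex (log2 fold change, default magnitudes 0.3–1.0), BMI slope (0.02–0.06
log2/unit, anchored at BMI 35), metabolic-syndrome shift (0.2–0.6), and a
diet-phase pattern per gene — `opposite_down_up`/`opposite_up_down`
(transient shift at CID2), `end_down`/`end_up` (half shift at CID2, full
at CID3), or `null`. Defaults give moderate, realistically mixed effect
maps; magnitudes were chosen so that effects are recoverable, not
trivially obvious, at the cohort sizes such trials enrol (100–500).

**Random structure.** Centre intercepts (SD 0.15), subject intercepts
(SD 0.25, shared across visits), residual noise (SD 0.3), all on the log2
scale. A `ggm_scale` knob scales the biological (graphical-model) draw;
analyses of within-subject change scores use smaller scales in tests
because two independent visit draws enter every change score.

**Clinical variables** come from a one-factor latent metabolic-syndrome
model: waist, blood pressure, triglycerides, HDL (negative loading),
glucose, insulin, CRP and adiponectin (negative) load on one standard-
normal factor per subject with sex-specific means; weight loss improves
risk factors proportionally to the fraction of weight lost. This
reproduces the MetS-component correlation structure the network stage
needs without copying any real data. Weight trajectories: CID2 weight is
CID1 × (1 − loss) with loss = 8% + half-normal noise; the CID3 regain
ratio is drawn from a three-part mixture so that regainers (≥50% of lost
weight regained), continued losers (≥50% further loss) and maintainers
all exist in configurable proportions (defaults 0.3/0.3/0.4).

**Ct plates.** Ct(gene, well) = baseline_Ct(gene) − log2 expression +
plate offset + well noise, with plate offsets ~ N(0, 0.3) and well noise
~ N(0, 0.15) — magnitudes chosen so ΔCt and global normalization methods
differ measurably. One calibrator profile is replicated on every plate;
one water well per plate reads the 999 missing sentinel; a configurable
fraction of wells is set to the sentinel and designated genes can be
forced above the Ct 30 QC threshold. The reference transcript (GUSB) is
simulated with constant zero log2 expression, and per-gene baselines are
stored with the plate set, so the zero-noise round trip
(generate → ΔCt-normalize → re-add baselines) is exact to float
precision.

**Genotypes.** Doses ~ binomial(2, MAF) for Hardy–Weinberg SNPs;
designated violators are drawn with an inbreeding-style heterozygote
deficit (F = 0.6); designated low-call SNPs get 10% missing entries.
eQTL effects (default 0.2–0.5 log2/allele on one SNP per affected gene)
are recorded in the ground truth and added to expression as static
(visit-invariant) shifts.

## qPCR QC and normalization

* Gene exclusion: a gene is dropped when more than 50% of its sample
  wells read Ct > 30 or the 999 sentinel (majority rule — a stated,
  testable operationalization of "too low or inconsistent expression"),
  or when more than 20% of its calibrator replicates are outliers, an
  outlier lying beyond median ± 3·MAD across plates. The MAD rule needs
  replication and is skipped below 5 calibrator replicates.
* ΔCt normalization is invariant to per-plate additive shifts by
  construction; samples whose reference well is absent are flagged
  missing for all genes (and dropped, with provenance, before
  imputation, where gene-wise imputation is undefined).
* Quantile normalization maps each column's ranks onto the row-mean
  reference distribution; ties share averaged ranks; missing entries are
  excluded from rank computation and re-inserted.
* Rank-invariant normalization selects genes whose rank differs from the
  reference (median pseudo-sample) rank by ≤5% of the gene count, fits a
  LOWESS curve through the invariant set, isotonicizes it, and maps all
  genes; it refuses columns whose invariant set falls below 5 genes.
* geNorm ranking: V_jk = SD over samples of the log2 ratio of candidates
  j, k; M_j = mean over k ≠ j; the highest-M candidate is dropped
  iteratively. Verified against a brute-force double loop.
* Missing values: k-nearest-neighbour imputation in gene space (genes as
  rows; Euclidean distance on shared samples, distance-weighted mean,
  k = 10). The method is standard for qPCR panels; k and the metric are
  package defaults, exposed as parameters.
* Method comparison: mean per-gene CV of the linear-scale calibrator
  across plates. Under the generator's default noise model ΔCt and
  quantile normalization both beat raw data (plate offsets cancel);
  which of the two wins depends on the reference-gene well noise —
  quantile pools information across the whole calibrator profile, so
  with a noisy reference it can undercut ΔCt. The package therefore
  asserts the ordering against raw data only.

## Mixed-model screening

Designs are declared as `DesignSpec`s (fixed terms, random terms, subset,
log-transformed covariates); the named designs S4–S9 preconfigure the
standard screens (visit contrasts with/without weight, end-of-diet
regulation with diet arm, weight-regain markers on CID3−CID2 change
scores, sexual dimorphism with/without fat mass, MetS contrast, per-visit
BMI dependence with diet added at CID3). Sex-stratified screens fit the
sexes separately.

Fitting is REML via `statsmodels` `MixedLM` with a centre random
intercept and, for repeated measures, subject variance components nested
in centre. Inference on fixed effects uses Wald t/F statistics with
residual degrees of freedom (n − p). Numerical safeguards: when the
estimated random-effect covariance is entirely singular, or the REML
Hessian yields non-finite standard errors, the fit falls back to its
zero-variance limit (OLS), flagged `singular` — statsmodels' internal
lbfgs retry can otherwise return unoptimized fixed effects in exactly
this boundary case. Rank-deficient fixed designs flag the gene and
exclude it from screens.

Visit contrasts use the studentized-range distribution (k = 3) on
model-based standard errors (q = |est|/(SE/√2)); a two-level factor
reduces to the unadjusted t-contrast. Across genes, Benjamini–Hochberg
(step-up, monotone-enforced q-values, rejections at q ≤ 0.05) is applied
per contrast. Pattern labels: `opposite_*` requires both phase contrasts
significant with opposite signs; `end_*` requires the baseline-to-end
contrast; the labels are recorded independently. Median fold changes are
per-subject linear-scale ratios, then the median — the within-subject
pairing is this package's interpretation. Covariate robustness
("weight-independent", "fat-mass-independent") flags genes BH-significant
both without and with the covariate. Decile reporting ratios divide the
mean linear-scale expression of the top BMI decile by the bottom decile.

## Networks

Neighborhood selection is implemented directly on the covariance: the
lasso regression of node j on the rest depends on S only, and is solved
by cyclic coordinate descent (tolerance 1e-8, cap 5000 sweeps). The AND
policy keeps edge i–j only if both directed selections are nonzero. The
precision estimate is assembled from the node-wise fits (Θ_jj = 1 /
residual variance; Θ_ij = sign-consistent average of the two directed
estimates on kept edges); partial correlations follow the standard
formula and are verified against a regression-residual oracle. A
graphical-lasso backend (scikit-learn) is available behind the same
contract.

Density calibration bisects λ between ~0 and max|off-diagonal S| (60
iterations); the achieved edge count is non-increasing in λ along the
path, ties at the target break toward the smaller λ (denser network), and
an exactly-zero penalty is excluded because the node-wise lasso is
ill-posed when observations < nodes — a non-converged solve at a small
penalty is treated as denser than any target. With 41 nodes and the 15%
target the calibration lands exactly on 123 of 820 pairs at n = 150 per
group.

Edge "significance" is the sparsity pattern at the calibrated penalty —
there is no separate per-edge p-value; this realizes "significantly
non-zero partial correlation" operationally and is stated here
explicitly. Shared-edge fractions are reported under all three
denominators (Jaccard, per-network A, per-network B) because the
convention is ambiguous in the field. Betweenness is unnormalized
(pair-counting), matching the usual hub-highlighting usage.

## cis-eQTL

Windows are closed intervals, strand-aware (upstream 10 kb, downstream
15 kb relative to transcription direction), with 1-based inclusive
coordinates throughout (VCF convention). Hardy–Weinberg filtering uses
the χ² (1 df) goodness-of-fit test by default (appropriate for P > 0.05
filtering at panel scale); an exact enumeration test is available. The
call-rate cutoff (≥95%) is inclusive. Sex-by-genotype independence uses
χ², routing to an exact Freeman–Halton enumeration when any expected cell
is below 5. Dose associations use the same mixed-model machinery as the
screens (dose + sex (± BMI) fixed, centre random); monomorphic SNPs are
skipped with a flag; recoding the dose exactly negates the slope.
Persistence keeps baseline-significant pairs that stay BH-significant at
both follow-up visits; change-score associations (Δlog2 on dose) test
for genotype-by-diet interaction, and static eQTL effects cancel in them
by construction.

## Pipeline

A YAML config with five stage blocks drives simulate → qpcr → screen →
network → eqtl; the stage seeds derive from the global seed by hashing,
outputs are plain TSV/GraphML/JSON with fixed float formatting, and
re-running a config is byte-identical. The manifest records stages,
parameters and seed; `validate` checks input schemas (Ct range and plate
structure, cohort consistency, dose domain, annotation coordinates) and
exits non-zero on violations.

## Problem sizes used by the test suite

The suite exercises the study conditions at desk scale: FDR control uses
200 replicates of 40 genes × 150 subjects (baseline visit, 90% null
genes); recovery checks use n = 500 subjects (sex effect, averaged over
3 replicate cohorts) and n = 400 (eQTL slope, 5 replicates) — averaging
keeps the Monte-Carlo error of the check well below the ±0.1 tolerance
being asserted; network recovery uses p = 40, n = 300/group, and the
intertwining comparison 20 seeds at n = 150/group.

## Known limitations

* The generator draws independent graphical-model vectors per visit;
  real longitudinal expression is autocorrelated beyond the subject
  intercept, so change scores here are noisier than in real cohorts.
* Amplification-efficiency correction, standard curves and 18S handling
  are out of scope; plate effects are purely additive in Ct.
* Clinical covariates follow a single-factor dependence model; real
  phenotype correlation structure is richer.
* MetS classification omits medication criteria (not simulated).
* At most two network groups; no edge-wise confidence intervals; no
  graph layout (exports target external tools).
* No trans-eQTL, genotype imputation or LD structure: SNPs are drawn
  independently.
* Passing tests demonstrate internal correctness and recoverability
  under the generator's assumptions, not biological validity on any
  real cohort.
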