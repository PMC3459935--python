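"""Synthetic dietary-intervention cohort generator.

Emulates the data structure of a multi-centre weight-loss trial: a 3-visit
design (baseline, end of an 8-week low-calorie diet, end of a 26-week
weight-maintenance diet), subjects spread over 8 centres and 5 maintenance
diet arms, adipose-tissue gene expression with sex / BMI / metabolic-syndrome
/ diet-phase effects and a sparse Gaussian-graphical dependence structure,
plate-structured qPCR Ct measurement with a shared calibrator sample, and
biallelic cis SNPs with additive allele-dose effects on expression.

Every generator is a pure function of (config, seed): the same arguments
produce bit-identical output.  The ground truth (:class:`SimTruth`) retains
everything downstream recovery tests need: precision supports, effect maps,
eQTL betas and variance components.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CT_MISSING, CIDS, CtSet, ExpressionSet, GenotypeSet, sample_key

DIET_PATTERNS = ("opposite_down_up", "opposite_up_down", "end_down", "end_up", "null")

#: Reference transcript included in every assay set; simulated with constant
#: (zero) log2 relative expression so the delta-Ct method has a stable anchor.
REFERENCE_GENE = "GUSB"


# --------------------------------------------------------------------------- #
# configuration                                                               #
# --------------------------------------------------------------------------- #

@dataclass
class SimConfig:
    """Generative parameters.

    Defaults describe the study conditions the downstream analyses assume:
    40 target genes, two sexes as network groups, 15% precision-support
    density with 75% of edges shared between the groups, and moderate fixed
    effects against residual noise of 0.3 log2 units.
    """

    n_genes: int = 40
    density: float = 0.15
    shared_fraction: float = 0.75
    partial_range: tuple[float, float] = (0.15, 0.35)

    sex_effect_fraction: float = 0.25
    sex_effect_range: tuple[float, float] = (0.3, 1.0)
    bmi_fraction: float = 0.25
    bmi_slope_range: tuple[float, float] = (0.02, 0.06)
    mets_fraction: float = 0.25
    mets_shift_range: tuple[float, float] = (0.2, 0.6)
    # proportions of genes per diet-regulation class (remainder is null)
    opposite_fraction: float = 0.20
    end_fraction: float = 0.20
    diet_shift_range: tuple[float, float] = (0.3, 0.7)

    noise_sd: float = 0.3
    centre_sd: float = 0.15
    subject_sd: float = 0.25
    #: scale on the Gaussian-graphical draw (biological variability); 1.0
    #: gives roughly unit marginal variance per gene
    ggm_scale: float = 1.0

    n_centres: int = 8
    n_diet_arms: int = 5
    lcd_loss_mean: float = 0.08
    lcd_loss_sd: float = 0.02
    regain_fraction: float = 0.30
    loss_fraction: float = 0.30


@dataclass
class PlateDesign:
    """Plate layout for Ct generation.

    Genes are split into up to three assay sets (A, B, C); each set is run
    on its own series of plates.  Every plate carries one calibrator well
    block (the same cDNA profile on all plates) and one water control.
    """

    samples_per_plate: int = 46
    n_sets: int = 1
    plate_offset_sd: float = 0.3
    well_noise_sd: float = 0.15
    missing_fraction: float = 0.01
    high_ct_genes: tuple[str, ...] = ()
    baseline_ct_mean: float = 25.0
    baseline_ct_sd: float = 0.0
    high_ct_baseline: float = 34.0


@dataclass
class SnpConfig:
    """cis-SNP panel parameters."""

    snps_per_gene: int = 3
    maf_range: tuple[float, float] = (0.1, 0.5)
    hwe_violator_fraction: float = 0.05
    low_call_fraction: float = 0.05
    low_call_missing_rate: float = 0.10
    inbreeding_f: float = 0.6
    cds_length: int = 5000
    upstream: int = 10_000
    downstream: int = 15_000
    outside_window_fraction: float = 0.1


@dataclass
class SimTruth:
    """Ground-truth generative parameters used by recovery tests."""

    config: SimConfig
    genes: list[str]
    groups: list[str]
    precision_by_group: dict[str, np.ndarray]
    shared_edges: set[tuple[int, int]]
    sex_effect: dict[str, float]
    bmi_slope: dict[str, float]
    diet_pattern: dict[str, str]
    mets_shift: dict[str, float]
    eqtl_effect: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def noise_sd(self) -> float:
        return self.config.noise_sd

    def support(self, group: str) -> set[tuple[int, int]]:
        """Off-diagonal support of a group's precision as (i<j) index pairs."""
        theta = self.precision_by_group[group]
        idx = np.argwhere(np.triu(theta, 1) != 0)
        return {(int(i), int(j)) for i, j in idx}


# --------------------------------------------------------------------------- #
# truth                                                                       #
# --------------------------------------------------------------------------- #

def _sample_edge_sets(rng: np.random.Generator, p: int, density: float,
                      shared_fraction: float) -> tuple[set, set, set]:
    """Sample two edge sets of equal size with an exact shared subset."""
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_pairs = len(pairs)
    m = int(round(density * n_pairs))
    s = int(round(shared_fraction * m))
    if 2 * m - s > n_pairs:
        raise ValueError("density/shared_fraction combination needs more pairs "
                         "than exist")
    order = rng.permutation(n_pairs)
    shared = {pairs[k] for k in order[:s]}
    g1 = shared | {pairs[k] for k in order[s:m]}
    g2 = shared | {pairs[k] for k in order[m:2 * m - s]}
    return shared, g1, g2


def _precision_from_support(rng: np.random.Generator, p: int,
                            edges: set[tuple[int, int]],
                            weight_of: dict[tuple[int, int], float]) -> np.ndarray:
    theta = np.zeros((p, p))
    for (i, j) in edges:
        theta[i, j] = theta[j, i] = weight_of[(i, j)]
    np.fill_diagonal(theta, 1.0)
    # diagonal loading: shift spectrum so the smallest eigenvalue is +0.1
    lam_min = np.linalg.eigvalsh(theta)[0]
    if lam_min <= 0.1:
        theta += (abs(lam_min) + 0.1) * np.eye(p)
    if np.linalg.eigvalsh(theta)[0] <= 0:
        raise RuntimeError("precision matrix not positive definite after loading")
    return theta


def generate_truth(config: SimConfig, seed: int) -> SimTruth:
    """Draw the generative ground truth for one simulated study."""
    rng = np.random.default_rng(seed)
    p = config.n_genes
    genes = [f"G{i + 1:03d}" for i in range(p)]
    groups = ["M", "F"]

    shared, e1, e2 = _sample_edge_sets(rng, p, config.density,
                                       config.shared_fraction)
    lo, hi = config.partial_range
    weight_of = {}
    for edge in sorted(e1 | e2):
        sign = rng.choice([-1.0, 1.0])
        weight_of[edge] = sign * rng.uniform(lo, hi)
    precision = {
        "M": _precision_from_support(rng, p, e1, weight_of),
        "F": _precision_from_support(rng, p, e2, weight_of),
    }

    def _effect_map(fraction: float, rng_range: tuple[float, float],
                    signed: bool = True) -> dict[str, float]:
        n_hit = int(round(fraction * p))
        hits = rng.choice(p, size=n_hit, replace=False)
        out = {g: 0.0 for g in genes}
        for i in hits:
            mag = rng.uniform(*rng_range)
            if signed and rng.random() < 0.5:
                mag = -mag
            out[genes[i]] = mag
        return out

    sex_effect = _effect_map(config.sex_effect_fraction, config.sex_effect_range)
    bmi_slope = _effect_map(config.bmi_fraction, config.bmi_slope_range)
    mets_shift = _effect_map(config.mets_fraction, config.mets_shift_range)

    n_opp = int(round(config.opposite_fraction * p))
    n_end = int(round(config.end_fraction * p))
    perm = rng.permutation(p)
    diet_pattern = {g: "null" for g in genes}
    for k, i in enumerate(perm[:n_opp]):
        diet_pattern[genes[i]] = "opposite_down_up" if k % 2 == 0 else "opposite_up_down"
    for k, i in enumerate(perm[n_opp:n_opp + n_end]):
        diet_pattern[genes[i]] = "end_down" if k % 2 == 0 else "end_up"

    return SimTruth(config=config, genes=genes, groups=groups,
                    precision_by_group=precision, shared_edges=shared,
                    sex_effect=sex_effect, bmi_slope=bmi_slope,
                    diet_pattern=diet_pattern, mets_shift=mets_shift)


# --------------------------------------------------------------------------- #
# cohort                                                                      #
# --------------------------------------------------------------------------- #

# loadings of clinical variables on the one-factor latent metabolic-syndrome
# score z (per-unit shift and residual sd, on each variable's natural scale)
_CLINICAL_MODEL = {
    # variable: (male mean, female mean, loading on z, residual sd)
    "waist": (102.0, 95.0, 6.0, 5.0),
    "fat_mass": (30.0, 42.0, 2.0, 4.0),
    "sbp": (125.0, 120.0, 7.0, 8.0),
    "dbp": (80.0, 77.0, 4.0, 5.0),
    "triglycerides": (1.5, 1.3, 0.45, 0.35),
    "hdl": (1.15, 1.35, -0.16, 0.15),
    "glucose": (5.4, 5.2, 0.5, 0.4),
    "insulin": (11.0, 10.0, 4.0, 3.5),
    "crp": (3.0, 3.5, 1.0, 1.5),
    "adiponectin": (7.0, 10.0, -1.5, 2.0),
}

_POSITIVE_FLOOR = {"triglycerides": 0.3, "hdl": 0.4, "glucose": 3.5,
                   "insulin": 1.0, "crp": 0.1, "adiponectin": 0.5,
                   "waist": 60.0, "fat_mass": 10.0, "sbp": 90.0, "dbp": 50.0}


def generate_cohort(truth: SimTruth, n_subjects: int, seed: int) -> pd.DataFrame:
    """Simulate the subject-visit clinical table.

    Weight trajectories follow the trial design: every completer loses at
    least the configured mean fraction (default 8%) of baseline weight
    during the low-calorie phase, then either regains, keeps losing, or
    roughly maintains during weight maintenance, in configured proportions.
    Clinical variables load on a single latent metabolic-syndrome factor.
    """
    cfg = truth.config
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects to populate the design")
    rng = np.random.default_rng(seed)

    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    centres = np.array([i % cfg.n_centres for i in range(n_subjects)]) + 1
    sexes = np.array(["M", "F"])[np.arange(n_subjects) % 2]
    rng.shuffle(sexes)
    diet_arm = rng.integers(1, cfg.n_diet_arms + 1, size=n_subjects)

    height = np.where(sexes == "M",
                      rng.normal(1.78, 0.06, n_subjects),
                      rng.normal(1.65, 0.06, n_subjects))
    bmi0 = rng.uniform(30.0, 45.0, n_subjects)
    w1 = bmi0 * height ** 2

    loss_frac = cfg.lcd_loss_mean + np.abs(rng.normal(0, cfg.lcd_loss_sd,
                                                      n_subjects))
    w2 = w1 * (1.0 - loss_frac)
    lost = w1 - w2

    u = rng.random(n_subjects)
    g = np.empty(n_subjects)          # regain ratio (w3 - w2) / lost
    regain = u < cfg.regain_fraction
    losing = (~regain) & (u < cfg.regain_fraction + cfg.loss_fraction)
    neither = ~(regain | losing)
    g[regain] = rng.uniform(0.5, 1.2, regain.sum())
    g[losing] = rng.uniform(-1.2, -0.5, losing.sum())
    g[neither] = rng.uniform(-0.45, 0.45, neither.sum())
    w3 = w2 + g * lost

    z = rng.normal(0.0, 1.0, n_subjects)      # latent MetS factor
    mets_latent = z > 0.25

    rows = []
    for k, sid in enumerate(subjects):
        weights = {1: w1[k], 2: w2[k], 3: w3[k]}
        for cid in CIDS:
            # clinical state improves in proportion to weight lost so far
            improvement = (w1[k] - weights[cid]) / w1[k]
            row = {
                "subject_id": sid, "cid": cid, "centre": int(centres[k]),
                "sex": sexes[k], "diet_arm": int(diet_arm[k]),
                "weight": weights[cid], "height": height[k],
                "completer": True, "mets_latent": bool(mets_latent[k]),
            }
            for var, (mu_m, mu_f, load, sd) in _CLINICAL_MODEL.items():
                mu = mu_m if sexes[k] == "M" else mu_f
                val = mu + load * z[k] + rng.normal(0, sd)
                # weight loss pulls risk factors toward better values
                if var not in ("hdl", "adiponectin"):
                    val *= (1.0 - 0.5 * improvement)
                else:
                    val *= (1.0 + 0.3 * improvement)
                row[var] = max(val, _POSITIVE_FLOOR[var])
            rows.append(row)
    cohort = pd.DataFrame(rows)
    cohort["waist"] = cohort["waist"] + 0.5 * (cohort["weight"]
                                               - cohort["weight"].mean())
    return cohort


# --------------------------------------------------------------------------- #
# expression                                                                  #
# --------------------------------------------------------------------------- #

_PATTERN_SHIFTS = {
    # diet-pattern class -> per-CID mean shift in units of the gene's shift
    "opposite_down_up": (0.0, -1.0, 0.0),
    "opposite_up_down": (0.0, 1.0, 0.0),
    "end_down": (0.0, -0.5, -1.0),
    "end_up": (0.0, 0.5, 1.0),
    "null": (0.0, 0.0, 0.0),
}

#: BMI value at which the BMI fixed effect contributes zero.
BMI_REFERENCE = 35.0


def generate_expression(truth: SimTruth, cohort: pd.DataFrame, seed: int,
                        diet_shift: float = 0.5) -> ExpressionSet:
    """Draw the log2 relative expression matrix for every subject-visit.

    Per visit, gene vectors come from the subject's sex-group Gaussian
    graphical model; fixed effects (sex, BMI, metabolic syndrome,
    diet-phase pattern), centre and subject random intercepts and residual
    noise are then added on the log2 scale.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    genes = truth.genes
    p = len(genes)

    cov = {grp: np.linalg.inv(theta)
           for grp, theta in truth.precision_by_group.items()}
    chol = {grp: np.linalg.cholesky(c) for grp, c in cov.items()}

    base = cohort[cohort["cid"] == 1].set_index("subject_id")
    subjects = list(base.index)
    centres = sorted(cohort["centre"].unique())

    centre_fx = {(c): rng.normal(0, cfg.centre_sd, p) for c in centres}
    subject_fx = {s: rng.normal(0, cfg.subject_sd, p) for s in subjects}

    sex_vec = np.array([truth.sex_effect[g] for g in genes])
    bmi_vec = np.array([truth.bmi_slope[g] for g in genes])
    mets_vec = np.array([truth.mets_shift[g] for g in genes])
    pattern_mat = np.array([_PATTERN_SHIFTS[truth.diet_pattern[g]]
                            for g in genes]) * diet_shift

    cohort_idx = cohort.set_index(["subject_id", "cid"])
    cids_present = sorted(cohort["cid"].unique())
    cols, data = [], []
    for sid in subjects:
        grp = base.loc[sid, "sex"]
        for cid in cids_present:
            draw = cfg.ggm_scale * (chol[grp] @ rng.standard_normal(p))
            row = cohort_idx.loc[(sid, cid)]
            bmi = row["weight"] / row["height"] ** 2
            x = draw + pattern_mat[:, cid - 1]
            if grp == "F":
                x = x + sex_vec
            x = x + bmi_vec * (bmi - BMI_REFERENCE)
            if row["mets_latent"]:
                x = x + mets_vec
            x = x + centre_fx[row["centre"]] + subject_fx[sid]
            if cfg.noise_sd > 0:
                x = x + rng.normal(0, cfg.noise_sd, p)
            cols.append(sample_key(sid, cid))
            data.append(x)
    values = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    return ExpressionSet(values, provenance={"source": "simulated",
                                             "seed": seed})


def apply_eqtl_effects(expr: ExpressionSet, genotypes: GenotypeSet,
                       truth: SimTruth) -> ExpressionSet:
    """Add per-allele additive genotype effects to the linked genes.

    The effect is static across visits: the same dose shift applies to a
    subject's expression at every clinical investigation day.
    """
    out = expr.copy()
    for (snp, gene), beta in truth.eqtl_effect.items():
        if beta == 0 or gene not in out.values.index:
            continue
        dose = genotypes.doses.loc[snp]
        for col in out.values.columns:
            sid = col.rsplit(":", 1)[0]
            d = dose.get(sid, np.nan)
            if not np.isnan(d):
                out.values.loc[gene, col] += beta * d
    out.provenance["eqtl_effects_applied"] = True
    return out


# --------------------------------------------------------------------------- #
# Ct plates                                                                   #
# --------------------------------------------------------------------------- #

def generate_ct_plates(expr: ExpressionSet, plate_design: PlateDesign,
                       seed: int) -> CtSet:
    """Lay the expression matrix onto qPCR plates and emit raw Ct values.

    Ct(gene, well) = baseline_Ct(gene) - log2(relative expression)
    + plate offset + well noise.  One calibrator cDNA profile is replicated
    on every plate; one water well per plate reads the missing sentinel.
    The reference transcript (GUSB) is appended with true expression zero.
    """
    rng = np.random.default_rng(seed)
    pd_ = plate_design
    genes = list(expr.values.index)
    if REFERENCE_GENE not in genes:
        genes = genes + [REFERENCE_GENE]

    baselines = pd.Series(
        pd_.baseline_ct_mean + rng.normal(0, pd_.baseline_ct_sd, len(genes)),
        index=genes)
    for g in pd_.high_ct_genes:
        if g in baselines.index:
            baselines[g] = pd_.high_ct_baseline

    # fixed calibrator profile, shared by every plate of every set
    cal_profile = pd.Series(rng.normal(0.0, 0.5, len(genes)), index=genes)
    cal_profile[REFERENCE_GENE] = 0.0

    n_sets = max(1, min(pd_.n_sets, 3))
    set_names = ["A", "B", "C"][:n_sets]
    target_genes = [g for g in genes if g != REFERENCE_GENE]
    gene_sets = {name: list(chunk) + [REFERENCE_GENE]
                 for name, chunk in zip(set_names,
                                        np.array_split(target_genes, n_sets))}

    samples = list(expr.values.columns)
    n_plates = max(1, int(np.ceil(len(samples) / pd_.samples_per_plate)))

    rows = []
    plate_id = 0
    for set_name in set_names:
        sgenes = gene_sets[set_name]
        for pi in range(n_plates):
            plate_id += 1
            offset = rng.normal(0, pd_.plate_offset_sd) if pd_.plate_offset_sd > 0 else 0.0
            chunk = samples[pi * pd_.samples_per_plate:(pi + 1) * pd_.samples_per_plate]
            well = 0
            for sample in chunk + ["__calibrator__", "__water__"]:
                is_cal = sample == "__calibrator__"
                is_water = sample == "__water__"
                for g in sgenes:
                    well += 1
                    if is_water:
                        ct = CT_MISSING
                    else:
                        if is_cal:
                            x = cal_profile[g]
                            sid, cid = "CAL", 0
                        else:
                            x = 0.0 if g == REFERENCE_GENE else expr.values.loc[g, sample]
                            sid, cid = sample.rsplit(":", 1)
                        noise = (rng.normal(0, pd_.well_noise_sd)
                                 if pd_.well_noise_sd > 0 else 0.0)
                        ct = baselines[g] - x + offset + noise
                        if pd_.missing_fraction > 0 and rng.random() < pd_.missing_fraction:
                            ct = CT_MISSING
                    if is_cal or is_water:
                        sid, cid = ("CAL", 0) if is_cal else ("WATER", 0)
                    else:
                        sid, cid = sample.rsplit(":", 1)
                    rows.append((plate_id, set_name, well, sid, int(cid), g,
                                 float(ct), is_cal, is_water))
    wells = pd.DataFrame(rows, columns=["plate", "set", "well", "sample_id",
                                        "cid", "gene", "ct", "is_calibrator",
                                        "is_water"])
    return CtSet(wells=wells, gene_baselines=baselines,
                 meta={"calibrator_profile": cal_profile,
                       "reference_gene": REFERENCE_GENE})


def invert_delta_ct(expr_norm: ExpressionSet, ct: CtSet) -> ExpressionSet:
    """Undo the per-gene baseline offset left by delta-Ct normalization.

    Delta-Ct expression is -(Ct_gene - Ct_ref) = x_gene - x_ref
    + baseline(ref) - baseline(gene); adding back the baseline difference
    recovers the generated expression exactly when noise and the reference
    gene's expression are zero.
    """
    ref = ct.meta.get("reference_gene", REFERENCE_GENE)
    base = ct.gene_baselines
    out = expr_norm.copy()
    for g in out.values.index:
        out.values.loc[g] += base[g] - base[ref]
    out.provenance["baseline_corrected"] = True
    return out


# --------------------------------------------------------------------------- #
# genotypes                                                                   #
# --------------------------------------------------------------------------- #

def make_gene_annotation(genes: list[str], cds_length: int = 5000) -> pd.DataFrame:
    """Deterministic gene coordinate table (1-based inclusive CDS bounds)."""
    rows = []
    for i, g in enumerate(genes):
        chrom = str(i % 22 + 1)
        start = 1_000_000 * (i // 22 + 1) + 50_000 * i
        rows.append({"gene": g, "chrom": chrom,
                     "strand": "+" if i % 2 == 0 else "-",
                     "cds_start": start, "cds_end": start + cds_length - 1})
    return pd.DataFrame(rows).set_index("gene")


def generate_genotypes(truth: SimTruth, cohort: pd.DataFrame,
                       snp_config: SnpConfig, seed: int,
                       eqtl_fraction: float = 0.3,
                       eqtl_beta_range: tuple[float, float] = (0.2, 0.5),
                       ) -> tuple[GenotypeSet, pd.DataFrame]:
    """Simulate the cis-SNP panel for the cohort.

    Doses are binomial(2, MAF) for SNPs in Hardy-Weinberg equilibrium;
    designated violators are drawn from an inbreeding-style heterozygote-
    deficit mixture; designated low-call SNPs receive >5% missing entries.
    eQTL betas are drawn here and written into ``truth.eqtl_effect``; apply
    them to an expression matrix with :func:`apply_eqtl_effects`.

    Returns the genotype set and the gene annotation table used to place
    the SNPs.
    """
    cfg = snp_config
    lo, hi = cfg.maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("MAF range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)

    subjects = sorted(cohort["subject_id"].unique())
    n = len(subjects)
    gene_ann = make_gene_annotation(truth.genes, cfg.cds_length)

    snp_rows, dose_rows, snp_ids = [], [], []
    truth.eqtl_effect = {}
    for g in truth.genes:
        ann = gene_ann.loc[g]
        lo_w = ann.cds_start - (cfg.upstream if ann.strand == "+" else cfg.downstream)
        hi_w = ann.cds_end + (cfg.downstream if ann.strand == "+" else cfg.upstream)
        has_eqtl = rng.random() < eqtl_fraction
        for k in range(cfg.snps_per_gene):
            snp = f"rs{g[1:]}{k:02d}"
            if rng.random() < cfg.outside_window_fraction:
                pos = hi_w + rng.integers(10_000, 50_000)   # outside cis window
            else:
                pos = int(rng.integers(max(1, lo_w), hi_w + 1))
            maf = rng.uniform(lo, hi)
            violator = rng.random() < cfg.hwe_violator_fraction
            low_call = rng.random() < cfg.low_call_fraction
            if violator:
                f = cfg.inbreeding_f
                p_het = 2 * maf * (1 - maf) * (1 - f)
                p_hom_min = maf ** 2 + f * maf * (1 - maf)
                p_hom_maj = 1.0 - p_het - p_hom_min
                dose = rng.choice([0, 1, 2], size=n,
                                  p=[p_hom_maj, p_het, p_hom_min]).astype(float)
            else:
                dose = rng.binomial(2, maf, size=n).astype(float)
            if low_call:
                miss = rng.random(n) < cfg.low_call_missing_rate
                dose[miss] = np.nan
            snp_rows.append({"snp": snp, "chrom": ann.chrom, "pos": int(pos),
                             "minor": "A", "major": "G", "maf": maf,
                             "gene_hint": g})
            dose_rows.append(dose)
            snp_ids.append(snp)
            if has_eqtl and k == 0 and not violator and not low_call:
                beta = rng.uniform(*eqtl_beta_range)
                truth.eqtl_effect[(snp, g)] = float(beta)
    doses = pd.DataFrame(np.array(dose_rows), index=pd.Index(snp_ids, name="snp"),
                         columns=subjects)
    annotation = pd.DataFrame(snp_rows).set_index("snp")
    return GenotypeSet(doses=doses, annotation=annotation), gene_ann.reset_index()


# --------------------------------------------------------------------------- #
# one-call convenience                                                        #
# --------------------------------------------------------------------------- #

def simulate_study(config: SimConfig | None = None, n_subjects: int = 300,
                   seed: int = 0, plate_design: PlateDesign | None = None,
                   snp_config: SnpConfig | None = None):
    """Generate a complete synthetic study: truth, cohort, expression
    (with eQTL effects applied), Ct plates and genotypes.

    Stage seeds are derived deterministically from ``seed``.
    """
    config = config or SimConfig()
    plate_design = plate_design or PlateDesign()
    snp_config = snp_config or SnpConfig()
    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    truth = generate_truth(config, seeds[0])
    cohort = generate_cohort(truth, n_subjects, seeds[1])
    expr = generate_expression(truth, cohort, seeds[2])
    genotypes, gene_ann = generate_genotypes(truth, cohort, snp_config, seeds[3])
    expr = apply_eqtl_effects(expr, genotypes, truth)
    ct = generate_ct_plates(expr, plate_design, seeds[4])
    return truth, cohort, expr, ct, genotypes, gene_ann
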