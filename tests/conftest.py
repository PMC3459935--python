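"""Shared fixtures: one small synthetic study reused across test modules."""
import numpy as np
import pandas as pd
import pytest

from atgex import phenotypes
from atgex.simulate import (PlateDesign, SimConfig, SnpConfig,
                            apply_eqtl_effects, generate_cohort,
                            generate_ct_plates, generate_expression,
                            generate_genotypes, generate_truth)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return generate_cohort(small_truth, n_subjects=60, seed=12)


@pytest.fixture(scope="session")
def small_cohort_derived(small_cohort):
    return phenotypes.derive_phenotypes(small_cohort)


@pytest.fixture(scope="session")
def small_expression(small_truth, small_cohort):
    return generate_expression(small_truth, small_cohort, seed=13)


@pytest.fixture(scope="session")
def small_ct(small_expression):
    return generate_ct_plates(small_expression, PlateDesign(), seed=14)


@pytest.fixture(scope="session")
def small_genotypes(small_truth, small_cohort):
    geno, gene_ann = generate_genotypes(small_truth, small_cohort,
                                        SnpConfig(), seed=15)
    return geno, gene_ann


@pytest.fixture(scope="session")
def small_expression_eqtl(small_truth, small_cohort, small_genotypes):
    geno, _ = small_genotypes
    expr = generate_expression(small_truth, small_cohort, seed=13)
    return apply_eqtl_effects(expr, geno, small_truth)


def draw_ggm_data(truth, n_per_group, seed):
    """Multivariate-normal draws from each group's precision matrix."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for g in truth.groups:
        cov = np.linalg.inv(truth.precision_by_group[g])
        L = np.linalg.cholesky(cov)
        blocks.append((L @ rng.standard_normal((len(truth.genes),
                                                n_per_group))).T)
        labels += [g] * n_per_group
    data = pd.DataFrame(np.vstack(blocks), columns=truth.genes)
    return data, pd.Series(labels, index=data.index)
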