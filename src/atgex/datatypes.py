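"""Core in-memory containers shared across the pipeline stages.

All tabular data are pandas objects; the thin dataclass wrappers exist to
carry provenance (how a matrix was produced) and side tables (per-gene Ct
baselines, QC reports) alongside the values without inventing a new file
format.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Sentinel Ct value written by the instrument for wells with no amplification.
CT_MISSING = 999.0

#: Visit labels: baseline, end of the 8-week low-calorie diet, end of the
#: 26-week weight-maintenance diet.
CIDS = (1, 2, 3)


def sample_key(subject_id: str, cid: int) -> str:
    """Column key identifying one subject-visit, e.g. ``'S0012:2'``."""
    return f"{subject_id}:{cid}"


def split_sample_key(key: str) -> tuple[str, int]:
    subject, cid = key.rsplit(":", 1)
    return subject, int(cid)


@dataclass
class CtSet:
    """Raw per-well qPCR cycle-threshold measurements.

    ``wells`` is a long-format frame with one row per reaction well and
    columns ``plate, set, well, sample_id, cid, gene, ct, is_calibrator,
    is_water``.  ``ct`` is either a cycle value in (0, 40] or the sentinel
    999 for absent amplification.  ``gene_baselines`` maps each gene to the
    reference Ct it would show at log2 relative expression zero; the
    simulator records it so that zero-noise round trips are exact.
    """

    wells: pd.DataFrame
    gene_baselines: pd.Series | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.wells["gene"].unique())

    def plates(self) -> list[int]:
        return sorted(self.wells["plate"].unique())

    def sample_wells(self) -> pd.DataFrame:
        """Wells belonging to study samples (not calibrator, not water)."""
        w = self.wells
        return w[~w["is_calibrator"] & ~w["is_water"]]

    def calibrator_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["is_calibrator"]]


@dataclass
class ExpressionSet:
    """Genes x sample-visits matrix of log2 relative expression.

    ``values`` rows are genes, columns are ``subject:cid`` sample keys.
    ``provenance`` records how the matrix was obtained (normalization
    method, reference gene, QC report).
    """

    values: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def for_cid(self, cid: int) -> pd.DataFrame:
        """Sub-matrix of one visit, columns relabelled to subject ids."""
        cols = [c for c in self.values.columns if split_sample_key(c)[1] == cid]
        out = self.values[cols].copy()
        out.columns = [split_sample_key(c)[0] for c in cols]
        return out

    def copy(self) -> "ExpressionSet":
        return ExpressionSet(self.values.copy(), dict(self.provenance))


@dataclass
class GenotypeSet:
    """Allele-dose matrix (SNP x subject; 0/1/2 minor-allele counts, NaN missing)
    plus per-SNP annotation with columns ``chrom, pos, minor, major``."""

    doses: pd.DataFrame
    annotation: pd.DataFrame

    def call_rate(self) -> pd.Series:
        return self.doses.notna().mean(axis=1)

    def genotype_counts(self, snp: str) -> tuple[int, int, int]:
        """(n_homozygous_major, n_heterozygous, n_homozygous_minor)."""
        d = self.doses.loc[snp].dropna()
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


@dataclass
class GgmNetwork:
    """Group-labelled undirected partial-correlation network.

    ``adjacency`` and ``weights`` are symmetric matrices indexed by
    ``nodes``; ``weights[i, j]`` is the partial correlation on edge i-j
    (zero off the support).  ``density`` is |E| / (p(p-1)/2).
    """

    nodes: list[str]
    adjacency: np.ndarray
    weights: np.ndarray
    penalty: float
    group: str = ""
    precision: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    @property
    def density(self) -> float:
        p = self.n_nodes
        pairs = p * (p - 1) // 2
        return self.n_edges / pairs if pairs else 0.0

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as sorted node-name pairs."""
        out = set()
        idx = np.argwhere(np.triu(self.adjacency, 1))
        for i, j in idx:
            a, b = self.nodes[i], self.nodes[j]
            out.add((a, b) if a <= b else (b, a))
        return out
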