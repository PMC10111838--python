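"""Kinship from microbiome (OTU) and transcriptome (expression) abundances.

Microbiome relatedness M averages the cross-products of log-transformed,
column-standardized OTU abundances:

    O_ij = (log(X_ij + c) - mean_j) / sd_j,      M = O O' / q

with q the number of retained OTU columns.  Transcriptome relatedness T uses
plain per-gene z-scores (no log) and, in its literal form, no division by the
gene count:

    r_ij = (X_ij - mean_j) / sd_j,               T = R R'

so diag(T) grows with the number of genes; ``scale_by_genes=True`` divides by
q for comparability with M.  Standard deviations use the population divisor n
by default (making mean(diag(M)) exactly 1 when nothing is dropped); a flag
switches to n - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinship import KinshipMatrix

__all__ = [
    "AbundanceMatrix",
    "NormalizedFeatures",
    "normalize_abundance",
    "normalize_expression",
    "make_M",
    "make_T",
]

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """n x q nonnegative feature matrix (OTU counts or expression values)."""

    values: np.ndarray
    individual_ids: list[str]
    feature_ids: list[str]
    kind: str = "otu"  # "otu" | "expression"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("abundance values must be a 2-D array")
        n, q = self.values.shape
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.feature_ids = [str(i) for i in self.feature_ids]
        if len(self.individual_ids) != n or len(self.feature_ids) != q:
            raise ValueError("label lengths do not match value shape")
        if self.kind not in ("otu", "expression"):
            raise ValueError("kind must be 'otu' or 'expression'")
        if not np.isfinite(self.values).all():
            raise ValueError("abundance values must be finite")
        if self.kind == "otu" and (self.values < 0).any():
            raise ValueError("OTU abundances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizedFeatures:
    """Column-standardized feature matrix with dropped zero-variance labels."""

    values: np.ndarray
    individual_ids: list[str]
    feature_ids: list[str]
    dropped_features: list[str] = field(default_factory=list)


def _standardize(values: np.ndarray, feature_ids: list[str],
                 ddof: int) -> tuple[np.ndarray, list[str], list[str]]:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    keep = sd > 0.0
    dropped = [feature_ids[j] for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info("dropping %d zero-variance features", len(dropped))
    Z = (values[:, keep] - mean[keep]) / sd[keep]
    kept = [feature_ids[j] for j in np.flatnonzero(keep)]
    return Z, kept, dropped


def normalize_abundance(
    x: AbundanceMatrix, pseudocount: float = 1.0, ddof: int = 0
) -> NormalizedFeatures:
    """Log-transform and column-standardize OTU abundances.

    O_ij = (log(X_ij + c) - mean_j) / sd_j with pseudocount c.  Zero
    abundances require c > 0; zero-variance columns are dropped and reported.
    """
    if x.kind != "otu":
        raise ValueError("normalize_abundance expects kind='otu'")
    if x.n < 2:
        raise ValueError("need at least 2 individuals to standardize")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0.0 and (x.values == 0).any():
        ii, jj = np.nonzero(x.values == 0)
        cells = ", ".join(
            f"({x.individual_ids[i]},{x.feature_ids[j]})"
            for i, j in list(zip(ii, jj))[:5]
        )
        raise ValueError(
            f"zero abundances (e.g. {cells}) cannot be log-transformed; "
            "supply a positive pseudocount")
    L = np.log(x.values + pseudocount)
    Z, kept, dropped = _standardize(L, x.feature_ids, ddof)
    return NormalizedFeatures(Z, x.individual_ids, kept, dropped)


def normalize_expression(x: AbundanceMatrix, ddof: int = 0) -> NormalizedFeatures:
    """Per-gene z-scores r_ij = (X_ij - mean_j) / sd_j; constant genes dropped."""
    if x.kind != "expression":
        raise ValueError("normalize_expression expects kind='expression'")
    if x.n < 2:
        raise ValueError("need at least 2 individuals to standardize")
    Z, kept, dropped = _standardize(x.values, x.feature_ids, ddof)
    return NormalizedFeatures(Z, x.individual_ids, kept, dropped)


def make_M(x: AbundanceMatrix, pseudocount: float = 1.0,
           ddof: int = 0) -> KinshipMatrix:
    """Microbiome kinship M = O O' / q over the q retained OTU columns."""
    norm = normalize_abundance(x, pseudocount=pseudocount, ddof=ddof)
    q = norm.values.shape[1]
    if q == 0:
        raise ValueError("all OTU columns had zero variance; nothing to use")
    M = (norm.values @ norm.values.T) / q
    M = 0.5 * (M + M.T)
    return KinshipMatrix(M, norm.individual_ids,
                         {"method": "microbiome_M", "n_features": q,
                          "pseudocount": pseudocount, "sd_divisor_ddof": ddof,
                          "dropped": len(norm.dropped_features)})


def make_T(x: AbundanceMatrix, scale_by_genes: bool = False,
           ddof: int = 0) -> KinshipMatrix:
    """Transcriptome kinship T = R R' (optionally divided by the gene count)."""
    norm = normalize_expression(x, ddof=ddof)
    q = norm.values.shape[1]
    if q == 0:
        raise ValueError("all genes had zero variance; nothing to use")
    T = norm.values @ norm.values.T
    if scale_by_genes:
        T = T / q
    T = 0.5 * (T + T.T)
    return KinshipMatrix(T, norm.individual_ids,
                         {"method": "transcriptome_T", "n_features": q,
                          "scale_by_genes": scale_by_genes,
                          "sd_divisor_ddof": ddof,
                          "dropped": len(norm.dropped_features)})
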