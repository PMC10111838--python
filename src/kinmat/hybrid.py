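"""Single-step H matrix: blending pedigree and genomic relationships.

When only part of a population is genotyped, the H matrix extends the genomic
relationship matrix to ungenotyped individuals through the pedigree.  With
subscript 1 the ungenotyped and 2 the genotyped individuals,

    H11 = A11 + A12 A22^-1 (Gw - A22) A22^-1 A21
    H12 = A12 A22^-1 Gw          H21 = H12'
    H22 = Gw

where Gw = (1 - w) G* + w A22 and G* = a + b G with (a, b) solving

    avg(diag(G))    b + a = avg(diag(A22))
    avg(offdiag(G)) b + a = avg(offdiag(A22)),

the standard rescaling that places G on the scale of the pedigree A22.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .genomic import GenotypeMatrix, make_G
from .kinship import KinshipMatrix
from .pedigree import PedigreeTable, make_A

__all__ = ["HBlendConfig", "TunedG", "tune_G", "blend_G", "make_H"]

logger = logging.getLogger(__name__)

#: A22 condition-number estimate above which make_H refuses to solve.
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class HBlendConfig:
    """Blending weight w in [0, 1] and whether to rescale G first."""

    w: float = 0.05
    tune: bool = True

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


@dataclass
class TunedG:
    """Rescaled genomic matrix G* = a + b G matched to A22 averages."""

    a: float
    b: float
    G_star: KinshipMatrix


def _check_same_ids(x: KinshipMatrix, y: KinshipMatrix) -> None:
    if x.ids != y.ids:
        raise ValueError("matrices must cover the same individuals in the "
                         "same order")


def _avg_diag_offdiag(M: np.ndarray) -> tuple[float, float]:
    n = M.shape[0]
    diag = float(np.mean(np.diag(M)))
    if n < 2:
        raise ValueError("need at least 2 individuals")
    off = float((M.sum() - np.trace(M)) / (n * (n - 1)))
    return diag, off


def tune_G(G: KinshipMatrix, A22: KinshipMatrix) -> TunedG:
    """Solve the two-equation calibration for a and b and return G* = a + bG."""
    _check_same_ids(G, A22)
    Gd = G.dense()
    Ad = A22.dense()
    dg, og = _avg_diag_offdiag(Gd)
    da, oa = _avg_diag_offdiag(Ad)
    denom = dg - og
    if abs(denom) < 1e-12:
        raise ValueError("tuning system is singular: avg diagonal equals avg "
                         "off-diagonal of G")
    b = (da - oa) / denom
    a = da - b * dg
    meta = dict(G.meta)
    meta.update({"tuned": True, "tune_a": a, "tune_b": b})
    return TunedG(a, b, KinshipMatrix(a + b * Gd, G.ids, meta))


def blend_G(G_star: KinshipMatrix, A22: KinshipMatrix, w: float) -> KinshipMatrix:
    """Convex combination Gw = (1 - w) G* + w A22."""
    _check_same_ids(G_star, A22)
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    meta = dict(G_star.meta)
    meta["w"] = w
    return KinshipMatrix((1.0 - w) * G_star.dense() + w * A22.dense(),
                         G_star.ids, meta)


def make_H(
    ped: PedigreeTable,
    g: GenotypeMatrix,
    config: HBlendConfig | None = None,
    g_method: str = "vanraden",
    original_order: bool = False,
) -> KinshipMatrix:
    """Single-step H matrix for genotyped and ungenotyped individuals.

    Every genotyped individual must appear in the pedigree.  By default rows
    are ordered [ungenotyped; genotyped] (pedigree order within block 1,
    genotype-matrix order within block 2); ``original_order`` restores the
    pedigree record order instead.  Degenerates to the pedigree A when nobody
    is genotyped and to Gw when everybody is.
    """
    config = config or HBlendConfig()
    A = make_A(ped)
    ped_ids = A.ids
    geno_ids = [str(i) for i in g.individual_ids]
    missing = [i for i in geno_ids if i not in ped.index]
    if missing:
        raise ValueError(f"genotyped individuals missing from the pedigree: "
                         f"{', '.join(missing[:5])}")
    geno_set = set(geno_ids)
    ungeno_ids = [i for i in ped_ids if i not in geno_set]
    if not geno_ids:
        return A
    A22 = A.submatrix(geno_ids)
    G = make_G(g, method=g_method)
    G_star = tune_G(G, A22).G_star if config.tune else G
    Gw = blend_G(G_star, A22, config.w)
    if not ungeno_ids:
        meta = dict(Gw.meta)
        meta["method"] = "single_step_H"
        return KinshipMatrix(Gw.dense(), Gw.ids, meta)

    Ad = A.dense()
    pos = {label: k for k, label in enumerate(ped_ids)}
    i1 = np.array([pos[i] for i in ungeno_ids], dtype=int)
    i2 = np.array([pos[i] for i in geno_ids], dtype=int)
    A11 = Ad[np.ix_(i1, i1)]
    A12 = Ad[np.ix_(i1, i2)]
    A22d = A22.dense()
    cond = np.linalg.cond(A22d)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"A22 is numerically singular (condition estimate {cond:.3g}); "
            "check the pedigree for duplicated or disconnected individuals")
    cf = cho_factor(A22d, lower=True)
    S = cho_solve(cf, A12.T)            # A22^-1 A21, shape (n2, n1)
    Gwd = Gw.dense()
    H12 = (Gwd @ S).T                    # A12 A22^-1 Gw
    M = Gwd - A22d
    H11 = A11 + S.T @ M @ S
    H11 = 0.5 * (H11 + H11.T)
    n1, n2 = i1.size, i2.size
    H = np.empty((n1 + n2, n1 + n2))
    H[:n1, :n1] = H11
    H[:n1, n1:] = H12
    H[n1:, :n1] = H12.T
    H[n1:, n1:] = Gwd
    ids = ungeno_ids + geno_ids
    meta = {"method": "single_step_H", "w": config.w, "tuned": config.tune,
            "g_method": g_method, "n_ungenotyped": n1, "n_genotyped": n2}
    K = KinshipMatrix(H, ids, meta)
    if original_order:
        K = K.submatrix(ped_ids)
        K.meta = meta | {"order": "pedigree"}
    return K
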