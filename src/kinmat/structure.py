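"""Population-structure views of a kinship matrix.

PCA treats the kinship matrix as a similarity (Gram) matrix: it is double
centered and eigendecomposed (classical multidimensional scaling), scores
being eigenvectors scaled by the square root of their eigenvalues.
Hierarchical clustering converts kinship to the distance d = max(K) - K and
runs standard agglomeration.  Heat-map ordering and family-tree extraction
return data, not pictures; rendering is an optional layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .kinship import KinshipMatrix
from .pedigree import PedigreeTable

__all__ = [
    "PCAResult",
    "DendrogramNode",
    "kinship_pca",
    "kinship_cluster",
    "heatmap_matrix",
    "family_tree",
]


@dataclass
class PCAResult:
    """Scores (n x k), variance fractions and the full eigenvalue spectrum."""

    scores: np.ndarray
    variance_explained: np.ndarray
    eigenvalues: np.ndarray
    ids: list[str]
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class DendrogramNode:
    """Binary merge tree; leaves carry a single individual id."""

    children: Optional[tuple["DendrogramNode", "DendrogramNode"]]
    merge_height: float
    member_ids: list[str]
    linkage_matrix: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


def kinship_pca(K: KinshipMatrix, k: int, center: bool = True) -> PCAResult:
    """PCA of a kinship matrix.

    With ``center`` (default), the matrix is double centered (J K J with
    J = I - 11'/n) before eigendecomposition — classical MDS on a Gram
    matrix; ``center=False`` eigendecomposes K as is.  Scores are
    v_i * sqrt(lambda_i) for the top k nonnegative eigenvalues; variance
    fractions are taken over the nonnegative eigenvalues only, any negative
    ones (possible for tuned/blended matrices) being reported separately.
    """
    n = K.n
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and n")
    M = K.dense()
    if np.max(np.abs(M - M.T)) > 1e-8:
        raise ValueError("kinship matrix is not symmetric")
    if center:
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        M = J @ M @ J
        M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    nonneg = vals >= 0.0
    total = float(vals[nonneg].sum())
    k_eff = min(k, int(nonneg.sum()))
    lam = vals[:k_eff]
    scores = vecs[:, :k_eff] * np.sqrt(np.clip(lam, 0.0, None))
    var = (lam / total) if total > 0 else np.zeros(k_eff)
    return PCAResult(scores, var, vals, list(K.ids),
                     negative_eigenvalues=vals[~nonneg])


def _build_tree(node, ids: list[str], Z: np.ndarray) -> DendrogramNode:
    if node.is_leaf():
        return DendrogramNode(None, 0.0, [ids[node.id]])
    left = _build_tree(node.get_left(), ids, Z)
    right = _build_tree(node.get_right(), ids, Z)
    return DendrogramNode((left, right), float(node.dist),
                          left.member_ids + right.member_ids)


def kinship_cluster(K: KinshipMatrix, linkage_method: str = "average"
                    ) -> DendrogramNode:
    """Agglomerative clustering of individuals on d = max(K) - K."""
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError("linkage must be 'average', 'complete' or 'single'")
    n = K.n
    if n < 2:
        raise ValueError("clustering needs at least 2 individuals")
    M = K.dense()
    D = np.max(M) - M
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    root = _build_tree(to_tree(Z), list(K.ids), Z)
    root.linkage_matrix = Z
    return root


def heatmap_matrix(K: KinshipMatrix, order: str = "input"
                   ) -> tuple[np.ndarray, list[str]]:
    """Reorder a kinship matrix for heat-map display.

    ``order='input'`` keeps the given order; ``order='dendrogram'`` uses the
    leaf order of :func:`kinship_cluster`.  Returns the reordered matrix and
    the id permutation.
    """
    if order == "input":
        return K.dense().copy(), list(K.ids)
    if order != "dendrogram":
        raise ValueError("order must be 'input' or 'dendrogram'")
    root = kinship_cluster(K)
    perm = leaves_list(root.linkage_matrix)
    ids = [K.ids[i] for i in perm]
    return K.dense()[np.ix_(perm, perm)], ids


def family_tree(ped: PedigreeTable, id: str, generations: int = 3
                ) -> list[tuple[str, str, str]]:
    """Ancestor edges (child, parent, role) of one individual.

    Walks up to ``generations`` parental levels; unknown parents are simply
    omitted.  With the default 3 generations the list holds at most
    2 + 4 + 8 = 14 edges.
    """
    label = str(id)
    if label not in ped.index:
        raise KeyError(f"individual {label!r} not in pedigree")
    edges: list[tuple[str, str, str]] = []
    seen_edges = set()
    frontier = [label]
    for _ in range(generations):
        nxt: list[str] = []
        for child in frontier:
            r = ped.records[ped.index[child]]
            for parent, role in ((r.sire, "sire"), (r.dam, "dam")):
                if parent is None:
                    continue
                e = (child, parent, role)
                if e not in seen_edges:
                    seen_edges.add(e)
                    edges.append(e)
                nxt.append(parent)
        frontier = nxt
        if not frontier:
            break
    return edges
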