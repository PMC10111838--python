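"""Shared kinship-matrix container.

Every builder in this package (pedigree A/D, genomic G, epistatic K, the
single-step H, microbiome M and transcriptome T) returns a
:class:`KinshipMatrix`: an n x n symmetric matrix of pairwise relatedness
tagged with individual ids and provenance metadata.  The values array may be
dense (``numpy.ndarray``) or a ``scipy.sparse`` matrix (pedigree A in sparse
mode); :meth:`dense` always yields a dense view for numerical work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["KinshipMatrix"]

_SYM_TOL = 1e-10


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix with individual ids and provenance.

    Parameters
    ----------
    values
        n x n symmetric matrix (dense ndarray or scipy sparse).
    ids
        n unique individual labels, in row/column order.
    meta
        Provenance: method tag, normalization constants, parameters used.
    """

    values: Any
    ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("kinship matrix ids must be unique")
        shape = self.values.shape
        if shape != (n, n):
            raise ValueError(f"values shape {shape} does not match {n} ids")
        dense = self.dense()
        if n and np.max(np.abs(dense - dense.T)) > _SYM_TOL:
            raise ValueError("kinship matrix is not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def diagonal(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.diagonal(), dtype=float)
        return np.diag(self.dense()).copy()

    def index_of(self, label: str) -> int:
        try:
            return self.ids.index(str(label))
        except ValueError:
            raise KeyError(f"individual {label!r} not in kinship matrix") from None

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        """Extract the principal submatrix for ``ids`` in the given order."""
        idx = np.array([self.index_of(i) for i in ids], dtype=int)
        return KinshipMatrix(self.dense()[np.ix_(idx, idx)], list(map(str, ids)),
                             dict(self.meta))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.ids, columns=self.ids)
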