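"""Pedigree validation, sorting, subsetting and pedigree-based kinship.

A pedigree is a list of (id, sire, dam) records, optionally carrying a birth
order (proxy for birth date) and a sex.  Unknown parents are ``None``
internally; files encode them as ``0``, empty or NA.  The additive
(numerator) relationship matrix A follows Meuwissen & Luo's ancestor-path
algorithm for inbreeding coefficients, with the full matrix assembled by the
classical tabular recursion; the dominance matrix D uses the standard
sire/dam product decomposition.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kinship import KinshipMatrix

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "PedigreeTable",
    "PedigreeIssue",
    "IssueKind",
    "PedigreeError",
    "sort_pedigree",
    "select_pedigree",
    "make_A",
    "make_D",
    "inbreeding_coefficients",
    "kinship_coefficients",
]

logger = logging.getLogger(__name__)

#: Sentinel used in files for an unknown parent ("0", "", NA all map here).
UNKNOWN = None

_UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", "null", "."}


def _parent(value) -> Optional[str]:
    """Normalize a raw parent field to a label or ``None`` (unknown)."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s.lower() in _UNKNOWN_TOKENS:
        return None
    return s


class PedigreeError(ValueError):
    """Fatal pedigree problem (loop, conflicting duplicates, ...)."""


class IssueKind(str, Enum):
    PARENT_AFTER_OFFSPRING = "PARENT_AFTER_OFFSPRING"
    DUPLICATE_ID_CONFLICTING_PARENTS = "DUPLICATE_ID_CONFLICTING_PARENTS"
    LOOP = "LOOP"
    TWO_GENDERS = "TWO_GENDERS"
    MISSING_PARENT_RECORD = "MISSING_PARENT_RECORD"


@dataclass(frozen=True)
class PedigreeIssue:
    kind: IssueKind
    ids: tuple[str, ...]
    fatal: bool
    message: str = ""


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    birth_order: Optional[int] = None
    sex: Optional[str] = None  # "male" | "female" | None

    def __post_init__(self):
        object.__setattr__(self, "id", str(self.id).strip())
        object.__setattr__(self, "sire", _parent(self.sire))
        object.__setattr__(self, "dam", _parent(self.dam))
        if self.id == "" or self.id.lower() in _UNKNOWN_TOKENS:
            raise PedigreeError("individual id may not be the unknown sentinel")


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree: parents precede offspring."""

    records: list[PedigreeRecord]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {r.id: i for i, r in enumerate(self.records)}
        if len(self.index) != len(self.records):
            raise PedigreeError("duplicate ids in pedigree table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam positions per record; -1 encodes an unknown parent."""
        s = np.full(len(self.records), -1, dtype=np.int64)
        d = np.full(len(self.records), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire is not None:
                s[i] = self.index[r.sire]
            if r.dam is not None:
                d[i] = self.index[r.dam]
        return s, d

    def is_sorted(self) -> bool:
        """True when every known parent appears before its offspring."""
        for i, r in enumerate(self.records):
            for p in (r.sire, r.dam):
                if p is not None and (p not in self.index or self.index[p] >= i):
                    return False
        return True

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire if r.sire is not None else "0" for r in self.records],
                "dam": [r.dam if r.dam is not None else "0" for r in self.records],
                "birth_order": [r.birth_order for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# sorting / validation
# ---------------------------------------------------------------------------

def sort_pedigree(
    records: Iterable[PedigreeRecord],
) -> tuple[Optional[PedigreeTable], list[PedigreeIssue]]:
    """Validate and topologically sort a raw pedigree.

    Returns the sorted table and the list of detected issues.  When any fatal
    issue is found (loop, conflicting duplicate ids, two-gender parent) no
    table is returned.  Referenced-but-absent parents are promoted to founder
    records and reported as repairable ``MISSING_PARENT_RECORD`` issues.
    Exact duplicate records are dropped with a logged warning.  Sorting is
    deterministic: ties break by birth_order, then by input order.
    """
    issues: list[PedigreeIssue] = []
    recs: list[PedigreeRecord] = []
    seen: dict[str, PedigreeRecord] = {}
    for r in records:
        if not isinstance(r, PedigreeRecord):
            r = PedigreeRecord(*r)
        prev = seen.get(r.id)
        if prev is None:
            seen[r.id] = r
            recs.append(r)
        elif (prev.sire, prev.dam) == (r.sire, r.dam):
            logger.warning("duplicate identical record for id %s dropped", r.id)
        else:
            issues.append(
                PedigreeIssue(
                    IssueKind.DUPLICATE_ID_CONFLICTING_PARENTS,
                    (r.id,),
                    fatal=True,
                    message=(
                        f"id {r.id!r} recorded with parents "
                        f"({prev.sire},{prev.dam}) and ({r.sire},{r.dam})"
                    ),
                )
            )

    # self-parenting is the smallest loop
    for r in recs:
        if r.id in (r.sire, r.dam):
            issues.append(
                PedigreeIssue(IssueKind.LOOP, (r.id,), fatal=True,
                              message=f"{r.id!r} is its own parent")
            )

    # founder promotion for referenced-but-absent parents
    known = {r.id for r in recs}
    for r in list(recs):
        for p in (r.sire, r.dam):
            if p is not None and p not in known:
                known.add(p)
                recs.append(PedigreeRecord(p))
                issues.append(
                    PedigreeIssue(IssueKind.MISSING_PARENT_RECORD, (p,), fatal=False,
                                  message=f"parent {p!r} had no record; founder added")
                )

    # two-gender check: same id used both as a sire and as a dam, or used in
    # a role contradicting its declared sex
    as_sire = {r.sire for r in recs if r.sire is not None}
    as_dam = {r.dam for r in recs if r.dam is not None}
    by_id = {r.id: r for r in recs}
    for label in sorted(as_sire & as_dam):
        issues.append(
            PedigreeIssue(IssueKind.TWO_GENDERS, (label,), fatal=True,
                          message=f"{label!r} appears both as sire and as dam")
        )
    for label in sorted(as_sire | as_dam):
        sex = by_id[label].sex if label in by_id else None
        if sex == "female" and label in as_sire and label not in as_dam:
            issues.append(PedigreeIssue(IssueKind.TWO_GENDERS, (label,), fatal=True,
                                        message=f"female {label!r} used as sire"))
        elif sex == "male" and label in as_dam and label not in as_sire:
            issues.append(PedigreeIssue(IssueKind.TWO_GENDERS, (label,), fatal=True,
                                        message=f"male {label!r} used as dam"))

    # birth-order sanity (only checkable when both sides carry birth_order)
    for r in recs:
        if r.birth_order is None:
            continue
        for p in (r.sire, r.dam):
            if p is None:
                continue
            pb = by_id[p].birth_order if p in by_id else None
            if pb is not None and pb > r.birth_order:
                issues.append(
                    PedigreeIssue(IssueKind.PARENT_AFTER_OFFSPRING, (r.id, p),
                                  fatal=False,
                                  message=f"parent {p!r} born after offspring {r.id!r}")
                )

    # Kahn topological sort, deterministic tie-break (birth_order, input order)
    pos = {r.id: i for i, r in enumerate(recs)}
    children: dict[str, list[str]] = {r.id: [] for r in recs}
    indeg = {r.id: 0 for r in recs}
    for r in recs:
        for p in {p for p in (r.sire, r.dam) if p is not None and p != r.id}:
            children[p].append(r.id)
            indeg[r.id] += 1

    def _key(label: str):
        r = by_id[label]
        bo = r.birth_order if r.birth_order is not None else float("inf")
        return (bo, pos[label])

    heap = [(_key(r.id), r.id) for r in recs if indeg[r.id] == 0]
    heapq.heapify(heap)
    order: list[str] = []
    while heap:
        _, label = heapq.heappop(heap)
        order.append(label)
        for c in children[label]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (_key(c), c))

    if len(order) != len(recs):
        stuck = sorted((label for label, k in indeg.items() if k > 0),
                       key=lambda x: pos[x])
        issues.append(
            PedigreeIssue(IssueKind.LOOP, tuple(stuck), fatal=True,
                          message="loop in pedigree: " + ",".join(stuck))
        )

    if any(i.fatal for i in issues):
        return None, issues
    table = PedigreeTable([by_id[label] for label in order])
    return table, issues


def select_pedigree(
    ped: PedigreeTable, targets: Sequence[str], generations: int
) -> PedigreeTable:
    """Minimal sub-pedigree of ``targets`` plus ancestors ``generations`` back.

    Parents falling outside the horizon are replaced by the unknown sentinel.
    The returned table is sorted.
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    targets = [str(t) for t in targets]
    for t in targets:
        if t not in ped.index:
            raise KeyError(f"target individual {t!r} not in pedigree")
    kept: set[str] = set(targets)
    frontier = set(targets)
    for _ in range(generations):
        nxt: set[str] = set()
        for label in frontier:
            r = ped.records[ped.index[label]]
            for p in (r.sire, r.dam):
                if p is not None and p not in kept:
                    nxt.add(p)
        kept |= nxt
        frontier = nxt
        if not frontier:
            break
    sub = []
    for label in sorted(kept, key=lambda x: ped.index[x]):
        r = ped.records[ped.index[label]]
        sub.append(
            PedigreeRecord(
                r.id,
                r.sire if r.sire in kept else None,
                r.dam if r.dam in kept else None,
                r.birth_order,
                r.sex,
            )
        )
    table, issues = sort_pedigree(sub)
    assert table is not None, issues
    return table


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def _require_sorted(ped: PedigreeTable) -> None:
    if not ped.is_sorted():
        raise PedigreeError(
            "pedigree is not sorted (parents must precede offspring); "
            "run sort_pedigree first"
        )


def _meuwissen_luo_inbreeding(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the ancestor-path (L-matrix) algorithm.

    For individual i, A_ii = sum_j L_ij^2 * w_j where L_ij traces the flow of
    genes from ancestor j to i and w_j is the within-family segregation
    variance of j.  Only ancestors of i are visited, so the cost is far below
    a full tabular pass on shallow pedigrees.
    """
    n = s.size
    F = np.zeros(n)
    w = np.empty(n)  # segregation variance per individual
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            w[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0:
            w[i] = 0.75 - 0.25 * F[si]
        elif di >= 0:
            w[i] = 0.75 - 0.25 * F[di]
        else:
            w[i] = 1.0
        if si < 0 or di < 0:
            F[i] = 0.0  # one unknown parent: relationship term is zero
            continue
        L = np.zeros(i + 1)
        L[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            a_ii += lj * lj * w[j]
            if s[j] >= 0:
                L[s[j]] += 0.5 * lj
            if d[j] >= 0:
                L[d[j]] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


def make_A(ped: PedigreeTable, sparse: bool = False) -> KinshipMatrix:
    """Additive (numerator) relationship matrix from a sorted pedigree.

    Diagonal entries are 1 + F_i with F_i computed by the Meuwissen-Luo
    ancestor-path algorithm; off-diagonals follow the tabular recursion
    A_ij = 0.5 (A_j,s(i) + A_j,d(i)).  Founders are assumed non-inbred and
    unrelated.  With ``sparse=True`` the result is stored as CSR.
    """
    _require_sorted(ped)
    n = len(ped)
    s, d = ped.parent_indices()
    F = _meuwissen_luo_inbreeding(s, d)
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            row = 0.5 * (A[si, :i] + A[di, :i])
        elif si >= 0:
            row = 0.5 * A[si, :i]
        elif di >= 0:
            row = 0.5 * A[di, :i]
        else:
            row = np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + F[i]
    values = sp.csr_matrix(A) if sparse else A
    return KinshipMatrix(values, ped.ids, {"method": "pedigree_additive",
                                           "sparse": sparse})


def make_D(ped: PedigreeTable) -> KinshipMatrix:
    """Pedigree dominance relationship matrix.

    D_ij = 0.25 (A_s(i)s(j) A_d(i)d(j) + A_s(i)d(j) A_d(i)s(j)) for i != j and
    D_ii = 1; any term involving an unknown parent contributes zero.  The
    diagonal deliberately ignores inbreeding.
    """
    _require_sorted(ped)
    n = len(ped)
    A = make_A(ped).dense()
    s, d = ped.parent_indices()
    # pad A with a zero row/column standing in for the unknown parent
    Ap = np.zeros((n + 1, n + 1))
    Ap[:n, :n] = A
    si = np.where(s < 0, n, s)
    di = np.where(d < 0, n, d)
    D = 0.25 * (
        Ap[np.ix_(si, si)] * Ap[np.ix_(di, di)]
        + Ap[np.ix_(si, di)] * Ap[np.ix_(di, si)]
    )
    np.fill_diagonal(D, 1.0)
    return KinshipMatrix(D, ped.ids, {"method": "pedigree_dominance"})


def inbreeding_coefficients(A: KinshipMatrix) -> pd.Series:
    """Per-individual inbreeding coefficients F_i = A_ii - 1.

    Valid for any additive matrix following the diag = 1 + F convention;
    genomic matrices may yield negative F.
    """
    return pd.Series(A.diagonal() - 1.0, index=A.ids, name="F")


def kinship_coefficients(A: KinshipMatrix) -> KinshipMatrix:
    """Pairwise coancestry (kinship) coefficients theta_ij = A_ij / 2."""
    meta = dict(A.meta)
    meta["method"] = "coancestry"
    return KinshipMatrix(A.dense() / 2.0, A.ids, meta)
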