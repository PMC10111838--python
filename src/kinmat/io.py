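"""File formats: pedigree/genotype/abundance readers and kinship writers.

Kinship matrices can be written three ways so downstream mixed-model
software loads them directly:

square_csv
    Ids in the header, full symmetric matrix, 10 significant digits.
gcta_grm
    The binary GRM triplet ``<stem>.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``:
    little-endian float32 of the lower triangle including the diagonal in
    (1,1),(2,1),(2,2),... order, the per-pair marker counts in the same
    layout, and two tab-separated id columns (family id repeated).
dmu_triplet
    Text lines ``i j value`` with 1-based integer codes, lower triangle
    including diagonal, 15-digit scientific notation, plus a ``<stem>.ids``
    sidecar mapping codes to labels.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .kinship import KinshipMatrix
from .omics import AbundanceMatrix
from .pedigree import PedigreeRecord

__all__ = [
    "read_pedigree",
    "read_genotypes_csv",
    "read_genotypes_raw",
    "read_population",
    "read_abundance",
    "write_kinship",
    "read_kinship",
    "KINSHIP_FORMATS",
]

logger = logging.getLogger(__name__)

KINSHIP_FORMATS = ("square_csv", "gcta_grm", "dmu_triplet")


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    # comma/tab/whitespace separated, auto-detected
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       skipinitialspace=True)


def read_pedigree(path) -> list[PedigreeRecord]:
    """Pedigree CSV: ``id,sire,dam[,birth_order][,sex]``; 0/empty = unknown."""
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("id", "sire", "dam"):
        if req not in cols:
            raise ValueError(f"pedigree file {path} lacks a {req!r} column")
    records = []
    for _, row in df.iterrows():
        bo = row[cols["birth_order"]] if "birth_order" in cols else None
        if bo is not None and not pd.isna(bo):
            bo = int(float(bo))
        else:
            bo = None
        sex = row[cols["sex"]] if "sex" in cols else None
        if sex is not None and pd.isna(sex):
            sex = None
        records.append(PedigreeRecord(row[cols["id"]], row[cols["sire"]],
                                      row[cols["dam"]], bo, sex))
    return records


def read_genotypes_csv(path, marker_map: Optional[str] = None) -> GenotypeMatrix:
    """Genotype CSV: first column individual id, remaining columns dosages.

    ``marker_map`` is an optional companion CSV ``marker,chromosome``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    markers = [str(c) for c in df.columns[1:]]
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    chrom = None
    if marker_map is not None:
        mm = pd.read_csv(marker_map, sep=None, engine="python", dtype=str)
        lookup = dict(zip(mm.iloc[:, 0], mm.iloc[:, 1]))
        missing = [m for m in markers if m not in lookup]
        if missing:
            raise ValueError(f"marker map lacks {len(missing)} markers "
                             f"(e.g. {missing[0]!r})")
        chrom = [lookup[m] for m in markers]
    return GenotypeMatrix(dosages, ids, markers, chrom)


_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_genotypes_raw(path) -> GenotypeMatrix:
    """PLINK .raw dialect: whitespace table with FID IID PAT MAT SEX
    PHENOTYPE then one ``<SNP>_<allele>`` dosage column per marker, NA
    missing.  IID is used as the individual id."""
    df = pd.read_csv(path, sep=r"\s+")
    for col in _RAW_META:
        if col not in df.columns:
            raise ValueError(f".raw file {path} lacks the {col} column")
    snp_cols = [c for c in df.columns if c not in _RAW_META]
    markers = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    dosages = df[snp_cols].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, df["IID"].astype(str).tolist(), markers)


def read_population(path) -> dict[str, str]:
    """Population file ``id,population`` -> mapping."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError("population file needs two columns: id,population")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_abundance(path, kind: str = "otu") -> AbundanceMatrix:
    """Abundance CSV: rows individuals (first column id), columns features."""
    df = pd.read_csv(path, sep=None, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    features = [str(c) for c in df.columns[1:]]
    return AbundanceMatrix(df.iloc[:, 1:].to_numpy(dtype=float), ids,
                           features, kind)


# ---------------------------------------------------------------------------
# kinship writers / readers
# ---------------------------------------------------------------------------

def write_kinship(K: KinshipMatrix, stem, fmt: str = "square_csv",
                  n_markers: Optional[int] = None) -> list[Path]:
    """Write a kinship matrix; returns the list of files produced."""
    if fmt not in KINSHIP_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {KINSHIP_FORMATS}")
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    M = K.dense()
    n = K.n
    if fmt == "square_csv":
        path = stem if stem.suffix == ".csv" else stem.with_suffix(".csv")
        df = pd.DataFrame(M, index=K.ids, columns=K.ids)
        df.to_csv(path, float_format="%.10g", index_label="id")
        return [path]
    tri_i, tri_j = np.tril_indices(n)
    if fmt == "gcta_grm":
        if n_markers is None:
            raise ValueError("gcta_grm requires n_markers")
        vals = M[tri_i, tri_j].astype("<f4")
        counts = np.full(vals.size, float(n_markers), dtype="<f4")
        p_bin = Path(str(stem) + ".grm.bin")
        p_n = Path(str(stem) + ".grm.N.bin")
        p_id = Path(str(stem) + ".grm.id")
        vals.tofile(p_bin)
        counts.tofile(p_n)
        with open(p_id, "w") as fh:
            for label in K.ids:
                fh.write(f"{label}\t{label}\n")
        return [p_bin, p_n, p_id]
    # dmu_triplet
    p_txt = Path(str(stem) + ".dmu.txt")
    p_ids = Path(str(stem) + ".ids")
    with open(p_txt, "w") as fh:
        for i, j in zip(tri_i, tri_j):
            fh.write(f"{i + 1} {j + 1} {M[i, j]:.15e}\n")
    with open(p_ids, "w") as fh:
        fh.write("code,id\n")
        for k, label in enumerate(K.ids, start=1):
            fh.write(f"{k},{label}\n")
    return [p_txt, p_ids]


def read_kinship(stem, fmt: str = "square_csv") -> KinshipMatrix:
    """Read a kinship matrix written by :func:`write_kinship`."""
    if fmt not in KINSHIP_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {KINSHIP_FORMATS}")
    stem = Path(stem)
    if fmt == "square_csv":
        path = stem if stem.suffix == ".csv" else stem.with_suffix(".csv")
        df = pd.read_csv(path, index_col=0)
        M = df.to_numpy(dtype=float)
        M = 0.5 * (M + M.T)  # undo round-off asymmetry from decimal storage
        return KinshipMatrix(M, [str(i) for i in df.index],
                             {"source": str(path)})
    if fmt == "gcta_grm":
        p_bin = Path(str(stem) + ".grm.bin")
        p_id = Path(str(stem) + ".grm.id")
        ids = [line.split()[1] for line in p_id.read_text().splitlines() if line]
        n = len(ids)
        expected = n * (n + 1) // 2
        vals = np.fromfile(p_bin, dtype="<f4")
        if vals.size != expected:
            raise ValueError(
                f"{p_bin} holds {vals.size} floats; expected {expected} "
                f"(= n(n+1)/2 for n={n})")
        M = np.zeros((n, n))
        tri_i, tri_j = np.tril_indices(n)
        M[tri_i, tri_j] = vals
        M[tri_j, tri_i] = vals
        return KinshipMatrix(M, ids, {"source": str(p_bin)})
    # dmu_triplet
    p_txt = Path(str(stem) + ".dmu.txt")
    p_ids = Path(str(stem) + ".ids")
    id_df = pd.read_csv(p_ids)
    ids = id_df["id"].astype(str).tolist()
    n = len(ids)
    M = np.full((n, n), np.nan)
    for line in p_txt.read_text().splitlines():
        if not line.strip():
            continue
        i_s, j_s, v_s = line.split()
        i, j = int(i_s) - 1, int(j_s) - 1
        M[i, j] = M[j, i] = float(v_s)
    if np.isnan(np.diag(M)).any():
        k = int(np.flatnonzero(np.isnan(np.diag(M)))[0]) + 1
        raise ValueError(f"dmu triplet is missing the diagonal entry for "
                         f"individual code {k}")
    if np.isnan(M).any():
        raise ValueError("dmu triplet is missing off-diagonal entries")
    return KinshipMatrix(M, ids, {"source": str(p_txt)})
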