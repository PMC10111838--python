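"""Genomic kinship matrices from marker dosages.

Additive G matrices come in four flavours: VanRaden (single ratio of sums),
Yang (per-marker scaling averaged over m markers), and two combined-population
estimators that account for heterogeneous allele frequencies — Chen (per-marker
geometric-mean cross denominator) and Wientjes (product of the two population
scaling constants).  Dominance and epistatic kinships (d, aa, dd, ad, da) use
the +1/0/-1 additive and 0/1/0 dominance marker codings, with pairwise-locus
matrices normalized to mean diagonal one.

Dosages are 0/1/2 counts of an arbitrary reference allele; missing calls are
NaN.  Allele frequency p is the frequency of the counted allele (the additive
estimators are invariant to which allele is counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinship import KinshipMatrix

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "CodingPair",
    "allele_frequencies",
    "make_G",
    "make_G_chunked",
    "encode_dominance",
    "make_G_inter",
    "normalize_by_mean_diag",
    "G_METHODS",
    "INTER_EFFECTS",
]

logger = logging.getLogger(__name__)

G_METHODS = ("vanraden", "yang", "chen", "wientjes")
INTER_EFFECTS = ("d", "aa", "dd", "ad", "da")


@dataclass
class GenotypeMatrix:
    """n x m dosage matrix with individual/marker labels.

    ``dosages`` holds counts in {0, 1, 2} with NaN for missing calls.
    ``chromosome`` (per marker) enables split-chromosome computation;
    ``population`` (per individual) enables the combined-population methods.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    chromosome: Optional[list[str]] = None
    population: Optional[list[str]] = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(i) for i in self.marker_ids]
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("label lengths do not match dosage shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad}")
        if self.chromosome is not None:
            self.chromosome = [str(c) for c in self.chromosome]
            if len(self.chromosome) != m:
                raise ValueError("chromosome labels do not match marker count")
        if self.population is not None:
            self.population = [str(p) for p in self.population]
            if len(self.population) != n:
                raise ValueError("population labels do not match individuals")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class AlleleFrequencies:
    """Per-marker frequency of the dosage-counted allele."""

    p: np.ndarray
    population: Optional[str] = None
    all_missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.all_missing is None:
            self.all_missing = np.zeros(self.p.size, dtype=bool)


@dataclass
class CodingPair:
    """Additive (Z in {-1,0,+1}) and dominance (W in {0,1}) marker codings."""

    Z: np.ndarray
    W: np.ndarray


def allele_frequencies(g: GenotypeMatrix, by_population: bool = False):
    """Allele frequencies p_j = mean dosage / 2 over non-missing calls.

    With ``by_population`` returns ``{population: AlleleFrequencies}``
    computed within each population.  Markers with no non-missing call are
    flagged (``all_missing``) and logged.
    """
    if by_population:
        if g.population is None:
            raise ValueError("by_population requires population labels")
        out = {}
        pops = list(dict.fromkeys(g.population))
        labels = np.asarray(g.population)
        for pop in pops:
            rows = g.dosages[labels == pop]
            out[pop] = _freqs(rows, pop)
        return out
    return _freqs(g.dosages, None)


def _freqs(dosages: np.ndarray, population: Optional[str]) -> AlleleFrequencies:
    count = np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * count)
    all_missing = count == 0
    if all_missing.any():
        logger.warning("%d markers have no non-missing call%s; flagged for "
                       "exclusion", int(all_missing.sum()),
                       f" in population {population}" if population else "")
        p[all_missing] = np.nan
    return AlleleFrequencies(p, population, all_missing)


def _impute_center(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Center by 2p with missing entries imputed to 2p (zero contribution)."""
    X = dosages - 2.0 * p
    return np.where(np.isnan(dosages), 0.0, X)


def _polymorphic(freqs: AlleleFrequencies) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        mask = (freqs.p > 0.0) & (freqs.p < 1.0)
    mask &= ~freqs.all_missing
    return mask


# ---------------------------------------------------------------------------
# additive G
# ---------------------------------------------------------------------------

def make_G(
    g: GenotypeMatrix,
    method: str = "vanraden",
    freqs: Optional[AlleleFrequencies] = None,
) -> KinshipMatrix:
    """Additive genomic relationship matrix.

    vanraden
        G = sum_j (x_j - 2p_j)(x_j - 2p_j)' / sum_j 2 p_j (1-p_j).
    yang
        G = (1/m) sum_j (x_j - 2p_j)(x_j - 2p_j)' / (2 p_j (1-p_j)), the same
        expression applied to diagonal cells as well.
    chen / wientjes
        Combined-population block estimators with within-population allele
        frequencies; require ``g.population``.  Chen scales cross-population
        blocks by sum_j 2 sqrt(p_1j q_1j p_2j q_2j); Wientjes by
        sqrt(sum_j 2 p_1j q_1j) sqrt(sum_j 2 p_2j q_2j).  More than two
        populations are handled block-pairwise.

    Monomorphic markers are excluded; missing dosages are imputed to the
    (population) mean dosage 2p and so contribute nothing.
    """
    if method not in G_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {G_METHODS}")
    if method in ("chen", "wientjes"):
        if freqs is not None:
            raise ValueError("explicit freqs are only supported for "
                             "single-population methods")
        return _make_G_multipop(g, method)

    f = freqs if freqs is not None else allele_frequencies(g)
    if f.p.size != g.m:
        raise ValueError("frequency vector length does not match marker count")
    keep = _polymorphic(f)
    n_dropped = g.m - int(keep.sum())
    if n_dropped:
        logger.info("excluding %d monomorphic/all-missing markers", n_dropped)
    if not keep.any():
        raise ValueError("no polymorphic markers available")
    p = f.p[keep]
    Xc = _impute_center(g.dosages[:, keep], p)
    if method == "vanraden":
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        G = (Xc @ Xc.T) / denom
        meta = {"method": "vanraden", "denominator": denom}
    else:  # yang
        scale = np.sqrt(2.0 * p * (1.0 - p))
        Xs = Xc / scale
        m = int(keep.sum())
        G = (Xs @ Xs.T) / m
        meta = {"method": "yang"}
    meta["n_markers"] = int(keep.sum())
    G = 0.5 * (G + G.T)
    return KinshipMatrix(G, g.individual_ids, meta)


def _pop_blocks(g: GenotypeMatrix):
    if g.population is None:
        raise ValueError("combined-population methods require population labels")
    labels = np.asarray(g.population)
    pops = list(dict.fromkeys(g.population))
    idx = {pop: np.flatnonzero(labels == pop) for pop in pops}
    for pop, rows in idx.items():
        if rows.size < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
    return pops, idx


def _make_G_multipop(g: GenotypeMatrix, method: str) -> KinshipMatrix:
    pops, idx = _pop_blocks(g)
    pooled = allele_frequencies(g)
    keep = _polymorphic(pooled)
    if not keep.any():
        raise ValueError("no markers polymorphic in the pooled data")
    per_pop = allele_frequencies(g, by_population=True)
    n = g.n
    G = np.zeros((n, n))
    # centered (within-population frequency) genotype blocks on pooled-kept markers
    W = {}
    het = {}
    poly = {}
    for pop in pops:
        f = per_pop[pop]
        p = f.p[keep]
        W[pop] = _impute_center(g.dosages[np.ix_(idx[pop], np.flatnonzero(keep))], p)
        het[pop] = 2.0 * p * (1.0 - p)
        with np.errstate(invalid="ignore"):
            poly[pop] = (f.p[keep] > 0) & (f.p[keep] < 1) & ~f.all_missing[keep]
    for a, pa in enumerate(pops):
        for pb in pops[a:]:
            if pa == pb:
                denom = float(np.sum(het[pa]))
                block = (W[pa] @ W[pa].T) / denom
                block = 0.5 * (block + block.T)
                G[np.ix_(idx[pa], idx[pa])] = block
            else:
                # markers must be polymorphic within both populations for the
                # cross block; others are excluded from these sums only
                both = poly[pa] & poly[pb]
                if not both.any():
                    raise ValueError(
                        f"no marker polymorphic in both {pa!r} and {pb!r}")
                n_excl = int((~both).sum())
                if n_excl:
                    logger.info("cross block %s/%s: excluding %d markers "
                                "monomorphic within one population", pa, pb, n_excl)
                num = W[pa][:, both] @ W[pb][:, both].T
                if method == "chen":
                    denom = float(np.sum(2.0 * np.sqrt(
                        het[pa][both] * het[pb][both] / 4.0)))
                else:  # wientjes
                    denom = float(np.sqrt(np.sum(het[pa][both]))
                                  * np.sqrt(np.sum(het[pb][both])))
                block = num / denom
                G[np.ix_(idx[pa], idx[pb])] = block
                G[np.ix_(idx[pb], idx[pa])] = block.T
    return KinshipMatrix(G, g.individual_ids,
                         {"method": method, "populations": pops,
                          "n_markers": int(keep.sum())})


def make_G_chunked(
    g: GenotypeMatrix,
    method: str = "vanraden",
    chunk_by: str = "chromosome",
    n_blocks: int = 4,
) -> KinshipMatrix:
    """Additive G accumulated over marker chunks.

    Numerator cross-products and denominator sums are accumulated per chunk
    (per chromosome, or ``n_blocks`` contiguous marker blocks) and combined,
    giving the same matrix as the single-pass computation.  Allele
    frequencies and marker filters are computed once, globally, exactly as in
    :func:`make_G`.
    """
    if method not in G_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {G_METHODS}")
    if chunk_by == "chromosome":
        if g.chromosome is None:
            raise ValueError("chunk_by='chromosome' requires chromosome labels")
        chroms = np.asarray(g.chromosome)
        chunks = [np.flatnonzero(chroms == c)
                  for c in dict.fromkeys(g.chromosome)]
    elif chunk_by == "marker_blocks":
        chunks = [np.asarray(c, dtype=int)
                  for c in np.array_split(np.arange(g.m), max(1, n_blocks))
                  if len(c)]
    else:
        raise ValueError("chunk_by must be 'chromosome' or 'marker_blocks'")

    n = g.n
    if method in ("vanraden", "yang"):
        f = allele_frequencies(g)
        keep = _polymorphic(f)
        if not keep.any():
            raise ValueError("no polymorphic markers available")
        num = np.zeros((n, n))
        den = 0.0
        m_total = 0
        for cols in chunks:
            sub = cols[keep[cols]]
            if sub.size == 0:
                continue
            p = f.p[sub]
            Xc = _impute_center(g.dosages[:, sub], p)
            if method == "vanraden":
                num += Xc @ Xc.T
                den += float(np.sum(2.0 * p * (1.0 - p)))
            else:
                Xs = Xc / np.sqrt(2.0 * p * (1.0 - p))
                num += Xs @ Xs.T
                m_total += sub.size
        G = num / den if method == "vanraden" else num / m_total
        G = 0.5 * (G + G.T)
        meta = {"method": method, "chunks": len(chunks),
                "n_markers": int(keep.sum())}
        return KinshipMatrix(G, g.individual_ids, meta)

    # combined-population methods: accumulate block numerators and the
    # denominator components per chunk
    pops, idx = _pop_blocks(g)
    pooled = allele_frequencies(g)
    keep = _polymorphic(pooled)
    if not keep.any():
        raise ValueError("no markers polymorphic in the pooled data")
    per_pop = allele_frequencies(g, by_population=True)
    poly = {}
    for pop in pops:
        f = per_pop[pop]
        with np.errstate(invalid="ignore"):
            poly[pop] = (f.p > 0) & (f.p < 1) & ~f.all_missing
    pairs = [(pa, pb) for a, pa in enumerate(pops) for pb in pops[a:]]
    num = {pr: np.zeros((idx[pr[0]].size, idx[pr[1]].size)) for pr in pairs}
    den = {pr: 0.0 for pr in pairs}
    den2 = {pr: 0.0 for pr in pairs}  # second factor for wientjes cross blocks
    for cols in chunks:
        sub = cols[keep[cols]]
        if sub.size == 0:
            continue
        Wc = {}
        hetc = {}
        for pop in pops:
            p = per_pop[pop].p[sub]
            Wc[pop] = _impute_center(g.dosages[np.ix_(idx[pop], sub)], p)
            hetc[pop] = 2.0 * p * (1.0 - p)
        for pr in pairs:
            pa, pb = pr
            if pa == pb:
                num[pr] += Wc[pa] @ Wc[pa].T
                den[pr] += float(np.sum(hetc[pa]))
            else:
                both = poly[pa][sub] & poly[pb][sub]
                num[pr] += Wc[pa][:, both] @ Wc[pb][:, both].T
                if method == "chen":
                    den[pr] += float(np.sum(2.0 * np.sqrt(
                        hetc[pa][both] * hetc[pb][both] / 4.0)))
                else:
                    den[pr] += float(np.sum(hetc[pa][both]))
                    den2[pr] += float(np.sum(hetc[pb][both]))
    G = np.zeros((n, n))
    for pr in pairs:
        pa, pb = pr
        if pa == pb:
            block = num[pr] / den[pr]
            block = 0.5 * (block + block.T)
            G[np.ix_(idx[pa], idx[pa])] = block
        else:
            if method == "chen":
                d = den[pr]
            else:
                d = float(np.sqrt(den[pr]) * np.sqrt(den2[pr]))
            if d == 0.0:
                raise ValueError(f"no usable marker in cross block {pa}/{pb}")
            block = num[pr] / d
            G[np.ix_(idx[pa], idx[pb])] = block
            G[np.ix_(idx[pb], idx[pa])] = block.T
    return KinshipMatrix(G, g.individual_ids,
                         {"method": method, "chunks": len(chunks),
                          "populations": pops, "n_markers": int(keep.sum())})


# ---------------------------------------------------------------------------
# dominance / epistasis
# ---------------------------------------------------------------------------

def encode_dominance(g: GenotypeMatrix) -> CodingPair:
    """Additive/dominance marker codings.

    Z = dosage - 1 maps the first homozygote to +1, the heterozygote to 0 and
    the second homozygote to -1; W is the heterozygosity indicator.  Missing
    dosages must be imputed beforehand.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("missing dosages present; impute before encoding "
                         "(make_G_inter imputes to the per-marker mode)")
    Z = g.dosages - 1.0
    W = (g.dosages == 1.0).astype(float)
    return CodingPair(Z, W)


def _impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Missing dosages replaced by the marker's most frequent genotype
    (ties toward the smaller dosage)."""
    X = g.dosages
    if not np.isnan(X).any():
        return g
    X = X.copy()
    for j in np.flatnonzero(np.isnan(X).any(axis=0)):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"marker {g.marker_ids[j]!r} entirely missing")
        counts = [(np.sum(obs == v), -v) for v in (0.0, 1.0, 2.0)]
        mode = -max(counts)[1]
        col[np.isnan(col)] = mode
    logger.info("imputed missing dosages to per-marker modal genotype")
    return GenotypeMatrix(X, g.individual_ids, g.marker_ids,
                          g.chromosome, g.population)


def normalize_by_mean_diag(K_raw: KinshipMatrix) -> KinshipMatrix:
    """Scale a raw kinship matrix so its mean diagonal element is one."""
    c = float(np.mean(K_raw.diagonal()))
    if c <= 0.0:
        raise ValueError("mean diagonal of the raw kinship matrix is not "
                         "positive; cannot normalize")
    meta = dict(K_raw.meta)
    meta["scale_constant"] = c
    return KinshipMatrix(K_raw.dense() / c, K_raw.ids, meta)


def make_G_inter(
    g: GenotypeMatrix, effect: str, threads: int = 1
) -> KinshipMatrix:
    """Dominance (d) or epistatic (aa, dd, ad, da) kinship matrix.

    Raw matrices sum outer products of per-locus (d) or ordered pair-of-loci
    (k < k') coding vectors:

    - d:  sum_k w_k w_k'
    - aa: sum_{k<k'} (z_k * z_k')(z_k * z_k')'   (* elementwise)
    - dd: the same with w; ad uses z_k * w_k'; da uses w_k * z_k'.

    aa and dd are evaluated via the Hadamard identity
    2 K* = (XX') o (XX') - (X o X)(X o X)'; the triangular ad/da sums via a
    running suffix accumulation.  The result is scaled to mean diagonal one.
    ``threads`` is accepted for API stability; dense products are delegated
    to BLAS and the summation order is fixed, so results never depend on it.
    """
    if effect not in INTER_EFFECTS:
        raise ValueError(f"unknown effect {effect!r}; choose from {INTER_EFFECTS}")
    if threads < 1:
        raise ValueError("threads must be a positive integer")
    if effect != "d" and g.m < 2:
        raise ValueError("pairwise effects need at least 2 markers")
    coding = encode_dominance(_impute_mode(g))
    Z, W = coding.Z, coding.W
    if effect == "d":
        K = W @ W.T
    elif effect in ("aa", "dd"):
        X = Z if effect == "aa" else W
        XXt = X @ X.T
        X2 = X * X
        K = 0.5 * (XXt * XXt - X2 @ X2.T)
    else:
        first, second = (Z, W) if effect == "ad" else (W, Z)
        n = g.n
        K = np.zeros((n, n))
        suffix = np.zeros((n, n))  # sum_{k' > k} second_k' second_k''
        for k in range(g.m - 1, -1, -1):
            f = first[:, k]
            K += np.outer(f, f) * suffix
            s = second[:, k]
            suffix += np.outer(s, s)
    K = 0.5 * (K + K.T)
    if float(np.mean(np.diag(K))) <= 0.0:
        raise ValueError(f"degenerate effect matrix for {effect!r}: "
                         "mean diagonal of the raw kinship is zero")
    raw = KinshipMatrix(K, g.individual_ids, {"method": f"inter_{effect}"})
    return normalize_by_mean_diag(raw)
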