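"""Deterministic simulators for pedigrees, genotypes and abundance data.

These generators are the package's test substrate and double as example-data
producers (CLI subcommand ``simulate``).  Pedigreed genotypes are produced by
gene dropping — founder haplotypes drawn from per-marker allele frequencies
and transmitted Mendelianly — so the expected genomic relationship of a pair
equals its pedigree relationship, which links the genomic and pedigree
builders in cross-module tests.  Two-population genotypes follow a
Balding-Nichols-style model: population frequencies are Beta-perturbed
around a shared ancestral frequency with a divergence parameter playing the
role of Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genomic import GenotypeMatrix
from .omics import AbundanceMatrix
from .pedigree import PedigreeRecord, PedigreeTable, sort_pedigree

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulated_marker_frequencies",
    "simulate_two_populations",
    "simulate_abundance",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all simulators; every output is a pure function of these.

    Defaults give a small three-generation livestock-style pedigree
    (20 founders, litters of 2) typed at 500 markers on 2 chromosomes with
    allele frequencies in [0.05, 0.5], a mild two-population divergence of
    0.1, and 200-feature abundance matrices.
    """

    seed: int = 0
    # pedigree
    n_founders: int = 20
    n_generations: int = 3
    litter_size: int = 2
    # genotypes
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chromosomes: int = 2
    # two-population genotypes
    n_per_pop: int = 50
    fst_like_divergence: float = 0.1
    # abundance
    n_individuals: int = 40
    n_features: int = 200
    lognormal_params: tuple[float, float] = (2.0, 1.0)
    zero_inflation: float = 0.0
    group_effect: float = 1.0

    def __post_init__(self):
        for name in ("n_founders", "n_generations", "litter_size", "n_markers",
                     "n_chromosomes", "n_per_pop", "n_individuals",
                     "n_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise ValueError("fst_like_divergence must lie in [0, 1)")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per simulator
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Multi-generation pedigree with random (non-self) mate assignment.

    Founders alternate male/female; each later generation draws a sire and a
    dam at random from the previous generations and produces ``litter_size``
    full sibs per mating, with sire reuse across matings creating half-sib
    families.  Birth order equals generation index.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders (one male, one female)")
    rng = _rng(cfg, 1)
    records: list[PedigreeRecord] = []
    males: list[str] = []
    females: list[str] = []
    next_id = 1
    for k in range(cfg.n_founders):
        sex = "male" if k % 2 == 0 else "female"
        label = str(next_id)
        next_id += 1
        records.append(PedigreeRecord(label, None, None, 0, sex))
        (males if sex == "male" else females).append(label)
    n_matings = max(1, cfg.n_founders // 2)
    for gen in range(1, cfg.n_generations):
        sires = rng.choice(males, size=n_matings, replace=True)
        dams = rng.choice(females, size=n_matings, replace=True)
        new_m: list[str] = []
        new_f: list[str] = []
        for sire, dam in zip(sires, dams):
            for _ in range(cfg.litter_size):
                sex = "male" if rng.random() < 0.5 else "female"
                label = str(next_id)
                next_id += 1
                records.append(PedigreeRecord(label, sire, dam, gen, sex))
                (new_m if sex == "male" else new_f).append(label)
        males += new_m
        females += new_f
    table, issues = sort_pedigree(records)
    assert table is not None and not any(i.fatal for i in issues)
    return table


def simulated_marker_frequencies(cfg: SimConfig) -> np.ndarray:
    """The base-population allele frequencies :func:`simulate_genotypes`
    drops genes from (same seed stream, so the values match exactly).

    Relatedness estimated from markers is only unbiased for the pedigree
    expectation when dosages are centered by these base frequencies, so
    tests of that expectation need access to them.
    """
    rng = _rng(cfg, 2)
    return rng.uniform(*cfg.maf_range, size=cfg.n_markers)


def simulate_genotypes(ped: PedigreeTable, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-dropped genotypes down a sorted pedigree.

    Founder haplotypes are Bernoulli draws from per-marker frequencies in
    ``maf_range``; offspring inherit one random allele from each known
    parent (unknown parents contribute a fresh founder draw).  Markers are
    assigned to ``n_chromosomes`` contiguous blocks.
    """
    if not ped.is_sorted():
        raise ValueError("pedigree must be sorted")
    rng = _rng(cfg, 2)
    n, m = len(ped), cfg.n_markers
    p = rng.uniform(*cfg.maf_range, size=m)
    s, d = ped.parent_indices()
    h1 = np.empty((n, m), dtype=np.int8)
    h2 = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        for h, parent in ((h1, s[i]), (h2, d[i])):
            if parent < 0:
                h[i] = rng.random(m) < p
            else:
                pick = rng.random(m) < 0.5
                h[i] = np.where(pick, h1[parent], h2[parent])
    dosages = (h1 + h2).astype(float)
    chrom_labels = [
        f"chr{c + 1}"
        for c, block in enumerate(np.array_split(np.arange(m),
                                                 cfg.n_chromosomes))
        for _ in block
    ]
    markers = [f"snp{j + 1}" for j in range(m)]
    return GenotypeMatrix(dosages, ped.ids, markers, chrom_labels)


def simulate_two_populations(cfg: SimConfig) -> GenotypeMatrix:
    """Two unrelated populations with heterogeneous allele frequencies.

    Ancestral frequencies are drawn from ``maf_range``; each population's
    frequency is Beta(p (1-F)/F, (1-p)(1-F)/F) around the ancestral p with
    F = ``fst_like_divergence`` (F = 0 reproduces the ancestral p exactly).
    Genotypes are independent binomial draws within population.
    """
    rng = _rng(cfg, 3)
    m = cfg.n_markers
    p_anc = rng.uniform(*cfg.maf_range, size=m)
    F = cfg.fst_like_divergence
    dosages = []
    pops = []
    ids = []
    for k, pop in enumerate(("pop1", "pop2")):
        if F == 0.0:
            p_pop = p_anc
        else:
            c = (1.0 - F) / F
            p_pop = rng.beta(p_anc * c, (1.0 - p_anc) * c)
            p_pop = np.clip(p_pop, 1e-6, 1.0 - 1e-6)
        dosages.append(rng.binomial(2, p_pop, size=(cfg.n_per_pop, m)))
        pops += [pop] * cfg.n_per_pop
        ids += [f"{pop}_{i + 1}" for i in range(cfg.n_per_pop)]
    chrom_labels = [
        f"chr{c + 1}"
        for c, block in enumerate(np.array_split(np.arange(m),
                                                 cfg.n_chromosomes))
        for _ in block
    ]
    markers = [f"snp{j + 1}" for j in range(m)]
    return GenotypeMatrix(np.vstack(dosages).astype(float), ids, markers,
                          chrom_labels, pops)


def simulate_abundance(cfg: SimConfig, kind: str = "otu") -> AbundanceMatrix:
    """Synthetic OTU counts or gene-expression values.

    OTU: per-feature log-normal abundances (parameters ``lognormal_params``)
    with optional zero-inflation.  Expression: Gaussian per-gene values with
    random means/scales and a planted two-group structure — the first half of
    individuals is shifted by ``group_effect`` standard deviations on a
    random 10% subset of genes — so structure-recovery tests have a known
    answer.
    """
    if kind not in ("otu", "expression"):
        raise ValueError("kind must be 'otu' or 'expression'")
    rng = _rng(cfg, 4 if kind == "otu" else 5)
    n, q = cfg.n_individuals, cfg.n_features
    ids = [f"ind{i + 1}" for i in range(n)]
    features = [(f"otu{j + 1}" if kind == "otu" else f"gene{j + 1}")
                for j in range(q)]
    if kind == "otu":
        mu, sigma = cfg.lognormal_params
        base = rng.normal(mu, 0.5, size=q)  # per-OTU abundance level
        X = np.exp(rng.normal(base, sigma, size=(n, q)))
        X = np.ceil(X)  # count-like; zeros only from explicit zero-inflation
        if cfg.zero_inflation > 0:
            X[rng.random((n, q)) < cfg.zero_inflation] = 0.0
        return AbundanceMatrix(X, ids, features, "otu")
    means = rng.normal(8.0, 2.0, size=q)
    sds = np.abs(rng.normal(1.0, 0.3, size=q)) + 0.2
    X = rng.normal(means, sds, size=(n, q))
    n_hit = max(1, q // 10)
    hit = rng.choice(q, size=n_hit, replace=False)
    X[: n // 2, hit] += cfg.group_effect * sds[hit]
    return AbundanceMatrix(X, ids, features, "expression")
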