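# kinmat

Kinship (relationship) matrices from pedigree, genomic, microbiome and
transcriptome data, with outputs ready for downstream mixed-model software
(GCTA-style binary GRMs, DMU-style triplets, plain CSV).

Relationship matrices are the variance–covariance backbone of best linear
unbiased prediction (BLUP/GBLUP/ssGBLUP) and of mixed-model association
studies: they encode pairwise relatedness so polygenic effects and cryptic
relatedness can be modelled. Different data call for different estimators,
and `kinmat` collects them behind one consistent interface, for animal and
plant breeders and quantitative geneticists who need to build, inspect and
export these matrices.

## What it computes

**Pedigree.** The numerator relationship matrix **A** (Meuwissen–Luo
ancestor-path inbreeding + tabular recursion; `A_ii = 1 + F_i`), the
dominance matrix **D** via the sire/dam decomposition
`D_ij = ¼(A_s(i)s(j) A_d(i)d(j) + A_s(i)d(j) A_d(i)s(j))`, inbreeding
coefficients `F = diag(A) − 1` and coancestries `θ = A/2`. Pedigrees are
validated first: loops, conflicting duplicate ids, two-gender parents,
offspring recorded before parents, missing parent records (auto-promoted to
founders).

**Genotypes** (0/1/2 dosages). Four additive GRMs:

- VanRaden: `G = Σ_j (x_j − 2p_j)(x_j − 2p_j)' / Σ_j 2p_j(1−p_j)`
- Yang: `G = (1/m) Σ_j (x_j − 2p_j)(x_j − 2p_j)' / (2p_j(1−p_j))`
- Chen and Wientjes: combined-population block estimators using
  within-population allele frequencies, differing in how the
  cross-population block is scaled (per-marker geometric mean vs product of
  the per-population scaling constants).

Dominance and epistatic kinships (`d`, `aa`, `dd`, `ad`, `da`) from the
`Z ∈ {−1,0,+1}` / `W ∈ {0,1}` codings, each scaled to mean diagonal 1.
Computation can be chunked per chromosome or marker block with results
identical to the whole-matrix pass.

**Single-step H.** For partially genotyped populations,
`H22 = G_w`, `H12 = A12 A22⁻¹ G_w`,
`H11 = A11 + A12 A22⁻¹ (G_w − A22) A22⁻¹ A21`, where
`G_w = (1−w) G* + w A22` and `G* = a + bG` matches G's diagonal and
off-diagonal averages to A22's.

**Abundances.** Microbiome `M = OO'/q` from log-transformed, per-OTU
z-scored abundances; transcriptome `T = RR'` from per-gene z-scores
(optionally `/q`).

**Structure.** Kinship PCA (double-centered eigendecomposition), hierarchical
clustering on `d = max(K) − K`, heat-map ordering, family-tree extraction —
all returning data; plotting is optional.

## Worked example

```python
import numpy as np
import kinmat as km

records = [
    km.PedigreeRecord("1"), km.PedigreeRecord("2"),
    km.PedigreeRecord("3", "1", "2"), km.PedigreeRecord("4", "1", "2"),
    km.PedigreeRecord("5", "3", "4"),          # full-sib mating
]
ped, issues = km.sort_pedigree(records)
A = km.make_A(ped)
print(A.to_dataframe().round(3))
print(km.inbreeding_coefficients(A))
```

```
     1    2     3     4     5
1  1.0  0.0  0.50  0.50  0.50
2  0.0  1.0  0.50  0.50  0.50
3  0.5  0.5  1.00  0.50  0.75
4  0.5  0.5  0.50  1.00  0.75
5  0.5  0.5  0.75  0.75  1.25
1    0.00
2    0.00
3    0.00
4    0.00
5    0.25
```

Parent–offspring pairs show the expected 0.5; full sibs 3 and 4 are related
0.5 and their offspring 5 is inbred with `F = 0.25` (diagonal 1.25). On
simulated genotypes:

```python
cfg = km.SimConfig(seed=7, n_founders=10, n_generations=3, n_markers=400)
sped = km.simulate_pedigree(cfg)
g = km.simulate_genotypes(sped, cfg)
G = km.make_G(g, method="vanraden")
print("mean diag G:", round(float(np.mean(np.diag(G.dense()))), 3))
K_aa = km.make_G_inter(g, "aa")
print("mean diag K_aa:", float(np.mean(np.diag(K_aa.dense()))))
```

```
mean diag G: 0.954
mean diag K_aa: 1.0000000000000002
```

The realized GRM diagonal sits near 1 (sample-frequency centering), and the
additive×additive epistatic kinship is normalized to mean diagonal exactly 1.

The same operations are available from the shell:

```bash
kinmat simulate --seed 1 --out-dir example
kinmat make-a --ped example/pedigree.csv --out A.csv
kinmat make-g --geno example/genotypes.csv --out-format gcta_grm --out G
kinmat make-h --ped example/pedigree.csv --geno example/genotypes.csv --w 0.05 --out H.csv
kinmat pca --kin A.csv --k 2 --out-prefix A_pca
```

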