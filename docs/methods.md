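# Methods

This note records the models implemented, the conventions chosen where the
literature admits more than one, the numerical decisions, and what the
synthetic data do and do not establish.

## Pedigree relationships

A pedigree is an acyclic parent–offspring graph with an unknown-parent
sentinel (`0`, empty or NA in files). Validation treats loops (including
self-parenting) and same-id-different-parents records as fatal; an id used
both as a sire and as a dam ("two genders"), or in a role contradicting a
declared sex, is also fatal. Referenced-but-absent parents are repairable:
they are promoted to founder records and reported. Sorting is Kahn's
topological sort with deterministic tie-breaking (birth order when present,
then input order); birth-order violations are reported but repaired by the
sort itself.

`make_A` computes inbreeding by the Meuwissen–Luo ancestor-path algorithm —
`A_ii = Σ_j L_ij² w_j` over the ancestors of `i`, with `w_j` the
within-family segregation variance (`0.5 − 0.25(F_s + F_d)` with both
parents known, `0.75 − 0.25 F_p` with one, `1` with none) — and assembles
the full matrix with the tabular recursion
`A_ij = 0.5(A_j,s(i) + A_j,d(i))`. Founders are assumed non-inbred and
unrelated; the two routes agree to 1e-12 against an independent tabular
oracle in the tests. The `sparse=True` option returns CSR storage of the
same values.

`make_D` uses the classical sire/dam product decomposition with `D_ii = 1`,
i.e. the diagonal deliberately ignores inbreeding's effect on dominance
variance. This is the simplest convention in the pedigree-dominance
literature and keeps D a correlation-like matrix; it is a genuine choice
(some software adjusts the diagonal) and is documented here rather than
hidden. "Ancestry coefficients" are interpreted as coancestry
(kinship) coefficients `θ = A/2`, the only standard quantity derivable from
the relationship matrix alone.

## Genomic relationships

Allele frequency `p_j` is the frequency of the dosage-counted allele,
`mean(dosage)/2` over non-missing calls — not folded to minor. The additive
estimators are invariant to which allele is counted (tested), so the
distinction is cosmetic. Monomorphic markers are excluded from numerator
and denominator sums (the per-marker-scaled estimator would divide by
zero); missing dosages are imputed to the population mean `2p_j`, hence
contribute nothing after centering.

The combined-population estimators center each population's dosages by its
*own* frequencies ("standardized genotypes" are centered-only — any scaling
inside them would double-count the printed denominators). Within-population
diagonal blocks therefore equal the single-population VanRaden matrix on
that population alone (tested). A marker must be polymorphic in the pooled
data; if it is monomorphic within one population its cross-block
denominator term vanishes and it is excluded from the cross-block sums
only. More than two populations are handled block-pairwise. Note a design
consequence verified empirically: because within-population centering
absorbs the between-population mean shift, PCA on these matrices does *not*
separate the populations — the pooled-frequency VanRaden matrix does. That
is the point of the estimator, not a defect.

The per-marker-scaled (Yang) estimator is applied verbatim to all cells
including the diagonal; GCTA's original formulation uses a distinct
diagonal estimator, so diagonals differ slightly from GCTA output by
construction.

Dominance/epistatic kinships use the codings `Z = dosage − 1`,
`W = 1{dosage = 1}` and triangular pair sums over loci `k < k'`. Because
the sums are triangular, the additive×dominance and dominance×additive
matrices differ in general and both are provided. `aa`/`dd` are evaluated
through the Hadamard identity
`2K* = (XX')∘(XX') − (X∘X)(X∘X)'`; `ad`/`da` through a running
suffix accumulation (O(m·n²)); a literal O(m²) pair sum serves as the test
oracle. Raw matrices are scaled by the mean of their diagonal so the
diagonal averages exactly 1; an all-homozygous input makes the dominance
matrix degenerate (zero diagonal) and is an error. For these codings,
missing dosages are imputed to the per-marker modal genotype (ties toward
the smaller dosage) — mean imputation would leave non-integer dosages with
no code. The `threads` argument is accepted for API stability; the heavy
products are single fixed-order BLAS calls, so results are independent of
it by construction.

Chunked computation accumulates per-chunk numerator cross-products and
denominator sums (per chromosome or contiguous marker blocks) with
frequencies and filters computed once globally, and agrees with the
single-pass result to summation-order round-off (≤1e-10 asserted, ~1e-15
observed).

## Single-step H

The calibration `G* = a + bG` solves the 2×2 system matching G's diagonal
and off-diagonal averages to A22's; it is singular when G's diagonal and
off-diagonal averages coincide (error). Blending is the convex combination
`G_w = (1−w)G* + wA22` with default `w = 0.05` and tuning enabled — common
ssGBLUP practice; both are exposed. Block assembly uses Cholesky solves
with A22 (no explicit inverse); a condition estimate above 1e8 aborts with
a pedigree-check hint. Output order is [ungenotyped; genotyped], with a
flag restoring pedigree order. Endpoints collapse exactly: `w = 1`
reproduces the reordered pedigree A, and a fully genotyped population
yields `H = G_w`.

## Abundance-based relationships

OTU abundances are log-transformed with a pseudocount (default 1; zeros
with pseudocount 0 are an error naming the cells) and z-scored per feature;
`M = OO'/q` over the `q` retained features. Expression values are z-scored
without a log; `T = RR'` with no division by gene count in its literal
form, so `diag(T)` scales with `q` — the deliberate asymmetry between the
two estimators is preserved, and `scale_by_genes=True` provides the
reconciled `T/q`. Standard deviations use the population divisor `n` by
default, which makes `mean(diag(M)) = 1` exactly when nothing is dropped;
`ddof=1` switches to the sample divisor and rescales both matrices by
`(n−1)/n`. Zero-variance features are dropped and reported, never errors.

## Structure analysis

PCA double-centers the kinship matrix (`JKJ`) before eigendecomposition —
classical multidimensional scaling of a Gram matrix; a flag gives the plain
eigendecomposition. Scores are `v√λ`; variance fractions are taken over the
nonnegative eigenvalues, negative ones (possible after tuning/blending)
being reported separately. Clustering converts kinship to the monotone
distance `d = max(K) − K` and delegates to standard agglomeration; heat-map
ordering uses the dendrogram leaf order. Family-tree extraction walks up to
a set number of parental generations (default 3, hence ≤ 14 edges).

## Synthetic data

The simulators define the test conditions: a three-generation random-mating
pedigree (20 founders, litters of 2 by default), gene-dropped genotypes
(founder haplotypes Bernoulli(p) with p uniform on [0.05, 0.5], Mendelian
transmission, 500 markers on 2 chromosomes by default), two-population
genotypes with Beta-perturbed frequencies around a shared ancestral value
(divergence 0.1 by default, playing the role of Fst), log-normal OTU counts
with optional zero-inflation, and Gaussian expression with a planted
two-group shift. All generators are pure functions of the configuration and
seed.

Gene dropping links the genomic and pedigree builders: realized marker
relatedness is unbiased for the pedigree expectation *when dosages are
centered by the base-population frequencies* the genes were dropped from
(exposed as `simulated_marker_frequencies`); sample-frequency centering on
a related population is systematically offset, a well-known property, which
is why the recovery test centers by the base frequencies. The standard
error in that test comes from a delete-one-marker-block jackknife, because
all sampling noise (founder alleles, Mendelian segregation) is independent
across markers while pair-level differences are strongly correlated.

What the simulations do not emulate: linkage disequilibrium (markers segregate
independently), selection and non-random mating, genotyping error,
compositional structure in OTU counts, and count-model mean–variance
relationships in expression. Passing tests therefore establish algebraic
and statistical correctness of the estimators under their own assumptions,
not robustness to those real-data features.

## Numerical conventions

- Symmetry is enforced at 1e-10 on every `KinshipMatrix`; builders
  symmetrize (`(K + K')/2`) only to absorb BLAS round-off.
- Deterministic tie-breaks everywhere: pedigree sorting (birth order, input
  order), modal-genotype imputation (smaller dosage), clustering (input
  order via standard linkage).
- Writers: square CSV at 10 significant digits; GRM binaries as
  little-endian float32 lower triangle including diagonal in
  (1,1),(2,1),(2,2),… order; triplet text at 15-digit scientific notation
  with a code→id sidecar. Readers validate sizes and missing diagonals.
- CLI exit codes: 0 success, 2 usage error, 1 data error; runs log input
  SHA-256 digests, and identical inputs produce byte-identical outputs.

## Known limitations

No inverses (A⁻¹, H⁻¹) — solvers that need them should factorize the
written matrices. No VCF/BED parsing (dosage CSV and the PLINK text dialect
only). The pedigree dominance diagonal ignores inbreeding (above). The
per-marker-scaled GRM diagonal follows the printed formula, not GCTA's
variant. Acceptance-scale problem sizes (≤ 200 individuals, ≤ 5000 markers
in tests) were chosen so the full suite runs in seconds; the algorithms
themselves are dense-matrix bound and scale as O(n²m) / O(n³).
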