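# Methods

This note documents the models, estimators and numerical choices behind
`strpop`, and what the synthetic-data generator does and does not
emulate.

## Data model and the missing-data policy

Alleles are integer fragment sizes in base pairs, exactly as delivered
by size calling; no binning into repeat counts is attempted, because
every statistic downstream is frequency-based and never interprets
allele size. Missingness is defined per genotype: a failed reaction
loses both gene copies, and a half-called genotype (one allele) is
treated as fully missing — the data model has no way to weight half a
genotype consistently across H_E, HWE and the frequency estimates.

Multi-locus analyses require complete (population, locus) coverage, so
a panel is split by a missing-rate tolerance (default 0.40): the
*full-loci* subset keeps every locus and drops populations with any
cell above tolerance (maximising bootstrap information per locus); the
*full-population* subset keeps every population and drops offending
loci (establishing every population's position). Both subsets are
always produced and the policy is idempotent.

## Diversity and Hardy–Weinberg

H_E uses the unbiased estimator `n/(n−1) · (1 − Σ p²)` over `n`
successfully typed gene copies, clipped at 0. Per-locus summaries
exclude cells whose missing rate exceeds the tolerance, mirroring the
practice of crossing out unreliable cells before averaging.

The HWE test is the exact conditional test given allele counts, with
the Levene table probability
`P(f) = n! Π n_i! 2^H / ((2n)! Π f_ij!)` and p-value equal to the
total probability of tables no more probable than the observed one.
Tables are fully enumerated when the conditional distribution has at
most `max_enumeration` members. Beyond that the default Monte Carlo
draws tables i.i.d. from the conditional null by randomly re-pairing
the 2n gene copies (the "conventional" Monte Carlo of the exact-test
literature); it carries a rigorous binomial standard error
(floored at 1/reps). A switch Markov chain over labelled genotype
configurations is also provided — conditioned on allele counts the
target over labelled configurations is uniform and the one-copy swap
proposal is symmetric, so acceptance is identically 1 — but its
batch-means standard error underestimates badly when an extreme table
dominates the tail, which is why the i.i.d. sampler is the default.
Significance follows the p < 0.05 convention with no multiple-testing
correction. Monomorphic cells return p = 1 with a degenerate flag.

## Genetic distances and bootstrap

`D_A = 1 − (1/r) Σ_j Σ_i √(x_ij y_ij)` and
`D_C = (2/(π r)) Σ_j √(2 (1 − Σ_i √(x_ij y_ij)))`, the chord distance
in the normalisation that puts 1/r inside the prefactor; this choice is
pinned testably by the closed form `(2/π)√2` for a single locus with
disjoint allele sets. Allele support per locus is the union of alleles
observed in the pair; absent alleles contribute zero terms. D_A is
linear over loci (the multilocus value is the mean of single-locus
values), which the tests exploit as an exact algebraic check. Pairs
with incomplete locus coverage are an error in strict mode; a
documented fallback averages over loci present in both populations.

Bootstrap-over-loci resamples locus indices uniformly with replacement
(no stratification); a replicate containing a locus twice weights it
twice. With a single locus every replicate equals the original matrix.

## Phylogenies

Neighbor joining follows Saitou–Nei with the Q-criterion; ties break
toward the lowest (row, column) index pair so output is deterministic
across platforms. Negative branch lengths are retained (the writer can
clamp them for display). Split support is the percentage of bootstrap
replicates containing the same leaf bipartition, normalised to the side
away from the lexicographically smallest leaf; majority-rule consensus
keeps splits present in more than half of the inputs, which are
compatible by construction. Newick parsing goes through dendropy;
serialisation is the package's own writer so that write→read→write is
bit-exact. The NJ test oracle enumerates all unrooted binary topologies
up to 8 taxa and identifies the unique zero-residual least-squares fit.

## PCA and parallel analysis

Observations are populations; variables are (locus, allele) pairs. No
allele is dropped to break the within-locus sum-to-one constraint (it
only contributes one zero eigenvalue per locus). Columns are Z-scored
with the population (divisor n) standard deviation — the divisor
rescales all columns by the same factor and is therefore irrelevant to
variance shares, but is fixed for reproducibility. Zero-variance
columns are dropped and reported. Components come from the SVD;
`percent_variance_k = 100 s_k²/Σ s²`.

Parallel analysis draws random datasets of the same shape —
independent standard normals by default, with column permutation of
the real data available as an alternative null (the choice of random
model is an assumption, so it is a config switch) — pushes them
through the identical normalise-and-decompose path, and refers every
observed contribution to the random *first*-component distribution:
`significance = (#{random PC1 ≥ observed} + 1)/(reps + 1)`.

## Mantel tests

The statistic is the Pearson correlation of the vectorised upper
off-diagonal entries, after aligning matrices by label (never by
position). Permutation p-values use the add-one convention
`(count + 1)/(permutations + 1)` — an exact zero is not a reproducible
claim — one-tailed positive by default (the hypotheses are
directional), with a two-sided option. The partial test residualises
both vectors on the control and permutes the first matrix,
re-residualising each permutation (Smouse–Long–Sokal). A matrix
collinear with the control has no residual signal and returns r = 0
rather than amplified floating-point noise. The exclusion analysis
reruns all tests on the complement of each language group, flagging
(not computing) complements with fewer than 4 populations.

## External distances

Linguistic distance between populations is the age of the most recent
common ancestor of their language groups on a dated tree, which makes
the matrix ultrametric by construction. The shipped default encodes
exactly three ages — Chinese/Tibeto-Burman 7,000 yrs BP,
Mongolian/Turkic 8,000, root 50,000 — with all finer structure
collapsed, because only those three are fixed by the design; richer
trees are plain YAML config. Within-group distance defaults to 0 with
a per-leaf override. Geographic distance is the haversine great-circle
arc on a sphere of radius 6,371 km, untransformed: a log transform
would distort non-linearly and send same-location pairs to −∞.

## Admixture model

The sampler implements the admixture model with correlated allele
frequencies: gene-copy origins `z ~ Categorical(q_i)`, memberships
`q_i ~ Dirichlet(α,…,α)` with α given a uniform (0, 10) prior and a
Metropolis random-walk update, and cluster frequencies
`p_kl ~ Dirichlet(p_l^anc (1−F_k)/F_k)` with independent per-cluster
drift parameters under uniform (0, 1) priors. The ancestral
frequencies are fixed at the pooled sample frequencies instead of being
sampled — a deliberate collapse that keeps the P update conjugate and
has negligible posterior effect at panel scale; the uncorrelated
alternative uses a flat Dirichlet(1) prior (lambda fixed at 1).
Missing genotypes contribute no likelihood terms. `lnPr(X|K)` is
estimated from the recorded log-likelihood trace as
`mean − var/2` (sample variance), and K is chosen by the plateau rule:
the smallest K whose median lnP lies within one median absolute
deviation (of the best K's runs) of the maximum — ties therefore break
toward smaller K. Run alignment is greedy column matching by Pearson
correlation of membership columns, which is adequate for K ≤ 7.

Defaults are desk-scale — burn-in 2,000, run length 2,000, 5 restarts
— so a panel analysis finishes in seconds to minutes; production-scale
settings (50,000/50,000, 15 restarts, K = 2…7) are ordinary config
values.

## Synthetic-data generator

The generator is the F-model, deliberately the same model class as the
clustering prior, so parameter recovery has clean semantics: ancestral
frequencies per locus are symmetric-Dirichlet draws over 5–12 alleles
(giving expected heterozygosities of roughly 0.6–0.9, the observed STR
range), and each tree edge draws
`child ~ Dirichlet(parent (1−F)/F)`, so a child allele's variance
around its parent is `p(1−p)F` — a closed form the tests verify.
Genotypes are drawn with inbreeding coefficient F_IS (F_IS = 0 is
exact HWE sampling); missingness is injected per cell. The
study-scale panel uses the shipped design constants: 30 populations in
seven language groups (two-level tree, group edges F = 0.06,
population edges F = 0.05), sample sizes 37–95 with median 50 (1,538
individuals), 10 loci, 3% background missingness, and five cells above
60% missingness placed so the 40% policy drops exactly four
populations or two loci.

What the generator does **not** emulate: stepwise mutation (allele
sizes are labels, so size-based statistics would be meaningless),
linkage between loci, selection, spatially continuous gene flow, and
real sampling artefacts beyond per-cell missingness. Passing tests
therefore demonstrate that the estimators recover F-model truth, not
that any particular real panel satisfies the F-model. The shipped
population panel itself is a synthetic stand-in: names and
language-group memberships follow the survey design where recoverable,
coordinates are approximate representative locations, and two
Tibeto-Burman populations are plausible fillers.

## Problem sizes and numerical choices

Tests and the acceptance script run at sizes chosen to exercise every
code path while staying desk-scale: HWE Monte Carlo at 3,000–4,000
i.i.d. replicates per table and 1,000 panels for the type-I
calibration; Mantel-null calibration at 500 pairs × 199 permutations;
bootstrap supports at B = 1,000; admixture chains of 400–500 recorded
sweeps for recovery and K-selection checks (the K-selection check uses
10 generator seeds, 3 × 40 individuals, 15 loci, F = 0.25). Frequency
vectors are validated to sum to 1 within 1e-9; distance matrices to be
symmetric within 1e-12 with exactly zero diagonals; permutation
p-values can never be 0 by the add-one convention; Dirichlet draws use
gamma variates with zero-shape entries mapped to exact zeros for
invalid allele slots.

## Known limitations

Exact-test enumeration is practical only for small conditional
distributions (the limit is configurable); the i.i.d. sampler's
standard error is binomial, so agreement checks against enumeration
must expect the usual ~0.3% of tables outside a 3-SE band. The greedy
run alignment is not CLUMPP's exhaustive search and can be suboptimal
for large K. lnPr(X|K) model choice is a heuristic, and with weak
differentiation or few loci the plateau rule's preference for smaller
K dominates. Great-circle distances ignore landform barriers, which
systematically shortens distances across mountainous terrain.
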