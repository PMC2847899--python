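# strpop

Population-structure analysis of microsatellite (STR) panels: genetic
distances, bootstrap phylogenies, PCA with parallel-analysis
significance, admixture clustering, exact Hardy–Weinberg tests, and
Mantel comparisons of genetic, geographic and linguistic distance
matrices.

`strpop` is aimed at population geneticists working with classical
multiallelic marker surveys — tens of populations typed at a handful of
highly polymorphic autosomal STRs — who want the complete
frequencies-to-figures workflow as one reproducible, seeded pipeline.
Its shipped design constants describe a 10-marker chromosome-3 survey
of 30 ethnic-minority populations from China (1,538 individuals,
sample sizes 37–95), and an F-model synthetic-data generator emulates
that panel so every stage is testable end to end.

## The statistics at the core

With `x_ij`, `y_ij` the frequencies of allele `i` at locus `j` in
populations X and Y and `r` loci:

* **Nei D_A distance** — `D_A = 1 − (1/r) Σ_j Σ_i √(x_ij · y_ij)`;
* **Cavalli-Sforza & Edwards chord distance** —
  `D_C = (2/(π r)) Σ_j √(2 (1 − Σ_i √(x_ij · y_ij)))`;
* **Expected heterozygosity** — unbiased
  `H_E = n/(n−1) (1 − Σ_i p_i²)` over `n` typed gene copies;
* **Exact HWE test** — Guo–Thompson conditional test given allele
  counts, by full enumeration or Monte Carlo;
* **Neighbor joining** (Saitou–Nei) with **bootstrap over loci** and
  majority-rule consensus;
* **PCA** of Z-scored allele frequencies with **parallel analysis**
  (leading components judged against random same-shape data);
* **Admixture model** — Gibbs sampling of membership vectors Q and
  cluster frequencies P under the correlated-frequencies (F-model)
  prior, `lnPr(X|K) ≈ mean − var/2` for choosing K, and CLUMPP-style
  alignment of runs;
* **Mantel / partial Mantel tests** with permutation p-values
  `(count + 1)/(permutations + 1)`, plus leave-one-language-group-out
  rows;
* **Linguistic distances** as MRCA ages on a dated language tree
  (Chinese–Tibeto-Burman 7,000 yrs BP, Mongolian–Turkic 8,000,
  root 50,000), **geographic distances** as great-circle arc lengths.

A dataset-subsetting policy handles missing data: populations with any
locus above a 40% missing-rate tolerance are dropped from the
*full-loci* subset; loci exceeding the tolerance anywhere are dropped
from the *full-population* subset.

## Worked example

Generate a study-scale synthetic panel and run the full pipeline:

```sh
strpop simulate --out bundle --seed 3
strpop analyze --genotypes bundle/genotypes.str \
    --metadata bundle/populations.csv --language-tree bundle/language_tree.yaml \
    --out report --bootstrap 200 --permutations 999 --parallel-reps 1000 --seed 3
```

or, in Python:

```python
from strpop import *
from strpop.synthetic import study_like_panel

ds, truth = study_like_panel(seed=1)        # 30 populations, 1,538 individuals
full_loci, full_population = subset_by_missing_policy(ds)   # 26 pops / 8 loci
table = allele_frequencies(full_loci)
gen = pairwise_matrix(table, "DA")
tree = neighbor_joining(gen)
```

On the seed-1 panel the toolkit computes, among others:

* `full_loci` keeps **26 of 30** populations (the four populations with
  a >60%-missing locus are dropped), `full_population` keeps **8 of
  10** loci — the two failure-prone markers go;
* PCA of the normalised frequencies: **PC1 16.5%, PC2 12.2%** of
  variance, against a random-data PC1 mean of **8.6%** (max 10.8% in
  10,000 replicates), i.e. parallel-analysis significance `0.0001`;
* bootstrap-over-loci NJ supports for the generator's true
  language-group clades between **82%** and **99%** at B = 1,000;
* Mantel correlations genetic×geographic **r = 0.266**,
  genetic×linguistic **r = 0.686**, linguistic×geographic **r = 0.356**
  (5,000 permutations), with the partial genetic×linguistic
  correlation dropping to **0.656** once geography is controlled.

These numbers quantify how much population structure the generator
built in and how faithfully each stage recovers it; on real data the
same products (CSV/Newick/PHYLIP under the output directory) are the
analysis deliverables.

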