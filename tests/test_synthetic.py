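"""F-model generators: frequencies, genotypes, missingness, admixed individuals."""

import numpy as np
import pytest

from strpop.dataset import allele_frequencies, missing_rates
from strpop.distance import pairwise_matrix
from strpop.diversity import expected_heterozygosity, genotype_counts, hwe_exact_test
from strpop.synthetic import (
    GeneratorTruth,
    generate_admixed,
    generate_frequencies,
    generate_genotypes,
    inject_missing,
    study_like_panel,
)
from strpop.study import STUDY_POPULATIONS


class TestGenerateFrequencies:
    def test_tiny_drift_keeps_frequencies_near_ancestral(self):
        # sd of an allele draw is sqrt(p(1-p)F); F = 1e-5 keeps 3 sigma << 0.01
        truth = GeneratorTruth(
            tree={"name": "root", "children": [{"name": "P", "F": 1e-5}]},
            n_loci=6, seed=0,
        )
        table, truth = generate_frequencies(truth)
        for j, locus in enumerate(table.loci):
            anc = truth.ancestral[j]
            for allele, p in anc.items():
                assert abs(table.freqs["P"][locus].get(allele, 0.0) - p) < 0.01

    def test_f_model_variance_matches_closed_form(self):
        """Mean squared deviation around ancestral equals p(1-p)F within 10%."""
        F = 0.5
        truth = GeneratorTruth(
            tree={"name": "root", "children": [{"name": "P", "F": F}]},
            n_loci=400, seed=1,
        )
        table, truth = generate_frequencies(truth)
        num, den = 0.0, 0.0
        for j, locus in enumerate(table.loci):
            anc = truth.ancestral[j]
            for allele, p in anc.items():
                x = table.freqs["P"][locus].get(allele, 0.0)
                num += (x - p) ** 2
                den += p * (1 - p) * F
        assert num / den == pytest.approx(1.0, rel=0.10)

    def test_siblings_closer_than_cousins(self):
        """Tree-structured drift orders D_A: within-clade < between-clade."""
        closer = 0
        for seed in range(30):
            tree = {
                "name": "root",
                "children": [
                    {"name": "left", "F": 0.08, "children": [
                        {"name": "A", "F": 0.05}, {"name": "B", "F": 0.05}]},
                    {"name": "right", "F": 0.08, "children": [
                        {"name": "C", "F": 0.05}, {"name": "D", "F": 0.05}]},
                ],
            }
            truth = GeneratorTruth(tree=tree, n_loci=10, seed=1000 + seed)
            table, _ = generate_frequencies(truth)
            m = pairwise_matrix(table, "DA")
            sib = (m.get("A", "B") + m.get("C", "D")) / 2
            cousin = np.mean([m.get(a, b) for a in "AB" for b in "CD"])
            closer += sib < cousin
        assert closer >= 27  # in expectation, and nearly always realised

    def test_invalid_drift_rejected(self):
        truth = GeneratorTruth(
            tree={"name": "root", "children": [{"name": "P", "F": 1.5}]}, n_loci=2
        )
        with pytest.raises(ValueError, match="drift"):
            generate_frequencies(truth)

    def test_allele_labels_are_fragment_sizes(self):
        truth = GeneratorTruth(
            tree={"name": "root", "children": [{"name": "P", "F": 0.1}]}, n_loci=3, seed=2
        )
        table, _ = generate_frequencies(truth)
        for locus in table.loci:
            for allele in table.freqs["P"][locus]:
                assert allele >= 120 and allele % 2 == 0

    def test_bit_reproducible_from_seed(self):
        def build():
            t = GeneratorTruth(
                tree={"name": "root", "children": [{"name": "P", "F": 0.2}]},
                n_loci=5, seed=33,
            )
            return generate_frequencies(t)[0]

        a, b = build(), build()
        assert a.freqs == b.freqs


class TestGenerateGenotypes:
    def test_hwe_sampling_observed_heterozygosity(self):
        """At F_IS = 0, observed heterozygosity tracks H_E within 3 SEs."""
        truth = GeneratorTruth(
            tree={"name": "root", "children": [{"name": "P", "F": 0.1}]},
            n_loci=6, sizes={"P": 400}, seed=3,
        )
        table, _ = generate_frequencies(truth)
        ds = generate_genotypes(table, seed=4)
        for j, locus in enumerate(ds.locus_names):
            calls = ds.calls[:, j]
            h_obs = float(np.mean(calls[:, 0] != calls[:, 1]))
            p = np.array(list(table.freqs["P"][locus].values()))
            h_exp = 1.0 - float(np.sum(p * p))
            se = np.sqrt(h_exp * (1 - h_exp) / 400)
            assert abs(h_obs - h_exp) < 3.5 * se

    def test_inbreeding_breaks_hwe_detectably(self):
        """F_IS = 0.5 drives exact-test rejection at over 80% of cells."""
        rejections, total = 0, 0
        for seed in range(3):
            truth = GeneratorTruth(
                tree={"name": "root", "children": [{"name": "P", "F": 0.1}]},
                n_loci=8, sizes={"P": 50}, seed=50 + seed,
            )
            table, _ = generate_frequencies(truth)
            ds = generate_genotypes(table, inbreeding=0.5, seed=60 + seed)
            for locus in ds.locus_names:
                counts = genotype_counts(ds, "P", locus)
                res = hwe_exact_test(counts, max_enumeration=500, chain_steps=2000,
                                     seed=70 + total)
                rejections += res.p_value < 0.05
                total += 1
        assert rejections / total > 0.8

    def test_invalid_inbreeding(self):
        truth = GeneratorTruth(
            tree={"name": "root", "children": [{"name": "P", "F": 0.1}]},
            n_loci=2, seed=5,
        )
        table, _ = generate_frequencies(truth)
        with pytest.raises(ValueError):
            generate_genotypes(table, inbreeding=1.0)

    def test_study_sizes_reproduce_design_scale(self):
        sizes = [m.sample_size for m in STUDY_POPULATIONS]
        assert min(sizes) == 37 and max(sizes) == 95
        assert float(np.median(sizes)) == 50.0
        assert sum(sizes) == 1538
        by_name = {m.name: m.sample_size for m in STUDY_POPULATIONS}
        assert by_name["Tu"] == 37 and by_name["Zhuang"] == 95


class TestInjectMissing:
    def test_zero_rate_is_identity(self):
        ds, _ = _small_panel()
        assert inject_missing(ds, default_rate=0.0, seed=0) == ds

    def test_rate_one_erases_cell(self):
        ds, _ = _small_panel()
        out = inject_missing(ds, design={("P", ds.locus_names[0]): 1.0}, seed=0)
        rates = missing_rates(out)
        assert rates.loc["P", ds.locus_names[0]] == 1.0

    def test_reproducible(self):
        ds, _ = _small_panel()
        a = inject_missing(ds, default_rate=0.3, seed=9)
        b = inject_missing(ds, default_rate=0.3, seed=9)
        assert a == b


def _small_panel():
    truth = GeneratorTruth(
        tree={"name": "root", "children": [{"name": "P", "F": 0.1}]},
        n_loci=4, sizes={"P": 30}, seed=8,
    )
    table, truth = generate_frequencies(truth)
    return generate_genotypes(table, seed=9), truth


@pytest.fixture(scope="module")
def parents():
    tree = {"name": "root",
            "children": [{"name": "X", "F": 0.4}, {"name": "Y", "F": 0.4}]}
    truth = GeneratorTruth(tree=tree, n_loci=8, sizes={"X": 50, "Y": 50}, seed=12)
    table, _ = generate_frequencies(truth)
    return table


class TestGenerateAdmixed:
    def test_pure_q_matches_parent_sampling(self, parents):
        n = 300
        Q = np.tile([1.0, 0.0], (n, 1))
        ds, _ = generate_admixed(parents, Q, seed=13)
        est = allele_frequencies(ds)
        for locus in parents.loci:
            for allele, p in parents.freqs["X"][locus].items():
                se = max(np.sqrt(p * (1 - p) / (2 * n)), 1.0 / (2 * n))
                assert abs(est.freqs["admixed"][locus].get(allele, 0.0) - p) < 4 * se

    def test_even_admixture_heterozygosity_bounds(self, parents):
        n = 400
        Q = np.tile([0.5, 0.5], (n, 1))
        ds, _ = generate_admixed(parents, Q, seed=14)
        est = allele_frequencies(ds)
        for locus in parents.loci:
            support = parents.allele_support(locus)
            px = parents.vector("X", locus, support)
            py = parents.vector("Y", locus, support)
            mix = (px + py) / 2
            h_mix = 1 - float(np.sum(mix**2))
            h_parents = [1 - float(np.sum(px**2)), 1 - float(np.sum(py**2))]
            vec = est.freqs["admixed"][locus]
            h_est = 1 - sum(v * v for v in vec.values())
            assert min(h_parents) - 0.1 < h_est < h_mix + 0.1
            # concavity: the mixture is at least as diverse as the parental mean
            assert h_mix >= np.mean(h_parents) - 1e-12

    def test_dimension_mismatch(self, parents):
        with pytest.raises(ValueError):
            generate_admixed(parents, np.ones((5, 3)) / 3, seed=0)


class TestStudyPanel:
    def test_reproducible_and_correct_shape(self, study_panel):
        ds, truth = study_panel
        ds2, _ = study_like_panel(seed=1)
        assert ds2 == ds
        assert ds.n_individuals == 1538

    def test_generated_data_pass_own_hwe_diagnostics(self):
        """HWE sampling yields non-extreme exact-test p-values overall."""
        ds, _ = _small_panel()
        pvals = []
        for locus in ds.locus_names:
            res = hwe_exact_test(genotype_counts(ds, "P", locus),
                                 max_enumeration=2000, chain_steps=2000, seed=5)
            pvals.append(res.p_value)
        assert np.mean([p < 0.05 for p in pvals]) <= 0.5
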