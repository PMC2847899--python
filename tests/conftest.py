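"""Shared fixtures: small hand-built panels and the study-scale synthetic panel."""

import numpy as np
import pytest

from strpop.dataset import (
    AlleleFrequencyTable,
    GenotypeDataset,
    Marker,
    PopulationMeta,
    allele_frequencies,
    subset_by_missing_policy,
)
from strpop.synthetic import study_like_panel


def make_dataset(calls_by_pop, locus_names=("L1",), metas=None):
    """Build a GenotypeDataset from {pop: [[ (a,b) or None per locus ], ...]}."""
    markers = [Marker(name) for name in locus_names]
    ids, pop_of, rows = [], [], []
    for pop, individuals in calls_by_pop.items():
        for i, genos in enumerate(individuals):
            ids.append(f"{pop}_{i}")
            pop_of.append(pop)
            row = []
            for g in genos:
                row.append([-9, -9] if g is None else [g[0], g[1]])
            rows.append(row)
    if metas is None:
        metas = [
            PopulationMeta(name=p, sample_size=len(v)) for p, v in calls_by_pop.items()
        ]
    return GenotypeDataset(markers, metas, ids, pop_of, np.array(rows, dtype=np.int64))


def make_freq_table(freqs, n_genes=100, sample_sizes=None):
    """Build an AlleleFrequencyTable from {pop: {locus: {allele: freq}}}."""
    pops = list(freqs)
    loci = list(next(iter(freqs.values())))
    return AlleleFrequencyTable(
        populations=pops,
        loci=loci,
        freqs={p: {l: dict(v) for l, v in freqs[p].items()} for p in pops},
        n_genes={p: {l: n_genes for l in loci} for p in pops},
        sample_sizes=sample_sizes or {p: n_genes // 2 for p in pops},
    )


@pytest.fixture(scope="session")
def study_panel():
    """Study-scale synthetic panel (30 populations, 10 loci, 1,538 individuals)."""
    ds, truth = study_like_panel(seed=1)
    return ds, truth


@pytest.fixture(scope="session")
def study_subsets(study_panel):
    ds, _ = study_panel
    full_loci, full_population = subset_by_missing_policy(ds)
    return full_loci, full_population


@pytest.fixture(scope="session")
def full_loci_freqs(study_subsets):
    full_loci, _ = study_subsets
    return allele_frequencies(full_loci)
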