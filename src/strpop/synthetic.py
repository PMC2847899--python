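"""Synthetic STR panels with known truth, for testing every pipeline stage.

The generator follows the F-model (correlated allele frequencies), the
same model class the admixture sampler assumes, which gives clean
parameter-recovery semantics: ancestral allele frequencies are drawn
symmetric-Dirichlet per locus (5-12 alleles, matching STR allele
richness and expected heterozygosities of roughly 0.6-0.9), and each
edge of a population tree draws its child's frequencies from
``Dirichlet(parent * (1 - F) / F)``, so a child's per-allele variance
around its parent is ``p (1 - p) F``.  Genotypes are drawn with
inbreeding coefficient ``F_IS`` (``F_IS = 0`` is exact Hardy-Weinberg
sampling); missingness is injected per (population, locus) cell.
Allele labels are plausible fragment sizes (``120 + 2k`` bp) so
fixtures exercise the real I/O paths.  Stepwise-mutation structure of
allele sizes is deliberately not modelled — every downstream distance
is frequency-based.

``study_like_panel`` assembles the default study-scale fixture:
30 populations grouped by language family, sample sizes 37-95 with
median 50 (1,538 individuals), 10 loci, and five (population, locus)
cells with >60% missingness arranged so the 40% policy drops exactly
four populations or two loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    Marker,
    PopulationMeta,
    write_genotypes,
    write_population_metadata,
)
from .study import (
    DEFAULT_LANGUAGE_TREE,
    LANGUAGE_GROUP,
    STUDY_MARKERS,
    STUDY_MISSINGNESS_CELLS,
    STUDY_POPULATIONS,
)

__all__ = [
    "GeneratorTruth",
    "generate_frequencies",
    "generate_genotypes",
    "inject_missing",
    "generate_admixed",
    "study_like_panel",
    "write_fixture_bundle",
]


@dataclass
class GeneratorTruth:
    """Ground truth of a synthetic panel.

    ``tree`` is a nested population tree: each node is a mapping with
    ``name``, ``F`` (drift of the edge to its parent; in (0,1), absent
    on the root) and either ``children`` or nothing (a leaf is a
    population).  ``ancestral`` and ``frequencies`` are filled in by
    :func:`generate_frequencies`.
    """

    tree: dict
    n_loci: int = 10
    locus_names: list[str] = field(default_factory=list)
    allele_count_range: tuple[int, int] = (5, 12)
    allele_base: int = 120
    allele_step: int = 2
    sizes: dict[str, int] = field(default_factory=dict)
    inbreeding: float = 0.0
    missingness: dict[tuple[str, str], float] = field(default_factory=dict)
    background_missingness: float = 0.0
    seed: int = 0
    ancestral: list[dict[int, float]] = field(default_factory=list)
    frequencies: AlleleFrequencyTable | None = None
    Q_truth: np.ndarray | None = None

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: Mapping) -> None:
            children = node.get("children", [])
            if not children:
                out.append(str(node["name"]))
            for c in children:
                walk(c)

        walk(self.tree)
        return out


def _check_drift(f: float, where: str) -> float:
    if not 0.0 < f < 1.0:
        raise ValueError(f"drift parameter F must be in (0, 1) at {where}, got {f}")
    return float(f)


def generate_frequencies(truth: GeneratorTruth) -> tuple[AlleleFrequencyTable, GeneratorTruth]:
    """Draw ancestral and per-population allele frequencies along the tree.

    Returns the truth frequencies as an :class:`AlleleFrequencyTable`
    (``n_genes`` set to twice each population's design sample size) and
    the truth object with ``ancestral`` and ``frequencies`` filled in.
    """
    rng = np.random.default_rng(truth.seed)
    pops = truth.leaf_names()
    if not truth.locus_names:
        if truth.n_loci == len(STUDY_MARKERS):
            truth.locus_names = [m.name for m in STUDY_MARKERS]
        else:
            truth.locus_names = [f"L{j + 1:02d}" for j in range(truth.n_loci)]
    loci = truth.locus_names
    lo, hi = truth.allele_count_range
    ancestral: list[dict[int, float]] = []
    per_pop: dict[str, dict[str, dict[int, float]]] = {p: {} for p in pops}
    for j, locus in enumerate(loci):
        k = int(rng.integers(lo, hi + 1))
        sizes_bp = [truth.allele_base + truth.allele_step * i for i in range(k)]
        anc = rng.dirichlet(np.ones(k))
        ancestral.append(dict(zip(sizes_bp, anc)))

        def descend(node: Mapping, freq: np.ndarray) -> None:
            children = node.get("children", [])
            if not children:
                per_pop[str(node["name"])][locus] = dict(zip(sizes_bp, freq))
                return
            for c in children:
                f = _check_drift(float(c.get("F", 0.05)), str(c.get("name")))
                child_freq = rng.dirichlet(np.clip(freq, 1e-12, None) * (1.0 - f) / f)
                descend(c, child_freq)

        descend(truth.tree, anc)
    truth.ancestral = ancestral
    sizes = truth.sizes or {p: 50 for p in pops}
    table = AlleleFrequencyTable(
        populations=pops,
        loci=list(loci),
        freqs={p: {l: {a: float(v) for a, v in per_pop[p][l].items() if v > 0}
                   for l in loci} for p in pops},
        n_genes={p: {l: 2 * sizes[p] for l in loci} for p in pops},
        sample_sizes=dict(sizes),
    )
    # re-normalise after dropping numerically-zero alleles
    for p in pops:
        for l in loci:
            tot = sum(table.freqs[p][l].values())
            table.freqs[p][l] = {a: v / tot for a, v in table.freqs[p][l].items()}
    truth.frequencies = table
    return table, truth


def generate_genotypes(
    freqs: AlleleFrequencyTable,
    sizes: Mapping[str, int] | None = None,
    inbreeding: float = 0.0,
    seed: int | None = 0,
    populations: Sequence[PopulationMeta] | None = None,
    markers: Sequence[Marker] | None = None,
) -> GenotypeDataset:
    """Draw diploid genotypes from population allele frequencies.

    Allele pairs follow inbreeding-adjusted proportions: with
    probability ``F_IS`` the two copies are identical by descent (one
    draw), otherwise independent — giving ``p_i^2 + p_i (1-p_i) F_IS``
    homozygotes and ``2 p_i p_j (1 - F_IS)`` heterozygotes, which is
    exact Hardy-Weinberg sampling at ``F_IS = 0``.
    """
    if not 0.0 <= inbreeding < 1.0:
        raise ValueError("inbreeding F_IS must be in [0, 1)")
    sizes = dict(sizes) if sizes is not None else dict(freqs.sample_sizes)
    for p in freqs.populations:
        if sizes.get(p, 0) < 1:
            raise ValueError(f"sample size for {p!r} must be >= 1")
    rng = np.random.default_rng(seed)
    if markers is None:
        by_name = {m.name: m for m in STUDY_MARKERS}
        markers = [by_name.get(l, Marker(l)) for l in freqs.loci]
    ids, pop_of, rows = [], [], []
    for pop in freqs.populations:
        n = sizes[pop]
        calls = np.empty((n, len(freqs.loci), 2), dtype=np.int64)
        for j, locus in enumerate(freqs.loci):
            vec = freqs.freqs[pop][locus]
            alleles = np.array(sorted(vec), dtype=np.int64)
            probs = np.array([vec[a] for a in sorted(vec)])
            probs = probs / probs.sum()
            first = rng.choice(alleles, size=n, p=probs)
            second = rng.choice(alleles, size=n, p=probs)
            ibd = rng.random(n) < inbreeding
            second[ibd] = first[ibd]
            calls[:, j, 0] = first
            calls[:, j, 1] = second
        rows.append(calls)
        ids.extend(f"{pop}_{i + 1:03d}" for i in range(n))
        pop_of.extend([pop] * n)
    if populations is None:
        populations = [
            PopulationMeta(name=p, sample_size=sizes[p]) for p in freqs.populations
        ]
    return GenotypeDataset(markers, populations, ids, pop_of, np.concatenate(rows))


def inject_missing(
    ds: GenotypeDataset,
    design: Mapping[tuple[str, str], float] | None = None,
    seed: int | None = 0,
    default_rate: float = 0.0,
) -> GenotypeDataset:
    """Set genotypes missing independently per the (population, locus) design."""
    design = dict(design or {})
    for rate in list(design.values()) + [default_rate]:
        if not 0.0 <= rate <= 1.0:
            raise ValueError("missingness rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    pop_arr = np.asarray(ds.population_of)
    for pi, pop in enumerate(ds.population_names):
        sel = np.flatnonzero(pop_arr == pop)
        for j, locus in enumerate(ds.locus_names):
            rate = design.get((pop, locus), default_rate)
            if rate <= 0:
                continue
            hit = sel[rng.random(sel.size) < rate]
            calls[hit, j] = MISSING
    return GenotypeDataset(
        list(ds.markers), list(ds.populations), list(ds.individual_ids),
        list(ds.population_of), calls,
    )


def generate_admixed(
    parents: AlleleFrequencyTable,
    Q_truth: np.ndarray,
    seed: int | None = 0,
    population_labels: Sequence[str] | None = None,
    markers: Sequence[Marker] | None = None,
) -> tuple[GenotypeDataset, GeneratorTruth]:
    """Draw genotypes for individuals with known admixture proportions.

    ``Q_truth`` is individuals x K with rows on the simplex; column k
    refers to the k-th population of *parents*.  Each gene copy first
    draws its population of origin from the individual's Q row, then an
    allele from that population's frequencies.
    """
    Q = np.asarray(Q_truth, dtype=float)
    K = len(parents.populations)
    if Q.ndim != 2 or Q.shape[1] != K:
        raise ValueError(f"Q_truth must be n x {K} for {K} parent populations")
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("Q_truth rows must sum to 1")
    rng = np.random.default_rng(seed)
    n = Q.shape[0]
    loci = parents.loci
    if markers is None:
        markers = [Marker(l) for l in loci]
    calls = np.empty((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        support = parents.allele_support(locus)
        mat = np.stack([parents.vector(p, locus, support) for p in parents.populations])
        for c in range(2):
            origin = (rng.random(n)[:, None] >= np.cumsum(Q, axis=1)).sum(axis=1)
            for i in range(n):
                probs = mat[origin[i]]
                calls[i, j, c] = support[int(rng.choice(len(support), p=probs / probs.sum()))]
    labels = list(population_labels) if population_labels is not None else ["admixed"] * n
    uniq = list(dict.fromkeys(labels))
    counts = {u: labels.count(u) for u in uniq}
    metas = [PopulationMeta(name=u, sample_size=counts[u]) for u in uniq]
    ds = GenotypeDataset(
        markers, metas, [f"adm_{i + 1:04d}" for i in range(n)], labels, calls
    )
    truth = GeneratorTruth(
        tree={"name": "root", "children": [{"name": p, "F": 0.5} for p in parents.populations]},
        n_loci=len(loci), locus_names=list(loci), seed=seed or 0,
        frequencies=parents, Q_truth=Q,
    )
    return ds, truth


# ----------------------------------------------------------------------
# Study-scale fixture
# ----------------------------------------------------------------------

def study_tree(group_F: float = 0.06, pop_F: float = 0.05) -> dict:
    """Two-level population tree: language groups, then populations."""
    groups: dict[str, list[str]] = {}
    for pop in [m.name for m in STUDY_POPULATIONS]:
        groups.setdefault(LANGUAGE_GROUP[pop], []).append(pop)
    return {
        "name": "root",
        "children": [
            {
                "name": g,
                "F": group_F,
                "children": [{"name": p, "F": pop_F} for p in members],
            }
            for g, members in groups.items()
        ],
    }


def study_like_panel(
    seed: int = 0,
    inbreeding: float = 0.0,
    background_missingness: float = 0.03,
    high_missing_cells: Mapping[tuple[str, str], float] = STUDY_MISSINGNESS_CELLS,
) -> tuple[GenotypeDataset, GeneratorTruth]:
    """Full study-scale synthetic panel: 30 populations, 10 loci, 1,538 individuals.

    Sample sizes, marker names, language-group structure and the
    high-missingness design mirror the study's published design
    constants; frequencies and genotypes are F-model draws.
    """
    sizes = {m.name: m.sample_size for m in STUDY_POPULATIONS}
    truth = GeneratorTruth(
        tree=study_tree(),
        n_loci=len(STUDY_MARKERS),
        sizes=sizes,
        inbreeding=inbreeding,
        missingness=dict(high_missing_cells),
        background_missingness=background_missingness,
        seed=seed,
    )
    ss = np.random.SeedSequence(seed).spawn(3)
    truth.seed = int(ss[0].generate_state(1)[0] % (2**31))
    table, truth = generate_frequencies(truth)
    ds = generate_genotypes(
        table,
        sizes=sizes,
        inbreeding=inbreeding,
        seed=int(ss[1].generate_state(1)[0] % (2**31)),
        populations=STUDY_POPULATIONS,
        markers=STUDY_MARKERS,
    )
    ds = inject_missing(
        ds,
        design=truth.missingness,
        seed=int(ss[2].generate_state(1)[0] % (2**31)),
        default_rate=background_missingness,
    )
    return ds, truth


def write_fixture_bundle(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full input bundle for a study-like panel.

    Emits STRUCTURE-format genotypes, population metadata CSV, the
    default language-tree YAML and a structured truth file; returns the
    paths keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds, truth = study_like_panel(seed=seed)
    paths = {
        "genotypes": directory / "genotypes.str",
        "metadata": directory / "populations.csv",
        "language_tree": directory / "language_tree.yaml",
        "truth": directory / "truth.yaml",
    }
    write_genotypes(ds, paths["genotypes"], dialect="structure_format")
    write_population_metadata(STUDY_POPULATIONS, paths["metadata"])
    with open(paths["language_tree"], "w") as fh:
        yaml.safe_dump(
            {"tree": DEFAULT_LANGUAGE_TREE, "populations": dict(LANGUAGE_GROUP)},
            fh, sort_keys=False,
        )
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "tree": truth.tree,
                "sizes": truth.sizes,
                "missingness": {f"{p}|{l}": r for (p, l), r in truth.missingness.items()},
                "background_missingness": truth.background_missingness,
                "ancestral": [
                    {int(a): float(v) for a, v in anc.items()} for anc in truth.ancestral
                ],
            },
            fh, sort_keys=False,
        )
    return paths
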