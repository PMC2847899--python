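"""Data model and I/O for diploid microsatellite (STR) genotype panels.

An STR panel is a set of individuals, each belonging to exactly one
population, typed at a common set of multiallelic loci.  Alleles are
integer fragment sizes in base pairs, as delivered by capillary
electrophoresis size calling; no binning into repeat counts is performed
here.  Missingness is per genotype: a PCR reaction that failed for an
individual at a locus leaves both gene copies unknown, and a genotype
with only one called allele is treated as fully missing.

Two text dialects are supported: the STRUCTURE convention (whitespace
table, one row per individual, two adjacent columns per locus, ``-9`` for
missing) and a long CSV with one row per (individual, locus).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -9  #: sentinel used only in file dialects and the internal array

__all__ = [
    "MISSING",
    "Marker",
    "PopulationMeta",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "read_genotypes",
    "write_genotypes",
    "read_population_metadata",
    "write_population_metadata",
    "missing_rates",
    "subset_by_missing_policy",
    "allele_frequencies",
    "adjacent_map_distances",
]


@dataclass(frozen=True)
class Marker:
    """A mapped STR locus.

    Parameters
    ----------
    name : str
        Locus identifier (e.g. ``"D3S1263"``).
    map_position : float
        Genetic-map location in centimorgans; must be non-negative.
    chromosome : str
        Chromosome label the locus maps to.
    """

    name: str
    map_position: float = 0.0
    chromosome: str = "3"

    def __post_init__(self) -> None:
        if self.map_position < 0:
            raise ValueError(f"map_position must be >= 0, got {self.map_position}")


@dataclass(frozen=True)
class PopulationMeta:
    """Sampling metadata for one population.

    ``lineage`` is the ordered path of language-tree node labels from
    phylum down to the population's own language group; it is what the
    linguistic-distance construction consumes.
    """

    name: str
    latitude: float = 0.0
    longitude: float = 0.0
    lineage: tuple[str, ...] = ()
    sample_size: int = 1

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


class GenotypeDataset:
    """Diploid STR calls for a panel of population-tagged individuals.

    Calls are stored as an ``(n_individuals, n_loci, 2)`` integer array of
    fragment sizes, with both entries equal to :data:`MISSING` for an
    untyped genotype.  Allele order within a genotype carries no meaning;
    pairs are normalised to ``(small, large)`` on construction.
    """

    def __init__(
        self,
        markers: Sequence[Marker],
        populations: Sequence[PopulationMeta],
        individual_ids: Sequence[str],
        population_of: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.markers = list(markers)
        self.populations = list(populations)
        self.individual_ids = list(individual_ids)
        self.population_of = list(population_of)
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individual_ids), len(self.markers), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.markers)} loci x 2"
            )
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        pop_names = {p.name for p in self.populations}
        if len(pop_names) != len(self.populations):
            raise ValueError("population names must be unique")
        unknown = set(self.population_of) - pop_names
        if unknown:
            raise ValueError(f"individuals assigned to unknown populations: {sorted(unknown)}")
        # normalise: half-missing -> fully missing; sort pairs
        half = (calls == MISSING).sum(axis=2) == 1
        calls[half] = MISSING
        bad = (calls <= 0) & (calls != MISSING)
        if bad.any():
            raise ValueError("allele sizes must be positive integers (or the missing code)")
        typed = calls[:, :, 0] != MISSING
        calls[typed] = np.sort(calls[typed], axis=-1)
        self.calls = calls

    # ------------------------------------------------------------------
    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)``; True where untyped."""
        return self.calls[:, :, 0] == MISSING

    def indices_of(self, population: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.population_of) == population)

    def subset(
        self,
        populations: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeDataset":
        """Restrict to the given populations and/or loci (order preserved)."""
        pops = list(populations) if populations is not None else self.population_names
        locs = list(loci) if loci is not None else self.locus_names
        missing_pops = set(pops) - set(self.population_names)
        missing_locs = set(locs) - set(self.locus_names)
        if missing_pops or missing_locs:
            raise KeyError(f"unknown populations {sorted(missing_pops)} / loci {sorted(missing_locs)}")
        keep_ind = np.isin(np.asarray(self.population_of), pops)
        locus_idx = [self.locus_names.index(l) for l in locs]
        return GenotypeDataset(
            markers=[self.markers[i] for i in locus_idx],
            populations=[p for p in self.populations if p.name in set(pops)],
            individual_ids=[i for i, k in zip(self.individual_ids, keep_ind) if k],
            population_of=[p for p, k in zip(self.population_of, keep_ind) if k],
            calls=self.calls[keep_ind][:, locus_idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.populations == other.populations
            and self.individual_ids == other.individual_ids
            and self.population_of == other.population_of
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele-frequency vectors with gene-copy counts.

    ``freqs[pop][locus]`` maps observed allele -> relative frequency over
    the successfully typed gene copies; alleles a population does not
    carry are simply absent from its mapping.  A (population, locus) cell
    with zero typed copies is absent from ``freqs[pop]`` entirely rather
    than zero-filled, and its ``n_genes`` entry is 0.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[str, dict[str, dict[int, float]]]
    n_genes: dict[str, dict[str, int]]
    sample_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in self.populations:
            for locus, vec in self.freqs.get(pop, {}).items():
                total = sum(vec.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"frequencies for ({pop}, {locus}) sum to {total}")
                if any(v < 0 or v > 1 for v in vec.values()):
                    raise ValueError(f"frequency out of [0,1] for ({pop}, {locus})")

    @property
    def r(self) -> int:
        """Number of loci."""
        return len(self.loci)

    def has(self, population: str, locus: str) -> bool:
        return locus in self.freqs.get(population, {})

    def vector(self, population: str, locus: str, support: Sequence[int]) -> np.ndarray:
        """Frequency vector over an explicit allele support (zeros where absent)."""
        vec = self.freqs[population][locus]
        return np.array([vec.get(a, 0.0) for a in support])

    def allele_support(self, locus: str, populations: Iterable[str] | None = None) -> list[int]:
        """Sorted union of alleles observed at *locus* in the populations given."""
        pops = list(populations) if populations is not None else self.populations
        support: set[int] = set()
        for pop in pops:
            support.update(self.freqs.get(pop, {}).get(locus, {}))
        return sorted(support)

    def subset(self, populations: Sequence[str] | None = None,
               loci: Sequence[str] | None = None) -> "AlleleFrequencyTable":
        pops = list(populations) if populations is not None else list(self.populations)
        locs = list(loci) if loci is not None else list(self.loci)
        return AlleleFrequencyTable(
            populations=pops,
            loci=locs,
            freqs={p: {l: dict(self.freqs[p][l]) for l in locs if l in self.freqs.get(p, {})}
                   for p in pops},
            n_genes={p: {l: self.n_genes[p].get(l, 0) for l in locs} for p in pops},
            sample_sizes={p: self.sample_sizes[p] for p in pops if p in self.sample_sizes},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: population, locus, allele, frequency, n_genes."""
        rows = []
        for pop in self.populations:
            for locus in self.loci:
                if not self.has(pop, locus):
                    continue
                ng = self.n_genes[pop][locus]
                for allele in sorted(self.freqs[pop][locus]):
                    rows.append((pop, locus, allele, self.freqs[pop][locus][allele], ng))
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency", "n_genes"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   sample_sizes: Mapping[str, int] | None = None) -> "AlleleFrequencyTable":
        pops = list(dict.fromkeys(frame["population"]))
        loci = list(dict.fromkeys(frame["locus"]))
        freqs: dict[str, dict[str, dict[int, float]]] = {p: {} for p in pops}
        n_genes: dict[str, dict[str, int]] = {p: {l: 0 for l in loci} for p in pops}
        for (pop, locus), grp in frame.groupby(["population", "locus"], sort=False):
            freqs[pop][locus] = dict(zip(grp["allele"].astype(int), grp["frequency"].astype(float)))
            n_genes[pop][locus] = int(grp["n_genes"].iloc[0])
        return cls(pops, loci, freqs, n_genes, dict(sample_sizes or {}))

    @classmethod
    def read_csv(cls, path: str | Path) -> "AlleleFrequencyTable":
        return cls.from_frame(pd.read_csv(path))


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed genotype input; message names the offending line."""


def _build_dataset(
    locus_names: Sequence[str],
    ids: Sequence[str],
    pops: Sequence[str],
    calls: np.ndarray,
    populations: Sequence[PopulationMeta] | None,
    markers: Sequence[Marker] | None,
) -> GenotypeDataset:
    if populations is None:
        order = list(dict.fromkeys(pops))
        counts = {p: 0 for p in order}
        for p in pops:
            counts[p] += 1
        populations = [PopulationMeta(name=p, sample_size=counts[p]) for p in order]
    if markers is None:
        markers = [Marker(name=n) for n in locus_names]
    elif [m.name for m in markers] != list(locus_names):
        raise ValueError("supplied markers do not match the file's locus names")
    return GenotypeDataset(markers, populations, ids, pops, calls)


def read_genotypes(
    path: str | Path,
    dialect: str = "structure_format",
    populations: Sequence[PopulationMeta] | None = None,
    markers: Sequence[Marker] | None = None,
) -> GenotypeDataset:
    """Read a genotype table in STRUCTURE or long-CSV dialect.

    STRUCTURE dialect: a header row of locus names followed by one
    whitespace-delimited row per individual — individual id, population
    label, then two adjacent allele columns per locus; ``-9`` codes a
    missing allele.  CSV dialect: columns ``individual, population,
    locus, allele1, allele2`` with empty allele fields for missing.

    Population metadata may be supplied explicitly; otherwise populations
    are inferred from the population column with file order preserved.
    """
    path = Path(path)
    if dialect == "structure_format":
        return _read_structure(path, populations, markers)
    if dialect == "csv":
        return _read_long_csv(path, populations, markers)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_structure(path: Path, populations, markers=None) -> GenotypeDataset:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    locus_names = lines[0].split()
    r = len(locus_names)
    ids, pops, rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) != 2 + 2 * r:
            if (len(fields) - 2) % 2:
                raise ParseError(f"{path}:{lineno}: odd allele count ({len(fields) - 2})")
            raise ParseError(
                f"{path}:{lineno}: expected {2 + 2 * r} fields for {r} loci, got {len(fields)}"
            )
        ids.append(fields[0])
        pops.append(fields[1])
        try:
            alleles = [int(x) for x in fields[2:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer allele field ({exc})") from None
        for a in alleles:
            if a <= 0 and a != MISSING:
                raise ParseError(f"{path}:{lineno}: unknown missing code {a} (expected {MISSING})")
        rows.append(alleles)
    calls = np.asarray(rows, dtype=np.int64).reshape(len(ids), r, 2)
    return _build_dataset(locus_names, ids, pops, calls, populations, markers)


def _read_long_csv(path: Path, populations, markers=None) -> GenotypeDataset:
    frame = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: CSV must have columns {sorted(required)}")
    locus_names = list(dict.fromkeys(frame["locus"]))
    ids = list(dict.fromkeys(frame["individual"]))
    pop_of = dict(zip(frame["individual"], frame["population"]))
    li = {l: j for j, l in enumerate(locus_names)}
    ii = {i: k for k, i in enumerate(ids)}
    calls = np.full((len(ids), len(locus_names), 2), MISSING, dtype=np.int64)
    for row in frame.itertuples(index=False):
        a1, a2 = row.allele1, row.allele2
        if pd.isna(a1) or pd.isna(a2):
            continue
        calls[ii[row.individual], li[row.locus]] = (int(a1), int(a2))
    return _build_dataset(locus_names, ids, [pop_of[i] for i in ids], calls, populations, markers)


def write_genotypes(ds: GenotypeDataset, path: str | Path, dialect: str = "structure_format") -> None:
    """Write a dataset in the requested dialect (inverse of :func:`read_genotypes`)."""
    path = Path(path)
    if dialect == "structure_format":
        with open(path, "w") as fh:
            fh.write(" ".join(ds.locus_names) + "\n")
            for k, (ind, pop) in enumerate(zip(ds.individual_ids, ds.population_of)):
                fh.write(" ".join([ind, pop] + [str(a) for a in ds.calls[k].ravel()]) + "\n")
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["individual", "population", "locus", "allele1", "allele2"])
            for k, (ind, pop) in enumerate(zip(ds.individual_ids, ds.population_of)):
                for j, locus in enumerate(ds.locus_names):
                    a1, a2 = ds.calls[k, j]
                    if a1 == MISSING:
                        writer.writerow([ind, pop, locus, "", ""])
                    else:
                        writer.writerow([ind, pop, locus, a1, a2])
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_population_metadata(path: str | Path) -> list[PopulationMeta]:
    """Read a metadata CSV: population, latitude, longitude, lineage, sample_size.

    ``lineage`` is a semicolon-joined node path from phylum to population.
    """
    frame = pd.read_csv(path)
    metas = []
    for row in frame.itertuples(index=False):
        lineage = tuple(str(row.lineage).split(";")) if "lineage" in frame.columns else ()
        metas.append(
            PopulationMeta(
                name=str(row.population),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                lineage=lineage,
                sample_size=int(getattr(row, "sample_size", 1)),
            )
        )
    return metas


def write_population_metadata(metas: Sequence[PopulationMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["population", "latitude", "longitude", "lineage", "sample_size"])
        for m in metas:
            writer.writerow([m.name, m.latitude, m.longitude, ";".join(m.lineage), m.sample_size])


# ----------------------------------------------------------------------
# Missingness accounting and the dataset-subsetting policy
# ----------------------------------------------------------------------

def missing_rates(ds: GenotypeDataset) -> pd.DataFrame:
    """Fraction of untyped individuals per (population, locus).

    Returns a population x locus DataFrame of rates in [0, 1], computed
    as missing genotypes over the population's sample size.
    """
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("dataset is empty")
    mask = ds.missing_mask
    pop_arr = np.asarray(ds.population_of)
    rows = []
    for pop in ds.population_names:
        sel = pop_arr == pop
        rows.append(mask[sel].mean(axis=0))
    return pd.DataFrame(rows, index=ds.population_names, columns=ds.locus_names)


def subset_by_missing_policy(
    ds: GenotypeDataset, tolerance: float = 0.40
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Split a panel into the two analysis subsets used for multi-locus work.

    ``full_loci`` keeps every locus and drops any population that has a
    missing rate above *tolerance* at any locus; ``full_population``
    keeps every population and drops any locus that exceeds the
    tolerance in any population.  The first maximises per-locus
    information for bootstrap support, the second retains every
    population's position at the cost of markers.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must be in (0, 1)")
    rates = missing_rates(ds)
    bad = rates.to_numpy() > tolerance
    keep_pops = [p for p, row_bad in zip(ds.population_names, bad.any(axis=1)) if not row_bad]
    keep_loci = [l for l, col_bad in zip(ds.locus_names, bad.any(axis=0)) if not col_bad]
    if not keep_pops:
        raise ValueError("no population passes the missing-rate tolerance; raise the tolerance")
    if not keep_loci:
        raise ValueError("no locus passes the missing-rate tolerance; raise the tolerance")
    full_loci = ds.subset(populations=keep_pops)
    full_population = ds.subset(loci=keep_loci)
    return full_loci, full_population


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Allele frequencies over successfully typed gene copies.

    A (population, locus) cell where every genotype is missing gets no
    frequency vector (absent, not zero-filled) and ``n_genes`` 0.
    """
    pop_arr = np.asarray(ds.population_of)
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    n_genes: dict[str, dict[str, int]] = {}
    sizes: dict[str, int] = {}
    for pop in ds.population_names:
        sel = pop_arr == pop
        sizes[pop] = int(sel.sum())
        freqs[pop] = {}
        n_genes[pop] = {}
        sub = ds.calls[sel]
        for j, locus in enumerate(ds.locus_names):
            copies = sub[:, j].ravel()
            copies = copies[copies != MISSING]
            n_genes[pop][locus] = copies.size
            if copies.size == 0:
                continue
            alleles, counts = np.unique(copies, return_counts=True)
            freqs[pop][locus] = {
                int(a): float(c) / copies.size for a, c in zip(alleles, counts)
            }
    return AlleleFrequencyTable(
        populations=ds.population_names,
        loci=ds.locus_names,
        freqs=freqs,
        n_genes=n_genes,
        sample_sizes=sizes,
    )


def adjacent_map_distances(markers: Sequence[Marker]) -> np.ndarray:
    """Distances (cM) between map-adjacent markers on one chromosome.

    Markers are sorted by map position before differencing; the mean of
    the result summarises marker spacing and its minimum bounds the
    tightest linkage on the panel.
    """
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    pos = np.sort(np.array([m.map_position for m in markers], dtype=float))
    return np.diff(pos)
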