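"""Population-pair genetic distances from STR allele frequencies.

Two frequency-based measures are provided.  With ``x_ij`` and ``y_ij``
the frequencies of allele ``i`` at locus ``j`` in populations X and Y,
and ``r`` the number of loci,

* ``D_A = 1 - (1/r) sum_j sum_i sqrt(x_ij * y_ij)``
  (Nei-Tajima-Tateno distance; one minus the locus-averaged
  Bhattacharyya affinity), bounded in [0, 1];
* ``D_C = (2 / (pi * r)) sum_j sqrt(2 * (1 - sum_i sqrt(x_ij * y_ij)))``
  (Cavalli-Sforza & Edwards chord distance in the Takezaki-Nei
  normalisation, with the 1/r inside the prefactor); a single locus
  with fully disjoint allele sets contributes ``(2/pi) * sqrt(2)``.

Both are frequency-only: allele sizes never enter, so stepwise-mutation
structure is deliberately ignored.  Branch support for trees built from
these distances comes from resampling loci with replacement
("bootstrap over loci").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import AlleleFrequencyTable

__all__ = [
    "DistanceMatrix",
    "BootstrapSet",
    "da_distance",
    "dc_distance",
    "pairwise_matrix",
    "bootstrap_over_loci",
]

FreqVectors = Mapping[str, Mapping[int, float]]  # locus -> allele -> frequency


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    ``kind`` tags provenance: ``"DA"``, ``"DC"``, ``"geographic"``,
    ``"linguistic"`` or ``"pc_score"``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "DA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper off-diagonal entries, row-major (scipy 'condensed' order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def align_to(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Reorder (and/or subset) rows and columns to the given labels."""
        try:
            idx = [self.labels.index(l) for l in labels]
        except ValueError as exc:
            raise KeyError(f"label not in matrix: {exc}") from None
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)].copy(), self.kind)

    def drop(self, labels: Sequence[str]) -> "DistanceMatrix":
        keep = [l for l in self.labels if l not in set(labels)]
        return self.align_to(keep)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    # ---------------- text interchange ----------------
    def to_phylip(self, path: str | Path) -> None:
        """Write PHYLIP square format: count line, then label + full row."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, kind: str = "DA") -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        n = int(tokens[0])
        labels, rows, k = [], [], 1
        for _ in range(n):
            labels.append(tokens[k])
            rows.append([float(x) for x in tokens[k + 1 : k + 1 + n]])
            k += 1 + n
        return cls(labels, np.array(rows), kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class BootstrapSet:
    """Bootstrap-over-loci replicates of a distance matrix."""

    replicates: list[DistanceMatrix]
    resampled_loci: list[list[str]]
    seed: int | None = None
    measure: str = "DA"

    @property
    def B(self) -> int:
        return len(self.replicates)

    def mean_matrix(self) -> DistanceMatrix:
        stack = np.stack([m.values for m in self.replicates])
        return DistanceMatrix(self.replicates[0].labels, stack.mean(axis=0), self.measure)


def _affinity(x: Mapping[int, float], y: Mapping[int, float]) -> float:
    """Bhattacharyya affinity sum_i sqrt(x_i * y_i) over the shared support."""
    return sum(math.sqrt(x[a] * y[a]) for a in x.keys() & y.keys())


def da_distance(x: FreqVectors, y: FreqVectors, loci: Sequence[str] | None = None) -> float:
    """D_A distance between two populations' per-locus frequency vectors."""
    loci = list(loci) if loci is not None else sorted(x.keys() & y.keys())
    if not loci:
        raise ValueError("no shared loci between the two populations")
    total = sum(_affinity(x[j], y[j]) for j in loci)
    return min(max(1.0 - total / len(loci), 0.0), 1.0)


def dc_distance(x: FreqVectors, y: FreqVectors, loci: Sequence[str] | None = None) -> float:
    """Chord distance D_C between two populations' per-locus frequency vectors."""
    loci = list(loci) if loci is not None else sorted(x.keys() & y.keys())
    if not loci:
        raise ValueError("no shared loci between the two populations")
    total = 0.0
    for j in loci:
        total += math.sqrt(max(2.0 * (1.0 - _affinity(x[j], y[j])), 0.0))
    return 2.0 / (math.pi * len(loci)) * total


_MEASURES = {"DA": da_distance, "DC": dc_distance}


def pairwise_matrix(
    table: AlleleFrequencyTable,
    measure: str = "DA",
    loci: Sequence[str] | None = None,
    strict: bool = True,
) -> DistanceMatrix:
    """All-pairs genetic distance matrix from an allele-frequency table.

    With ``strict`` (default), every population must carry a frequency
    vector at every requested locus; otherwise each pair is averaged
    over the loci present in both — a documented fallback for panels
    that were not pre-subset by the missing-rate policy.
    """
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {sorted(_MEASURES)}")
    loci = list(loci) if loci is not None else list(table.loci)
    if strict:
        for pop in table.populations:
            absent = [l for l in loci if not table.has(pop, l)]
            if absent:
                raise ValueError(f"population {pop!r} has no frequencies at loci {absent}")
    fn = _MEASURES[measure]
    pops = table.populations
    vectors = {p: {l: table.freqs[p][l] for l in loci if table.has(p, l)} for p in pops}
    n = len(pops)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = fn(vectors[pops[a]], vectors[pops[b]], None if not strict else loci)
            values[a, b] = values[b, a] = d
    return DistanceMatrix(list(pops), values, measure)


def bootstrap_over_loci(
    table: AlleleFrequencyTable,
    measure: str = "DA",
    B: int = 1000,
    seed: int | None = 0,
) -> BootstrapSet:
    """Resample loci with replacement and recompute the averaged matrix.

    Each of the *B* replicates draws ``r`` locus indices uniformly with
    replacement (no stratification) and recomputes the multi-locus
    distance matrix over that multiset; a replicate's average weights a
    locus by its multiplicity.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    loci = list(table.loci)
    if not loci:
        raise ValueError("no loci to resample")
    rng = np.random.default_rng(seed)
    replicates, resampled = [], []
    for _ in range(B):
        draw = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        replicates.append(pairwise_matrix(table, measure, loci=draw))
        resampled.append(draw)
    return BootstrapSet(replicates=replicates, resampled_loci=resampled, seed=seed, measure=measure)


def distances_to_long_csv(
    matrices: Mapping[str, DistanceMatrix], path: str | Path
) -> None:
    """Long-format CSV: pop1, pop2, locus_set, measure, value."""
    rows = []
    for locus_set, m in matrices.items():
        for a in range(m.n):
            for b in range(a + 1, m.n):
                rows.append((m.labels[a], m.labels[b], locus_set, m.kind, m.values[a, b]))
    pd.DataFrame(rows, columns=["pop1", "pop2", "locus_set", "measure", "value"]).to_csv(
        path, index=False
    )
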