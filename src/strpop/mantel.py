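"""Mantel and partial Mantel tests, and leave-one-language-group-out rows.

The Mantel statistic is the Pearson correlation of the vectorised upper
off-diagonal entries of two labelled distance matrices (aligned by
label, never by position).  Significance comes from jointly permuting
the row-and-column order of one matrix; with the add-one correction the
permutation p-value is ``(#{r_perm >= r_obs} + 1) / (permutations + 1)``
and can never be exactly zero.  The default tail is one-sided positive,
matching directional hypotheses of the form "genetically closer
populations are also geographically/linguistically closer"; a two-sided
option is available.

The partial (3-way) test residualises both vectors on the control
matrix's vector and correlates the residuals; permutations follow the
Smouse-Long-Sokal scheme — the first matrix is permuted, re-residualised
against the (fixed) control, and correlated with the fixed residuals of
the second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = ["MantelResult", "mantel", "partial_mantel", "exclusion_analysis"]


@dataclass
class MantelResult:
    """Correlation, permutation p-value and provenance of one test."""

    r: float
    p_value: float
    permutations: int
    tail: str = "greater"
    controlled: str | None = None
    excluded_group: str | None = None


def _standardise(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return (v - v.mean()) / sd


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    permutations: int = 5000,
    seed: int | None = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel test of association between two distance matrices."""
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if set(a.labels) != set(b.labels):
        raise ValueError("matrices are labelled with different population sets")
    b = b.align_to(a.labels)
    n = a.n
    iu0, iu1 = _pair_indices(n)
    va = a.values[iu0, iu1]
    vb = b.values[iu0, iu1]
    za, zb = _standardise(va), _standardise(vb)
    m = za.size
    r_obs = float(za @ zb) / m

    rng = np.random.default_rng(seed)
    mu, sd = va.mean(), va.std()
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        pv = a.values[perm[iu0], perm[iu1]]
        r_perm = float(((pv - mu) / sd) @ zb) / m
        if tail == "greater":
            count += r_perm >= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    p = (count + 1.0) / (permutations + 1.0)
    return MantelResult(r=r_obs, p_value=p, permutations=permutations, tail=tail)


def _residualise(v: np.ndarray, control: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(control), control])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    control: DistanceMatrix,
    permutations: int = 5000,
    seed: int | None = 0,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel test of *a* vs *b* controlling for a third matrix."""
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if not (set(a.labels) == set(b.labels) == set(control.labels)):
        raise ValueError("all three matrices must share one label set")
    b = b.align_to(a.labels)
    control = control.align_to(a.labels)
    n = a.n
    iu0, iu1 = _pair_indices(n)
    va = a.values[iu0, iu1]
    vb = b.values[iu0, iu1]
    vc = control.values[iu0, iu1]
    for v in (va, vb, vc):
        if v.std() == 0:
            raise ValueError("constant distance matrix: correlation undefined")
    ra = _residualise(va, vc)
    rb = _residualise(vb, vc)
    # a matrix collinear with the control has no residual signal: r = 0
    if ra.std() <= 1e-12 * va.std() or rb.std() <= 1e-12 * vb.std():
        return MantelResult(r=0.0, p_value=1.0, permutations=permutations, tail=tail,
                            controlled=control.kind)
    za, zb = _standardise(ra), _standardise(rb)
    m = za.size
    r_obs = float(za @ zb) / m

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        pv = a.values[perm[iu0], perm[iu1]]
        pra = _residualise(pv, vc)
        sd = pra.std()
        if sd == 0:
            continue
        r_perm = float(((pra - pra.mean()) / sd) @ zb) / m
        if tail == "greater":
            count += r_perm >= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    p = (count + 1.0) / (permutations + 1.0)
    return MantelResult(r=r_obs, p_value=p, permutations=permutations, tail=tail,
                        controlled=control.kind)


def exclusion_analysis(
    matrices: Mapping[str, DistanceMatrix],
    groups: Mapping[str, str],
    permutations: int = 5000,
    seed: int | None = 0,
    min_populations: int = 4,
) -> pd.DataFrame:
    """Full and leave-one-language-group-out Mantel comparisons.

    *matrices* maps ``"GEN"``, ``"GEO"``, ``"LING"`` to distance
    matrices on one population set; *groups* maps every population to
    its language group.  For the full set and for each "non-<group>"
    complement, all three 2-way tests plus the two 3-way tests involving
    genetics (controlling the matrix absent from the pair) are run.
    Exclusions leaving fewer than *min_populations* populations are
    flagged and skipped.
    """
    for key in ("GEN", "GEO", "LING"):
        if key not in matrices:
            raise ValueError(f"matrices must include {key!r}")
    labels = list(matrices["GEN"].labels)
    uncovered = [l for l in labels if l not in groups]
    if uncovered:
        raise ValueError(f"populations without a language group: {uncovered}")
    group_names = sorted(set(groups[l] for l in labels))
    rows = []
    datasets: list[tuple[str, list[str]]] = [("full", labels)]
    datasets += [
        (f"non-{g}", [l for l in labels if groups[l] != g]) for g in group_names
    ]
    pairs = [("GEN", "GEO", "LING"), ("GEN", "LING", "GEO"), ("LING", "GEO", "GEN")]
    rng = np.random.default_rng(seed)
    for name, keep in datasets:
        if len(keep) < min_populations:
            for x, y, _ in pairs:
                rows.append((name, "2-way", f"{x},{y}", np.nan, np.nan, True))
            continue
        sub = {k: m.align_to([l for l in labels if l in keep]) for k, m in matrices.items()}
        for x, y, z in pairs:
            res = mantel(sub[x], sub[y], permutations, int(rng.integers(2**31)))
            rows.append((name, "2-way", f"{x},{y}", res.r, res.p_value, False))
        for x, y, z in pairs[:2]:  # 3-way tests involve genetics
            res = partial_mantel(sub[x], sub[y], sub[z], permutations, int(rng.integers(2**31)))
            rows.append((name, "3-way", f"{x},{y}", res.r, res.p_value, False))
    return pd.DataFrame(
        rows, columns=["dataset", "test", "pair", "r", "p", "flagged"]
    )


def write_mantel_report(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
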