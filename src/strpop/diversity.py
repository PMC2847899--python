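"""Expected heterozygosity and exact tests of Hardy-Weinberg equilibrium.

Heterozygosity uses the unbiased estimator
``H_E = n/(n-1) * (1 - sum_i p_i^2)`` over ``n`` successfully typed gene
copies, the standard small-sample correction for multiallelic loci.

The Hardy-Weinberg test is the exact conditional test: given the allele
counts, genotype tables are weighted by the Levene conditional
probability

    P(f) = n! * prod_i n_i! * 2^H / ((2n)! * prod_{i<=j} f_ij!)

(``H`` = number of heterozygotes) and the p-value is the total
probability of tables no more probable than the observed one.  Small
tables are fully enumerated.  Larger ones default to conventional Monte
Carlo: the 2n gene copies are randomly re-paired, which draws genotype
tables i.i.d. from the exact conditional null, so the p-value estimate
carries a rigorous binomial standard error.  A switch Markov chain over
genotype configurations is available as an alternative sampler —
conditioned on allele counts the null over *labelled* configurations is
uniform, so the chain that swaps one gene copy between two random
individuals is reversible with acceptance probability one (the
Guo-Thompson switch chain with its acceptance ratio folded in); its
standard error comes from batch means and is less trustworthy when the
chain mixes slowly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "expected_heterozygosity",
    "HeterozygosityTable",
    "heterozygosity_summary",
    "HweResult",
    "hwe_exact_test",
    "genotype_counts",
    "hwe_scan",
]

_LOG2 = math.log(2.0)


def expected_heterozygosity(freqs: Sequence[float] | np.ndarray, n_genes: int) -> float:
    """Unbiased expected heterozygosity from an allele-frequency vector.

    Parameters
    ----------
    freqs : sequence of float
        Allele frequencies summing to 1.
    n_genes : int
        Number of gene copies the frequencies were estimated from
        (at least 2).
    """
    p = np.asarray(freqs, dtype=float)
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    h = n_genes / (n_genes - 1.0) * (1.0 - float(np.sum(p * p)))
    return max(h, 0.0)


@dataclass
class HeterozygosityTable:
    """H_E per (population, locus) with per-locus summaries.

    ``per_locus`` has columns ``mean`` and ``sd`` (sample standard
    deviation across populations; absent when fewer than two populations
    contribute).  ``percentiles`` summarises the pooled H_E values.
    """

    values: pd.DataFrame  # population x locus, NaN where absent
    per_locus: pd.DataFrame  # locus x {mean, sd, n_populations}
    percentiles: dict[str, float]


def heterozygosity_summary(
    table: AlleleFrequencyTable, tolerance: float = 0.40
) -> HeterozygosityTable:
    """H_E for every (population, locus) cell plus per-locus mean and sd.

    Cells whose missing rate exceeds *tolerance* (when sample sizes are
    known) are excluded from the per-locus summaries, mirroring the
    practice of crossing out unreliable cells before averaging.
    """
    values = pd.DataFrame(np.nan, index=table.populations, columns=table.loci)
    usable = pd.DataFrame(False, index=table.populations, columns=table.loci)
    for pop in table.populations:
        size = table.sample_sizes.get(pop)
        for locus in table.loci:
            if not table.has(pop, locus):
                continue
            ng = table.n_genes[pop][locus]
            if ng < 2:
                continue
            p = np.array(list(table.freqs[pop][locus].values()))
            values.loc[pop, locus] = expected_heterozygosity(p, ng)
            if size is not None:
                miss = 1.0 - ng / (2.0 * size)
                usable.loc[pop, locus] = miss <= tolerance
            else:
                usable.loc[pop, locus] = True
    masked = values.where(usable)
    per_locus = pd.DataFrame(
        {
            "mean": masked.mean(axis=0),
            "sd": masked.std(axis=0, ddof=1),
            "n_populations": masked.notna().sum(axis=0),
        }
    )
    pooled = masked.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    percentiles = {}
    if pooled.size:
        percentiles = {
            "p10": float(np.percentile(pooled, 10)),
            "p90": float(np.percentile(pooled, 90)),
            "min": float(pooled.min()),
            "max": float(pooled.max()),
        }
    return HeterozygosityTable(values=values, per_locus=per_locus, percentiles=percentiles)


# ----------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ----------------------------------------------------------------------

@dataclass
class HweResult:
    """Outcome of one exact HWE test."""

    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    chain_length: int = 0
    mc_stderr: float | None = None
    degenerate: bool = False


def genotype_counts(ds: GenotypeDataset, population: str, locus: str) -> dict[tuple[int, int], int]:
    """Observed genotype counts (allele pairs ordered small<=large) for one cell."""
    j = ds.locus_names.index(locus)
    sel = ds.indices_of(population)
    counts: dict[tuple[int, int], int] = {}
    for a, b in ds.calls[sel, j]:
        if a == MISSING:
            continue
        counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    return counts


def _table_from_counts(counts: Mapping[tuple[int, int], int]) -> tuple[np.ndarray, list[int]]:
    alleles = sorted({a for pair in counts for a in pair})
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    f = np.zeros((k, k), dtype=np.int64)
    for (a, b), c in counts.items():
        i, j = sorted((idx[a], idx[b]))
        f[i, j] += c
    return f, alleles


def _log_stat(f: np.ndarray, lf: np.ndarray) -> float:
    """Varying part of log P(f): H*log2 - sum log f_ij! (upper triangle)."""
    k = f.shape[0]
    iu = np.triu_indices(k)
    het = int(f[iu].sum() - np.trace(f))
    return het * _LOG2 - float(lf[f[iu]].sum())


def _enumerate_tables(allele_counts: np.ndarray, limit: int):
    """Yield all genotype tables consistent with the allele counts.

    Tables are upper-triangular k x k integer arrays; raises
    ``OverflowError`` once more than *limit* tables have been produced.
    """
    k = allele_counts.size
    f = np.zeros((k, k), dtype=np.int64)
    produced = 0

    def fill_row(i: int, c: np.ndarray):
        nonlocal produced
        if i == k:
            if c.any():
                return
            produced += 1
            if produced > limit:
                raise OverflowError("enumeration limit exceeded")
            yield f.copy()
            return
        ci = int(c[i])
        for fii in range(ci // 2 + 1):
            f[i, i] = fii
            rest = ci - 2 * fii
            yield from fill_offdiag(i, i + 1, rest, c)
        f[i, i] = 0

    def fill_offdiag(i: int, j: int, rest: int, c: np.ndarray):
        if j == k:
            if rest == 0:
                c2 = c.copy()
                c2[i] = 0
                yield from fill_row(i + 1, c2)
            return
        hi = min(rest, int(c[j]))
        # remaining capacity of columns beyond j bounds how little we may place
        cap_beyond = int(c[j + 1 :].sum())
        lo = max(0, rest - cap_beyond)
        for fij in range(lo, hi + 1):
            f[i, j] = fij
            c[j] -= fij
            yield from fill_offdiag(i, j + 1, rest - fij, c)
            c[j] += fij
        f[i, j] = 0

    yield from fill_row(0, allele_counts.astype(np.int64).copy())


def _exact_enumeration(f_obs: np.ndarray, lf: np.ndarray, limit: int) -> float:
    counts = np.zeros(f_obs.shape[0], dtype=np.int64)
    iu = np.triu_indices(f_obs.shape[0])
    for (i, j), c in np.ndenumerate(f_obs):
        if c:
            counts[i] += c
            counts[j] += c
    s_obs = _log_stat(f_obs, lf)
    total = 0.0
    tail = 0.0
    for table in _enumerate_tables(counts, limit):
        s = _log_stat(table, lf)
        w = math.exp(s)
        total += w
        if s <= s_obs + 1e-9:
            tail += w
    return tail / total


def _exact_monte_carlo(
    f_obs: np.ndarray, lf: np.ndarray, chain_steps: int, burn_in: int, rng: np.random.Generator
) -> tuple[float, float, int]:
    """Markov-chain p-value with a batch-means standard error."""
    k = f_obs.shape[0]
    pairs: list[list[int]] = []
    for (i, j), c in np.ndenumerate(f_obs):
        pairs.extend([i, j] for _ in range(int(c)))
    geno = np.array(pairs, dtype=np.int64)  # (n, 2)
    n = geno.shape[0]
    f = f_obs.astype(np.int64).copy()
    s_obs = _log_stat(f_obs, lf)
    s = s_obs
    log2 = _LOG2

    us = rng.integers(0, n, size=chain_steps + burn_in)
    vs = rng.integers(0, n - 1, size=chain_steps + burn_in)
    vs[vs >= us] += 1  # distinct individuals
    slots = rng.integers(0, 4, size=chain_steps + burn_in)

    def cell_delta(i: int, j: int, change: int) -> float:
        """Contribution change from f[i,j] += change (change in {-1, +1})."""
        a, b = (i, j) if i <= j else (j, i)
        old = f[a, b]
        f[a, b] = old + change
        d = -(lf[old + change] - lf[old])
        if a != b:
            d += change * log2
        return d

    indicator_sum = 0
    recorded = 0
    nbatch = 20  # long batches: the switch chain can be strongly autocorrelated
    batch_size = max(1, chain_steps // nbatch)
    batch_means = []
    batch_acc = 0

    for t in range(chain_steps + burn_in):
        u, v = int(us[t]), int(vs[t])
        su, sv = divmod(int(slots[t]), 2)
        au = geno[u, su]
        av = geno[v, sv]
        if au != av:
            # remove old genotypes, add swapped ones
            d = cell_delta(geno[u, 0], geno[u, 1], -1)
            d += cell_delta(geno[v, 0], geno[v, 1], -1)
            geno[u, su], geno[v, sv] = av, au
            d += cell_delta(geno[u, 0], geno[u, 1], +1)
            d += cell_delta(geno[v, 0], geno[v, 1], +1)
            s += d
        if t >= burn_in:
            hit = 1 if s <= s_obs + 1e-9 else 0
            indicator_sum += hit
            batch_acc += hit
            recorded += 1
            if recorded % batch_size == 0:
                batch_means.append(batch_acc / batch_size)
                batch_acc = 0
    p = indicator_sum / recorded
    if len(batch_means) >= 2:
        se = float(np.std(batch_means, ddof=1) / math.sqrt(len(batch_means)))
    else:
        se = float("nan")
    return p, se, recorded


def _exact_mc_pairing(
    f_obs: np.ndarray, lf: np.ndarray, reps: int, rng: np.random.Generator
) -> tuple[float, float]:
    """i.i.d. Monte Carlo: random re-pairings of the 2n gene copies."""
    k = f_obs.shape[0]
    copies = []
    for (i, j), c in np.ndenumerate(f_obs):
        copies.extend([i] * int(c) + [j] * int(c))
    copies = np.array(copies, dtype=np.int64)
    n = copies.size // 2
    s_obs = _log_stat(f_obs, lf)
    hits = 0
    chunk = max(1, min(reps, 4_000_000 // max(copies.size, 1)))
    done = 0
    while done < reps:
        b_sz = min(chunk, reps - done)
        # random re-pairings: argsort of uniform keys permutes the copies
        order = np.argsort(rng.random((b_sz, copies.size)), axis=1)
        perm = copies[order].reshape(b_sz, n, 2)
        a = perm.min(axis=2)
        b = perm.max(axis=2)
        cell = a * k + b + (np.arange(b_sz) * k * k)[:, None]
        counts = np.bincount(cell.ravel(), minlength=b_sz * k * k).reshape(b_sz, k * k)
        het = n - (a == b).sum(axis=1)
        s = het * _LOG2 - lf[counts].sum(axis=1)
        hits += int(np.sum(s <= s_obs + 1e-9))
        done += b_sz
    p = hits / reps
    se = math.sqrt(max(p * (1.0 - p), 0.0) / reps)
    return p, max(se, 1.0 / reps)


def hwe_exact_test(
    counts: Mapping[tuple[int, int], int],
    max_enumeration: int = 200_000,
    chain_steps: int = 100_000,
    burn_in: int = 10_000,
    seed: int | np.random.Generator = 0,
    sampler: str = "pairing",
) -> HweResult:
    """Exact conditional test of Hardy-Weinberg proportions.

    Parameters
    ----------
    counts : mapping (allele, allele) -> int
        Observed genotype counts; pair order is not semantic.
    max_enumeration : int
        Enumerate the full conditional distribution when it has at most
        this many tables, otherwise fall back to Monte Carlo.
    chain_steps, burn_in : int
        Monte Carlo effort: number of i.i.d. re-pairing replicates
        (``sampler="pairing"``, where ``burn_in`` is ignored) or
        recorded and discarded steps of the switch chain
        (``sampler="chain"``).
    seed : int or numpy Generator
        Seeds the sampler; ignored on the enumeration path.
    """
    if not counts or any(c < 0 for c in counts.values()):
        raise ValueError("counts must be a non-empty table of non-negative genotype counts")
    if sampler not in ("pairing", "chain"):
        raise ValueError("sampler must be 'pairing' or 'chain'")
    f_obs, alleles = _table_from_counts(counts)
    if len(alleles) < 2:
        return HweResult(p_value=1.0, method="enumeration", degenerate=True)
    n = int(f_obs.sum())
    lf = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, 2 * n + 1)))))
    try:
        p = _exact_enumeration(f_obs, lf, max_enumeration)
        return HweResult(p_value=p, method="enumeration")
    except OverflowError:
        pass
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sampler == "pairing":
        p, se = _exact_mc_pairing(f_obs, lf, chain_steps, rng)
        return HweResult(p_value=p, method="monte_carlo", chain_length=chain_steps, mc_stderr=se)
    p, se, recorded = _exact_monte_carlo(f_obs, lf, chain_steps, burn_in, rng)
    return HweResult(p_value=p, method="monte_carlo_chain", chain_length=recorded, mc_stderr=se)


def hwe_scan(
    ds: GenotypeDataset,
    max_enumeration: int = 2_000,
    chain_steps: int = 100_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact HWE p-values for every (population, locus) cell of a panel.

    Returns a population x locus DataFrame (NaN where a cell has no
    typed genotypes).  Each cell's chain is seeded deterministically
    from *seed* and the cell position.
    """
    out = pd.DataFrame(np.nan, index=ds.population_names, columns=ds.locus_names)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(ds.population_names) * len(ds.locus_names))
    k = 0
    for pop in ds.population_names:
        for locus in ds.locus_names:
            ss = children[k]
            k += 1
            counts = genotype_counts(ds, pop, locus)
            if not counts:
                continue
            res = hwe_exact_test(
                counts,
                max_enumeration=max_enumeration,
                chain_steps=chain_steps,
                burn_in=burn_in,
                seed=np.random.default_rng(ss),
            )
            out.loc[pop, locus] = res.p_value
    return out


def write_hwe_report(pvalues: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """CSV report of HWE p-values with sub-threshold cells flagged."""
    flagged = pvalues.copy().astype(object)
    for pop in pvalues.index:
        for locus in pvalues.columns:
            v = pvalues.loc[pop, locus]
            if pd.notna(v) and v < alpha:
                flagged.loc[pop, locus] = f"{v:.4g}*"
            elif pd.notna(v):
                flagged.loc[pop, locus] = f"{v:.4g}"
            else:
                flagged.loc[pop, locus] = ""
    flagged.to_csv(path, index_label="population")
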