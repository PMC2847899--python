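"""Model-based admixture clustering of diploid multilocus genotypes.

Each individual ``i`` carries a membership vector ``q_i`` on the
K-simplex; every gene copy independently draws a cluster of origin
``z ~ Categorical(q_i)`` and then an allele from that cluster's
frequency distribution at its locus.  Cluster frequencies follow the
correlated-frequencies (F-model) prior: at locus ``l`` cluster ``k``
draws ``p_kl ~ Dirichlet(p_l^anc * (1 - F_k) / F_k)`` around a shared
ancestral distribution, with an independent drift parameter ``F_k`` per
cluster.  Inference is by Gibbs sampling over (Z, Q, P) with
Metropolis updates for the admixture concentration ``alpha`` (uniform
prior on (0, 10)) and the drift parameters (uniform on (0, 1)).
Missing genotypes contribute no likelihood terms.

The ancestral frequencies are fixed at the pooled sample frequencies
rather than sampled — a collapse that leaves the P updates conjugate
and barely moves the posterior for the panel sizes this package
targets.  With the uncorrelated option the P prior is a flat
Dirichlet(lambda=1).

``lnPr(X|K)`` is estimated from the recorded log-likelihood trace as
``mean - variance/2``, and runs with different label orders are aligned
by greedy matching of membership columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import MISSING, GenotypeDataset

__all__ = [
    "AdmixtureConfig",
    "AdmixtureResult",
    "fit_admixture",
    "fit_admixture_runs",
    "estimate_lnP",
    "select_K",
    "align_runs",
]


@dataclass
class AdmixtureConfig:
    """Sampler settings.

    Defaults are desk-scale (short chains, few restarts) so that panel
    analyses finish in seconds to minutes; production settings of
    50,000/50,000 sweeps and 15 runs per K are plain config values.
    """

    K: int = 3
    burn_in: int = 2000
    run_length: int = 2000
    runs: int = 5
    alpha: float = 1.0
    sample_alpha: bool = True
    correlated_frequencies: bool = True
    drift_init: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 1 or self.run_length < 1:
            raise ValueError("burn_in and run_length must be >= 1")


@dataclass
class AdmixtureResult:
    """Posterior summaries of one chain."""

    K: int
    Q: np.ndarray  # individuals x K, rows on the simplex
    P: list[np.ndarray]  # per locus: K x n_alleles, rows on the simplex
    loglik_trace: np.ndarray
    lnP: float
    individuals: list[str]
    population_of: list[str]
    allele_codes: list[list[int]]  # per locus, allele sizes in column order
    alpha: float = 1.0
    drift: np.ndarray | None = None

    @property
    def mean_membership(self) -> pd.DataFrame:
        """Population x cluster averages of membership coefficients."""
        frame = pd.DataFrame(self.Q, columns=[f"C{k + 1}" for k in range(self.K)])
        frame["population"] = self.population_of
        return frame.groupby("population", sort=False).mean()

    def write_q(self, path: str | Path) -> None:
        """Structure-compatible columnar text: individual, population, memberships."""
        with open(path, "w") as fh:
            fh.write("individual population " +
                     " ".join(f"C{k + 1}" for k in range(self.K)) + "\n")
            for ind, pop, row in zip(self.individuals, self.population_of, self.Q):
                fh.write(f"{ind} {pop} " + " ".join(f"{v:.4f}" for v in row) + "\n")


def _encode(ds: GenotypeDataset):
    """Integer-code alleles per locus; returns flat copy arrays for typed copies."""
    if ds.calls.shape[2] != 2:
        raise ValueError("admixture model requires diploid data")
    codes: list[list[int]] = []
    coded = np.full(ds.calls.shape, -1, dtype=np.int64)
    for j in range(ds.n_loci):
        col = ds.calls[:, j].ravel()
        alleles = sorted(int(a) for a in np.unique(col[col != MISSING]))
        codes.append(alleles)
        lut = {a: c for c, a in enumerate(alleles)}
        for c in range(2):
            vals = ds.calls[:, j, c]
            coded[:, j, c] = [lut.get(int(v), -1) for v in vals]
    typed = coded >= 0
    n_idx, l_idx, c_idx = np.nonzero(typed)
    a_idx = coded[n_idx, l_idx, c_idx]
    return codes, n_idx, l_idx, a_idx


def _log_dirichlet_pdf(p: np.ndarray, conc: np.ndarray, valid: np.ndarray) -> float:
    c = conc[valid]
    x = np.clip(p[valid], 1e-300, None)
    return float(gammaln(c.sum()) - gammaln(c).sum() + ((c - 1.0) * np.log(x)).sum())


def fit_admixture(ds: GenotypeDataset, cfg: AdmixtureConfig) -> AdmixtureResult:
    """Run one Gibbs chain and return posterior-mean memberships.

    ``Q`` and ``P`` are means over the recorded sweeps; the data
    log-likelihood is recorded every sweep after burn-in and feeds the
    ``lnPr(X|K)`` estimate.
    """
    K = cfg.K
    codes, n_idx, l_idx, a_idx = _encode(ds)
    N, L = ds.n_individuals, ds.n_loci
    if all(len(c) < 2 for c in codes):
        raise ValueError("no polymorphic locus in the dataset")
    amax = max(len(c) for c in codes)
    valid = np.zeros((L, amax), dtype=bool)
    for j, c in enumerate(codes):
        valid[j, : len(c)] = True

    # pooled (ancestral) frequencies per locus
    anc = np.zeros((L, amax))
    for j in range(L):
        sel = l_idx == j
        cnt = np.bincount(a_idx[sel], minlength=amax).astype(float)
        anc[j] = cnt / max(cnt.sum(), 1.0)

    rng = np.random.default_rng(cfg.seed)

    if K == 1:
        # degenerate simplex: memberships are all 1, P is the pooled draw
        q = np.ones((N, 1))
        trace = []
        p_sum = np.zeros((1, L, amax))
        prior = np.where(valid, 1.0, 0.0)
        for sweep in range(cfg.burn_in + cfg.run_length):
            cnts = np.zeros((L, amax))
            np.add.at(cnts, (l_idx, a_idx), 1.0)
            p = rng.gamma(np.where(valid, prior + cnts, 0.0))
            p /= np.clip(p.sum(axis=1, keepdims=True), 1e-300, None)
            if sweep >= cfg.burn_in:
                p_sum[0] += p
                trace.append(float(np.log(np.clip(p[l_idx, a_idx], 1e-300, None)).sum()))
        p_mean = p_sum / cfg.run_length
        tr = np.array(trace)
        return AdmixtureResult(
            K=1, Q=q, P=[p_mean[:, j, : len(codes[j])] for j in range(L)],
            loglik_trace=tr, lnP=estimate_lnP(tr), individuals=list(ds.individual_ids),
            population_of=list(ds.population_of), allele_codes=codes, alpha=cfg.alpha,
        )

    alpha = float(cfg.alpha)
    drift = np.full(K, cfg.drift_init)
    q = rng.dirichlet(np.ones(K), size=N)
    p = np.where(valid, anc, 0.0)[None, :, :].repeat(K, axis=0)
    p /= np.clip(p.sum(axis=2, keepdims=True), 1e-300, None)

    M = n_idx.size
    q_sum = np.zeros((N, K))
    p_sum = np.zeros((K, L, amax))
    trace = []
    alpha_sum = 0.0
    drift_sum = np.zeros(K)

    for sweep in range(cfg.burn_in + cfg.run_length):
        # --- Z: cluster of origin per typed gene copy
        w = q[n_idx, :] * p[:, l_idx, a_idx].T  # (M, K)
        cum = np.cumsum(w, axis=1)
        u = rng.random(M) * cum[:, -1]
        z = (u[:, None] >= cum).sum(axis=1)

        # --- Q | Z
        cq = np.zeros((N, K))
        np.add.at(cq, (n_idx, z), 1.0)
        q = rng.gamma(alpha + cq)
        q /= np.clip(q.sum(axis=1, keepdims=True), 1e-300, None)

        # --- P | Z
        cp = np.zeros((K, L, amax))
        np.add.at(cp, (z, l_idx, a_idx), 1.0)
        if cfg.correlated_frequencies:
            conc = anc[None] * ((1.0 - drift) / drift)[:, None, None]
        else:
            conc = np.ones((K, L, amax))
        shape = np.where(valid[None], conc + cp, 0.0)
        p = rng.gamma(np.clip(shape, 0.0, None))
        p /= np.clip(p.sum(axis=2, keepdims=True), 1e-300, None)

        # --- alpha | Q  (Metropolis, uniform prior on (0, 10))
        if cfg.sample_alpha:
            prop = alpha + rng.normal(0.0, 0.1)
            if 0.0 < prop < 10.0:
                slq = float(np.log(np.clip(q, 1e-300, None)).sum())
                cur = N * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1.0) * slq
                new = N * (gammaln(K * prop) - K * gammaln(prop)) + (prop - 1.0) * slq
                if np.log(rng.random()) < new - cur:
                    alpha = prop

        # --- drift | P  (Metropolis per cluster, uniform prior on (0, 1))
        if cfg.correlated_frequencies:
            for k in range(K):
                prop = drift[k] + rng.normal(0.0, 0.05)
                if not 0.0 < prop < 1.0:
                    continue
                cur = new = 0.0
                c_cur = (1.0 - drift[k]) / drift[k]
                c_new = (1.0 - prop) / prop
                for j in range(L):
                    cur += _log_dirichlet_pdf(p[k, j], anc[j] * c_cur, valid[j])
                    new += _log_dirichlet_pdf(p[k, j], anc[j] * c_new, valid[j])
                if np.log(rng.random()) < new - cur:
                    drift[k] = prop

        if sweep >= cfg.burn_in:
            like = (q[n_idx, :] * p[:, l_idx, a_idx].T).sum(axis=1)
            trace.append(float(np.log(np.clip(like, 1e-300, None)).sum()))
            q_sum += q
            p_sum += p
            alpha_sum += alpha
            drift_sum += drift

    q_mean = q_sum / cfg.run_length
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    p_mean = p_sum / cfg.run_length
    p_mean /= np.clip(p_mean.sum(axis=2, keepdims=True), 1e-300, None)
    tr = np.array(trace)
    return AdmixtureResult(
        K=K,
        Q=q_mean,
        P=[p_mean[:, j, : len(codes[j])] for j in range(L)],
        loglik_trace=tr,
        lnP=estimate_lnP(tr),
        individuals=list(ds.individual_ids),
        population_of=list(ds.population_of),
        allele_codes=codes,
        alpha=alpha_sum / cfg.run_length,
        drift=drift_sum / cfg.run_length if cfg.correlated_frequencies else None,
    )


def fit_admixture_runs(ds: GenotypeDataset, cfg: AdmixtureConfig) -> list[AdmixtureResult]:
    """Independent restarts (``cfg.runs`` chains with spawned seeds)."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.runs)
    out = []
    for ss in seeds:
        sub = replace(cfg, seed=int(ss.generate_state(1)[0] % (2**31)))
        out.append(fit_admixture(ds, sub))
    return out


def estimate_lnP(trace: Sequence[float] | np.ndarray) -> float:
    """``lnPr(X|K) ~= mean(trace) - var(trace)/2`` from a log-likelihood trace."""
    tr = np.asarray(trace, dtype=float)
    if tr.size < 2:
        raise ValueError("trace must have at least 2 entries")
    return float(tr.mean() - tr.var(ddof=1) / 2.0)


def select_K(results: Mapping[int, Sequence[AdmixtureResult]]) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by the lnPr(X|K) plateau rule.

    Reports median and spread of lnP per K across runs; the chosen K is
    the smallest whose median lies within one median absolute deviation
    (of the best K's runs) of the maximum median — ties therefore break
    toward smaller K.
    """
    if not results:
        raise ValueError("no results supplied")
    rows = []
    for K in sorted(results):
        lnps = np.array([r.lnP for r in results[K]])
        rows.append((K, float(np.median(lnps)), float(lnps.min()), float(lnps.max()),
                     len(lnps)))
    summary = pd.DataFrame(rows, columns=["K", "median_lnP", "min_lnP", "max_lnP", "runs"])
    best_idx = int(summary["median_lnP"].idxmax())
    best_K = int(summary.loc[best_idx, "K"])
    best_median = float(summary.loc[best_idx, "median_lnP"])
    best_lnps = np.array([r.lnP for r in results[best_K]])
    mad = float(np.median(np.abs(best_lnps - np.median(best_lnps))))
    for _, row in summary.iterrows():
        if row["median_lnP"] >= best_median - mad:
            return int(row["K"]), summary
    return best_K, summary


def align_runs(results: Sequence[AdmixtureResult]) -> list[AdmixtureResult]:
    """Align cluster labels across runs to the first run.

    Greedy matching: repeatedly pair the reference and candidate
    membership columns with the highest Pearson correlation until all
    columns are assigned, then permute Q (and P) accordingly.
    """
    if not results:
        return []
    K = results[0].K
    for r in results[1:]:
        if r.K != K:
            raise ValueError("all runs must share the same K")
        if r.individuals != results[0].individuals:
            raise ValueError("all runs must cover the same individuals")
    ref = results[0].Q
    aligned = [results[0]]
    for r in results[1:]:
        corr = np.corrcoef(ref.T, r.Q.T)[:K, K:]  # ref columns x run columns
        corr = np.nan_to_num(corr, nan=-np.inf)
        perm = np.full(K, -1)
        free_ref, free_run = set(range(K)), set(range(K))
        while free_ref:
            best = max(
                ((i, j) for i in free_ref for j in free_run),
                key=lambda ij: corr[ij[0], ij[1]],
            )
            perm[best[0]] = best[1]
            free_ref.discard(best[0])
            free_run.discard(best[1])
        aligned.append(
            replace(
                r,
                Q=r.Q[:, perm],
                P=[pl[perm] for pl in r.P],
                drift=None if r.drift is None else r.drift[perm],
            )
        )
    return aligned
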