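"""Allele-frequency PCA with Z-score normalisation and parallel analysis.

Populations are observations, (locus, allele) frequencies are variables.
Each variable is standardised to mean 0 and standard deviation 1
(population divisor ``n``); principal components come from the singular
value decomposition of the standardised matrix, so component ``k``
explains ``s_k^2 / sum s^2`` of the total variance.

Parallel analysis judges whether leading components carry real
structure: random datasets of the same shape are generated (independent
standard normals by default, or column permutations of the real data),
pushed through the identical normalise-and-decompose path, and an
observed contribution is deemed significant when it exceeds what the
first component of random data attains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import AlleleFrequencyTable
from .distance import DistanceMatrix

__all__ = [
    "PcaResult",
    "ParallelAnalysisResult",
    "normalize_frequencies",
    "pca",
    "parallel_analysis",
    "pc_score_distances",
]


def normalize_frequencies(
    table: AlleleFrequencyTable, populations: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Population x (locus, allele) matrix of Z-scored allele frequencies.

    One column per (locus, allele) pair observed in the population
    subset; a population that lacks an allele contributes frequency 0.
    Columns with zero variance across populations are dropped and
    returned as the second element.  No allele is removed to break the
    within-locus sum-to-one constraint — that constraint only adds one
    zero eigenvalue per locus.
    """
    pops = list(populations) if populations is not None else list(table.populations)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    for pop in pops:
        absent = [l for l in table.loci if not table.has(pop, l)]
        if absent:
            raise ValueError(f"population {pop!r} has no frequency vector at loci {absent}")
    columns: list[str] = []
    data: list[np.ndarray] = []
    for locus in table.loci:
        support = table.allele_support(locus, pops)
        for allele in support:
            columns.append(f"{locus}:{allele}")
            data.append(np.array([table.freqs[p][locus].get(allele, 0.0) for p in pops]))
    raw = np.column_stack(data)
    sd = raw.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all allele-frequency columns have zero variance")
    dropped = [c for c, k in zip(columns, keep) if not k]
    z = (raw[:, keep] - raw[:, keep].mean(axis=0)) / sd[keep]
    frame = pd.DataFrame(z, index=pops, columns=[c for c, k in zip(columns, keep) if k])
    return frame, dropped


@dataclass
class PcaResult:
    """Principal components of a normalised frequency matrix."""

    scores: pd.DataFrame  # observation x component
    loadings: pd.DataFrame  # variable x component
    percent_variance: np.ndarray  # sums to 100 (unless degenerate)
    variable_names: list[str]
    degenerate: bool = False


def pca(matrix: pd.DataFrame | np.ndarray) -> PcaResult:
    """PCA by singular value decomposition of an observations x variables matrix.

    Components are ordered by decreasing explained variance;
    ``percent_variance`` is ``100 * s_k^2 / sum s^2``.  A matrix with no
    variance at all yields a degenerate result with all percentages 0.
    """
    if isinstance(matrix, pd.DataFrame):
        index = list(matrix.index)
        variables = [str(c) for c in matrix.columns]
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = [f"obs{i}" for i in range(x.shape[0])]
        variables = [f"var{j}" for j in range(x.shape[1])]
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        percent = np.zeros_like(s)
        degenerate = True
    else:
        percent = 100.0 * s**2 / total
        degenerate = False
    comp_names = [f"PC{k + 1}" for k in range(s.size)]
    scores = pd.DataFrame(u * s, index=index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=variables, columns=comp_names)
    return PcaResult(scores, loadings, percent, variables, degenerate)


@dataclass
class ParallelAnalysisResult:
    """Leading-component contributions of random same-shape datasets."""

    replicate_contributions: np.ndarray  # reps x n_components, percent
    summary: pd.DataFrame  # component x {mean, sd, max}
    significance: np.ndarray | None  # per observed contribution
    observed: np.ndarray | None


def _component_percents(x: np.ndarray, n_components: int) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    s = np.linalg.svd(z, compute_uv=False)
    pct = 100.0 * s**2 / np.sum(s**2)
    out = np.zeros(n_components)
    out[: min(n_components, pct.size)] = pct[:n_components]
    if pct.size < n_components and pct.size > 0:
        pass  # trailing zeros for rank-deficient draws
    return out


def parallel_analysis(
    n_obs: int,
    n_vars: int,
    reps: int = 10_000,
    seed: int | None = 0,
    observed: Sequence[float] | None = None,
    n_components: int = 2,
    null: str = "normal",
    data: np.ndarray | None = None,
) -> ParallelAnalysisResult:
    """Null distribution of leading PCA contributions in random data.

    Each replicate draws an ``n_obs x n_vars`` matrix — independent
    standard normals (``null="normal"``, default) or an independent
    permutation of each column of the supplied real matrix
    (``null="permute"``) — applies the same column standardisation and
    SVD, and records the percent variance of the leading components.

    The significance of an observed contribution is
    ``(count of replicates whose first component >= observed + 1) /
    (reps + 1)``: every observed value is referred to the random
    first-component distribution, the strictest of the leading ones.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_obs < 2 or n_vars < 1:
        raise ValueError("need n_obs >= 2 and n_vars >= 1")
    if null not in ("normal", "permute"):
        raise ValueError("null must be 'normal' or 'permute'")
    if null == "permute" and data is None:
        raise ValueError("null='permute' requires the real data matrix")
    rng = np.random.default_rng(seed)
    contributions = np.empty((reps, n_components))
    for b in range(reps):
        if null == "normal":
            x = rng.standard_normal((n_obs, n_vars))
        else:
            x = np.column_stack([rng.permutation(col) for col in np.asarray(data).T])
        contributions[b] = _component_percents(x, n_components)
    summary = pd.DataFrame(
        {
            "mean": contributions.mean(axis=0),
            "sd": contributions.std(axis=0, ddof=1) if reps > 1 else np.nan,
            "max": contributions.max(axis=0),
        },
        index=[f"PC{k + 1}" for k in range(n_components)],
    )
    significance = None
    obs_arr = None
    if observed is not None:
        obs_arr = np.asarray(observed, dtype=float)
        first = contributions[:, 0]
        significance = np.array(
            [(np.sum(first >= o) + 1.0) / (reps + 1.0) for o in obs_arr]
        )
    return ParallelAnalysisResult(contributions, summary, significance, obs_arr)


def pc_score_distances(result: PcaResult, k: int = 2) -> DistanceMatrix:
    """Euclidean distances between population scores on the first *k* components."""
    if k > result.scores.shape[1]:
        raise ValueError(f"only {result.scores.shape[1]} components available")
    pts = result.scores.to_numpy()[:, :k]
    diff = pts[:, None, :] - pts[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(result.scores.index), values, kind="pc_score")
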