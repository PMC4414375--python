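"""Unsupervised structure discovery: Spearman-distance hierarchical
clustering and Brunet-style consensus NMF with cophenetic rank selection.

Hierarchical clustering is the textbook greedy agglomeration (global-minimum
merge each step) so that tie-breaking is fully specified: on equal distances
the pair with the smallest indices merges first.  NMF minimizes the
generalized Kullback-Leibler divergence with the classic multiplicative
updates; consensus clustering aggregates sample co-assignment over random
restarts, and the cophenetic correlation of the consensus matrix drives the
factorization-rank survey.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import DendrogramResult, NmfConsensusResult

__all__ = [
    "spearman_distance",
    "hierarchical_cluster",
    "nmf_brunet",
    "consensus_matrix",
    "cophenetic_coefficient",
    "rank_survey",
    "select_rank",
]

_EPS = 1e-12


def spearman_distance(matrix: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """Pairwise d(i, j) = 1 - Spearman rho between profiles.

    axis "samples": profiles are columns (distance between samples across
    genes); axis "genes": profiles are rows.  Ties get average ranks.  A
    constant profile has undefined rank correlation and raises.
    """
    if axis == "samples":
        profiles = matrix.to_numpy().T
        labels = list(matrix.columns)
    elif axis == "genes":
        profiles = matrix.to_numpy()
        labels = list(matrix.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 observations per profile")
    const = np.ptp(profiles, axis=1) == 0
    if const.any():
        bad = [labels[i] for i in np.where(const)[0]]
        raise ValueError(f"constant profile(s), rank correlation undefined: {bad}")
    ranks = np.apply_along_axis(stats.rankdata, 1, profiles)
    corr = np.corrcoef(ranks)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def hierarchical_cluster(dist: pd.DataFrame,
                         linkage: str = "complete",
                         axis: str = "samples",
                         metric: str = "spearman") -> DendrogramResult:
    """Agglomerative clustering by greedy global-minimum merging.

    Supported linkages: complete (max), single (min), average (size-weighted
    mean).  Ties are broken deterministically by the smallest pair of active
    leaf/cluster indices.  Input must be a symmetric matrix with a zero
    diagonal.
    """
    D = dist.to_numpy(dtype=float).copy()
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if linkage not in ("complete", "single", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")

    labels = list(dist.index)
    node_id = list(range(n))          # current node id per active row
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    work[~active] = np.inf
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        flat = int(np.argmin(masked))      # first occurrence = smallest (i, j)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = masked[i, j]
        merges.append((node_id[i], node_id[j], float(h)))
        if linkage == "complete":
            new_row = np.maximum(work[i], work[j])
        elif linkage == "single":
            new_row = np.minimum(work[i], work[j])
        else:
            new_row = (sizes[i] * work[i] + sizes[j] * work[j]) / (sizes[i] + sizes[j])
        work[i] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        node_id[i] = n + step

    return DendrogramResult(merges=merges, labels=labels, axis=axis,
                            metric=metric, linkage=linkage)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # generalized KL with the 0*log0 = 0 convention; WH floored at _EPS
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(term.sum() - V.sum() + WH.sum())


def nmf_brunet(V: np.ndarray | pd.DataFrame, rank: int,
               max_iter: int = 2000, tol: float = 1e-6,
               seed: int | None = None,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NMF by multiplicative KL-divergence updates with random init.

    Minimizes D(V || WH) = sum V log(V / WH) - V + WH.  Stops at
    ``max_iter`` or when the relative divergence change drops below ``tol``.
    Returns (W, H, divergence trace); the trace is non-increasing.
    """
    V = np.asarray(V, dtype=float) if not isinstance(V, pd.DataFrame) else V.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("V must be elementwise non-negative")
    if (V.sum(axis=1) == 0).any() or (V.sum(axis=0) == 0).any():
        raise ValueError("V must have no all-zero row or column")
    m, n = V.shape
    if not 1 <= rank < min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n) - 1}]")

    rng = np.random.default_rng(seed)
    vmax = V.max()
    W = rng.uniform(_EPS, vmax, size=(m, rank))
    H = rng.uniform(_EPS, vmax, size=(rank, n))

    trace = [_kl_divergence(V, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        d = _kl_divergence(V, W @ H)
        prev = trace[-1]
        trace.append(d)
        if abs(prev - d) <= tol * max(abs(prev), _EPS):
            break
    return W, H, np.asarray(trace)


def consensus_matrix(V: pd.DataFrame, rank: int, n_runs: int = 200,
                     seed: int | None = None, max_iter: int = 2000,
                     tol: float = 1e-6) -> NmfConsensusResult:
    """Consensus of sample cluster assignments over random NMF restarts.

    Per run each sample joins the arg-max row of H (lowest factor index on
    ties); C(i, j) is the fraction of runs clustering i with j.
    """
    samples = list(V.columns)
    n = len(samples)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    C = np.zeros((n, n))
    assignments = np.empty((n_runs, n), dtype=int)
    for r, s in enumerate(run_seeds):
        _, H, _ = nmf_brunet(V, rank, max_iter=max_iter, tol=tol, seed=int(s))
        labels = H.argmax(axis=0)
        assignments[r] = labels
        C += (labels[:, None] == labels[None, :])
    C /= n_runs
    np.fill_diagonal(C, 1.0)
    Cdf = pd.DataFrame(C, index=samples, columns=samples)
    rho = cophenetic_coefficient(Cdf)
    return NmfConsensusResult(rank=rank, consensus=Cdf, cophenetic_rho=rho,
                              n_runs=n_runs, seed=seed, assignments=assignments)


def cophenetic_coefficient(C: pd.DataFrame | np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    Pearson correlation between the consensus distances (1 - C) and the
    cophenetic distances of the average-linkage dendrogram built on them.
    A perfectly crisp block-structured consensus gives 1.
    """
    arr = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, float)
    d = 1.0 - arr
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.ptp(condensed) == 0:
        raise ValueError("constant consensus distances; "
                         "cophenetic correlation undefined")
    Z = hierarchy.linkage(condensed, method="average")
    coph = hierarchy.cophenet(Z)
    if np.ptp(coph) == 0:
        # every merge at one height: agreement is exact iff the observed
        # distances were constant too, which was already excluded above
        return 1.0 if np.allclose(condensed, coph) else float("nan")
    return float(np.corrcoef(condensed, coph)[0, 1])


def _permute_rows(V: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    arr = V.to_numpy().copy()
    for i in range(arr.shape[0]):
        rng.shuffle(arr[i])
    return pd.DataFrame(arr, index=V.index, columns=V.columns)


def rank_survey(V: pd.DataFrame, ranks: list[int], n_runs: int = 50,
                n_runs_randomized: int = 25, seed: int | None = None,
                max_iter: int = 2000, tol: float = 1e-6) -> pd.DataFrame:
    """Cophenetic-correlation curve over candidate factorization ranks.

    For each rank the consensus procedure runs ``n_runs`` times on the data
    and ``n_runs_randomized`` times on a randomized baseline in which every
    gene row is independently permuted (destroying sample structure while
    keeping per-gene marginals).  Returns a table of
    (rank, cophenetic_rho, cophenetic_rho_randomized).
    """
    rng = np.random.default_rng(seed)
    V_rand = _permute_rows(V, rng)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * len(ranks))
    rows = []
    for k, rank in enumerate(ranks):
        real = consensus_matrix(V, rank, n_runs=n_runs,
                                seed=int(sub_seeds[2 * k]),
                                max_iter=max_iter, tol=tol)
        rand = consensus_matrix(V_rand, rank, n_runs=n_runs_randomized,
                                seed=int(sub_seeds[2 * k + 1]),
                                max_iter=max_iter, tol=tol)
        rows.append({"rank": rank,
                     "cophenetic_rho": real.cophenetic_rho,
                     "cophenetic_rho_randomized": rand.cophenetic_rho})
    return pd.DataFrame(rows)


def select_rank(survey: pd.DataFrame, tol: float = 1e-9) -> int:
    """Pick the factorization rank from a survey table.

    The rank chosen is the last one before the cophenetic correlation
    begins to fall: the first rank k (in survey order) whose coefficient
    exceeds the next rank's by more than ``tol``.  If the curve never
    drops, the rank with the maximal coefficient is returned.  The
    tolerance only absorbs floating-point noise, so that exactly
    saturated coefficients (several ranks with perfectly reproducible
    consensus) form a flat plateau while any genuine loss of stability,
    however small, counts as the start of the fall.
    """
    rho = survey["cophenetic_rho"].to_numpy()
    ranks = survey["rank"].to_numpy()
    for i in range(len(rho) - 1):
        if rho[i] > rho[i + 1] + tol:
            return int(ranks[i])
    return int(ranks[np.argmax(rho)])
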