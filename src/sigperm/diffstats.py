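"""Per-gene and per-assay inferential statistics.

Mann-Whitney U with Benjamini-Hochberg correction for two-group differential
expression, a limma-style moderated 2x2 factorial synergy test, the
Jonckheere-Terpstra trend test for ordered disease stages, and Spearman rank
correlation for paired assays.  Rank tests switch between exact enumeration
(small samples; ties handled with half credit) and the tie-corrected normal
approximation.  Two-sided exact p-values are the doubled smaller tail,
capped at 1.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleDesign

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "de_genes",
    "factorial_interaction_test",
    "jonckheere_terpstra",
    "spearman_correlation",
]

_TIE_EPS = 1e-9


def _credit_matrix(pooled: np.ndarray) -> np.ndarray:
    """credit[i, j] = 1 if x_i > x_j, 0.5 on ties, else 0."""
    diff = pooled[:, None] - pooled[None, :]
    return (diff > 0) + 0.5 * (diff == 0)


def _subset_matrix(n_total: int, k: int) -> np.ndarray:
    """All C(n, k) subsets as a boolean membership matrix."""
    combos = list(itertools.combinations(range(n_total), k))
    M = np.zeros((len(combos), n_total), dtype=float)
    rows = np.repeat(np.arange(len(combos)), k)
    M[rows, np.fromiter(itertools.chain.from_iterable(combos), int)] = 1.0
    return M


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 exact_threshold: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U counts pairs where a > b (+0.5 ties).

    Exact mode (both groups <= ``exact_threshold``): the null distribution is
    built by enumerating every split of the pooled values, which handles ties
    without approximation.  Otherwise: normal approximation with tie
    correction (and continuity correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    credit = _credit_matrix(np.concatenate([a, b]))
    u_obs = credit[:a.size, a.size:].sum()

    if a.size <= exact_threshold and b.size <= exact_threshold:
        M = _subset_matrix(a.size + b.size, a.size)
        u_all = ((M @ credit) * (1.0 - M)).sum(axis=1)
        lower = np.mean(u_all <= u_obs + _TIE_EPS)
        upper = np.mean(u_all >= u_obs - _TIE_EPS)
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue)
    return float(u_obs), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_genes(expr: ExpressionMatrix, design: SampleDesign,
             group_a: str, group_b: str, fdr: float = 0.05,
             exact_threshold: int = 8) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Mann-Whitney + BH differential expression between two groups.

    Returns the full result table (statistic, raw p, BH q, median difference
    of ``group_b`` minus ``group_a`` on the matrix scale) and the list of
    genes selected at ``q < fdr``.
    """
    import warnings
    ids_a = design.samples_in(group_a)
    ids_b = design.samples_in(group_b)
    if min(len(ids_a), len(ids_b)) < 3:
        warnings.warn("fewer than 3 samples in a group; the rank test has "
                      "very little power", stacklevel=2)
    A = expr.values[ids_a].to_numpy()
    B = expr.values[ids_b].to_numpy()

    if len(ids_a) <= exact_threshold and len(ids_b) <= exact_threshold:
        stat = np.empty(A.shape[0])
        pvals = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            stat[i], pvals[i] = mann_whitney(A[i], B[i], exact_threshold)
    else:
        res = stats.mannwhitneyu(A, B, alternative="two-sided",
                                 method="asymptotic", axis=1)
        stat, pvals = res.statistic, res.pvalue
    qvals = bh_adjust(pvals)
    effect = np.median(B, axis=1) - np.median(A, axis=1)
    table = pd.DataFrame({"U": stat, "p": pvals, "q": qvals,
                          "median_diff": effect}, index=expr.gene_ids)
    selected = table.index[table["q"] < fdr].tolist()
    return table, selected


def _trigamma_inverse(y: float) -> float:
    # Newton solve of trigamma(x) = y; large y -> small x.
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * abs(x):
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance shrinkage toward a consensus.

    Models s^2 ~ s0^2 * F(df, d0) (a scaled inverse-chi-squared prior on the
    true variances) and estimates (d0, s0^2) by matching the mean and
    variance of log s^2 via digamma/trigamma identities.  Returns the
    posterior variances (d0*s0^2 + df*s^2) / (d0 + df), d0 and s0^2.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0 or not np.isfinite(evar):
        d0 = np.inf
        log_s02 = z.mean() - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
        s02 = float(np.exp(log_s02))
        return np.full_like(s2, s02), d0, s02
    d0 = 2.0 * _trigamma_inverse(float(evar))
    log_s02 = (z.mean() - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
               + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    s02 = float(np.exp(log_s02))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0), s02


def factorial_interaction_test(expr: ExpressionMatrix, design: SampleDesign,
                               moderated: bool = True) -> pd.DataFrame:
    """Per-gene 2x2 factorial linear model y ~ A + B + A:B.

    ``design.factors`` must provide two binary treatment columns.  Reports
    coefficient, t statistic and (unadjusted) two-sided p per term.  When
    ``moderated``, residual variances are shrunk toward their consensus via
    an inverse-gamma empirical-Bayes update with estimated prior df, and the
    t reference distribution gains those prior degrees of freedom.
    """
    if design.factors is None or design.factors.shape[1] != 2:
        raise ValueError("design must carry exactly two treatment factors")
    fa, fb = design.factors.columns
    f = design.factors.reindex(expr.sample_ids)
    if f.isna().any().any():
        raise ValueError("factors missing for some samples")
    a = f[fa].to_numpy(dtype=float)
    b = f[fb].to_numpy(dtype=float)
    cells, counts = np.unique(np.c_[a, b], axis=0, return_counts=True)
    if len(cells) < 4:
        raise ValueError("all four factor cells must be populated")
    n = a.size
    df = n - 4
    if df < 1:
        raise ValueError("need residual degrees of freedom (>= 2 per cell)")
    if not moderated and counts.min() < 2:
        raise ValueError("unmoderated test needs >= 2 replicates per cell")

    X = np.column_stack([np.ones(n), a, b, a * b])
    xtx_inv = np.linalg.inv(X.T @ X)
    Y = expr.values.to_numpy()
    beta = Y @ X @ xtx_inv                      # genes x 4
    resid = Y - beta @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    c = np.diag(xtx_inv)

    if moderated:
        s2_post, d0, s02 = _squeeze_var(s2, df)
        df_t = df + d0
    else:
        s2_post, d0, s02 = s2, 0.0, float("nan")
        df_t = df
    se = np.sqrt(np.outer(s2_post, c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if np.isfinite(df_t):
        p = 2.0 * stats.t.sf(np.abs(t), df_t)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))

    out = {}
    for j, term in enumerate(["intercept", fa, fb, f"{fa}:{fb}"]):
        out[f"coef_{term}"] = beta[:, j]
        out[f"t_{term}"] = t[:, j]
        out[f"p_{term}"] = p[:, j]
    table = pd.DataFrame(out, index=expr.gene_ids)
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s02
    table.attrs["residual_df"] = df
    table.attrs["moderated"] = moderated
    return table


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for g in range(len(groups)):
        for h in range(g + 1, len(groups)):
            diff = groups[h][None, :] - groups[g][:, None]
            jt += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(jt)


def _assignments(n_total: int, sizes: list[int]):
    """Yield every partition of range(n_total) into ordered groups of the
    given sizes, as tuples of index tuples."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in rec(rest, sizes_left[1:]):
                yield (combo, *tail)
    yield from rec(tuple(range(n_total)), sizes)


def jonckheere_terpstra(groups: Sequence[Sequence[float]],
                        two_sided: bool = True,
                        exact_threshold_total: int = 12
                        ) -> tuple[float, float]:
    """Jonckheere-Terpstra trend test across ordered groups.

    ``groups`` must be given in the hypothesized increasing order (e.g.
    normal -> chronic phase -> blast crisis).  JT is the sum of pairwise
    Mann-Whitney counts over ordered group pairs.  Exact permutation
    enumeration when the total sample size is <= ``exact_threshold_total``;
    otherwise the normal approximation with tie-corrected variance.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("need >= 3 ordered groups; use mann_whitney for 2")
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group")
    jt_obs = _jt_statistic(gs)
    pooled = np.concatenate(gs)
    sizes = [g.size for g in gs]
    n_total = pooled.size

    if n_total <= exact_threshold_total:
        credit = 1.0 - _credit_matrix(pooled)   # credit'[i,j]: x_i < x_j (+0.5 tie)
        np.fill_diagonal(credit, 0.0)
        jt_all = []
        for assign in _assignments(n_total, sizes):
            val = 0.0
            for g in range(len(sizes)):
                for h in range(g + 1, len(sizes)):
                    val += credit[np.ix_(assign[g], assign[h])].sum()
            jt_all.append(val)
        jt_all = np.asarray(jt_all)
        upper = np.mean(jt_all >= jt_obs - _TIE_EPS)
        lower = np.mean(jt_all <= jt_obs + _TIE_EPS)
        p = min(1.0, 2.0 * min(lower, upper)) if two_sided else upper
        return jt_obs, float(p)

    # tie-corrected normal approximation (Hollander & Wolfe)
    N = float(n_total)
    ni = np.asarray(sizes, dtype=float)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tj = tie_counts.astype(float)
    mean = (N ** 2 - np.sum(ni ** 2)) / 4.0
    A = (N * (N - 1) * (2 * N + 5)
         - np.sum(ni * (ni - 1) * (2 * ni + 5))
         - np.sum(tj * (tj - 1) * (2 * tj + 5)))
    B = np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(tj * (tj - 1) * (tj - 2))
    C = np.sum(ni * (ni - 1)) * np.sum(tj * (tj - 1))
    var = (A / 72.0 + B / (36.0 * N * (N - 1) * (N - 2))
           + C / (8.0 * N * (N - 1)))
    if var <= 0:
        return jt_obs, 1.0
    z = (jt_obs - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z)) if two_sided else float(stats.norm.sf(z))
    return jt_obs, float(min(1.0, p))


@lru_cache(maxsize=8)
def _spearman_null_rhos(n: int) -> np.ndarray:
    """Exact null distribution of Spearman rho for untied samples of size n."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    ident = np.arange(n)
    d2 = ((perms - ident) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))


def spearman_correlation(x: Sequence[float], y: Sequence[float],
                         exact_threshold: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with exact small-sample p-value.

    Ties get average ranks.  For n <= ``exact_threshold`` with no ties in
    either vector the two-sided p is exact: the proportion of the n!
    permutations with |rho| at least the observed.  Otherwise the usual
    t approximation with n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    no_ties = (np.unique(x).size == n) and (np.unique(y).size == n)
    if n <= exact_threshold and no_ties:
        null = _spearman_null_rhos(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - _TIE_EPS))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(1.0, p)
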