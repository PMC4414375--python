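"""SAM-ranked gene-set enrichment with gene-label permutation.

Genes are ranked by the SAM moderated difference statistic
d_g = (mean_1 - mean_2) / (s_g + s0), where s_g is the pooled two-sample
standard error of the difference and s0 a variance-stabilizing constant.
The enrichment score of a pathway is the signed maximal excursion of the
classic Kolmogorov-Smirnov-style running sum over the ranked list
(unweighted by default: +1/k at set genes, -1/(N-k) elsewhere).  The null
is built by permuting gene labels, i.e. shuffling the gene-to-score
assignment and recomputing every pathway's score from the same permuted
ranking, which preserves the correlation between overlapping pathways.
Per-pathway nominal p, an FDR q over the analyzed pathways, and a maxT
family-wise p over a declared pathway family are all computed on the
normalized score scale (ES divided by the mean |null ES| of matching sign).
The core enrichment (leading edge) subset is the set members at or beyond
the running-sum extremum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection, GseaResult, SampleDesign

__all__ = [
    "SamConfig",
    "sam_statistic",
    "rank_genes",
    "gsea_es",
    "permutation_null",
    "family_wise_p",
    "core_enrichment_subset",
    "run_gsea",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SamConfig:
    """SAM fudge-constant configuration.

    ``s0`` is either a fixed non-negative constant or "auto", which resolves
    to the given percentile (default: the median) of the per-gene standard
    errors.  The resolved value is recorded on the returned scores.
    """

    s0: float | str = "auto"
    auto_percentile: float = 50.0

    def resolve(self, se: np.ndarray) -> float:
        if isinstance(self.s0, str):
            if self.s0 != "auto":
                raise ValueError(f"unknown s0 mode {self.s0!r}")
            return float(np.percentile(se, self.auto_percentile))
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        return float(self.s0)


def sam_statistic(expr: ExpressionMatrix, design: SampleDesign,
                  group_a: str, group_b: str,
                  config: SamConfig | None = None) -> pd.Series:
    """Per-gene SAM d scores for ``group_a`` minus ``group_b``."""
    config = config or SamConfig()
    A = expr.values[design.samples_in(group_a)].to_numpy()
    B = expr.values[design.samples_in(group_b)].to_numpy()
    n1, n2 = A.shape[1], B.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    diff = A.mean(axis=1) - B.mean(axis=1)
    pooled = (((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              + ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              ) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    s0 = config.resolve(se)
    d = diff / (se + s0)
    out = pd.Series(d, index=expr.gene_ids, name="sam_d")
    out.attrs["s0"] = s0
    return out


def rank_genes(d: pd.Series) -> list[str]:
    """Gene ids sorted by descending score; ties broken by gene id."""
    if d.isna().any():
        raise ValueError("NaN scores cannot be ranked")
    order = np.lexsort((np.asarray(d.index, dtype=object), -d.to_numpy()))
    return [d.index[i] for i in order]


def gsea_es(ranked: list[str], gene_set: list[str] | set[str],
            scores: np.ndarray | None = None,
            weight_exponent: float = 0.0
            ) -> tuple[float, np.ndarray, int]:
    """Enrichment score of ``gene_set`` against a ranked gene list.

    Returns (ES, running sum over the list, extremum index).  Unweighted
    mode (exponent 0) increments 1/k on hits and decrements 1/(N-k) on
    misses; weighted mode increments |score|^exponent normalized over the
    set hits (``scores`` must then be given in ranked order).  ES is the
    running-sum value of largest magnitude (first occurrence on ties).
    """
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked), bool, len(ranked))
    k = int(hits.sum())
    N = len(ranked)
    if k == 0:
        raise ValueError("gene set has no genes in the ranked list")
    dec = 1.0 / (N - k) if N > k else 0.0
    miss_term = np.cumsum(~hits) * dec
    if weight_exponent == 0.0:
        # ratio of cumulative counts keeps boundary values (1, 0) exact
        running = np.cumsum(hits) / k - miss_term
    else:
        if scores is None:
            raise ValueError("weighted mode requires ranked scores")
        w = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent
        total = w[hits].sum()
        if total <= 0:
            raise ValueError("all hit weights are zero")
        running = np.cumsum(np.where(hits, w, 0.0)) / total - miss_term
    # first index attaining the maximal magnitude (1e-12 tie tolerance so
    # algebraically equal peaks resolve identically regardless of summation
    # order)
    absr = np.abs(running)
    ext = int(np.flatnonzero(absr >= absr.max() - 1e-12)[0])
    return float(running[ext]), running, ext


def _es_from_positions(pos: np.ndarray, N: int) -> float:
    """Unweighted ES from the sorted 0-based hit positions (O(k))."""
    k = pos.size
    dec = 1.0 / (N - k) if N > k else 0.0
    i = np.arange(k)
    after = (i + 1) / k - (pos - i) * dec       # running value at each hit
    before = i / k - (pos - i) * dec            # value just before each hit
    imax = int(np.argmax(after))
    imin = int(np.argmin(before))
    max_val, min_val = after[imax], before[imin]
    if min_val >= 0:
        return float(max_val)
    if max_val >= abs(min_val):
        if max_val == abs(min_val) and pos[imin] - 1 < pos[imax]:
            return float(min_val)       # earlier first occurrence wins
        return float(max_val)
    return float(min_val)


def permutation_null(expr: ExpressionMatrix, design: SampleDesign,
                     group_a: str, group_b: str,
                     pathways: GeneSetCollection, n_perm: int = 2000,
                     seed: int | None = None, mode: str = "gene_label",
                     sam_config: SamConfig | None = None,
                     weight_exponent: float = 0.0) -> pd.DataFrame:
    """Null enrichment-score matrix (pathways x permutations).

    mode "gene_label" (default, matching the procedure implemented here):
    each permutation shuffles the gene-to-score assignment once and every
    pathway's ES is recomputed from that shared permuted ranking.  mode
    "phenotype": sample group labels are permuted and the SAM scores
    recomputed per permutation (provided for comparison).
    """
    import warnings
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are unstable",
                      stacklevel=2)
    d = sam_statistic(expr, design, group_a, group_b, sam_config)
    ranked = rank_genes(d)
    restricted = pathways.restrict_to(ranked)
    names = restricted.names()
    N = len(ranked)
    pos_of = {g: i for i, g in enumerate(ranked)}
    set_positions = {n: np.array(sorted(pos_of[g] for g in restricted[n]),
                                 dtype=int) for n in names}
    for n in names:
        if set_positions[n].size == 0:
            raise ValueError(f"pathway {n!r} has no expressed genes")
    rng = np.random.default_rng(seed)
    null = np.empty((len(names), n_perm))

    if mode == "gene_label":
        ranked_scores = d.loc[ranked].to_numpy()
        for b in range(n_perm):
            pi = rng.permutation(N)
            for j, name in enumerate(names):
                new_pos = np.sort(pi[set_positions[name]])
                if weight_exponent == 0.0:
                    null[j, b] = _es_from_positions(new_pos, N)
                else:
                    hits = np.zeros(N, bool)
                    hits[new_pos] = True
                    w = np.abs(ranked_scores) ** weight_exponent
                    total = max(w[hits].sum(), _EPS)
                    dec = 1.0 / (N - new_pos.size) if N > new_pos.size else 0.0
                    running = (np.cumsum(np.where(hits, w, 0.0)) / total
                               - np.cumsum(~hits) * dec)
                    null[j, b] = running[np.argmax(np.abs(running))]
    elif mode == "phenotype":
        labels = design.groups.copy()
        for b in range(n_perm):
            perm_design = SampleDesign(
                pd.Series(rng.permutation(labels.to_numpy()),
                          index=labels.index, name="group"))
            d_b = sam_statistic(expr, perm_design, group_a, group_b, sam_config)
            ranked_b = rank_genes(d_b)
            scores_b = d_b.loc[ranked_b].to_numpy()
            for j, name in enumerate(names):
                es, _, _ = gsea_es(ranked_b, restricted[name], scores_b,
                                   weight_exponent)
                null[j, b] = es
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(null, index=names)


def _sign_matched_norms(null_row: np.ndarray) -> tuple[float, float]:
    """(mean positive null ES, mean |negative null ES|) with fallbacks."""
    pos = null_row[null_row > 0]
    neg = null_row[null_row < 0]
    fallback = max(float(np.abs(null_row).mean()), _EPS)
    pos_mean = float(pos.mean()) if pos.size else fallback
    neg_mean = float(np.abs(neg).mean()) if neg.size else fallback
    return max(pos_mean, _EPS), max(neg_mean, _EPS)


def _normalize(es, pos_mean: float, neg_mean: float):
    es = np.asarray(es, dtype=float)
    return np.where(es >= 0, es / pos_mean, es / neg_mean)


def normalized_scores(observed_es: pd.Series,
                      null_es: pd.DataFrame
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """Normalize observed and null ES per pathway (sign-matched means)."""
    nes_obs = {}
    nes_null = {}
    for name in observed_es.index:
        row = null_es.loc[name].to_numpy()
        pos_mean, neg_mean = _sign_matched_norms(row)
        nes_obs[name] = float(_normalize(observed_es[name], pos_mean, neg_mean))
        nes_null[name] = _normalize(row, pos_mean, neg_mean)
    return (pd.Series(nes_obs, name="nes"),
            pd.DataFrame(nes_null).T.loc[observed_es.index])


def nominal_pvalues(observed_es: pd.Series,
                    null_es: pd.DataFrame) -> pd.Series:
    """Two-sided nominal p per pathway: fraction of |null NES| >= |NES|."""
    nes_obs, nes_null = normalized_scores(observed_es, null_es)
    p = {name: float(np.mean(np.abs(nes_null.loc[name].to_numpy())
                             >= abs(nes_obs[name]) - _EPS))
         for name in observed_es.index}
    return pd.Series(p, name="nominal_p")


def fdr_qvalues(observed_es: pd.Series, null_es: pd.DataFrame) -> pd.Series:
    """FDR q by pooling normalized null scores across the analyzed pathways."""
    nes_obs, nes_null = normalized_scores(observed_es, null_es)
    pooled = np.abs(nes_null.to_numpy().ravel())
    obs_abs = np.abs(nes_obs.to_numpy())
    q = np.empty(obs_abs.size)
    for i, v in enumerate(obs_abs):
        null_frac = np.mean(pooled >= v - _EPS)
        obs_frac = np.mean(obs_abs >= v - _EPS)
        q[i] = min(1.0, null_frac / max(obs_frac, _EPS))
    # monotone: a stronger pathway never gets a larger q than a weaker one
    order = np.argsort(-obs_abs, kind="stable")
    q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return pd.Series(q, index=observed_es.index, name="fdr_q")


def family_wise_p(observed_es: pd.Series, null_es: pd.DataFrame,
                  family: list[str]) -> pd.Series:
    """maxT family-wise p over the declared pathway family.

    Per permutation the family maximum of |normalized ES| is recorded; the
    FWER p of a family pathway is the fraction of permutations whose family
    maximum reaches its observed |normalized ES|.  By construction
    FWER p >= nominal p for every pathway.
    """
    if not family:
        raise ValueError("empty pathway family")
    missing = set(family) - set(observed_es.index)
    if missing:
        raise KeyError(f"family pathways not analyzed: {sorted(missing)}")
    nes_obs, nes_null = normalized_scores(observed_es, null_es)
    fam_max = np.abs(nes_null.loc[family].to_numpy()).max(axis=0)
    p = {name: float(np.mean(fam_max >= abs(nes_obs[name]) - _EPS))
         for name in family}
    return pd.Series(p, name="fwer_p")


def core_enrichment_subset(ranked: list[str], gene_set: list[str] | set[str],
                           es: float, ext_idx: int) -> list[str]:
    """Leading-edge genes: set members at or beyond the running-sum extremum.

    Positive ES: set genes at list positions <= the extremum (top of the
    list); negative ES: set genes at positions past the extremum toward the
    bottom ("right-most").  Genes are returned in ranked order.
    """
    members = set(gene_set)
    if es >= 0:
        return [g for g in ranked[:ext_idx + 1] if g in members]
    return [g for g in ranked[ext_idx + 1:] if g in members]


def run_gsea(expr: ExpressionMatrix, design: SampleDesign,
             group_a: str, group_b: str, pathways: GeneSetCollection,
             family: list[str] | None = None, n_perm: int = 2000,
             seed: int | None = None, sam_config: SamConfig | None = None,
             weight_exponent: float = 0.0,
             mode: str = "gene_label") -> GseaResult:
    """Full enrichment analysis producing the summary table.

    Columns follow the reporting convention: pathway name, number of genes
    in the pathway, number expressed (present after filters), ES, NES,
    direction, nominal p, FDR q, family-wise p (for family members; NaN
    otherwise), and the core-enrichment gene list.
    """
    sam_config = sam_config or SamConfig()
    d = sam_statistic(expr, design, group_a, group_b, sam_config)
    ranked = rank_genes(d)
    ranked_scores = d.loc[ranked].to_numpy()
    restricted = pathways.restrict_to(ranked)
    names = restricted.names()
    if family is None:
        family = restricted.family_names or names

    observed = {}
    running_sums = {}
    cores = {}
    for name in names:
        es, running, ext = gsea_es(ranked, restricted[name], ranked_scores,
                                   weight_exponent)
        observed[name] = es
        running_sums[name] = running
        cores[name] = core_enrichment_subset(ranked, restricted[name], es, ext)
    observed = pd.Series(observed, name="es")

    null = permutation_null(expr, design, group_a, group_b, pathways,
                            n_perm=n_perm, seed=seed, mode=mode,
                            sam_config=sam_config,
                            weight_exponent=weight_exponent)
    nes_obs, _ = normalized_scores(observed, null)
    nominal = nominal_pvalues(observed, null)
    qvals = fdr_qvalues(observed, null)
    fwer = family_wise_p(observed, null, family)

    table = pd.DataFrame({
        "name": names,
        "n_genes_in_pathway": [len(pathways[n]) for n in names],
        "n_expressed": [len(restricted[n]) for n in names],
        "es": observed.to_numpy(),
        "nes": nes_obs.loc[names].to_numpy(),
        "direction": ["up" if observed[n] >= 0 else "down" for n in names],
        "nominal_p": nominal.loc[names].to_numpy(),
        "fdr_q": qvals.loc[names].to_numpy(),
        "fwer_p": [fwer.get(n, np.nan) for n in names],
        "core_genes": [cores[n] for n in names],
    })
    return GseaResult(table=table, running_sums=running_sums,
                      ranked_genes=ranked, null_es=null,
                      n_permutations=n_perm, seed=seed,
                      params={"s0": float(d.attrs["s0"]),
                              "weight_exponent": weight_exponent,
                              "mode": mode,
                              "group_a": group_a, "group_b": group_b,
                              "family": list(family)})
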