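"""Rank tests, BH correction and the factorial synergy test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigperm import (
    SampleDesign,
    bh_adjust,
    de_genes,
    factorial_interaction_test,
    jonckheere_terpstra,
    mann_whitney,
    simulate_factorial_treatment,
    spearman_correlation,
)
from conftest import make_expression


# --- enumeration oracles (plain Python, used only by tests) --------------

def mw_oracle(a, b):
    pooled = list(a) + list(b)
    n1 = len(a)
    idx = range(len(pooled))

    def ustat(subset):
        rest = [i for i in idx if i not in subset]
        u = 0.0
        for i in subset:
            for j in rest:
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    obs = ustat(tuple(range(n1)))
    all_u = [ustat(c) for c in itertools.combinations(idx, n1)]
    lo = sum(u <= obs + 1e-9 for u in all_u) / len(all_u)
    hi = sum(u >= obs - 1e-9 for u in all_u) / len(all_u)
    return obs, min(1.0, 2.0 * min(lo, hi))


def jt_oracle(groups):
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]

    def jt_of(partition):
        total = 0.0
        for gi in range(len(partition)):
            for hi in range(gi + 1, len(partition)):
                for x in partition[gi]:
                    for y in partition[hi]:
                        if x < y:
                            total += 1.0
                        elif x == y:
                            total += 0.5
        return total

    obs = jt_of(groups)
    all_jt = []

    def rec(remaining, sizes_left, acc):
        if not sizes_left:
            all_jt.append(jt_of(acc))
            return
        for combo in itertools.combinations(range(len(remaining)), sizes_left[0]):
            chosen = [remaining[i] for i in combo]
            rest = [remaining[i] for i in range(len(remaining)) if i not in combo]
            rec(rest, sizes_left[1:], acc + [chosen])

    rec(pooled, sizes, [])
    hi = sum(j >= obs - 1e-9 for j in all_jt) / len(all_jt)
    lo = sum(j <= obs + 1e-9 for j in all_jt) / len(all_jt)
    return obs, hi, min(1.0, 2.0 * min(lo, hi))


def spearman_oracle(x, y):
    from scipy import stats as ss
    rho = ss.spearmanr(x, y).statistic
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        r = ss.spearmanr(x, perm).statistic
        count += abs(r) >= abs(rho) - 1e-9
        total += 1
    return rho, count / total


# --- Mann-Whitney --------------------------------------------------------

def test_mw_textbook_cases():
    u, p = mann_whitney([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)
    _, p_same = mann_whitney([1, 2, 3], [1, 2, 3])
    assert p_same == 1.0
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mw_matches_enumeration_oracle(rng):
    for _ in range(25):
        n1, n2 = rng.integers(2, 7, size=2)
        a = rng.integers(0, 8, size=n1).astype(float)   # ties likely
        b = rng.integers(0, 8, size=n2).astype(float)
        u, p = mann_whitney(a, b)
        uo, po = mw_oracle(a, b)
        assert u == pytest.approx(uo)
        assert p == pytest.approx(po, abs=1e-12)


def test_mw_asymptotic_for_large_groups(rng):
    a = rng.normal(size=30)
    b = rng.normal(1.0, size=30)
    _, p = mann_whitney(a, b)
    from scipy import stats as ss
    ref = ss.mannwhitneyu(a, b, alternative="two-sided",
                          method="asymptotic").pvalue
    assert p == pytest.approx(float(ref))


# --- BH ------------------------------------------------------------------

def test_bh_hand_computation():
    q = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        bh_adjust([0.1, np.nan])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_is_monotone_and_dominates(pvals):
    q = bh_adjust(pvals)
    assert (q >= np.asarray(pvals) - 1e-12).all()
    order = np.argsort(pvals)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_controls_fdr_under_null(rng):
    """Average fraction of false discoveries at q < 0.05 stays below 0.05
    when all hypotheses are null."""
    false_rates = []
    for _ in range(200):
        p = rng.uniform(size=100)
        rej = bh_adjust(p) < 0.05
        false_rates.append(rej.mean())
    assert np.mean(false_rates) <= 0.05


# --- de_genes ------------------------------------------------------------

def two_group_expr(rng, n_genes=300, n_a=8, n_b=9, planted=0, shift=2.0,
                   sd=1.0):
    vals = rng.normal(scale=sd, size=(n_genes, n_a + n_b))
    vals[:planted, n_a:] += shift
    expr = make_expression(vals)
    design = SampleDesign(pd.Series(["a"] * n_a + ["b"] * n_b,
                                    index=expr.sample_ids))
    return expr, design


def test_de_genes_power_with_planted_effect(rng):
    expr, design = two_group_expr(rng, n_genes=1000, planted=100, shift=2.0,
                                  sd=0.5)
    table, selected = de_genes(expr, design, "a", "b")
    planted = set(expr.gene_ids[:100])
    assert len(planted & set(selected)) >= 90
    assert (table.loc[sorted(planted), "median_diff"] > 0).mean() > 0.95


def test_de_genes_zero_fdr_selects_nothing(rng):
    expr, design = two_group_expr(rng, planted=10)
    _, selected = de_genes(expr, design, "a", "b", fdr=0.0)
    assert selected == []


def test_de_genes_false_discoveries_bounded(rng):
    """No-effect simulation: false selections average below fdr * n_genes."""
    counts = []
    for _ in range(20):
        expr, design = two_group_expr(rng, n_genes=500, planted=0)
        _, selected = de_genes(expr, design, "a", "b")
        counts.append(len(selected))
    assert np.mean(counts) <= 0.05 * 500


# --- factorial interaction test ------------------------------------------

def test_additive_noiseless_data_has_zero_interaction():
    expr, design = simulate_factorial_treatment(
        5, (2.0, -1.0, 0.0), 3, seed=1, noise_sd=0.0)
    table = factorial_interaction_test(expr, design, moderated=False)
    assert np.allclose(table["coef_drugA:drugB"], 0.0, atol=1e-10)


def test_unmoderated_matches_statsmodels_oracle():
    import statsmodels.formula.api as smf
    expr, design = simulate_factorial_treatment(6, (1.0, 0.5, 1.5), 3, seed=4)
    table = factorial_interaction_test(expr, design, moderated=False)
    for g in expr.gene_ids[:3]:
        df = pd.DataFrame({"y": expr.values.loc[g].to_numpy(),
                           "A": design.factors["drugA"].to_numpy(),
                           "B": design.factors["drugB"].to_numpy()})
        fit = smf.ols("y ~ A * B", data=df).fit()
        assert table.loc[g, "coef_drugA:drugB"] == pytest.approx(
            fit.params["A:B"], rel=1e-9)
        assert table.loc[g, "p_drugA:drugB"] == pytest.approx(
            fit.pvalues["A:B"], rel=1e-9)


def test_interaction_null_calibration(rng):
    rates = []
    for seed in range(10):
        expr, design = simulate_factorial_treatment(
            500, (1.0, 1.0, 0.0), 3, seed=seed, noise_sd=0.5)
        table = factorial_interaction_test(expr, design)
        rates.append((table["p_drugA:drugB"] < 0.05).mean())
    # binomial band around 0.05 for 5000 draws
    assert 0.03 < np.mean(rates) < 0.07


def test_interaction_power(rng):
    expr, design = simulate_factorial_treatment(
        300, (0.0, 0.0, 2.0), 4, seed=2, noise_sd=0.5, n_affected=100)
    table = factorial_interaction_test(expr, design)
    assert (table["p_drugA:drugB"][:100] < 0.05).mean() >= 0.90


def test_factorial_requires_factors(rng):
    expr, _ = simulate_factorial_treatment(5, (0, 0, 0), 2, seed=0)
    bare = SampleDesign(pd.Series(["x"] * 8, index=expr.sample_ids))
    with pytest.raises(ValueError, match="factors"):
        factorial_interaction_test(expr, bare)


# --- Jonckheere-Terpstra -------------------------------------------------

def test_jt_textbook_case():
    jt, p = jonckheere_terpstra([[1], [2], [3]], two_sided=False)
    assert jt == 3.0
    assert p == pytest.approx(1 / 6)


def test_jt_all_tied_gives_one():
    _, p = jonckheere_terpstra([[5, 5], [5, 5], [5, 5]])
    assert p == 1.0


def test_jt_requires_three_groups():
    with pytest.raises(ValueError, match="mann_whitney"):
        jonckheere_terpstra([[1, 2], [3, 4]])


def test_jt_matches_enumeration_oracle(rng):
    for _ in range(10):
        sizes = rng.integers(2, 4, size=3)
        groups = [rng.integers(0, 10, size=s).astype(float) for s in sizes]
        jt, p = jonckheere_terpstra(groups)
        jto, _, po = jt_oracle([list(g) for g in groups])
        assert jt == pytest.approx(jto)
        assert p == pytest.approx(po, abs=1e-12)


def test_jt_normal_approximation_direction(rng):
    groups = [rng.normal(loc=i, size=8) for i in range(4)]   # strong trend
    jt, p = jonckheere_terpstra(groups)
    assert p < 1e-4


# --- Spearman ------------------------------------------------------------

def test_spearman_perfect_and_reversed():
    rho, p = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 120)     # both comonotone orders
    rho2, _ = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
    assert rho2 == pytest.approx(-1.0)


def test_spearman_matches_permutation_oracle(rng):
    for n in (4, 5, 6):
        for _ in range(3):
            x = rng.permutation(n * 10)[:n].astype(float)
            y = rng.permutation(n * 10)[:n].astype(float)
            rho, p = spearman_correlation(x, y)
            rho_o, p_o = spearman_oracle(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)


def test_spearman_errors():
    with pytest.raises(ValueError, match="constant"):
        spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="4"):
        spearman_correlation([1, 2, 3], [1, 2, 3])
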