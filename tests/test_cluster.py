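"""Spearman-distance clustering and consensus NMF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from sigperm import (
    consensus_matrix,
    cophenetic_coefficient,
    hierarchical_cluster,
    nmf_brunet,
    rank_survey,
    spearman_distance,
)


def profile_frame(arrs, names=None):
    names = names or [f"s{i}" for i in range(len(arrs))]
    return pd.DataFrame(np.asarray(arrs).T, columns=names)


# --- spearman distance ---------------------------------------------------

def test_spearman_distance_extremes():
    df = profile_frame([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
    d = spearman_distance(df, axis="samples")
    assert d.iloc[0, 1] == pytest.approx(0.0)      # identical rankings
    assert d.iloc[0, 2] == pytest.approx(2.0)      # exactly reversed
    assert np.allclose(np.diag(d), 0.0)


def test_spearman_distance_matches_rank_pearson_oracle(rng):
    df = profile_frame(rng.normal(size=(6, 20)))
    d = spearman_distance(df, axis="samples")
    for i in range(6):
        for j in range(6):
            ri = stats.rankdata(df.iloc[:, i])
            rj = stats.rankdata(df.iloc[:, j])
            expected = 1.0 - stats.pearsonr(ri, rj).statistic
            assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_spearman_distance_monotone_invariance(rng):
    base = rng.normal(size=(5, 30))
    d1 = spearman_distance(profile_frame(base))
    transformed = np.array([np.exp(p) if i % 2 else p ** 3
                            for i, p in enumerate(base)])
    d2 = spearman_distance(profile_frame(transformed))
    assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


def test_spearman_distance_errors():
    with pytest.raises(ValueError, match="constant"):
        spearman_distance(profile_frame([[1, 1, 1], [1, 2, 3]]))
    with pytest.raises(ValueError, match="observations"):
        spearman_distance(profile_frame([[1, 2], [3, 4]]))


# --- hierarchical clustering --------------------------------------------

def brute_force_complete(D):
    """Naive O(n^3) greedy complete-linkage oracle (plain Python)."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    nxt = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                h = max(D[x][y] for x in clusters[a] for y in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        merges.append((ids[a], ids[b], h))
        clusters[a] = clusters[a] + clusters[b]
        ids[a] = nxt
        nxt += 1
        active.remove(b)
    return merges


def dist_frame(D):
    labels = [f"x{i}" for i in range(D.shape[0])]
    return pd.DataFrame(D, index=labels, columns=labels)


def test_two_and_three_leaf_hand_cases():
    D = np.array([[0.0, 0.4], [0.4, 0.0]])
    dend = hierarchical_cluster(dist_frame(D))
    assert dend.merges == [(0, 1, 0.4)]

    D3 = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
    dend3 = hierarchical_cluster(dist_frame(D3))
    assert dend3.merges == [(0, 1, 0.1), (3, 2, 0.9)]


def test_matches_brute_force_oracle_small(rng):
    for _ in range(20):
        n = int(rng.integers(4, 9))
        M = rng.uniform(size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        got = hierarchical_cluster(dist_frame(D)).merges
        expected = brute_force_complete(D)
        for (a, b, h), (ea, eb, eh) in zip(got, expected):
            assert {a, b} == {ea, eb}
            assert h == pytest.approx(eh, abs=1e-12)


def test_matches_scipy_heights(rng):
    n = 9
    M = rng.uniform(size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    mine = hierarchical_cluster(dist_frame(D)).to_linkage()
    ref = hierarchy.linkage(squareform(D, checks=False), "complete")
    assert np.allclose(mine[:, 2], ref[:, 2], atol=1e-12)


def test_heights_nondecreasing(rng):
    M = rng.uniform(size=(10, 10))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    heights = [h for _, _, h in hierarchical_cluster(dist_frame(D)).merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))


def test_asymmetric_input_rejected():
    D = np.array([[0.0, 0.5], [0.4, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        hierarchical_cluster(dist_frame(D))


# --- NMF -----------------------------------------------------------------

def test_nmf_recovers_exact_factorization(rng):
    W0 = rng.uniform(0.5, 2.0, size=(20, 3))
    H0 = rng.uniform(0.5, 2.0, size=(3, 10))
    V = W0 @ H0
    best = np.inf
    for seed in range(5):
        _, _, trace = nmf_brunet(V, 3, max_iter=5000, tol=1e-12, seed=seed)
        best = min(best, trace[-1])
    assert best < 1e-6


def test_nmf_divergence_nonincreasing(rng):
    V = rng.uniform(0.0, 5.0, size=(25, 8))
    for seed in range(3):
        _, _, trace = nmf_brunet(V, 2, seed=seed)
        assert np.all(np.diff(trace) <= 1e-10 * max(trace[0], 1.0))


def test_nmf_rank_one_exact(rng):
    V = np.outer(rng.uniform(1, 3, 15), rng.uniform(1, 3, 6))
    W, H, _ = nmf_brunet(V, 1, max_iter=3000, tol=1e-13, seed=0)
    rel_err = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
    assert rel_err < 1e-6


def test_nmf_agrees_with_sklearn_objective(rng):
    """Independent route: sklearn's KL-loss multiplicative-update NMF should
    reach a comparable divergence on the same problem."""
    from sklearn.decomposition import NMF
    V = rng.uniform(0.1, 5.0, size=(30, 10))
    _, _, trace = nmf_brunet(V, 3, max_iter=3000, tol=1e-10, seed=1)
    sk = NMF(n_components=3, beta_loss="kullback-leibler", solver="mu",
             init="random", random_state=1, max_iter=3000, tol=1e-10)
    W = sk.fit_transform(V)
    from sigperm.cluster import _kl_divergence
    d_sk = _kl_divergence(V, W @ sk.components_)
    assert trace[-1] <= d_sk * 1.1 + 1e-6


def test_nmf_input_validation(rng):
    with pytest.raises(ValueError, match="non-negative"):
        nmf_brunet(np.array([[1.0, -1.0], [1.0, 1.0]]), 1)
    with pytest.raises(ValueError, match="rank"):
        nmf_brunet(rng.uniform(1, 2, size=(4, 4)), 4)


# --- consensus and cophenetic -------------------------------------------

def block_matrix(rng, n_blocks=3, genes_per_block=15, samples_per_block=4,
                 signal=8.0, noise=0.5):
    G = n_blocks * genes_per_block
    S = n_blocks * samples_per_block
    V = rng.uniform(0.5, 1.5, size=(G, S))
    for k in range(n_blocks):
        gs = slice(k * genes_per_block, (k + 1) * genes_per_block)
        ss = slice(k * samples_per_block, (k + 1) * samples_per_block)
        V[gs, ss] += signal + rng.uniform(0, noise, size=(genes_per_block,
                                                          samples_per_block))
    return pd.DataFrame(V, index=[f"g{i}" for i in range(G)],
                        columns=[f"s{j}" for j in range(S)])


def test_consensus_block_structure(rng):
    V = block_matrix(rng)
    res = consensus_matrix(V, 3, n_runs=30, seed=2)
    C = res.consensus.to_numpy()
    assert np.allclose(np.diag(C), 1.0)
    truth = np.repeat(np.arange(3), 4)
    same = truth[:, None] == truth[None, :]
    assert np.allclose(C[same], 1.0)
    assert np.allclose(C[~same], 0.0)
    assert res.cophenetic_rho == pytest.approx(1.0)


def test_consensus_deterministic(rng):
    V = block_matrix(rng, n_blocks=2, genes_per_block=10, samples_per_block=3)
    a = consensus_matrix(V, 2, n_runs=10, seed=7)
    b = consensus_matrix(V, 2, n_runs=10, seed=7)
    pd.testing.assert_frame_equal(a.consensus, b.consensus)


def test_cophenetic_matches_pairwise_oracle(rng):
    """Recompute via an explicit cophenetic-distance matrix from the
    average-linkage merge heights."""
    C = np.clip((rng.uniform(size=(8, 8)) + np.eye(8)) / 1.2, 0, 1)
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    rho = cophenetic_coefficient(C)
    d = squareform(1.0 - C + np.diag(np.diag(C) - 1.0), checks=False)
    Z = hierarchy.linkage(d, "average")
    coph = hierarchy.cophenet(Z)
    expected = np.corrcoef(d, coph)[0, 1]
    assert rho == pytest.approx(expected, abs=1e-9)


def test_cophenetic_degrades_under_noise(rng):
    V = block_matrix(rng)
    clean = consensus_matrix(V, 3, n_runs=20, seed=3).consensus.to_numpy()
    noisy = clean * 0.6 + 0.4 * rng.uniform(size=clean.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 1.0)
    assert cophenetic_coefficient(noisy) < cophenetic_coefficient(clean) + 1e-12


def test_cophenetic_constant_rejected():
    C = np.full((4, 4), 0.5)
    np.fill_diagonal(C, 1.0)
    C[:] = 1.0
    with pytest.raises(ValueError, match="constant"):
        cophenetic_coefficient(C)


def noisy_block_matrix(rng, n_blocks=3, genes_per_block=20,
                       samples_per_block=6, signal=3.0, noise_sdlog=0.8):
    """Planted block structure under multiplicative log-normal noise, the
    regime where only the true rank yields a reproducible consensus."""
    G = n_blocks * genes_per_block
    S = n_blocks * samples_per_block
    V = rng.uniform(0.5, 1.5, size=(G, S))
    for k in range(n_blocks):
        gs = slice(k * genes_per_block, (k + 1) * genes_per_block)
        ss = slice(k * samples_per_block, (k + 1) * samples_per_block)
        V[gs, ss] += signal
    V *= rng.lognormal(0.0, noise_sdlog, size=(G, S))
    return pd.DataFrame(V, index=[f"g{i}" for i in range(G)],
                        columns=[f"s{j}" for j in range(S)])


def test_select_rank_prefers_plateau_end_then_peak():
    from sigperm import select_rank
    t = pd.DataFrame({"rank": [2, 3, 4, 5],
                      "cophenetic_rho": [1.0, 1.0, 0.98, 0.99],
                      "cophenetic_rho_randomized": [0.9] * 4})
    assert select_rank(t) == 3          # plateau ends where the curve falls
    rising = pd.DataFrame({"rank": [2, 3, 4],
                           "cophenetic_rho": [0.90, 0.95, 0.99],
                           "cophenetic_rho_randomized": [0.9] * 3})
    assert select_rank(rising) == 4     # never falls: take the maximum


def test_rank_survey_single_rank(rng):
    V = block_matrix(rng, n_blocks=2, genes_per_block=10, samples_per_block=3)
    table = rank_survey(V, [2], n_runs=8, n_runs_randomized=4, seed=1)
    assert list(table.columns) == ["rank", "cophenetic_rho",
                                   "cophenetic_rho_randomized"]
    assert len(table) == 1
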