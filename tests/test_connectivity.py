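"""Coherence estimation and graph-metric tests: scipy cross-checks,
complete-graph closed forms, and Floyd-Warshall / exhaustive-triple
brute-force oracles on small graphs."""

import itertools

import numpy as np
import pytest
from scipy.signal import coherence as scipy_coherence

from mcieeg import connectivity as cg

ALPHA = cg.DEFAULT_BANDS[2]


def make_graph(W, threshold=0.5):
    W = np.asarray(W, dtype=float)
    A = (W > threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    return cg.BandGraph(
        W=W, A=A, channel_names=[f"n{i}" for i in range(len(W))],
        band=ALPHA, threshold=threshold,
    )


def complete_graph(n, w=1.0):
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return make_graph(W)


# ---------------------------------------------------------------------------
# brute-force oracles


def floyd_warshall(L):
    """All-pairs shortest path lengths on an edge-length matrix (0 = no edge)."""
    n = len(L)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if L[i, j] > 0:
                d[i, j] = L[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def betweenness_bruteforce(W):
    """Normalized weighted betweenness by exhaustive path enumeration."""
    n = len(W)
    L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1), 0.0)
    dist = floyd_warshall(L)
    bc = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[j, k]):
            continue
        paths, through = [], np.zeros(n)
        for perm_len in range(0, n - 2 + 1):
            for mids in itertools.permutations(
                [m for m in range(n) if m not in (j, k)], perm_len
            ):
                nodes = (j,) + mids + (k,)
                if any(L[nodes[i], nodes[i + 1]] == 0 for i in range(len(nodes) - 1)):
                    continue
                length = sum(L[nodes[i], nodes[i + 1]] for i in range(len(nodes) - 1))
                if np.isclose(length, dist[j, k], rtol=1e-12):
                    paths.append(nodes)
        sigma = len(paths)
        if sigma == 0:
            continue
        for p in paths:
            for m in p[1:-1]:
                through[m] += 1
        bc += through / sigma
    return 2.0 * bc / ((n - 1) * (n - 2))


def transitivity_bruteforce(A):
    n = len(A)
    tri = sum(
        A[i, j] * A[j, k] * A[i, k]
        for i, j, k in itertools.combinations(range(n), 3)
    )
    triplets = sum(
        A[i, j] * A[i, k]
        for i in range(n)
        for j, k in itertools.permutations([m for m in range(n) if m != i], 2)
    ) / 2
    return 3.0 * tri / triplets if triplets > 0 else 0.0


def clustering_bruteforce(W):
    wmax = W.max()
    n = len(W)
    out = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(W[i] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for m in range(n):
                s += (W[i, j] / wmax * W[j, m] / wmax * W[m, i] / wmax) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out


def assortativity_bruteforce(A):
    k = A.sum(axis=1).astype(float)
    xs, ys = [], []
    for i in range(len(A)):
        for j in range(len(A)):
            if A[i, j]:
                xs.append(k[i])
                ys.append(k[j])
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0:
        return np.nan
    return np.mean((xs - xs.mean()) * (ys - ys.mean())) / (xs.std() * ys.std())


# ---------------------------------------------------------------------------
# coherence estimation


def test_welch_coherence_matches_scipy_pairwise(rng):
    x = rng.standard_normal((4, 300))
    freqs, coh = cg.welch_coherence(x, 100.0)
    for a, b in itertools.combinations(range(4), 2):
        f_ref, c_ref = scipy_coherence(
            x[a], x[b], fs=100.0, nperseg=100, noverlap=50,
            window="hann", detrend="constant",
        )
        np.testing.assert_allclose(freqs, f_ref)
        np.testing.assert_allclose(coh[a, b], c_ref, atol=1e-12)


def test_identical_signals_full_coherence(rng):
    x = rng.standard_normal(300)
    g = cg.coherence_matrix(np.vstack([x, x]), 100.0, ALPHA)
    assert g.W[0, 1] == pytest.approx(1.0, abs=1e-6)


def test_independent_noise_low_coherence():
    vals = []
    for s in range(50):
        x = np.random.default_rng(s).standard_normal((2, 300))
        g = cg.coherence_matrix(x, 100.0, ALPHA)
        vals.append(g.W[0, 1])
    assert 0.0 < np.mean(vals) < 0.4  # positive bias expected at short epochs


def test_bandlimited_copy_concentrates_coherence(rng):
    from scipy.signal import butter, sosfiltfilt

    a = rng.standard_normal(3000)
    sos = butter(4, [8, 13], btype="bandpass", fs=100.0, output="sos")
    b = sosfiltfilt(sos, a) + 0.05 * rng.standard_normal(3000)
    x = np.vstack([a, b])
    g_alpha = cg.coherence_matrix(x, 100.0, ALPHA)
    g_gamma = cg.coherence_matrix(x, 100.0, cg.DEFAULT_BANDS[4])
    assert g_alpha.W[0, 1] > 3 * g_gamma.W[0, 1]


def test_coherence_matrix_contracts(rng):
    x = rng.standard_normal((6, 300))
    g = cg.coherence_matrix(x, 100.0, ALPHA)
    np.testing.assert_allclose(g.W, g.W.T, atol=1e-10)
    assert g.W.min() >= 0 and g.W.max() <= 1
    assert np.all(np.diag(g.W) == 0) and np.all(np.diag(g.A) == 0)
    with pytest.raises(ValueError):
        cg.coherence_matrix(x, 100.0, cg.BandDefinition("bad", 45.0, 60.0))


# ---------------------------------------------------------------------------
# closed forms


def test_triangle_closed_forms():
    m = cg.local_metrics(complete_graph(3))
    for name, want in [
        ("degree", 2.0), ("strength", 2.0), ("clustering", 1.0),
        ("betweenness", 0.0), ("local_efficiency", 1.0),
    ]:
        np.testing.assert_allclose(m.local[name], want, atol=1e-12)
    np.testing.assert_allclose(m.local["eigenvector"], 1 / np.sqrt(3), atol=1e-7)


def test_k4_global_closed_forms():
    g = cg.global_metrics(complete_graph(4))
    for name, want in [
        ("global_efficiency", 1.0), ("char_path_length", 1.0),
        ("avg_clustering", 1.0), ("density", 1.0), ("transitivity", 1.0),
    ]:
        assert g.global_[name] == pytest.approx(want, abs=1e-12), name


def test_path_graph_hand_enumeration():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    g = make_graph(W)
    loc = cg.local_metrics(g)
    np.testing.assert_allclose(loc.local["betweenness"], [0.0, 1.0, 0.0])
    glob = cg.global_metrics(g).global_
    assert glob["char_path_length"] == pytest.approx(4.0 / 3.0)
    assert glob["global_efficiency"] == pytest.approx(5.0 / 6.0)
    assert glob["transitivity"] == 0.0


def test_star_graph_disassortative():
    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = 1.0
    g = make_graph(W)
    assert cg.global_metrics(g).global_["assortativity"] < 0


def test_weighted_triangle_clustering_hand_formula():
    w = 0.3
    W = np.array([[0, 1, w], [1, 0, 1], [w, 1, 0]], dtype=float)
    m = cg.local_metrics(make_graph(W))
    # Onnela: C_i = (prod of normalized triangle weights)^(1/3) / (k(k-1)) * 2
    what = W / W.max()
    expected = []
    for i in range(3):
        j, k = [m_ for m_ in range(3) if m_ != i]
        t = 2 * (what[i, j] * what[j, k] * what[k, i]) ** (1 / 3)
        expected.append(t / (2 * 1))
    np.testing.assert_allclose(m.local["clustering"], expected, atol=1e-12)


def test_density_exact_on_hand_built_graph():
    W = np.zeros((5, 5))
    for i, j in [(0, 1), (1, 2), (3, 4)]:
        W[i, j] = W[j, i] = 0.9
    g = make_graph(W)
    assert cg.global_metrics(g).global_["density"] == pytest.approx(
        2 * 3 / (5 * 4)
    )


# ---------------------------------------------------------------------------
# oracle equivalence on random small graphs


@pytest.mark.parametrize("trial", range(20))
def test_graph_metrics_match_bruteforce_oracles(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(4, 7))
    W = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0, 1, len(iu[0]))
    vals[rng.random(len(vals)) < 0.3] = 0.0  # some missing edges
    W[iu] = vals
    W = W + W.T
    g = make_graph(W, threshold=0.4)
    loc = cg.local_metrics(g)
    glob = cg.global_metrics(g).global_

    np.testing.assert_allclose(loc.local["degree"], g.A.sum(axis=1), atol=0)
    np.testing.assert_allclose(loc.local["strength"], W.sum(axis=1), rtol=1e-12)
    np.testing.assert_allclose(
        loc.local["clustering"], clustering_bruteforce(W), atol=1e-10
    )
    np.testing.assert_allclose(
        loc.local["betweenness"], betweenness_bruteforce(W), atol=1e-10
    )

    L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1), 0.0)
    dist = floyd_warshall(L)
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / np.where(dist > 0, dist, 1), 0.0)
    assert glob["global_efficiency"] == pytest.approx(inv[off].mean(), rel=1e-10)

    assert glob["transitivity"] == pytest.approx(
        transitivity_bruteforce(g.A.astype(float)), abs=1e-12
    )
    r_oracle = assortativity_bruteforce(g.A)
    if np.isnan(r_oracle):
        assert np.isnan(glob["assortativity"])
    else:
        assert glob["assortativity"] == pytest.approx(r_oracle, abs=1e-10)

    # eigenvector centrality against the dense eigendecomposition
    comp_sizes = np.isfinite(dist).sum(axis=1)
    if comp_sizes.max() == n:  # connected: compare directly
        evals, evecs = np.linalg.eigh(W)
        v = np.abs(evecs[:, -1])
        np.testing.assert_allclose(
            loc.local["eigenvector"], v / np.linalg.norm(v), atol=1e-6
        )


def test_char_path_length_largest_component():
    # two components: a triangle (unit weights) and an isolated edge
    W = np.zeros((5, 5))
    for i, j in [(0, 1), (1, 2), (0, 2)]:
        W[i, j] = W[j, i] = 1.0
    W[3, 4] = W[4, 3] = 1.0
    g = make_graph(W)
    assert cg.global_metrics(g).global_["char_path_length"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# small-worldness nulls


def test_sigma_reproducible_and_unity_on_random_family():
    import networkx as nx

    sigmas = []
    for s in range(8):
        G = nx.gnm_random_graph(19, 60, seed=s)
        A = nx.to_numpy_array(G)
        g = cg.BandGraph(
            W=A * 0.9, A=A.astype(np.int8),
            channel_names=[str(i) for i in range(19)], band=ALPHA,
        )
        cfgn = cg.NullModelConfig(seed=100 + s)
        s1 = cg.global_metrics(g, cfgn).global_["small_worldness"]
        s2 = cg.global_metrics(g, cfgn).global_["small_worldness"]
        assert s1 == s2  # seeded nulls: bit-identical
        sigmas.append(s1)
    assert np.mean(sigmas) == pytest.approx(1.0, abs=0.15)


def test_empty_graph_sigma_flagged():
    W = np.zeros((4, 4))
    g = make_graph(W)
    gm = cg.global_metrics(g)
    assert gm.global_["density"] == 0.0
    assert np.isnan(gm.global_["small_worldness"])
    assert "small_worldness" in gm.flags


# ---------------------------------------------------------------------------
# per-epoch feature contract


def test_five_bands_yield_65_connectivity_features(rng):
    x = rng.standard_normal((19, 300))
    out = cg.connectivity_features(x, 100.0)
    count = sum(
        len(gm.local) + len(gm.global_) for gm in out.values()
    )
    assert count == 5 * (6 + 7) == 65


def test_single_band_yields_13(rng):
    x = rng.standard_normal((6, 300))
    out = cg.connectivity_features(x, 100.0, bands=(ALPHA,))
    gm = out["alpha"]
    assert len(gm.local) + len(gm.global_) == 13


def test_channel_permutation_equivariance(rng):
    x = rng.standard_normal((6, 300))
    perm = np.array([3, 1, 5, 0, 2, 4])
    g1 = cg.coherence_matrix(x, 100.0, ALPHA)
    g2 = cg.coherence_matrix(x[perm], 100.0, ALPHA)
    m1, m2 = cg.local_metrics(g1), cg.local_metrics(g2)
    for name in ("degree", "strength", "clustering", "betweenness"):
        np.testing.assert_allclose(m2.local[name], m1.local[name][perm], atol=1e-9)
    cfgn = cg.NullModelConfig(seed=5)
    gl1 = cg.global_metrics(g1, cfgn).global_
    gl2 = cg.global_metrics(g2, cfgn).global_
    for name in ("global_efficiency", "char_path_length", "avg_clustering",
                 "density", "transitivity"):
        assert gl1[name] == pytest.approx(gl2[name], abs=1e-9)
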