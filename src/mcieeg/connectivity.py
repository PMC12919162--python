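"""Coherence-based functional connectivity graphs and their metrics.

For each epoch and canonical frequency band, magnitude-squared coherence
between every channel pair is estimated from Welch segment-averaged
cross-spectra and interpreted as a weighted, undirected graph (channels
as nodes, coherence as edge weight).  Six node-level and seven
graph-level metrics are derived.  Shortest paths on the weighted graph
use edge lengths 1/w (stronger coupling = shorter distance); unweighted
metrics (degree, density, assortativity, transitivity and the
small-world comparison) operate on a binary adjacency obtained by
thresholding the coherence weights, since a dense coherence graph has
degenerate binary topology without a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "NullModelConfig",
    "BandGraph",
    "GraphMetrics",
    "LOCAL_METRIC_NAMES",
    "GLOBAL_METRIC_NAMES",
    "coherence_matrix",
    "betweenness_centrality",
    "eigenvector_centrality",
    "local_metrics",
    "global_metrics",
    "connectivity_features",
    "coherence_to_frame",
    "metrics_to_frame",
]

LOCAL_METRIC_NAMES = (
    "degree",
    "strength",
    "clustering",
    "betweenness",
    "eigenvector",
    "local_efficiency",
)
GLOBAL_METRIC_NAMES = (
    "global_efficiency",
    "char_path_length",
    "avg_clustering",
    "small_worldness",
    "assortativity",
    "density",
    "transitivity",
)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges for {self.name}")


#: Canonical EEG rhythm bands truncated to the 0.5-40 Hz analysis passband.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)


@dataclass(frozen=True)
class NullModelConfig:
    """Degree-preserving random-rewiring ensemble for small-worldness."""

    n_null: int = 10
    swaps_per_edge: float = 4.0
    seed: int = 0


@dataclass
class BandGraph:
    """Weighted coherence graph plus its thresholded binary topology."""

    W: np.ndarray
    A: np.ndarray
    channel_names: list[str]
    band: BandDefinition
    threshold: float = 0.5

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if W.min() < -1e-10 or W.max() > 1 + 1e-10:
            raise ValueError("coherence weights must lie in [0, 1]")


@dataclass
class GraphMetrics:
    local: dict[str, np.ndarray] = field(default_factory=dict)
    global_: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# coherence estimation


def welch_coherence(
    data: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs magnitude-squared coherence by Welch's method.

    Hann-windowed, constant-detrended segments (default one second with
    50% overlap); cross-spectra are averaged across segments and
    normalized per frequency bin.  Returns ``(freqs, coh)`` with ``coh``
    of shape (channels, channels, n_freqs).  Matches
    :func:`scipy.signal.coherence` at identical settings, computed for
    all pairs at once.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_s = data.shape
    if nperseg is None:
        nperseg = min(int(round(fs)), n_s)
    step = max(1, int(round(nperseg * (1 - overlap))))
    starts = np.arange(0, n_s - nperseg + 1, step)
    if len(starts) < 2:
        raise ValueError("epoch too short for at least two spectral windows")
    win = hann(nperseg, sym=False)
    segs = data[:, starts[:, None] + np.arange(nperseg)]
    segs = (segs - segs.mean(axis=-1, keepdims=True)) * win
    F = rfft(segs, axis=-1)
    # scaling constants cancel in the coherence ratio
    S = np.einsum("asf,bsf->abf", F, np.conj(F))
    auto = np.real(np.einsum("aaf->af", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(S) ** 2 / denom
    coh = np.nan_to_num(np.real(coh), nan=0.0)
    return rfftfreq(nperseg, 1.0 / fs), np.clip(coh, 0.0, 1.0)


def coherence_matrix(
    epoch: np.ndarray,
    fs: float,
    band: BandDefinition,
    channel_names: list[str] | None = None,
    threshold: float = 0.5,
    nperseg: int | None = None,
) -> BandGraph:
    """Band-averaged coherence weights for one epoch as a BandGraph.

    Band membership is the half-open interval [f_lo, f_hi) on the Welch
    frequency grid.  The binary adjacency keeps edges with weight
    strictly above ``threshold``.
    """
    epoch = np.asarray(epoch, dtype=float)
    if band.f_hi > fs / 2:
        raise ValueError(f"band {band.name} exceeds the Nyquist frequency")
    freqs, coh = welch_coherence(epoch, fs, nperseg=nperseg)
    sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if not sel.any():
        raise ValueError(f"no spectral bins inside band {band.name}")
    W = coh[:, :, sel].mean(axis=2)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    A = (W > threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(epoch.shape[0])]
    return BandGraph(W=W, A=A, channel_names=list(channel_names), band=band,
                     threshold=threshold)


# ---------------------------------------------------------------------------
# shortest-path helpers (edge lengths 1/w per the weighted-graph convention)


def _floyd_warshall(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on a dense edge-length matrix (0 = no
    edge).  Vectorized min-plus iteration; fast for the <=20-node graphs
    this package works with."""
    n = L.shape[0]
    d = np.where(L > 0, L, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :], out=d)
    return d


def _weighted_distances(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    return _floyd_warshall(L)


def _binary_distances(A: np.ndarray) -> np.ndarray:
    return _floyd_warshall(A.astype(float))


def _components(M: np.ndarray) -> list[np.ndarray]:
    """Connected components of the nonzero-weight topology."""
    n = M.shape[0]
    adj = M > 0
    unvisited = np.ones(n, dtype=bool)
    comps = []
    while unvisited.any():
        frontier = np.zeros(n, dtype=bool)
        frontier[int(np.flatnonzero(unvisited)[0])] = True
        comp = np.zeros(n, dtype=bool)
        while frontier.any():
            comp |= frontier
            frontier = (adj[frontier].any(axis=0)) & ~comp & unvisited
        unvisited &= ~comp
        comps.append(np.flatnonzero(comp))
    return comps


# ---------------------------------------------------------------------------
# local metrics


def _weighted_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering with weights normalized by max w."""
    wmax = W.max()
    if wmax == 0:
        return np.zeros(W.shape[0])
    cb = np.cbrt(W / wmax)
    t = np.einsum("ij,jk,ki->i", cb, cb, cb)
    k = np.count_nonzero(W > 0, axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, t / denom, 0.0)
    return c


def eigenvector_centrality(W: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 1000) -> np.ndarray:
    """Power iteration on the weight matrix, restricted to the dominant
    (largest) connected component; nonnegative, unit L2 norm."""
    n = W.shape[0]
    comps = _components(W)
    comp = max(comps, key=len)
    v = np.zeros(n)
    if len(comp) == 1:
        v[comp[0]] = 1.0
        return v
    Wc = W[np.ix_(comp, comp)]
    vc = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    for _ in range(max_iter):
        nxt = Wc @ vc
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.abs(nxt - vc).max() < tol:
            vc = nxt
            break
        vc = nxt
    vc = np.abs(vc)
    nrm = np.linalg.norm(vc)
    if nrm > 0:
        vc = vc / nrm
    v[comp] = vc
    return v


def betweenness_centrality(W: np.ndarray) -> np.ndarray:
    """Normalized weighted betweenness (Brandes' accumulation).

    Shortest paths use edge lengths 1/w; normalization is
    2 BC / ((N-1)(N-2)) for the undirected graph.
    """
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(n)
        sigma[s] = 1.0
        seen = np.zeros(n, dtype=bool)
        preds: list[list[int]] = [[] for _ in range(n)]
        order = []
        for _ in range(n):
            cand = np.where(seen, np.inf, dist)
            u = int(np.argmin(cand))
            if not np.isfinite(cand[u]):
                break
            seen[u] = True
            order.append(u)
            nd = dist[u] + L[u]
            for v in np.flatnonzero(np.isfinite(L[u])):
                if seen[v]:
                    continue
                if nd[v] < dist[v] - 1e-14:
                    dist[v] = nd[v]
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                elif abs(nd[v] - dist[v]) <= 1e-14:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    bc /= 2.0  # each undirected pair counted from both endpoints
    if n > 2:
        bc *= 2.0 / ((n - 1) * (n - 2))
    return bc


def local_metrics(g: BandGraph) -> GraphMetrics:
    """The six node-level metrics of one band graph.

    Degree counts thresholded binary edges; all other metrics use the
    weighted graph, with shortest paths on edge lengths 1/w.  Isolated
    nodes get zero clustering/efficiency by convention and are flagged.
    """
    W, A = g.W, g.A
    n = W.shape[0]
    out = GraphMetrics()
    out.local["degree"] = A.sum(axis=1).astype(float)
    out.local["strength"] = W.sum(axis=1)
    out.local["clustering"] = _weighted_clustering(W)
    out.local["betweenness"] = betweenness_centrality(W)

    out.local["eigenvector"] = eigenvector_centrality(W)

    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(W[i] > 0)
        if len(nb) < 2:
            out.flags.add(f"local_efficiency:isolated:{i}")
            continue
        sub = W[np.ix_(nb, nb)]
        d = _weighted_distances(sub)
        iu = np.triu_indices(len(nb), k=1)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d[iu]) & (d[iu] > 0), 1.0 / d[iu], 0.0)
        eloc[i] = 2.0 * inv.sum() / (len(nb) * (len(nb) - 1))
    out.local["local_efficiency"] = eloc
    return out


# ---------------------------------------------------------------------------
# global metrics


def _binary_clustering_avg(A: np.ndarray) -> float:
    t = np.einsum("ij,jk,ki->i", A, A, A).astype(float)
    k = A.sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, t / denom, 0.0)
    return float(c.mean())


def _char_path_length(dist: np.ndarray) -> float:
    """Mean shortest-path length over the largest connected component."""
    n = dist.shape[0]
    finite = np.isfinite(dist)
    # nodes of the largest component: maximal finite-row cluster
    comp_sizes = finite.sum(axis=1)
    nodes = np.flatnonzero(comp_sizes == comp_sizes.max())
    sub = dist[np.ix_(nodes, nodes)]
    iu = np.triu_indices(len(nodes), k=1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def _degree_assortativity(A: np.ndarray) -> float:
    """Pearson correlation of end-node degrees over all edges."""
    k = A.sum(axis=1).astype(float)
    ii, jj = np.nonzero(np.triu(A, k=1))
    if len(ii) == 0:
        return float("nan")
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    sx = x.std()
    if sx == 0:
        return float("nan")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * y.std()))


def _double_edge_swap(A: np.ndarray, rng: np.random.Generator,
                      nswap: int, max_tries: int) -> np.ndarray:
    """Degree-preserving rewiring: repeatedly replace edge pair
    (a-b, c-d) with (a-c, b-d) when that creates no self-loop or
    duplicate edge.  Unswappable topologies come back unchanged."""
    A = A.copy()
    ii, jj = np.nonzero(np.triu(A, k=1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    if len(edges) < 2:
        return A
    swaps = tries = 0
    while swaps < nswap and tries < max_tries:
        tries += 1
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if len({a, b, c, d}) < 4 or A[a, c] or A[b, d]:
            continue
        A[a, b] = A[b, a] = A[c, d] = A[d, c] = 0
        A[a, c] = A[c, a] = A[b, d] = A[d, b] = 1
        edges[e1] = (min(a, c), max(a, c))
        edges[e2] = (min(b, d), max(b, d))
        swaps += 1
    return A


def _null_ensemble(A: np.ndarray, cfg: NullModelConfig):
    """Seeded degree-preserving double-edge-swap randomizations of A."""
    n_edges = int(A.sum()) // 2
    nswap = max(1, int(cfg.swaps_per_edge * n_edges))
    return [
        _double_edge_swap(
            A, np.random.default_rng((cfg.seed, i)), nswap, nswap * 50
        )
        for i in range(cfg.n_null)
    ]


def global_metrics(
    g: BandGraph, null_cfg: NullModelConfig = NullModelConfig()
) -> GraphMetrics:
    """The seven graph-level metrics of one band graph.

    Efficiency treats disconnected pairs as zero contribution
    (1/d = 0); the characteristic path length is computed on the largest
    connected component.  Small-worldness compares binary clustering and
    path length of the thresholded adjacency with a seeded ensemble of
    degree-preserving rewired null graphs.
    """
    W, A = g.W, g.A
    n = W.shape[0]
    out = GraphMetrics()

    dist_w = _weighted_distances(W)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist_w) & (dist_w > 0), 1.0 / dist_w, 0.0)
    out.global_["global_efficiency"] = float(inv[off].mean()) if n > 1 else 0.0
    out.global_["char_path_length"] = _char_path_length(dist_w)
    out.global_["avg_clustering"] = float(_weighted_clustering(W).mean())

    n_edges = int(A.sum()) // 2
    out.global_["density"] = (
        2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    )

    t3 = float(np.einsum("ij,jk,ki->", A, A, A))
    k = A.sum(axis=1).astype(float)
    triplets = float((k * (k - 1)).sum())
    out.global_["transitivity"] = t3 / triplets if triplets > 0 else 0.0

    r = _degree_assortativity(A)
    out.global_["assortativity"] = r
    if np.isnan(r):
        out.flags.add("assortativity")

    # small-worldness on the binary topology vs degree-preserving nulls
    sigma = float("nan")
    if n_edges >= 2:
        c_bin = _binary_clustering_avg(A)
        l_bin = _char_path_length(_binary_distances(A))
        cr, lr = [], []
        for null in _null_ensemble(A, null_cfg):
            cr.append(_binary_clustering_avg(null))
            lr.append(_char_path_length(_binary_distances(null)))
        c_rand, l_rand = float(np.mean(cr)), float(np.nanmean(lr))
        if c_rand > 0 and l_rand > 0 and np.isfinite(l_bin) and l_bin > 0:
            sigma = (c_bin / c_rand) / (l_bin / l_rand)
    out.global_["small_worldness"] = sigma
    if np.isnan(sigma):
        out.flags.add("small_worldness")
    return out


def coherence_to_frame(g: BandGraph):
    """Square coherence matrix as a labelled DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(g.W, index=g.channel_names, columns=g.channel_names)


def metrics_to_frame(per_band: dict[str, GraphMetrics],
                     channel_names: list[str]):
    """Tidy export: one row per (band, channel|GLOBAL, metric, value)."""
    import pandas as pd

    rows = []
    for band, gm in per_band.items():
        for metric, vec in gm.local.items():
            for ch, v in zip(channel_names, vec):
                rows.append((band, ch, metric, float(v)))
        for metric, v in gm.global_.items():
            rows.append((band, "GLOBAL", metric, float(v)))
    return pd.DataFrame(rows, columns=["band", "channel", "metric", "value"])


def connectivity_features(
    epoch: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    null_cfg: NullModelConfig = NullModelConfig(),
    channel_names: list[str] | None = None,
    threshold: float = 0.5,
) -> dict[str, GraphMetrics]:
    """Per-band graph metrics of one epoch: 6 node vectors + 7 scalars each."""
    out: dict[str, GraphMetrics] = {}
    for band in bands:
        g = coherence_matrix(epoch, fs, band, channel_names=channel_names,
                             threshold=threshold)
        gm = local_metrics(g)
        glob = global_metrics(g, null_cfg)
        gm.global_ = glob.global_
        gm.flags |= glob.flags
        out[band.name] = gm
    return out
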