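"""Nonlinear dynamical descriptors of single-channel EEG epochs.

Twelve per-channel measures quantifying irregularity (approximate, sample,
multiscale and fuzzy entropy), algorithmic complexity (Lempel-Ziv),
fractal geometry (Katz, Higuchi, correlation dimension), long-range
temporal structure (DFA, Hurst) and chaoticity (largest Lyapunov exponent,
Kolmogorov-Sinai entropy).  All estimators operate on short series
(the default epoch is 300 samples at 100 Hz), so parameter defaults follow
the canonical short-series literature choices: m=2, r=0.2*SD, lag 1,
coarse-graining scales 1..5, Higuchi kmax=10, embedding dimension 5.

Degenerate inputs never raise: features whose defining ratio is undefined
(e.g. SampEn with zero template matches, Katz FD of a constant) are
returned as NaN and recorded in the flag set of the output vector, to be
imputed downstream from training-set statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "FEATURE_NAMES",
    "EntropyParams",
    "ChaosParams",
    "NonlinearVector",
    "approximate_entropy",
    "sample_entropy",
    "multiscale_entropy",
    "fuzzy_entropy",
    "ks_entropy",
    "correlation_dimension",
    "dfa_exponent",
    "katz_fd",
    "higuchi_fd",
    "hurst_exponent",
    "lyapunov_max",
    "lempel_ziv",
    "permutation_entropy",
    "compute_nonlinear_vector",
]

#: Fixed registry order of the twelve per-channel measures.
FEATURE_NAMES = (
    "ApEn",
    "SampEn",
    "MSE",
    "FuzzyEn",
    "KSEntropy",
    "CorrDim",
    "DFA",
    "KatzFD",
    "HiguchiFD",
    "Hurst",
    "Lyapunov",
    "LZC",
)


@dataclass(frozen=True)
class EntropyParams:
    """Parameters shared by the template-matching entropy family.

    ``r`` is a fraction of the signal's standard deviation; it is resolved
    to an absolute tolerance per series, which makes every entropy in the
    family invariant under affine rescaling of the input.
    """

    m: int = 2
    r: float = 0.2
    tau: int = 1
    fuzzy_n: float = 2.0
    mse_scales: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be > 0")
        if self.tau < 1:
            raise ValueError("embedding lag tau must be >= 1")
        if not self.mse_scales:
            raise ValueError("mse_scales must be nonempty")


@dataclass(frozen=True)
class ChaosParams:
    """Parameters for the chaos / fractal-scaling estimators."""

    embed_dim: int = 5
    embed_lag: int = 1
    theiler_window: int = 10
    radii: tuple[float, ...] | None = None
    dfa_windows: tuple[int, ...] | None = None
    lyap_fit_range: tuple[int, int] = (0, 8)
    n_exponents: int = 5
    ks_neighbors: int = 14
    ks_step: int = 3
    #: exponents below this resolution floor (nats/sample) count as zero
    #: when summing the positive part of the spectrum
    ks_positive_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.radii is not None and np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii grid must be strictly increasing")
        if self.dfa_windows is not None and np.any(np.diff(self.dfa_windows) <= 0):
            raise ValueError("dfa_windows grid must be strictly increasing")


@dataclass
class NonlinearVector:
    """Twelve named feature values plus flags for undefined entries."""

    values: dict[str, float]
    flags: set[str] = field(default_factory=set)

    def as_array(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# helpers


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN/Inf")
    return x


def _embed(x: np.ndarray, dim: int, lag: int) -> np.ndarray:
    """Delay embedding: rows are x[i], x[i+lag], ..., x[i+(dim-1)*lag]."""
    n = len(x) - (dim - 1) * lag
    if n < 1:
        raise ValueError("series too short for requested embedding")
    idx = np.arange(n)[:, None] + lag * np.arange(dim)[None, :]
    return x[idx]


def _cheb_templates(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all length-m delay templates."""
    T = _embed(x, m, tau)
    return cdist(T, T, metric="chebyshev")


# ---------------------------------------------------------------------------
# entropy family


def sample_entropy(x, p: EntropyParams = EntropyParams()) -> float:
    """SampEn = -ln(A/B): template-pair match ratio, self-matches excluded.

    A and B count matching pairs (Chebyshev distance <= r*SD) of length
    m+1 and m templates respectively, both over the first N-m templates.
    Returns NaN when no length-m pair matches (undefined logarithm).
    """
    x = _as_series(x)
    return _sample_entropy_abs(x, p.m, p.r * x.std(), p.tau)


def _sample_entropy_abs(x: np.ndarray, m: int, r_abs: float, tau: int) -> float:
    n_t = len(x) - m * tau  # number of templates usable at both lengths
    if n_t < 2:
        return float("nan")
    d_m = _cheb_templates(x, m, tau)[:n_t, :n_t]
    d_m1 = _cheb_templates(x, m + 1, tau)[:n_t, :n_t]
    iu = np.triu_indices(n_t, k=1)
    b = np.count_nonzero(d_m[iu] <= r_abs)
    a = np.count_nonzero(d_m1[iu] <= r_abs)
    if b == 0 or a == 0:
        return float("nan")
    return -math.log(a / b)


def approximate_entropy(x, p: EntropyParams = EntropyParams()) -> float:
    """ApEn = Phi_m(r) - Phi_{m+1}(r), self-matches included in Phi."""
    x = _as_series(x)
    r_abs = p.r * x.std()

    def phi(m: int) -> float:
        d = _cheb_templates(x, m, p.tau)
        c = np.count_nonzero(d <= r_abs, axis=1) / d.shape[0]
        return float(np.mean(np.log(c)))

    return phi(p.m) - phi(p.m + 1)


def fuzzy_entropy(x, p: EntropyParams = EntropyParams()) -> float:
    """FuzzyEn = ln(Phi_m / Phi_{m+1}) with membership exp(-(d/r)^n).

    Templates are baseline-removed (their own mean subtracted) before the
    Chebyshev distance; the membership exponent uses the dimensionless
    ratio d/r, which makes the measure exactly invariant under affine
    rescaling of the input (r is resolved as a fraction of the SD).
    Membership weights are never exactly zero, so the measure is defined
    for any non-degenerate series.
    """
    x = _as_series(x)
    sd = x.std()
    if sd == 0:
        return 0.0
    r_abs = p.r * sd

    def phi(m: int) -> float:
        T = _embed(x, m, p.tau)
        T = T - T.mean(axis=1, keepdims=True)
        n_t = len(x) - p.m * p.tau
        T = T[:n_t]
        d = cdist(T, T, metric="chebyshev")
        mu = np.exp(-((d / r_abs) ** p.fuzzy_n))
        np.fill_diagonal(mu, 0.0)
        return float(mu.sum(axis=1).mean() / (n_t - 1))

    return math.log(phi(p.m) / phi(p.m + 1))


def coarse_grain(x, scale: int) -> np.ndarray:
    """Non-overlapping block means at the given scale factor."""
    x = _as_series(x)
    n = len(x) // scale
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def multiscale_entropy(x, p: EntropyParams = EntropyParams()) -> float:
    """Mean SampEn over coarse-grained series at the configured scales.

    The tolerance r is resolved once from the original series' SD
    (Costa's convention), so coarse-graining genuinely reduces matchable
    variance instead of renormalizing it away.  Scales at which SampEn is
    undefined are dropped from the mean; all-undefined returns NaN.
    """
    x = _as_series(x)
    r_abs = p.r * x.std()
    vals = [
        _sample_entropy_abs(coarse_grain(x, s), p.m, r_abs, p.tau)
        for s in p.mse_scales
    ]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _chaos_embedding(x: np.ndarray, p: ChaosParams):
    """Shared delay embedding + full pairwise distance matrix."""
    Y = _embed(x, p.embed_dim, p.embed_lag)
    return Y, cdist(Y, Y)


# ---------------------------------------------------------------------------
# Lempel-Ziv


def _lz76_phrases(bits: np.ndarray) -> int:
    """Number of phrases in the Lempel-Ziv 1976 incremental parse."""
    s = bits.tolist()
    n = len(s)
    i, k, l = 0, 1, 1
    k_max = 1
    c = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def lempel_ziv(x) -> float:
    """Normalized Lempel-Ziv complexity c(n) * log2(n) / n.

    The series is binarized at its median (strictly-above -> 1); the
    phrase count follows the 1976 incremental parse, whose first symbol
    always opens phrase one, so any constant run parses to c = 2.
    """
    x = _as_series(x)
    if len(x) < 2:
        raise ValueError("series too short")
    bits = (x > np.median(x)).astype(np.int8)
    c = _lz76_phrases(bits)
    n = len(x)
    return c * math.log2(n) / n


# ---------------------------------------------------------------------------
# fractal dimensions


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension: slope of ln L(k) against ln(1/k)."""
    x = _as_series(x)
    n = len(x)
    if not (n > kmax >= 2):
        raise ValueError("need N > kmax >= 2")
    if np.ptp(x) == 0:
        return 1.0  # degenerate: flat curve
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lk), 1)[0]
    return float(slope)


def katz_fd(x) -> float:
    """Katz FD = log10(n) / (log10(n) + log10(d/L)) on the (index, value) curve.

    n is the number of steps, L the summed Euclidean step length and d the
    maximum distance from the first point.  The series is standardized
    (zero mean, unit SD) before the planar curve is formed, so the
    measure is exactly invariant under affine rescaling of the input.
    Constant input -> NaN.
    """
    x = _as_series(x)
    if len(x) < 3:
        raise ValueError("need N >= 3")
    if np.ptp(x) == 0:
        return float("nan")
    x = (x - x.mean()) / x.std()
    steps = np.sqrt(1.0 + np.diff(x) ** 2)
    L = steps.sum()
    i = np.arange(len(x))
    d = np.sqrt(i**2 + (x - x[0]) ** 2).max()
    n = len(x) - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


# ---------------------------------------------------------------------------
# scaling exponents


def _dfa_windows_default(n: int) -> np.ndarray:
    hi = max(n // 4, 8)
    w = np.unique(np.round(np.geomspace(4, hi, 12)).astype(int))
    return w[(w >= 4) & (w <= n // 4)]


def dfa_fluctuations(x, windows) -> np.ndarray:
    """Root-mean-square fluctuation of the linearly detrended profile.

    The profile is the cumulative sum of the mean-removed series, cut into
    floor(N/s) non-overlapping windows of size s; each window is detrended
    by its own least-squares line.
    """
    x = _as_series(x)
    y = np.cumsum(x - x.mean())
    out = np.empty(len(windows))
    for k, s in enumerate(windows):
        nw = len(y) // s
        seg = y[: nw * s].reshape(nw, s)
        t = np.arange(s)
        A = np.vstack([t, np.ones(s)]).T
        coef, *_ = np.linalg.lstsq(A, seg.T, rcond=None)
        resid = seg.T - A @ coef
        out[k] = np.sqrt(np.mean(resid**2))
    return out


def dfa_exponent(x, p: ChaosParams = ChaosParams()) -> float:
    """DFA scaling exponent alpha: log-log slope of F(s) against s."""
    x = _as_series(x)
    windows = (
        np.asarray(p.dfa_windows, dtype=int)
        if p.dfa_windows is not None
        else _dfa_windows_default(len(x))
    )
    if len(windows) < 3:
        raise ValueError("need at least 3 usable DFA window sizes")
    f = dfa_fluctuations(x, windows)
    good = f > 0
    if good.sum() < 3:
        raise ValueError("degenerate fluctuation function")
    return float(np.polyfit(np.log(windows[good]), np.log(f[good]), 1)[0])


def rescaled_range(x) -> float:
    """R/S of one segment: range of cumulative deviations over the SD."""
    x = _as_series(x)
    s = x.std(ddof=1)
    if s == 0:
        return float("nan")
    z = np.cumsum(x - x.mean())
    return float(np.ptp(z) / s)


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expected R/S of an uncorrelated series of length n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        return (n - 0.5) / n * s / math.sqrt(n * math.pi / 2)
    return (n - 0.5) / n * s / math.sqrt(n * math.pi / 2)


def hurst_exponent(x) -> float:
    """Hurst exponent by rescaled-range analysis, F(T) ~ c T^H.

    The raw R/S statistic is biased upward at short segment lengths; the
    Anis-Lloyd-Peters expected value under uncorrelated increments is
    divided out before fitting, and the resulting slope is offset by the
    0.5 baseline of uncorrelated noise.
    """
    x = _as_series(x)
    n = len(x)
    if n < 100:
        raise ValueError("need N >= 100 for R/S analysis")
    if np.ptp(x) == 0:
        return float("nan")
    sizes = np.unique(np.round(np.geomspace(10, n // 2, 10)).astype(int))
    rs_means = []
    used = []
    for t in sizes:
        nseg = n // t
        segs = x[: nseg * t].reshape(nseg, t)
        z = np.cumsum(segs - segs.mean(axis=1, keepdims=True), axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = segs.std(axis=1, ddof=1)
        ok = s > 0
        if ok.any():
            rs_means.append(np.mean(r[ok] / s[ok]))
            used.append(t)
    if len(used) < 3:
        return float("nan")
    used = np.asarray(used, dtype=float)
    corr = np.array([_expected_rs(int(t)) for t in used])
    slope = np.polyfit(np.log(used), np.log(np.asarray(rs_means) / corr), 1)[0]
    return float(0.5 + slope)


# ---------------------------------------------------------------------------
# chaos estimators


def lyapunov_max(x, p: ChaosParams = ChaosParams(), _embedded=None) -> float:
    """Largest Lyapunov exponent by Rosenstein's divergence method.

    Embed, pair each point with its nearest neighbor outside the Theiler
    window, then fit the slope of the mean log-divergence curve over the
    configured iteration range.  Units: nats per sample.
    """
    x = _as_series(x)
    Y, d0 = _embedded if _embedded is not None else _chaos_embedding(x, p)
    m = len(Y)
    if m < 2 * p.theiler_window + 4:
        return float("nan")
    d = d0.copy()
    ii, jj = np.indices(d.shape, sparse=True)
    d[np.abs(ii - jj) <= p.theiler_window] = np.inf
    nn = np.argmin(d, axis=1)
    finite = np.isfinite(d[np.arange(m), nn])
    if not finite.any():
        return float("nan")
    k0, k1 = p.lyap_fit_range
    ks, means = [], []
    for k in range(k0, k1 + 1):
        ok = finite & (np.arange(m) + k < m) & (nn + k < m)
        if ok.sum() < 10:
            continue
        idx = np.flatnonzero(ok)
        dk = np.linalg.norm(Y[idx + k] - Y[nn[idx] + k], axis=1)
        dk = dk[dk > 0]
        if len(dk) < 10:
            continue
        ks.append(k)
        means.append(np.mean(np.log(dk)))
    if len(ks) < 3:
        return float("nan")
    return float(np.polyfit(ks, means, 1)[0])


def ks_entropy(
    x, p: ChaosParams = ChaosParams(), _embedded=None
) -> tuple[float, bool]:
    """Kolmogorov-Sinai entropy: sum of positive Lyapunov exponents.

    The spectrum is estimated Eckmann-style: local linear (tangent-space)
    maps are fitted from nearest-neighbor displacements along the embedded
    trajectory and their product is QR-accumulated.  Exponents below the
    configured resolution floor count as zero.  Returns ``(value,
    fallback_used)``; on failure the estimate falls back to
    max(0, largest exponent by Rosenstein's method).
    """
    x = _as_series(x)
    dim = p.embed_dim
    try:
        Y, d0 = _embedded if _embedded is not None else _chaos_embedding(x, p)
        m = len(Y)
        k_nb = min(p.ks_neighbors, m - 2)
        if k_nb < dim + 1:
            raise ValueError("too few neighbors")
        d = d0[:-1, :-1].copy()
        ii, jj = np.indices(d.shape, sparse=True)
        d[np.abs(ii - jj) <= p.theiler_window] = np.inf
        t_idx = np.arange(0, m - 1, p.ks_step)
        dsub = d[t_idx]
        nbs = np.argpartition(dsub, k_nb, axis=1)[:, :k_nb]
        ok = np.all(
            np.isfinite(dsub[np.arange(len(t_idx))[:, None], nbs]), axis=1
        )
        t_idx, nbs = t_idx[ok], nbs[ok]
        if len(t_idx) < 10:
            raise ValueError("too few tangent-map steps")
        # batched ridge-regularized local Jacobians: Znext ~ Z @ A_t
        Z = Y[nbs] - Y[t_idx][:, None, :]
        Znext = Y[nbs + 1] - Y[t_idx + 1][:, None, :]
        G = np.einsum("tki,tkj->tij", Z, Z) + 1e-12 * np.eye(dim)
        B = np.einsum("tki,tkj->tij", Z, Znext)
        A_stack = np.linalg.solve(G, B)  # J_t = A_stack[t].T
        q = np.eye(dim)
        logsum = np.zeros(dim)
        steps = 0
        for A in A_stack:
            q, r = np.linalg.qr(A.T @ q)
            diag = np.abs(np.diag(r))
            if np.any(diag == 0):
                raise np.linalg.LinAlgError("rank-deficient tangent map")
            logsum += np.log(diag)
            steps += 1
        exponents = logsum / (steps * p.ks_step)
        hks = float(exponents[exponents > p.ks_positive_floor].sum())
        return hks, False
    except (ValueError, np.linalg.LinAlgError):
        lam = lyapunov_max(x, p)
        if math.isnan(lam):
            return float("nan"), True
        return max(0.0, lam), True


def correlation_dimension(x, p: ChaosParams = ChaosParams(), _embedded=None) -> float:
    """Correlation dimension D2 by the Grassberger-Procaccia method.

    The correlation sum C(r) counts pairs of embedded points closer than r
    (Theiler-corrected); D2 is the least-squares log-log slope over the
    scaling region, taken as the radii where C(r) lies in [0.05, 0.7]
    (small radii are dominated by the Theiler exclusion on short series).
    """
    x = _as_series(x)
    Y, d = _embedded if _embedded is not None else _chaos_embedding(x, p)
    m = len(Y)
    iu = np.triu_indices(m, k=p.theiler_window + 1)
    dists = d[iu]
    dists = dists[dists > 0]
    if len(dists) < 100:
        return float("nan")
    if p.radii is not None:
        radii = np.asarray(p.radii, dtype=float)
    else:
        lo, hi = np.percentile(dists, [0.5, 70.0])
        if lo <= 0 or hi <= lo:
            return float("nan")
        radii = np.geomspace(lo, hi, 20)
    c = np.searchsorted(np.sort(dists), radii, side="right") / len(dists)
    sel = (c >= 0.05) & (c <= 0.7)
    if sel.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log(radii[sel]), np.log(c[sel]), 1)[0])


def correlation_sum(x, radii, p: ChaosParams = ChaosParams()) -> np.ndarray:
    """C(r) for an explicit radii grid (Theiler-corrected pair fraction)."""
    x = _as_series(x)
    Y = _embed(x, p.embed_dim, p.embed_lag)
    d = cdist(Y, Y)
    iu = np.triu_indices(len(Y), k=p.theiler_window + 1)
    dists = np.sort(d[iu])
    return np.searchsorted(dists, np.asarray(radii, float), side="right") / len(dists)


# ---------------------------------------------------------------------------
# optional extra (appears in some EEG feature batteries; off by default)


def permutation_entropy(x, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy of ordinal patterns, in [0, 1]."""
    x = _as_series(x)
    T = _embed(x, order, delay)
    ranks = np.argsort(T, axis=1)
    _, counts = np.unique(ranks, axis=0, return_counts=True)
    prob = counts / counts.sum()
    h = -(prob * np.log2(prob)).sum()
    return float(h / math.log2(math.factorial(order)))


# ---------------------------------------------------------------------------
# vector assembly


def compute_nonlinear_vector(
    x,
    ep: EntropyParams = EntropyParams(),
    cp: ChaosParams = ChaosParams(),
    include_permutation: bool = False,
) -> NonlinearVector:
    """All twelve measures of one epoch channel, in fixed registry order.

    Undefined values are returned as NaN and named in ``flags`` — they are
    never silently zeroed.  ``include_permutation`` appends a 13th entry
    ("PermEn") for configurations that want the ordinal-pattern measure.
    """
    x = _as_series(x)
    values: dict[str, float] = {}
    flags: set[str] = set()

    constant = np.ptp(x) == 0
    if constant:
        # degenerate contract: entropies 0 where defined, NaN elsewhere
        values.update(
            ApEn=0.0, SampEn=float("nan"), MSE=float("nan"), FuzzyEn=0.0,
            KSEntropy=0.0, CorrDim=float("nan"), DFA=float("nan"),
            KatzFD=float("nan"), HiguchiFD=1.0, Hurst=float("nan"),
            Lyapunov=float("nan"), LZC=lempel_ziv(x),
        )
    else:
        emb = _chaos_embedding(x, cp)
        r_abs = ep.r * x.std()
        values["ApEn"] = approximate_entropy(x, ep)
        samp = _sample_entropy_abs(x, ep.m, r_abs, ep.tau)
        values["SampEn"] = samp
        # MSE: reuse the scale-1 value, coarse-grain only for scales > 1
        mse_vals = [
            samp if s == 1 else _sample_entropy_abs(coarse_grain(x, s), ep.m, r_abs, ep.tau)
            for s in ep.mse_scales
        ]
        mse_vals = [v for v in mse_vals if not math.isnan(v)]
        values["MSE"] = float(np.mean(mse_vals)) if mse_vals else float("nan")
        values["FuzzyEn"] = fuzzy_entropy(x, ep)
        hks, ks_fb = ks_entropy(x, cp, _embedded=emb)
        values["KSEntropy"] = hks
        if ks_fb:
            flags.add("KSEntropy:fallback")
        values["CorrDim"] = correlation_dimension(x, cp, _embedded=emb)
        try:
            values["DFA"] = dfa_exponent(x, cp)
        except ValueError:
            values["DFA"] = float("nan")
        values["KatzFD"] = katz_fd(x)
        values["HiguchiFD"] = higuchi_fd(x)
        try:
            values["Hurst"] = hurst_exponent(x)
        except ValueError:
            values["Hurst"] = float("nan")
        values["Lyapunov"] = lyapunov_max(x, cp, _embedded=emb)
        values["LZC"] = lempel_ziv(x)

    if include_permutation:
        values["PermEn"] = permutation_entropy(x)

    for name, v in values.items():
        if isinstance(v, float) and math.isnan(v):
            flags.add(name)
    return NonlinearVector(values=values, flags=flags)
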