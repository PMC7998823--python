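"""Single-scale entropy measures.

Histogram entropies (Shannon, Rényi, Tsallis), conditional and corrected
conditional entropy, the template-matching regularity family (ApEn,
SampEn, QSE, CoSEn, FuzzyEn, fSampEn), ordinal-pattern entropies (PE,
amplitude-aware PE, permutation min-entropy), dispersion entropy, bubble
entropy, slope entropy, distribution entropy, phase entropy,
Tone–Entropy for interval series, and entropy of entropy.

Conventions used throughout: tolerance r is a fraction of the SD of the
series handed to the operation (a multiscale wrapper may fix it at
scale 1 instead); template matching uses the Chebyshev distance with
"within tolerance" meaning d ≤ r_abs; ordinal ties are broken by order
of appearance (stable argsort).  Measures that can be undefined on a
valid input (SampEn with zero template matches) return NaN rather than
raising, so batch tables keep their alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .embedding import delay_embed

__all__ = [
    "shannon_like",
    "conditional_entropy",
    "regularity_family",
    "sample_entropy_counts",
    "ordinal_family",
    "dispersion_entropy",
    "dispersion_pattern_probs",
    "bubble_entropy",
    "slope_entropy",
    "distribution_entropy",
    "phase_entropy",
    "tone_entropy",
    "entropy_of_entropy",
]


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# histogram entropies


def shannon_like(x, kind: str = "shannon", bins: int = 64, q: float = 2.0) -> float:
    """Shannon, Rényi or Tsallis entropy (nats) of an equal-width histogram.

    Rényi: (1/(1−q))·ln Σ p^q; Tsallis: (1/(q−1))·(1 − Σ p^q); both
    reduce to Shannon as q → 1.  A constant series occupies one bin and
    returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("histogram entropy requires n >= 10")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    if kind == "shannon":
        return _shannon(p)
    if kind in ("renyi", "tsallis"):
        if q <= 0 or q == 1:
            raise ValueError("q must be positive and != 1")
        s = float(np.sum(p**q))
        if kind == "renyi":
            return math.log(s) / (1.0 - q)
        return (1.0 - s) / (q - 1.0)
    raise ValueError(f"unknown entropy kind {kind!r}")


# ---------------------------------------------------------------------------
# conditional entropy (Porta)


def _quantile_symbols(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(x, edges)


def _word_probs(sym: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    words = delay_embed(sym.astype(float), m, 1)
    _, inverse, counts = np.unique(words, axis=0, return_inverse=True, return_counts=True)
    return counts / counts.sum(), counts


def conditional_entropy(x, m: int = 2, bins: int = 6, corrected: bool = False) -> float:
    """Conditional entropy CE(m) = H(m-words) − H((m−1)-words), in nats.

    The series is coarse-grained to ``bins`` quantile levels.  The
    corrected form (CCE) adds perc(m)·H(1), where perc(m) is the
    fraction of m-words occurring exactly once — a bias correction for
    undersampled word distributions.
    """
    x = np.asarray(x, dtype=float)
    if m < 2:
        raise ValueError("conditional entropy requires m >= 2")
    if x.size < 10 * bins:
        raise ValueError(f"conditional entropy requires n >= {10 * bins}")
    sym = _quantile_symbols(x, bins)
    p_m, counts_m = _word_probs(sym, m)
    p_m1, _ = _word_probs(sym, m - 1)
    ce = _shannon(p_m) - _shannon(p_m1)
    if not corrected:
        return ce
    perc = float(np.mean(counts_m == 1))
    p1, _ = _word_probs(sym, 1)
    return ce + perc * _shannon(p1)


# ---------------------------------------------------------------------------
# regularity family (template matching, Chebyshev distance)


def sample_entropy_counts(x, m: int, r_abs: float) -> tuple[int, int]:
    """Template match counts (A, B) for sample entropy.

    B counts pairs of m-templates and A pairs of (m+1)-templates within
    Chebyshev distance ``r_abs`` (d ≤ r), self-matches excluded, both
    taken over the first n−m templates.  SampEn = −ln(A/B).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"sample entropy requires n >= m+2 = {m + 2}")
    tm = delay_embed(x, m, 1)[: n - m]
    tm1 = delay_embed(x, m + 1, 1)
    if n <= 1500:
        b = _pair_count_brute(tm, r_abs)
        a = _pair_count_brute(tm1, r_abs)
    else:
        b = _pair_count_tree(tm, r_abs)
        a = _pair_count_tree(tm1, r_abs)
    return a, b


def _pair_count_brute(t: np.ndarray, r: float) -> int:
    n = t.shape[0]
    count = 0
    chunk = max(1, int(4e6 // max(n, 1)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = np.max(np.abs(t[s:e, None, :] - t[None, :, :]), axis=2)
        mask = np.arange(n)[None, :] > np.arange(s, e)[:, None]
        count += int(np.count_nonzero((d <= r) & mask))
    return count


def _pair_count_tree(t: np.ndarray, r: float) -> int:
    tree = cKDTree(t)
    ordered = tree.count_neighbors(tree, r, p=np.inf)
    return (int(ordered) - t.shape[0]) // 2


def regularity_family(
    x,
    kind: str = "sampen",
    m: int = 2,
    r: float = 0.2,
    fuzzy_exponent: float = 2.0,
    envelope_window: int = 16,
    r_abs: Optional[float] = None,
) -> float:
    """ApEn / SampEn / QSE / CoSEn / FuzzyEn / fSampEn.

    ``r`` is a fraction of the SD of the input series; ``r_abs``
    overrides it with an absolute tolerance (used by multiscale wrappers
    that fix r at scale 1).  Returns NaN when no template matches exist
    (SampEn-style measures on highly irregular short series).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"requires n >= m+2 = {m + 2}")
    if kind == "fsampen":
        env = _moving_rms(x, envelope_window)
        return regularity_family(env, "sampen", m=m, r=r, r_abs=r_abs)
    if r_abs is None:
        sd = x.std()
        if sd == 0 and kind != "apen":
            return 0.0 if kind == "sampen" else math.nan
        r_abs = r * sd
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")

    if kind == "apen":
        return _apen(x, m, r_abs)
    if kind in ("sampen", "qse", "cosen"):
        a, b = sample_entropy_counts(x, m, r_abs)
        if a == 0 or b == 0:
            return math.nan
        sampen = -math.log(a / b)
        if kind == "sampen":
            return sampen
        qse = sampen + math.log(2 * r_abs)
        if kind == "qse":
            return qse
        mean = x.mean()
        if mean <= 0:
            return math.nan
        return qse - math.log(mean)
    if kind == "fuzzy":
        return _fuzzyen(x, m, r_abs, fuzzy_exponent)
    raise ValueError(f"unknown regularity kind {kind!r}")


def _apen(x: np.ndarray, m: int, r_abs: float) -> float:
    def phi(mm: int) -> float:
        t = delay_embed(x, mm, 1)
        tree = cKDTree(t)
        counts = tree.query_ball_point(t, r_abs, p=np.inf, return_length=True)
        return float(np.mean(np.log(counts / t.shape[0])))

    return phi(m) - phi(m + 1)


def _fuzzy_phi(t: np.ndarray, r_abs: float, p: float) -> float:
    t = t - t.mean(axis=1, keepdims=True)
    n = t.shape[0]
    total = 0.0
    chunk = max(1, int(4e6 // max(n, 1)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = np.max(np.abs(t[s:e, None, :] - t[None, :, :]), axis=2)
        mu = np.exp(-((d / r_abs) ** p))
        mask = np.arange(n)[None, :] > np.arange(s, e)[:, None]
        total += float(mu[mask].sum())
    pairs = n * (n - 1) / 2
    return total / pairs


def _fuzzyen(x: np.ndarray, m: int, r_abs: float, p: float) -> float:
    n = x.size
    tm = delay_embed(x, m, 1)[: n - m]
    tm1 = delay_embed(x, m + 1, 1)
    phi_m = _fuzzy_phi(tm, r_abs, p)
    phi_m1 = _fuzzy_phi(tm1, r_abs, p)
    if phi_m <= 0 or phi_m1 <= 0:
        return math.nan
    return math.log(phi_m) - math.log(phi_m1)


def _moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    if window < 2 or window > x.size:
        raise ValueError("envelope window must be in [2, n]")
    kernel = np.ones(window) / window
    ms = np.convolve(x**2, kernel, mode="valid")
    return np.sqrt(ms)


# ---------------------------------------------------------------------------
# ordinal family


def _ordinal_patterns(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    emb = delay_embed(x, m, tau)
    # stable argsort: ties broken by order of appearance
    ranks = np.argsort(emb, axis=1, kind="stable")
    base = m ** np.arange(m)
    return ranks @ base


def ordinal_family(x, kind: str = "pe", m: int = 3, tau: int = 1, aape_A: float = 0.5) -> float:
    """Normalized ordinal-pattern entropies in [0, 1].

    ``pe``: permutation entropy H(patterns)/ln(m!); ``pme``: permutation
    min-entropy −ln(max p)/ln(m!); ``aape``: amplitude-aware PE, each
    pattern occurrence weighted by A·mean|x| + (1−A)·mean|Δx| within the
    delay vector.
    """
    x = np.asarray(x, dtype=float)
    codes = _ordinal_patterns(x, m, tau)
    norm_const = math.log(math.factorial(m))
    if kind in ("pe", "pme"):
        _, counts = np.unique(codes, return_counts=True)
        p = counts / counts.sum()
        if kind == "pe":
            return _shannon(p) / norm_const
        return float(-math.log(p.max()) / norm_const)
    if kind == "aape":
        emb = delay_embed(x, m, tau)
        w = aape_A * np.mean(np.abs(emb), axis=1) + (1 - aape_A) * np.mean(
            np.abs(np.diff(emb, axis=1)), axis=1
        )
        if w.sum() == 0:
            return 0.0
        uniq = np.unique(codes)
        weights = np.array([w[codes == u].sum() for u in uniq])
        p = weights / weights.sum()
        return _shannon(p) / norm_const
    raise ValueError(f"unknown ordinal kind {kind!r}")


# ---------------------------------------------------------------------------
# dispersion entropy (Rostaghi & Azami)


def dispersion_pattern_probs(x, m: int = 2, c: int = 6, tau: int = 1) -> np.ndarray:
    """Probabilities of dispersion patterns (all c^m cells, many zero).

    The series is mapped through the normal CDF fitted to (mean, SD),
    partitioned into ``c`` equal classes, and delay vectors of class
    labels form the patterns.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("dispersion entropy undefined for a constant series")
    y = norm.cdf(x, loc=x.mean(), scale=sd)
    classes = np.clip(np.ceil(y * c), 1, c).astype(int)
    emb = delay_embed(classes.astype(float), m, tau).astype(int)
    codes = (emb - 1) @ (c ** np.arange(m))
    counts = np.bincount(codes, minlength=c**m)
    return counts / counts.sum()


def dispersion_entropy(x, m: int = 2, c: int = 6, tau: int = 1) -> tuple[float, float]:
    """Dispersion entropy in nats and its ln(c^m)-normalized form."""
    p = dispersion_pattern_probs(x, m, c, tau)
    de = _shannon(p)
    return de, de / math.log(float(c) ** m)


# ---------------------------------------------------------------------------
# bubble entropy (Manis)


def swap_count(v: np.ndarray) -> int:
    """Number of bubble-sort swaps (= inversions) needed to sort ``v``."""
    v = np.array(v, copy=True)
    n = v.size
    count = 0
    for i in range(n):
        for j in range(n - 1 - i):
            if v[j] > v[j + 1]:
                v[j], v[j + 1] = v[j + 1], v[j]
                count += 1
    return count


def _swap_counts_all(x: np.ndarray, m: int) -> np.ndarray:
    emb = delay_embed(x, m, 1)
    # inversions: pairs (i<j) with v_i > v_j
    i, j = np.triu_indices(m, k=1)
    return np.sum(emb[:, i] > emb[:, j], axis=1)


def _renyi2_of_counts(counts: np.ndarray) -> float:
    _, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    return float(-math.log(np.sum(p**2)))


def bubble_entropy(x, m: int = 10) -> float:
    """Bubble entropy (H_{m+1} − H_m) / ln((m+1)/(m−1)).

    H is the Rényi-2 entropy of the distribution of bubble-sort swap
    counts over delay vectors; rank-based, hence invariant under
    strictly monotone transforms of the input.
    """
    x = np.asarray(x, dtype=float)
    if m < 2:
        raise ValueError("bubble entropy requires m >= 2")
    if x.size < 3 * (m + 1):
        raise ValueError(f"bubble entropy requires n >= {3 * (m + 1)}")
    h_m = _renyi2_of_counts(_swap_counts_all(x, m))
    h_m1 = _renyi2_of_counts(_swap_counts_all(x, m + 1))
    return (h_m1 - h_m) / math.log((m + 1) / (m - 1))


# ---------------------------------------------------------------------------
# slope entropy (Cuesta-Frau)


def _slope_symbols(x: np.ndarray, delta: float, gamma: float) -> np.ndarray:
    d = np.diff(x)
    sym = np.zeros(d.size, dtype=int)
    sym[d > gamma] = 2
    sym[(d > delta) & (d <= gamma)] = 1
    sym[(d < -delta) & (d >= -gamma)] = -1
    sym[d < -gamma] = -2
    return sym


def slope_entropy(x, m: int = 2, delta: float = 0.001, gamma: float = 1.0) -> float:
    """Slope entropy: Shannon entropy (nats) of m-length words of
    5-class slope symbols (thresholds ±δ, ±γ on successive differences)."""
    if not (0 < delta < gamma):
        raise ValueError("thresholds must satisfy 0 < delta < gamma")
    x = np.asarray(x, dtype=float)
    if x.size < m + 1:
        raise ValueError(f"slope entropy requires n >= m+1 = {m + 1}")
    sym = _slope_symbols(x, delta, gamma)
    p, _ = _word_probs(sym, m)
    return _shannon(p)


# ---------------------------------------------------------------------------
# distribution entropy (Li)


def distribution_entropy(x, m: int = 2, bins: int = 64) -> float:
    """Distribution entropy in [0, 1]: normalized Shannon entropy of the
    histogram of all pairwise Chebyshev template distances."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"distribution entropy requires n >= m+2 = {m + 2}")
    t = delay_embed(x, m, 1)
    n = t.shape[0]
    if n < 2:
        raise ValueError("need at least two templates")
    dists = []
    chunk = max(1, int(4e6 // max(n, 1)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = np.max(np.abs(t[s:e, None, :] - t[None, :, :]), axis=2)
        mask = np.arange(n)[None, :] > np.arange(s, e)[:, None]
        dists.append(d[mask])
    d = np.concatenate(dists)
    top = d.max()
    if top == 0:
        return 0.0
    counts, _ = np.histogram(d, bins=bins, range=(0, top))
    p = counts[counts > 0] / counts.sum()
    return _shannon(p) / math.log(bins)


# ---------------------------------------------------------------------------
# phase entropy (Rohila & Sharma)


def phase_entropy(x, k_sectors: int = 16) -> float:
    """Phase entropy of the second-order difference plot, in [0, 1].

    Points (Δx_i, Δx_{i+1}) are assigned to ``k_sectors`` equal angular
    sectors weighted by radial magnitude; the normalized Shannon entropy
    of the sector weights is returned.  Isotropic scatter gives ≈1, a
    monotone ramp 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < k_sectors + 2:
        raise ValueError(f"phase entropy requires n >= k_sectors+2")
    d = np.diff(x)
    u, v = d[:-1], d[1:]
    r = np.hypot(u, v)
    keep = r > 0
    if not keep.any():
        raise ValueError("phase entropy undefined: all successive differences zero")
    theta = np.arctan2(v[keep], u[keep])  # [-pi, pi)
    sector = np.floor((theta + math.pi) / (2 * math.pi) * k_sectors).astype(int)
    sector = np.clip(sector, 0, k_sectors - 1)
    weights = np.bincount(sector, weights=r[keep], minlength=k_sectors)
    p = weights / weights.sum()
    return _shannon(p) / math.log(k_sectors)


# ---------------------------------------------------------------------------
# Tone-Entropy (Oida)


@dataclass(frozen=True)
class ToneEntropy:
    tone: float
    entropy: float  # bits
    tone_reliable: bool  # needs >= 250 points
    entropy_reliable: bool  # needs >= 50 points


def tone_entropy(x) -> ToneEntropy:
    """Tone and Entropy of the percentage index of an interval series.

    PI_i = 100·(x_i − x_{i+1})/x_i; tone is the mean PI (an
    acceleration–deceleration balance) and entropy the Shannon entropy
    in bits of PI binned into unit-percent bins.  Tone is flagged
    unreliable below 250 points, entropy below 50.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 50:
        raise ValueError("Tone-Entropy requires n >= 50")
    if np.any(x <= 0):
        raise ValueError("intervals must be strictly positive")
    pi = 100.0 * (x[:-1] - x[1:]) / x[:-1]
    tone = float(pi.mean())
    bins = np.floor(pi).astype(int)
    _, counts = np.unique(bins, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-np.sum(p * np.log2(p)))
    return ToneEntropy(
        tone=tone,
        entropy=entropy,
        tone_reliable=x.size >= 250,
        entropy_reliable=x.size >= 50,
    )


# ---------------------------------------------------------------------------
# entropy of entropy (Hsu)


def entropy_of_entropy(x, window_w: int = 5, state_levels: int = 4) -> float:
    """Two-stage entropy of entropy.

    Stage 1: within consecutive windows of length ``window_w``, Shannon
    entropy of a ``state_levels``-level amplitude discretisation (levels
    fixed over the whole series range).  Stage 2: Shannon entropy (nats)
    of the distribution of the distinct window-entropy values.
    """
    x = np.asarray(x, dtype=float)
    if window_w < 2:
        raise ValueError("window length must be >= 2")
    if x.size < 2 * window_w:
        raise ValueError("series too short for entropy of entropy")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    levels = np.clip(
        np.floor((x - lo) / (hi - lo) * state_levels).astype(int), 0, state_levels - 1
    )
    k = x.size // window_w
    win = levels[: k * window_w].reshape(k, window_w)
    ents = np.empty(k)
    for i in range(k):
        counts = np.bincount(win[i], minlength=state_levels)
        ents[i] = _shannon(counts[counts > 0] / window_w)
    cats = np.round(ents, 12)
    _, counts = np.unique(cats, return_counts=True)
    p = counts / counts.sum()
    return _shannon(p)
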