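"""State-space reconstruction and embedding-parameter estimation.

A scalar series x is embedded as delay vectors
(x[i], x[i+τ], …, x[i+(m−1)τ]).  The delay τ is conventionally chosen
at the first minimum of the average mutual information (AMI) or the
first 1/e crossing of the autocorrelation; the dimension m by the
false-nearest-neighbours (FNN) criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "delay_embed",
    "average_mutual_information",
    "false_nearest_neighbors",
    "autocorrelation_delay",
]


@dataclass(frozen=True)
class EmbeddingParams:
    m: int
    tau: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("embedding dimension and delay must be >= 1")


def delay_embed(x, m: int, tau: int = 1) -> np.ndarray:
    """Return the (n − (m−1)τ) × m matrix of delay vectors."""
    x = np.asarray(x, dtype=float)
    EmbeddingParams(m, tau)
    n = x.size
    rows = n - (m - 1) * tau
    if rows < 2:
        raise ValueError(
            f"series too short for m={m}, tau={tau}: need at least "
            f"{(m - 1) * tau + 2} points, got {n}"
        )
    if m == 1:
        return x[:, None].copy()
    # sliding windows over the strided view give the delay vectors
    return sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau].copy()


@dataclass(frozen=True)
class AMIResult:
    lags: np.ndarray
    ami: np.ndarray  # nats
    first_minimum: int
    minimum_found: bool


def _hist_mi(x: np.ndarray, y: np.ndarray, bins: int, lo: float, hi: float) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=bins, range=[[lo, hi], [lo, hi]])
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def average_mutual_information(x, max_lag: int = 50, bins: int = 16) -> AMIResult:
    """AMI(ℓ) between x[t] and x[t+ℓ] from a bins×bins equal-width histogram.

    Reports the first local minimum of the curve; when none exists the
    last lag is returned with ``minimum_found=False``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * bins:
        raise ValueError(f"need at least {10 * bins} samples for {bins} bins")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("AMI undefined for a constant series (zero-width bins)")
    lags = np.arange(1, max_lag + 1)
    ami = np.array([_hist_mi(x[:-l], x[l:], bins, lo, hi) for l in lags])
    first_min, found = max_lag, False
    for i in range(1, len(ami)):
        if ami[i] > ami[i - 1]:
            first_min, found = i - 1, True
            break
    if found:
        # flat valleys (e.g. periodic signals) are reported at their centre
        tol = 0.02 * (ami.max() - ami.min())
        j = first_min
        while j + 1 < len(ami) and ami[j + 1] <= ami[first_min] + tol:
            j += 1
        first_min = int(lags[int(round((first_min + j) / 2))])
    else:
        first_min = int(lags[-1])
    return AMIResult(lags=lags, ami=ami, first_minimum=first_min, minimum_found=found)


def marginal_entropy(x, bins: int = 16) -> float:
    """Shannon entropy (nats) of the equal-width marginal histogram; equals AMI at lag 0."""
    x = np.asarray(x, dtype=float)
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


@dataclass(frozen=True)
class FNNResult:
    m_values: np.ndarray
    fraction: np.ndarray
    suggested_m: int
    converged: bool


def false_nearest_neighbors(
    x, tau: int = 1, m_max: int = 10, rtol: float = 15.0, atol: float = 2.0
) -> FNNResult:
    """Kennel-style false-nearest-neighbour fractions for m = 1..m_max.

    A neighbour is false when the extra coordinate added at m+1 moves it
    away by more than ``rtol`` times the current distance, or when the
    new distance exceeds ``atol`` × SD(x).  The suggested dimension is
    the first m with fraction < 1% (else m_max, flagged).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError("FNN requires at least 100 samples")
    sd = x.std()
    m_values = np.arange(1, m_max + 1)
    fractions = np.zeros(m_max)
    for mi, m in enumerate(m_values):
        emb = delay_embed(x, m, tau)
        # rows for which the (m+1)-th coordinate exists
        n_ok = x.size - m * tau
        if n_ok < 2:
            fractions[mi] = np.nan
            continue
        emb = emb[:n_ok]
        # nearest neighbour by Euclidean distance, excluding self
        tree = cKDTree(emb)
        dist, nn = tree.query(emb, k=2)
        dist, nn = dist[:, 1], nn[:, 1]
        extra = np.abs(x[np.arange(n_ok) + m * tau] - x[nn + m * tau])
        new_dist = np.sqrt(dist**2 + extra**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, extra / dist, np.inf)
        false = (ratio > rtol) | (new_dist > atol * sd)
        fractions[mi] = false.mean()
    below = np.flatnonzero(fractions < 0.01)
    if below.size:
        return FNNResult(m_values, fractions, int(m_values[below[0]]), True)
    return FNNResult(m_values, fractions, int(m_max), False)


@dataclass(frozen=True)
class ACFResult:
    lags: np.ndarray
    acf: np.ndarray
    crossing_lag: int
    crossed: bool


def autocorrelation_delay(x, max_lag: int = 50) -> ACFResult:
    """Biased-normalisation autocorrelation and its first 1/e crossing."""
    x = np.asarray(x, dtype=float)
    if x.size <= max_lag + 1:
        raise ValueError("series must be longer than max_lag + 1")
    xc = x - x.mean()
    var = np.dot(xc, xc)
    if var == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    full = np.correlate(xc, xc, mode="full")[x.size - 1 :]
    acf = full[: max_lag + 1] / var
    lags = np.arange(max_lag + 1)
    below = np.flatnonzero(acf < 1.0 / np.e)
    if below.size:
        return ACFResult(lags, acf, int(lags[below[0]]), True)
    return ACFResult(lags, acf, int(max_lag), False)
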