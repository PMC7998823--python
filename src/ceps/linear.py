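"""Descriptive, linear and time-domain measures.

Mean, SD, CV, bias-corrected skewness and excess kurtosis, OLS trend,
RMSSD, Hjorth activity/mobility/complexity and the biased autocovariance
at lags 1..L.  These form the linear block of the standard battery and
serve as reference points for the nonlinear measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "descriptive_stats",
    "trend_fit",
    "rmssd",
    "hjorth_params",
    "autocovariance_lags",
]


@dataclass(frozen=True)
class Descriptives:
    mean: float
    sd: float
    cv: float  # nan when mean == 0
    skewness: float
    kurtosis: float  # excess


def descriptive_stats(x) -> Descriptives:
    """Sample mean, SD (n−1), CV, adjusted skewness and excess kurtosis.

    CV is reported as NaN (undefined) when the mean is zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("descriptive statistics require n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = sd / mean if mean != 0 else math.nan
    skew = float(stats.skew(x, bias=False)) if x.size > 2 else math.nan
    kurt = float(stats.kurtosis(x, bias=False, fisher=True)) if x.size > 3 else math.nan
    return Descriptives(mean=mean, sd=sd, cv=cv, skewness=skew, kurtosis=kurt)


def trend_fit(x) -> tuple[float, float]:
    """OLS slope and intercept of value against 0-based sample index."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("trend fit requires n >= 2")
    t = np.arange(x.size, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return float(slope), float(intercept)


def rmssd(x) -> float:
    """Root mean square of successive differences (ms for RRi input)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("RMSSD requires n >= 2")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


@dataclass(frozen=True)
class Hjorth:
    activity: float
    mobility: float
    complexity: float


def hjorth_params(x) -> Hjorth:
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sqrt(var(Δx)/var(x));
    complexity = mobility(Δx)/mobility(x), with first differences as the
    derivative surrogate.  A pure sinusoid has complexity 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Hjorth parameters require n >= 3")
    var0 = x.var()
    if var0 == 0:
        raise ValueError("Hjorth parameters undefined for a constant series")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var1, var2 = d1.var(), d2.var()
    mobility = math.sqrt(var1 / var0)
    mobility_d = math.sqrt(var2 / var1) if var1 > 0 else math.nan
    return Hjorth(
        activity=float(var0),
        mobility=float(mobility),
        complexity=float(mobility_d / mobility) if mobility > 0 else math.nan,
    )


def autocovariance_lags(x, L: int = 20) -> np.ndarray:
    """Biased autocovariance (1/n)Σ(x_t−x̄)(x_{t+ℓ}−x̄) at lags 1..L."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= L + 1:
        raise ValueError(f"need n > L+1 = {L + 1} samples, got {n}")
    xc = x - x.mean()
    full = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    return full[1 : L + 1].copy()
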