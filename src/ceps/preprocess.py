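"""Optional signal conditioning before measure computation.

Outlier removal (z-score or percentile rule, samples deleted — the
interval-series convention), zero-phase Butterworth filtering, seedable
white/pink noise injection, min-max / z-score rescaling, linear
detrending, trimming, and cubic-spline resampling of interval series to
a uniform grid (4 Hz is the common HRV choice).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import interpolate, signal as sps

from .signal import Signal

__all__ = [
    "remove_outliers",
    "filter_signal",
    "add_noise",
    "rescale_detrend",
    "trim",
    "resample_interpolate",
]


def remove_outliers(signal: Signal, rule: str) -> tuple[Signal, np.ndarray]:
    """Delete outlying samples and report their indices.

    ``rule`` is ``"none"``, ``"z:K"`` (|x−mean|/SD > K removed) or
    ``"percentile:LO,HI"`` (samples outside the empirical [LO, HI]
    percentile band removed).  Bounds are computed on the input and
    applied once, so the percentile rule is idempotent.
    """
    x = signal.values
    if rule == "none":
        return signal, np.array([], dtype=int)
    if len(x) < 3:
        raise ValueError("outlier removal requires at least 3 samples")
    if rule.startswith("z:"):
        k = float(rule[2:])
        sd = x.std()
        if sd == 0:
            warnings.warn("constant series: z-score outlier rule removes nothing")
            return signal, np.array([], dtype=int)
        keep = np.abs(x - x.mean()) / sd <= k
    elif rule.startswith("percentile:"):
        lo, hi = (float(v) for v in rule.split(":", 1)[1].split(","))
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentile bounds must satisfy 0 <= lo < hi <= 100")
        plo, phi = np.percentile(x, [lo, hi])
        keep = (x >= plo) & (x <= phi)
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    removed = np.flatnonzero(~keep)
    if removed.size == len(x):
        raise ValueError("outlier rule removed every sample")
    return signal.with_values(x[keep]), removed


def filter_signal(
    signal: Signal,
    kind: str,
    cutoffs_hz: float | Sequence[float],
    order: int = 4,
) -> Signal:
    """Zero-phase Butterworth filter (forward-backward ``filtfilt``).

    ``kind`` is lowpass, highpass or bandpass.  Requires a sampled time
    series; resample interval data first (:func:`resample_interpolate`).
    """
    if not signal.is_time_series:
        raise ValueError(
            "filtering requires a sampled time series; resample interval data "
            "with resample_interpolate first"
        )
    nyq = signal.sample_rate_hz / 2.0
    cut = np.atleast_1d(np.asarray(cutoffs_hz, dtype=float))
    if kind == "bandpass":
        if cut.size != 2:
            raise ValueError("bandpass needs (low, high) cutoffs")
        if cut[0] >= cut[1]:
            raise ValueError("bandpass low cutoff must be below high cutoff")
    elif kind in ("lowpass", "highpass"):
        if cut.size != 1:
            raise ValueError(f"{kind} needs a single cutoff")
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise ValueError(f"cutoffs must lie strictly inside (0, Nyquist={nyq} Hz)")
    wn = cut / nyq if kind == "bandpass" else float(cut[0] / nyq)
    sos = sps.butter(order, wn, btype=kind.replace("pass", ""), output="sos")
    y = sps.sosfiltfilt(sos, signal.values)
    return signal.with_values(y)


def add_noise(signal: Signal, kind: str, fraction_of_sd: float, seed: int) -> Signal:
    """Add white or pink (1/f) noise scaled to a fraction of the signal SD."""
    if fraction_of_sd < 0:
        raise ValueError("noise fraction must be >= 0")
    if kind not in ("white", "pink", "none"):
        raise ValueError(f"unknown noise kind {kind!r}")
    if kind == "none" or fraction_of_sd == 0:
        return signal
    from .synthetic import gen_noise  # local import to avoid cycle

    n = len(signal)
    noise = gen_noise(kind, n, seed)  # unit variance
    target_sd = fraction_of_sd * signal.values.std()
    return signal.with_values(signal.values + target_sd * noise)


def rescale_detrend(signal: Signal, rescale: str = "none", detrend: str = "none") -> Signal:
    """Apply linear detrending and/or min-max / z-score rescaling.

    Detrending (least-squares line removal) runs before rescaling.
    """
    x = signal.values.copy()
    if detrend == "linear":
        t = np.arange(len(x), dtype=float)
        slope, intercept = np.polyfit(t, x, 1)
        x = x - (slope * t + intercept)
    elif detrend != "none":
        raise ValueError(f"unknown detrend {detrend!r}")
    if rescale == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("min-max rescaling undefined for a constant series")
        x = (x - lo) / (hi - lo)
    elif rescale == "zscore":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("z-score rescaling undefined for a constant series")
        x = (x - x.mean()) / sd
    elif rescale != "none":
        raise ValueError(f"unknown rescale {rescale!r}")
    return signal.with_values(x)


def trim(signal: Signal, leading: int = 0, trailing: int = 0) -> Signal:
    """Drop ``leading``/``trailing`` samples from the ends."""
    if leading < 0 or trailing < 0:
        raise ValueError("trim counts must be >= 0")
    n = len(signal)
    if leading + trailing >= n:
        raise ValueError("trim would remove the entire series")
    stop = n - trailing if trailing else n
    return signal.with_values(signal.values[leading:stop])


def resample_interpolate(
    signal: Signal, target_rate_hz: float = 4.0, method: str = "cubic_spline"
) -> Signal:
    """Resample an event-interval series to a uniform grid.

    Event times are the cumulative sum of the intervals; a piecewise
    cubic spline of interval value against event time is evaluated on a
    uniform grid at ``target_rate_hz``.  The result is a sampled time
    series, suitable e.g. as a basis for frequency-domain analysis.
    """
    if method != "cubic_spline":
        raise ValueError(f"unknown resampling method {method!r}")
    x = signal.values
    if len(x) < 4:
        raise ValueError("resampling needs at least 4 intervals")
    if np.any(x <= 0):
        raise ValueError("intervals must be strictly positive")
    # treat values as ms when they look like RRi (mean > 10); grid in the
    # same time unit as the cumulative sum divided into seconds
    unit = 1000.0 if x.mean() > 10 else 1.0  # ms vs s heuristic
    times_s = np.cumsum(x) / unit
    spline = interpolate.CubicSpline(times_s, x)
    grid = np.arange(times_s[0], times_s[-1], 1.0 / target_rate_hz)
    y = spline(grid)
    return Signal(
        values=y,
        sample_rate_hz=target_rate_hz,
        is_time_series=True,
        label=signal.label + "@resampled",
        source=signal.source,
    )
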