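"""Coarse-graining and multiscale wrappers.

Multiscale entropy (MSE) applies a base measure to block-averaged
copies of the series at scales 1..s_max.  Refined-composite variants
(RCmSE, RCmFE, RCmDE) average the match counts / pattern probabilities
over the s offset-shifted coarse-grainings of each scale before taking
the logarithm, which stabilises short-series estimates; improved
(overlapping) multiscale PE (ImPE) averages the PE values over offsets.

For SampEn-based curves the tolerance policy matters: ``fixed_at_scale1``
(the Costa convention, default) computes r once from the original
series; ``per_scale`` recomputes it from each coarse-grained series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import entropy as ent

__all__ = [
    "ScaleGrid",
    "coarse_grain",
    "coarse_grain_offset",
    "multiscale_apply",
    "mse",
    "rcmse",
    "rcmfe",
    "rcmde",
    "impe",
]


@dataclass(frozen=True)
class ScaleGrid:
    scales: tuple[int, ...] = tuple(range(1, 11))
    variant: str = "coarse"  # coarse | refined_composite | improved_overlapping
    r_policy: str = "fixed_at_scale1"  # or per_scale

    def __post_init__(self) -> None:
        if not self.scales or min(self.scales) < 1:
            raise ValueError("scales must be positive integers")
        if self.variant not in ("coarse", "refined_composite", "improved_overlapping"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.r_policy not in ("fixed_at_scale1", "per_scale"):
            raise ValueError(f"unknown r_policy {self.r_policy!r}")


def coarse_grain(x, scale: int) -> np.ndarray:
    """Non-overlapping block means of length ``scale`` (remainder dropped)."""
    x = np.asarray(x, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale == 1:
        return x.copy()
    k = x.size // scale
    if k < 2:
        raise ValueError(f"series too short for scale {scale}")
    return x[: k * scale].reshape(k, scale).mean(axis=1)


def coarse_grain_offset(x, scale: int, offset: int) -> np.ndarray:
    """Coarse-graining starting at sample ``offset`` (0 <= offset < scale)."""
    x = np.asarray(x, dtype=float)
    if not 0 <= offset < scale:
        raise ValueError("offset must satisfy 0 <= offset < scale")
    return coarse_grain(x[offset:], scale)


def multiscale_apply(
    x, measure: Callable[[np.ndarray], float], scales: Sequence[int]
) -> np.ndarray:
    """Apply ``measure`` to the coarse-grained series at each scale.

    A scale at which the measure is undefined (raises, or returns NaN)
    yields NaN in the curve rather than aborting, so scale curves stay
    alignable across files.
    """
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        try:
            out[i] = measure(coarse_grain(x, s))
        except (ValueError, ZeroDivisionError):
            out[i] = math.nan
    return out


def mse(
    x,
    m: int = 2,
    r: float = 0.15,
    scales: Sequence[int] = range(1, 11),
    r_policy: str = "fixed_at_scale1",
) -> np.ndarray:
    """Multiscale sample entropy (Costa): SampEn of each coarse-graining."""
    x = np.asarray(x, dtype=float)
    r_abs = r * x.std() if r_policy == "fixed_at_scale1" else None

    def measure(y: np.ndarray) -> float:
        return ent.regularity_family(y, "sampen", m=m, r=r, r_abs=r_abs)

    return multiscale_apply(x, measure, scales)


def rcmse(
    x,
    m: int = 2,
    r: float = 0.15,
    scales: Sequence[int] = range(1, 11),
    r_policy: str = "fixed_at_scale1",
) -> np.ndarray:
    """Refined-composite multiscale sample entropy (Wu).

    At each scale the template match counts A and B are accumulated over
    all offset coarse-grainings before −ln(ΣA/ΣB); at scale 1 this
    equals plain SampEn exactly.
    """
    x = np.asarray(x, dtype=float)
    r_fixed = r * x.std() if r_policy == "fixed_at_scale1" else None
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        a_tot = b_tot = 0
        try:
            for off in range(s):
                y = coarse_grain_offset(x, s, off)
                r_abs = r_fixed if r_fixed is not None else r * y.std()
                a, b = ent.sample_entropy_counts(y, m, r_abs)
                a_tot += a
                b_tot += b
            out[i] = -math.log(a_tot / b_tot) if a_tot and b_tot else math.nan
        except ValueError:
            out[i] = math.nan
    return out


def rcmfe(
    x,
    m: int = 2,
    r: float = 0.2,
    scales: Sequence[int] = range(1, 11),
    fuzzy_exponent: float = 2.0,
    r_policy: str = "fixed_at_scale1",
) -> np.ndarray:
    """Refined-composite multiscale fuzzy entropy (Azami).

    Fuzzy membership totals φ_m and φ_{m+1} are averaged over offset
    coarse-grainings before the log ratio.  The membership width is
    σ = r × SD, with SD from scale 1 by default.
    """
    x = np.asarray(x, dtype=float)
    r_fixed = r * x.std() if r_policy == "fixed_at_scale1" else None
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        try:
            phis_m, phis_m1 = [], []
            for off in range(s):
                y = coarse_grain_offset(x, s, off)
                r_abs = r_fixed if r_fixed is not None else r * y.std()
                n = y.size
                if n < m + 2 or r_abs <= 0:
                    raise ValueError("scale too coarse")
                tm = ent.delay_embed(y, m, 1)[: n - m]
                tm1 = ent.delay_embed(y, m + 1, 1)
                phis_m.append(ent._fuzzy_phi(tm, r_abs, fuzzy_exponent))
                phis_m1.append(ent._fuzzy_phi(tm1, r_abs, fuzzy_exponent))
            pm, pm1 = np.mean(phis_m), np.mean(phis_m1)
            out[i] = math.log(pm) - math.log(pm1) if pm > 0 and pm1 > 0 else math.nan
        except ValueError:
            out[i] = math.nan
    return out


def rcmde(
    x,
    m: int = 2,
    c: int = 6,
    tau: int = 1,
    scales: Sequence[int] = range(1, 11),
) -> np.ndarray:
    """Refined-composite multiscale dispersion entropy (Azami).

    Dispersion-pattern probabilities are averaged over the offset
    coarse-grainings of each scale; the Shannon entropy of the averaged
    distribution is reported in nats.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        try:
            probs = [
                ent.dispersion_pattern_probs(coarse_grain_offset(x, s, off), m, c, tau)
                for off in range(s)
            ]
            p = np.mean(probs, axis=0)
            p = p[p > 0]
            out[i] = float(-np.sum(p * np.log(p)))
        except ValueError:
            out[i] = math.nan
    return out


def impe(
    x,
    m: int = 3,
    tau: int = 1,
    scales: Sequence[int] = range(1, 11),
) -> np.ndarray:
    """Improved multiscale permutation entropy: mean normalized PE over
    the offset coarse-grainings of each scale."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        try:
            vals = [
                ent.ordinal_family(coarse_grain_offset(x, s, off), "pe", m=m, tau=tau)
                for off in range(s)
            ]
            out[i] = float(np.mean(vals))
        except ValueError:
            out[i] = math.nan
    return out
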