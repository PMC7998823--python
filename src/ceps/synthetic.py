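"""Seedable synthetic-signal generators.

Reference noises (white, pink, brown), exact fractional Gaussian noise
and Brownian motion via circulant embedding, chaotic and mixed-process
map series (logistic map, Pincus's MIX), and a two-condition generator
of paired RR-interval and breath-interval series emulating a paced
(7 breaths/min) versus normal-breathing protocol of 300-s trials.

The RRi generator is an additive-oscillation model (baseline interval
plus LF and respiratory HF oscillations plus white jitter), not a
closed-loop cardiovascular model: it reproduces the lengths, rates and
direction-of-change behaviour of short paced-breathing recordings, not
their full physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "gen_noise",
    "gen_fgn",
    "gen_fbm",
    "gen_logistic",
    "gen_mix",
    "gen_rri",
    "RRiRecord",
]


def gen_noise(kind: str, n: int, seed: int) -> np.ndarray:
    """Unit-variance noise: white (i.i.d. Gaussian) or pink/brown
    (spectral synthesis with power ∝ f^−β, β = 1, 2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "white":
        return rng.standard_normal(n)
    if kind in ("pink", "brown"):
        beta = 1.0 if kind == "pink" else 2.0
        freqs = np.fft.rfftfreq(n)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** (-beta / 2)
        phases = rng.uniform(0, 2 * math.pi, freqs.size)
        spec = amp * np.exp(1j * phases)
        # real-signal (Hermitian) constraints on the edge bins
        spec[0] = 0.0
        if n % 2 == 0:
            spec[-1] = spec[-1].real
        x = np.fft.irfft(spec, n=n)
        sd = x.std()
        if sd == 0:
            raise ValueError("degenerate spectral synthesis")
        return x / sd
    raise ValueError(f"unknown noise kind {kind!r}")


def _fgn_autocov(k: np.ndarray, H: float) -> np.ndarray:
    return 0.5 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


def gen_fgn(H: float, n: int, seed: int) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    The circulant embedding of the fGn autocovariance
    γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) has non-negative
    eigenvalues for H ∈ (0, 1); sampling in the spectral domain then
    gives a Gaussian series with exactly that covariance (unit variance).
    """
    if not 0 < H < 1:
        raise ValueError("H must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    m = 2 * n
    gamma = _fgn_autocov(np.arange(n + 1, dtype=float), H)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    eig = np.fft.fft(row).real
    if np.min(eig) < -1e-8:
        raise ValueError("circulant embedding failed; try a larger n")
    eig = np.clip(eig, 0, None)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(eig / (2 * m)) * z)
    return w[:n].real * math.sqrt(2)


def gen_fbm(H: float, n: int, seed: int) -> np.ndarray:
    """Fractional Brownian motion: cumulative sum of exact fGn."""
    return np.cumsum(gen_fgn(H, n, seed))


def gen_logistic(n: int, seed: int, r: float = 4.0, burn_in: int = 1000) -> np.ndarray:
    """Logistic-map trajectory x_{t+1} = r·x_t(1−x_t), burn-in discarded."""
    if not 0 < r <= 4:
        raise ValueError("r must lie in (0, 4]")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.1, 0.9)
    out = np.empty(n)
    for t in range(burn_in + n):
        x = r * x * (1.0 - x)
        if t >= burn_in:
            out[t - burn_in] = x
    return out


def gen_mix(p: float, n: int, seed: int, period: int = 12) -> np.ndarray:
    """Pincus's MIX(p) process: a sine wave with each sample replaced by
    uniform noise with probability p.  MIX(0) is purely periodic,
    MIX(1) i.i.d. uniform; ApEn increases with p."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    x = math.sqrt(2) * np.sin(2 * math.pi * t / period)
    mask = rng.uniform(size=n) < p
    noise = rng.uniform(-math.sqrt(3), math.sqrt(3), size=n)
    x[mask] = noise[mask]
    return x


@dataclass(frozen=True)
class RRiRecord:
    rri_ms: np.ndarray  # beat-to-beat intervals
    bbi_s: np.ndarray  # breath-to-breath intervals
    condition: str


# Generator defaults: a 300-s trial at a ~64 bpm resting heart rate gives
# ~320 beats; normal breathing sits near 0.25 Hz with breath-to-breath
# variability, paced breathing at 7 cycles/min (0.1167 Hz) is regular and
# carries a strongly amplified respiratory sinus arrhythmia, as slow
# guided breathing does.
_BASE_RR_MS = 937.5
_LF_FREQ_HZ = 0.095
_LF_AMP_MS = 30.0
_HF_AMP_NORMAL_MS = 25.0
_HF_AMP_PACED_MS = 90.0
_JITTER_SD_MS = 15.0
_PACED_BREATH_S = 60.0 / 7.0
_NORMAL_BREATH_MEAN_S = 6.2
_NORMAL_BREATH_SUBJECT_SD_S = 1.2
_NORMAL_BREATH_CYCLE_CV = 0.12
_PACED_BREATH_CYCLE_CV = 0.02


def gen_rri(
    condition: str,
    duration_s: float = 300.0,
    seed: int = 0,
    mean_rr_ms: float = _BASE_RR_MS,
) -> RRiRecord:
    """Generate a paired RRi + BBi recording for one trial.

    Beat times are obtained by integrating an instantaneous RR interval
    composed of the baseline, an LF (Mayer-wave) oscillation, a
    respiratory HF oscillation locked to the breathing phase, and white
    jitter.  Mean heart rate is identical across conditions; only the
    variability structure changes.
    """
    if condition not in ("normal", "paced_7bpm"):
        raise ValueError(f"unknown condition {condition!r}")
    if duration_s <= 10:
        raise ValueError("duration must exceed 10 s")
    rng = np.random.default_rng(seed)

    # breathing cycle intervals for the whole trial
    if condition == "paced_7bpm":
        breath_mean = _PACED_BREATH_S
        cycle_cv = _PACED_BREATH_CYCLE_CV
        hf_amp = _HF_AMP_PACED_MS
    else:
        breath_mean = max(
            2.5, rng.normal(_NORMAL_BREATH_MEAN_S, _NORMAL_BREATH_SUBJECT_SD_S)
        )
        cycle_cv = _NORMAL_BREATH_CYCLE_CV
        hf_amp = _HF_AMP_NORMAL_MS
    breaths = []
    t = 0.0
    while t < duration_s + breath_mean:
        b = max(1.0, rng.normal(breath_mean, cycle_cv * breath_mean))
        breaths.append(b)
        t += b
    bbi = np.array(breaths)
    breath_onsets = np.concatenate([[0.0], np.cumsum(bbi)])

    lf_phase = rng.uniform(0, 2 * math.pi)

    def breath_phase(time_s: float) -> float:
        i = int(np.searchsorted(breath_onsets, time_s, side="right")) - 1
        i = min(max(i, 0), bbi.size - 1)
        return 2 * math.pi * (time_s - breath_onsets[i]) / bbi[i]

    # integrate beat times over the instantaneous interval
    rri = []
    t = 0.0
    while True:
        rr = (
            mean_rr_ms
            + _LF_AMP_MS * math.sin(2 * math.pi * _LF_FREQ_HZ * t + lf_phase)
            + hf_amp * math.sin(breath_phase(t))
            + rng.normal(0.0, _JITTER_SD_MS)
        )
        rr = max(300.0, rr)
        if t + rr / 1000.0 > duration_s:
            break
        rri.append(rr)
        t += rr / 1000.0
    bbi_trial = bbi[np.cumsum(bbi) <= duration_s]
    return RRiRecord(rri_ms=np.array(rri), bbi_s=bbi_trial, condition=condition)
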