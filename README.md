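# ceps — complexity and entropy measures for physiological signals

`ceps` is a scriptable Python library (with a thin CLI) for quantifying
the nonlinear dynamics of univariate physiological time series: RR
intervals from ECG, pulse intervals from PPG, breath-to-breath
intervals from respiration, or EEG-like sampled signals. It is aimed at
researchers who want to run a *battery* of complexity and entropy
measures over a set of recordings — not just one index — and then ask,
statistically, which measures moved between two conditions.

## What it computes

**Complexity estimators** — Higuchi and Katz fractal dimensions,
rescaled-range Hurst exponent H, detrended fluctuation analysis
(α, α1, α2), Allan factor for point processes, Grassberger–Procaccia
correlation dimension D2, Rosenstein largest Lyapunov exponent,
LZ76 Lempel–Ziv complexity (single- and multiscale), recurrence
quantification (RR, DET, ENT, Lmax, LAM, TT) and lagged Poincaré
descriptors (SD1, SD2, SD1/SD2, CCM).

**Entropy measures** — Shannon/Rényi/Tsallis histogram entropies,
conditional and corrected conditional entropy, ApEn, SampEn, QSE,
CoSEn, fuzzy and fSampEn, permutation entropy and its amplitude-aware
and min-entropy variants, dispersion entropy, bubble entropy, slope
entropy, distribution entropy, phase entropy, Tone–Entropy, and entropy
of entropy — plus multiscale (MSE), refined-composite (RCmSE, RCmFE,
RCmDE) and improved-overlapping (ImPE) wrappers built on block-mean
coarse-graining.

**Around the measures** — file loading (txt/csv/xlsx), epoching,
pre-processing (outlier removal, zero-phase Butterworth filtering,
noise injection, rescaling, cubic-spline resampling of interval series),
embedding-parameter estimation (AMI, autocorrelation, false nearest
neighbours for m and τ), one-parameter sweeps, batch pipelines with
per-row fault isolation, result export, and a two-condition group layer:
paired Cohen's d, seeded bootstrap-t p-values, Benjamini–Hochberg FDR
control and an exact binomial sign test. Seedable generators (white /
pink / brown noise, exact fractional Gaussian noise by circulant
embedding, logistic map, MIX process, paired RRi/BBi ensembles) provide
reference inputs.

Key conventions: template entropies use the Chebyshev distance with
tolerance r expressed as a fraction of the series SD (d ≤ r·SD counts
as a match); ordinal measures break ties by order of appearance; the
multiscale SampEn tolerance is fixed at scale 1 by default (the Costa
convention). See `docs/methods.md` for the full account.

## A worked example

```python
import ceps
from ceps.synthetic import gen_rri

x = gen_rri("normal", seed=42).rri_ms    # 320 synthetic RR intervals
print(ceps.rmssd(x))                      # 27.28  (ms)
print(ceps.dfa(x).alpha1)                 # 1.117
print(ceps.higuchi_fd(x, k_max=10))       # 1.876
print(ceps.regularity_family(x, "sampen", m=2, r=0.2))  # 1.985
```

RMSSD is ordinary beat-to-beat variability in milliseconds; a DFA α1
near 1 indicates 1/f-like short-range correlation; a Higuchi fractal
dimension of 1.88 says the interval curve is rough, close to the
noise-like limit of 2; the sample entropy of ~2.0 reflects high
template irregularity at tolerance 0.2·SD.

The same series run through the full 300-s battery and the group layer
(`examples/05_two_condition_study.py`, nine simulated subjects, normal
vs. 7-breaths/min paced breathing) prints

```
146 measures compared: 87 decrease, 59 increase under paced breathing;
130 significant at FDR 0.12
binomial sign test on the split: p = 0.0251
```

— slow paced breathing regularises heart-rate dynamics, so more
complexity/entropy measures fall than rise.

Each `examples/0*.py` script is a self-contained narrative: single-series
measures, embedding-parameter estimation, a k_max parameter sweep,
multiscale entropy of white vs pink noise, and the two-condition study.
The `ceps` command exposes the same workflows from a shell
(`ceps load`, `ceps sweep`, `ceps run --config run.yaml`,
`ceps compare`, `ceps synth`).

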