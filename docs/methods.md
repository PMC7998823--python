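# Methods

This note records the definitions, conventions and design choices
behind the measures in `ceps`, in enough detail to reproduce any number
the package prints.

## Signals and epoching

A `Signal` is a univariate finite series, either a sampled time series
(with a sample rate in Hz) or an event-interval series (RRi/PPi in ms,
BBi in s). Epoching tiles a prefix of the series with non-overlapping,
equal-length, half-open 0-based windows; for time series the window
length is round(epoch_seconds × rate) samples; a trailing remainder is
dropped, never padded. File reading accepts plain text, delimited CSV
(comma/tab/semicolon/whitespace, sniffed; decimal point fixed to ".")
and XLSX (first sheet); a single leading header row of labels is
skipped. Epoch windows are assumed aligned to the start of the
recording.

## Pre-processing

Outliers are *deleted*, not interpolated — the usual convention for
beat-interval artefacts, where removing the sample keeps the remaining
intervals physiological; interpolation onto a uniform grid is available
separately as cubic-spline resampling (default 4 Hz), which also
converts interval series into sampled ones for filtering or spectral
work. The z-score rule removes samples with |x−mean|/SD > k (population
SD); the percentile rule keeps the empirical [lo, hi] band, computed
once on the input, so it is idempotent. Filtering is a Butterworth
design (default order 4) applied forward–backward (`sosfiltfilt`) for
zero phase; cutoffs must lie strictly inside (0, Nyquist). Injected
noise is white or pink (inverse-FFT spectral shaping with Hermitian
symmetry, seeded), scaled to a requested fraction of the signal SD so
the option is scale-free. Every option set to "none"/zero is the
identity.

## Embedding parameters

Delay vectors are (x[i], x[i+τ], …, x[i+(m−1)τ]). The delay τ is
suggested by the first minimum of the average mutual information —
estimated from a 16-bin equal-width joint histogram, in nats. Because
strongly periodic signals produce a *flat* AMI valley, the reported lag
is the centre of the plateau around the first weak minimum (plateau =
contiguous lags within 2% of the curve range of the minimum); for
aperiodic signals this reduces to the ordinary first local minimum. The
1/e crossing of the biased autocorrelation is provided as the
conventional cross-check. The dimension m is suggested by
false-nearest-neighbour fractions (Kennel-style thresholds rtol = 15,
atol = 2·SD) with criterion fraction < 1%; when the criterion is never
met the maximum m is returned flagged.

## Complexity estimators

* **Higuchi FD** (default k_max 10, the mid-range of the usual 5–14
  sweep): curve lengths L(k) from the k-subsampled construction; FD is
  −slope of ln L(k) vs ln k. A ramp gives 1.00, white noise ≈ 2.
* **Katz FD** uses amplitude-only geometry: L = Σ|Δx|, d = max|x_i−x_0|,
  n′ = n−1, FD = ln n′/(ln n′ + ln(d/L)). This variant is
  scale-invariant and exactly 1 for a monotone ramp; variants that embed
  the time axis are neither.
* **Hurst (R/S)**: mean rescaled range over non-overlapping windows at
  log-spaced sizes (8 to n/4), slope of log R/S vs log size. Known to be
  biased towards 0.5 at the ends of (0,1); on exact fGn of length 2¹³
  the recovery is within ±0.1.
* **DFA**: profile = cumsum of the mean-centred series; per-scale
  non-overlapping windows are detrended with an order-p polynomial
  (default 1); F(s) = global RMS residual; α from all scales, α1/α2 over
  the conventional 4–16 and 16–64 bands (beats, for HRV use).
  Residuals at the float-noise floor (≤1e-10 of the profile magnitude)
  raise a degeneracy error rather than polluting the log fit.
* **Allan factor**: counts in contiguous windows of length T;
  AF(T) = mean((N_{i+1}−N_i)²)/(2 mean N). 1 for Poisson, →0 for
  periodic event streams.
* **Correlation dimension**: correlation sum over embedded pairs with a
  Theiler exclusion window, Chebyshev norm; D2 = slope of log C(r) over
  the user's radius band (default 12 radii, geometric, 0.05–1 SD). Fit
  ranges are explicit parameters, never auto-selected silently.
* **Largest Lyapunov (Rosenstein)**: nearest neighbour outside a
  mean-period exclusion, mean log Euclidean divergence per step, LLE =
  slope over the user's fit range (per sample step, nats).
* **Lempel–Ziv**: LZ76 exhaustive-history phrase count c(n)
  (Kaspar–Schuster algorithm), symbolization by median split (binary,
  default) or tertiles; normalized C = c(n)·log_a(n)/n for alphabet
  size a. Multiscale LZC applies the same to coarse-grained copies; the
  n ≥ 50 reliability guard applies to the parent series, relaxed to 16
  per scale so scale curves on ~320-beat epochs stay complete.
* **RQA**: recurrence when the Euclidean distance of embedded points is
  ≤ radius, with the radius specified as a fraction of the series SD
  (portable across signals; default 0.2); main diagonal excluded;
  DET/ENT (nats)/Lmax from diagonal lines ≥ min_line (default 2),
  LAM/TT from vertical lines. An empty matrix returns all-zero metrics
  with a warning.
* **Poincaré**: for lag ℓ, SD1/SD2 are the dispersions along the ±45°
  axes using the population (1/n) variance — conventions differ between
  HRV tools, so this is fixed and documented. CCM is the mean absolute
  triangle area of consecutive plot points normalized by the π·SD1·SD2
  ellipse area. The published lagged extension beyond SD1/SD2/ratio is
  implemented exactly as that lagged family and labelled accordingly.

## Entropy measures

Defaults, used whenever a parameter is unspecified: m = 2, τ = 1,
r = 0.2·SD (the de-facto HRV convention), dispersion classes c = 6,
histogram bins = 64, phase sectors k = 16, slope thresholds
δ = 0.001 / γ = 1.0, PE order m = 3. Every result row in a batch
records the full parameter set used.

* Histogram entropies use equal-width bins over [min, max];
  Rényi (1/(1−q))·ln Σp^q and Tsallis (1/(q−1))(1−Σp^q) with q ≠ 1.
  A constant series returns 0 by convention (one occupied bin).
* Conditional entropy coarse-grains to quantile levels; CE(m) = H(m) −
  H(m−1) over word distributions; the corrected form adds perc(m)·H(1)
  where perc(m) is the fraction of singleton m-words.
* The regularity family matches m-templates under the Chebyshev
  distance with d ≤ r_abs. SampEn counts pairs over the first n−m
  templates for both lengths and returns −ln(A/B); ApEn includes
  self-matches (Φ^m − Φ^{m+1}); QSE = SampEn + ln(2r_abs); CoSEn
  subtracts ln(mean); fuzzy entropy replaces the hard threshold with
  exp(−(d/r)^p) on mean-centred templates; fSampEn runs SampEn on a
  moving-RMS envelope. Zero matches yield NaN (an "undefined" marker in
  batch tables), not an exception. Pair counting switches from a
  chunked broadcast to KD-tree `count_neighbors` above n = 1500; both
  paths are exact and are tested against each other.
* Ordinal measures code each delay vector by stable argsort (ties by
  order of appearance, which matters on quantized RRi); PE is the
  normalized Shannon entropy of pattern frequencies, PME the min-entropy
  −ln(max p)/ln(m!), AAPE weights occurrences by A·mean|x| +
  (1−A)·mean|Δx|.
* Dispersion entropy maps through the normal CDF fitted to (mean, SD),
  ceil(c·y) classes clipped to 1..c; patterns are delay vectors of
  classes; normalized by ln(c^m).
* Bubble entropy: Rényi-2 entropy of bubble-sort swap (inversion)
  counts at orders m and m+1, (H_{m+1}−H_m)/ln((m+1)/(m−1)); rank-based,
  hence monotone-transform invariant.
* Slope entropy symbolizes successive differences into five classes by
  ±δ, ±γ and takes the Shannon entropy of m-length symbol words.
* Distribution entropy: normalized Shannon entropy of the histogram of
  all pairwise template distances, binned over [0, max distance].
* Phase entropy: second-order difference plot, angles assigned to k
  equal sectors weighted by radius, normalized; with even k the sector
  grid is antipodally symmetric, so PhEn(x) = PhEn(−x) exactly.
* Tone–Entropy: percentage index PI_i = 100(x_i−x_{i+1})/x_i; tone is
  mean PI, entropy the Shannon entropy (bits) of PI in unit-percent
  bins. Reliability flags follow the established data requirements:
  tone needs ≥ 250 points, entropy ≥ 50; below 50 the call errors,
  between 50 and 249 tone is returned but flagged.
* Entropy of entropy: per-window Shannon entropy of an amplitude
  discretisation whose levels are fixed over the whole series range,
  then Shannon entropy over the distinct window-entropy values
  (rounded at 1e-12 to form categories).

## Multiscale wrappers

Coarse-graining is the non-overlapping block mean; variance of white
noise falls as 1/s. The refined-composite variants accumulate the
scale's s offset-shifted coarse-grainings *before* the logarithm:
RCmSE sums match counts A and B over offsets, RCmDE averages
dispersion-pattern distributions, RCmFE averages fuzzy membership
totals (membership width σ = r·SD, r = 0.2 by default); ImPE averages
the per-offset PE values. At scale 1 every variant equals its base
measure exactly. The SampEn tolerance policy defaults to
`fixed_at_scale1` (compute r·SD once on the original series — the
Costa convention); `per_scale` is available and recorded, because the
two choices produce different MSE curves. Undefined scales are
reported as NaN, never dropped, so curves align across files.

## Sweeps, pipelines, battery

A sweep varies exactly one parameter of one measure over an inclusive
[min, max, step] grid (integer parameters on the integer lattice). A
pipeline run is deterministically ordered (file, epoch, spec), times
each row with a monotonic clock (indicative only), and isolates
failures as `error:` status rows — one bad file must not destroy a
batch. The `table3_300s` battery bundles the linear block,
autocovariance lags 1–20, Higuchi FD k_max 5–14, Hurst, RQA, lagged
Poincaré + CCM 1–10, LZC + multiscale LZC 1–9, Shannon entropy, EoE,
Tone–Entropy, PE and PME over τ 1–10, ImPE and RCmDE over scales 1–10,
DistEn, SlopeEn, bubble and phase entropy — 110 specs; seven named
measures without public definitions (RoCV, RoSlope, ACV, E-MC, AE,
EoD_m, KLD_m) are reported as skipped rather than guessed at.

## Group statistics

Paired Cohen's d uses the SD of the within-subject differences (n−1
denominator), reported as |d| plus a direction; a zero-SD non-zero-mean
difference is flagged as an infinite effect. The two-condition test is
a case-resampling bootstrap of the paired *t statistic*: resample the
subject differences B = 1000 times, compare |t*| = |(mean*−mean)/(s*/√n)|
with the observed |t|, clip the percentile p to [2/B, 1]. Bootstrapping
the studentized statistic rather than the raw mean is what keeps the
test calibrated at n = 9 (measured type-I rate 0.037–0.043 at nominal
0.05 over 1000 null simulations; the raw-mean percentile rule rejects
at ≈0.10 there, which is why it was not used). Benjamini–Hochberg runs
at FDR q = 0.12 by default; the exported table carries raw p, per-rank
critical value i·q/M and the decision, so rank- or corrected-p
reporting can both be reconstructed. The binomial sign test on the
increase/decrease split is exact (two-sided, doubled tail, capped at
1) — appropriate at battery sizes of ~45 where a normal approximation
would be crude, though it treats measures as independent, which they
are not; it is an indicative summary, not a primary test.

## Synthetic generators

White/pink/brown noises are unit-variance (pink/brown by spectral
synthesis, power ∝ f^−β with β = 1, 2). Fractional Gaussian noise uses
circulant embedding of the exact autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) — exact second-order
structure, chosen because the estimator round-trip tolerances in the
tests (H within ±0.05–0.1) depend on generator fidelity, which a
spectral approximation would not guarantee. The logistic map (r = 4,
1000-step burn-in) and the MIX(p) process (a sine with samples replaced
by uniform noise with probability p) provide deterministic-chaos and
tunable-irregularity fixtures.

The paired RRi/BBi generator emulates a 300-s two-trial protocol:
baseline interval 937.5 ms (≈320 beats/300 s), a Mayer-wave LF
oscillation (30 ms at 0.095 Hz), a respiratory oscillation locked to
the breathing phase, and 15 ms white jitter, with beat times obtained
by integrating the instantaneous interval. Under normal breathing the
subject's mean breath interval is drawn near 6.2 s (SD 1.2 s across
subjects, cycle CV 12%, RSA amplitude 25 ms), giving ≈50 breaths per
trial with realistic across-subject spread; under 7-breaths/min pacing
the breath interval is fixed at 60/7 s (cycle CV 2%) and the RSA
amplitude rises to 90 ms, reflecting the well-known amplification of
respiratory sinus arrhythmia during slow guided breathing. Mean heart
rate is identical across conditions, so only the variability structure
changes — exactly the contrast the measures are supposed to detect.
This is an additive-oscillation model, not a closed-loop baroreflex
model: it reproduces lengths, rates and directions of change, not
blood-pressure coupling, nonstationary drifts, ectopy or measurement
artefacts, so passing tests demonstrate sensitivity to regularisation
of dynamics, not robustness to real-world recording problems.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks run 50 random series of 60–300 points
(regimes where O(n²) double loops are exact and fast); known-limit and
cross-relation suites average 5–20 seeds at n = 8192–16384; multiscale
behaviour uses n = 2×10⁴; calibration uses 1000 null simulations of 9
pairs at B = 1000; the end-to-end study uses 9 subjects × 2 conditions
× 110 battery specs on ~320-beat series. These sizes give stable means
at the stated tolerances while keeping the full suite in the
low minutes.

## Known limitations

R/S Hurst is biased near the ends of (0,1) (≈0.38 recovered at
H = 0.3); D2 and LLE need user-chosen fit ranges and are sensitive to
them; LZC normalization is only asymptotic (≈1.02 at n = 10⁵ for
random binary); the binomial sign test ignores inter-measure
correlation; `.mat` input, frequency-domain HRV indices, smoothness-
priors detrending, ECG/PPG peak detection and classification are out of
scope. Measures whose published definitions could not be established
are excluded and reported as skipped instead of being approximated.
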