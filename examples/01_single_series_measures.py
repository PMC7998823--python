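"""Compute a spread of complexity and entropy measures on one RR-interval series.

Generates a 300-s synthetic RR-interval recording, then prints the
classic HRV descriptors next to several nonlinear measures with a note
on what each number means.
"""

import ceps
from ceps.synthetic import gen_rri

rec = gen_rri("normal", seed=42)
x = rec.rri_ms
print(f"RRi series: {x.size} beats, mean {x.mean():.0f} ms, SD {x.std(ddof=1):.1f} ms")

print(f"RMSSD            {ceps.rmssd(x):7.2f} ms   beat-to-beat variability")
d = ceps.dfa(x)
print(f"DFA alpha1       {d.alpha1:7.3f}      short-range scaling (~1 for 1/f)")
print(f"Higuchi FD       {ceps.higuchi_fd(x, k_max=10):7.3f}      curve roughness in (1, 2]")
se = ceps.regularity_family(x, "sampen", m=2, r=0.2)
print(f"SampEn(2, 0.2)   {se:7.3f}      template irregularity (lower = more regular)")
pe = ceps.ordinal_family(x, "pe", m=3, tau=1)
print(f"PE(3, 1)         {pe:7.3f}      ordinal-pattern entropy, normalized to [0, 1]")
de, nde = ceps.dispersion_entropy(x, m=2, c=6)
print(f"DE(2, 6)         {nde:7.3f}      dispersion entropy, normalized")
rqa = ceps.rqa_metrics(x, m=2, tau=1, radius_frac=0.2)
print(f"RQA DET          {rqa.det:7.3f}      fraction of recurrences on diagonal lines")
pp = ceps.poincare_lagged(x, lags=[1])[0]
print(f"Poincare SD1/SD2 {pp.ratio:7.3f}      short- vs long-term variability balance")
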