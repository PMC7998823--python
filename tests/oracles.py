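"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a measure by the most literal route available —
explicit double loops, exhaustive enumeration or staged hand
computation — sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def cheb(a, b) -> float:
    return max(abs(float(u) - float(v)) for u, v in zip(a, b))


def sampen_counts_oracle(x, m: int, r: float) -> tuple[int, int]:
    """(A, B) template-match pair counts by explicit double loop."""
    x = list(map(float, x))
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if cheb(x[i : i + m], x[j : j + m]) <= r:
                b += 1
            if cheb(x[i : i + m + 1], x[j : j + m + 1]) <= r:
                a += 1
    return a, b


def apen_oracle(x, m: int, r: float) -> float:
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        cnt = n - mm + 1
        logs = []
        for i in range(cnt):
            c = 0
            for j in range(cnt):
                if cheb(x[i : i + mm], x[j : j + mm]) <= r:
                    c += 1
            logs.append(math.log(c / cnt))
        return sum(logs) / cnt

    return phi(m) - phi(m + 1)


def disten_oracle(x, m: int, bins: int) -> float:
    x = list(map(float, x))
    n = len(x)
    d = []
    for i in range(n - m + 1):
        for j in range(i + 1, n - m + 1):
            d.append(cheb(x[i : i + m], x[j : j + m]))
    d = np.array(d)
    top = d.max()
    if top == 0:
        return 0.0
    counts, _ = np.histogram(d, bins=bins, range=(0, top))
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)) / math.log(bins))


def dispersion_census_oracle(x, m: int, c: int, tau: int) -> dict[tuple, int]:
    """Dispersion-pattern census by explicit enumeration."""
    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    y = norm.cdf(x, loc=x.mean(), scale=x.std())
    classes = [min(c, max(1, math.ceil(v * c))) for v in y]
    census: dict[tuple, int] = {}
    n = len(classes)
    for i in range(n - (m - 1) * tau):
        pat = tuple(classes[i + k * tau] for k in range(m))
        census[pat] = census.get(pat, 0) + 1
    return census


def lz76_oracle(symbols) -> int:
    """LZ76 phrase count by literal exhaustive-history parsing."""
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    i = 0
    c = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def rqa_oracle(x, m: int, tau: int, radius_frac: float, min_line: int) -> dict:
    """RQA metrics from an explicitly built recurrence matrix."""
    x = np.asarray(x, dtype=float)
    radius = radius_frac * x.std()
    rows = len(x) - (m - 1) * tau
    emb = np.array([[x[i + k * tau] for k in range(m)] for i in range(rows)])
    rec = np.zeros((rows, rows), dtype=bool)
    for i in range(rows):
        for j in range(rows):
            if i != j and math.dist(emb[i], emb[j]) <= radius:
                rec[i, j] = True
    n_rec = int(rec.sum())
    if n_rec == 0:
        return dict(rr=0.0, det=0.0, ent=0.0, lmax=0, lam=0.0, tt=0.0)
    rr = n_rec / (rows * (rows - 1))

    def runs(seq):
        out, c = [], 0
        for b in seq:
            if b:
                c += 1
            else:
                if c:
                    out.append(c)
                c = 0
        if c:
            out.append(c)
        return out

    diag = []
    for off in range(1, rows):
        diag += runs([rec[i, i + off] for i in range(rows - off)])
        diag += runs([rec[i + off, i] for i in range(rows - off)])
    vert = []
    for j in range(rows):
        vert += runs(rec[:, j])
    long_d = [L for L in diag if L >= min_line]
    long_v = [L for L in vert if L >= min_line]
    det = sum(long_d) / n_rec
    lam = sum(long_v) / n_rec
    tt = float(np.mean(long_v)) if long_v else 0.0
    lmax = max(diag) if diag else 0
    if long_d:
        vals, cnts = np.unique(long_d, return_counts=True)
        p = cnts / cnts.sum()
        ent = float(-np.sum(p * np.log(p)))
    else:
        ent = 0.0
    return dict(rr=rr, det=det, ent=ent, lmax=lmax, lam=lam, tt=tt)


def d2_pair_counts_oracle(x, m: int, tau: int, radii, theiler_w: int):
    """Correlation-sum pair counts by explicit double loop (Chebyshev)."""
    x = np.asarray(x, dtype=float)
    rows = len(x) - (m - 1) * tau
    emb = [[x[i + k * tau] for k in range(m)] for i in range(rows)]
    counts = np.zeros(len(radii), dtype=int)
    total = 0
    for i in range(rows):
        for j in range(i + 1, rows):
            if j - i <= theiler_w:
                continue
            total += 1
            d = cheb(emb[i], emb[j])
            for k, r in enumerate(radii):
                if d <= r:
                    counts[k] += 1
    return counts, total


def swap_count_oracle(v) -> int:
    """Inversion count: pairs (i < j) with v[i] > v[j]."""
    v = list(v)
    return sum(
        1 for i in range(len(v)) for j in range(i + 1, len(v)) if v[i] > v[j]
    )


def eoe_oracle(x, window_w: int, levels: int) -> float:
    """Entropy of entropy by literal two-stage computation."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    ents = []
    k = len(x) // window_w
    for w in range(k):
        win = x[w * window_w : (w + 1) * window_w]
        lv = [min(levels - 1, int((v - lo) / (hi - lo) * levels)) for v in win]
        ps = [lv.count(s) / window_w for s in range(levels) if lv.count(s)]
        ents.append(-sum(p * math.log(p) for p in ps))
    cats: dict[float, int] = {}
    for e in ents:
        key = round(e, 12)
        cats[key] = cats.get(key, 0) + 1
    ps = [c / len(ents) for c in cats.values()]
    return -sum(p * math.log(p) for p in ps)


def mi_permutation_bias(x, lag: int, bins: int, seed: int, n_perm: int = 20) -> float:
    """Mean histogram-MI of independently permuted copies (bias level)."""
    from ceps.embedding import average_mutual_information

    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_perm):
        y = rng.permutation(x)
        vals.append(average_mutual_information(y, max_lag=lag, bins=bins).ami[lag - 1])
    return float(np.mean(vals))
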