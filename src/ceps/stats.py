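"""Two-condition group statistics for measure batteries.

Paired comparisons of a measure computed under a baseline and an
intervention condition across subjects: paired Cohen's d, a seeded
case-resampling bootstrap percentile test (B = 1000), Benjamini–Hochberg
FDR control across the battery (default q = 0.12), an exact binomial
sign test on the increase/decrease split, and standard normality checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "cohen_d_paired",
    "bootstrap_paired_test",
    "benjamini_hochberg",
    "binomial_sign_test",
    "normality_check",
    "PairedOutcome",
    "compare_conditions",
]


def cohen_d_paired(baseline, condition) -> tuple[float, str]:
    """Paired Cohen's d = |mean(diff)| / SD(diff) (n−1 denominator).

    Returns ``(d, direction)`` with direction the sign of
    mean(condition − baseline).  A zero-SD, non-zero-mean difference
    yields ``inf`` (degenerate, perfectly consistent shift).
    """
    b = np.asarray(baseline, dtype=float)
    c = np.asarray(condition, dtype=float)
    if b.shape != c.shape or b.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    diff = c - b
    mean = diff.mean()
    direction = "increase" if mean > 0 else "decrease"
    sd = diff.std(ddof=1)
    if sd == 0:
        return (0.0, direction) if mean == 0 else (math.inf, direction)
    return float(abs(mean) / sd), direction


def bootstrap_paired_test(
    baseline, condition, B: int = 1000, seed: int = 0
) -> float:
    """Two-sided case-resampling bootstrap p for a paired t statistic.

    Subject pairs are resampled with replacement B times and the
    studentized statistic t* = (mean* − mean) / (s*/√n) compared with
    the observed t; p is the percentile position |t*| ≥ |t_obs|,
    clipped to [2/B, 1].  Bootstrapping the t statistic (rather than
    the raw mean) keeps the test calibrated at small n.
    """
    b = np.asarray(baseline, dtype=float)
    c = np.asarray(condition, dtype=float)
    if b.shape != c.shape or b.size < 3:
        raise ValueError("paired vectors of equal length >= 3 required")
    diff = c - b
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        return 2.0 / B if diff.mean() != 0 else 1.0
    t_obs = diff.mean() / (sd / math.sqrt(n))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    res = diff[idx]
    m = res.mean(axis=1)
    s = res.std(ddof=1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(s > 0, (m - diff.mean()) / (s / math.sqrt(n)), np.inf)
    p = float(np.mean(np.abs(t_star) >= abs(t_obs)))
    return float(min(1.0, max(2.0 / B, p)))


def benjamini_hochberg(p_values, q: float = 0.12) -> pd.DataFrame:
    """Benjamini–Hochberg step-up procedure at FDR level ``q``.

    Returns a DataFrame aligned with the input order: p, rank, the
    per-rank critical value i·q/M, and the significance decision (all
    tests up to the largest rank with p_(i) ≤ i·q/M are significant).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    crit = ranks * q / m
    sorted_p = p[order]
    passing = np.flatnonzero(sorted_p <= np.arange(1, m + 1) * q / m)
    cutoff_rank = int(passing[-1]) + 1 if passing.size else 0
    significant = ranks <= cutoff_rank
    return pd.DataFrame(
        {"p": p, "rank": ranks, "critical_value": crit, "significant": significant}
    )


def binomial_sign_test(k_increases: int, n_measures: int) -> float:
    """Exact two-sided binomial sign test, success probability 0.5.

    p = 2·min(P(X ≤ k), P(X ≥ k)), capped at 1.  Used as an indicative
    test of whether more measures moved one way than the other.
    """
    k, n = int(k_increases), int(n_measures)
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    p_low = sps.binom.cdf(k, n, 0.5)
    p_high = sps.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2 * min(p_low, p_high)))


def normality_check(x) -> pd.DataFrame:
    """Shapiro–Wilk and D'Agostino–Pearson omnibus normality tests.

    Returns statistics and p-values side by side; no decision is taken.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality tests require n >= 3")
    if np.all(x == x[0]):
        raise ValueError("normality tests undefined for a constant sample")
    sw = sps.shapiro(x)
    rows = [{"test": "shapiro", "statistic": float(sw.statistic), "p": float(sw.pvalue)}]
    if x.size >= 8:
        da = sps.normaltest(x)
        rows.append(
            {"test": "dagostino", "statistic": float(da.statistic), "p": float(da.pvalue)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedOutcome:
    measure: str
    baseline: np.ndarray
    condition: np.ndarray
    cohen_d: float
    direction: str
    p_boot: float
    bh_critical: float
    bh_significant: bool


def compare_conditions(
    baseline_table: pd.DataFrame,
    condition_table: pd.DataFrame,
    fdr_q: float = 0.12,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full two-condition comparison of a measure battery.

    Both tables must have one row per subject and one column per
    measure, aligned.  Computes per-measure paired Cohen's d, bootstrap
    p and the BH decision at ``fdr_q``; returns a DataFrame sorted by
    effect size (descending).  Measures with missing or constant
    differences are dropped with a ``dropped`` marker column.
    """
    common = [c for c in baseline_table.columns if c in condition_table.columns]
    if not common:
        raise ValueError("no common measure columns")
    rows = []
    rng = np.random.default_rng(seed)
    for name in common:
        b = baseline_table[name].to_numpy(dtype=float)
        c = condition_table[name].to_numpy(dtype=float)
        ok = np.isfinite(b) & np.isfinite(c)
        if ok.sum() < 3 or np.all((c - b)[ok] == (c - b)[ok][0]):
            rows.append({"measure": name, "cohen_d": math.nan, "direction": "",
                         "p_boot": math.nan, "dropped": True})
            continue
        d, direction = cohen_d_paired(b[ok], c[ok])
        p = bootstrap_paired_test(b[ok], c[ok], B=B, seed=int(rng.integers(2**31)))
        rows.append({"measure": name, "cohen_d": d, "direction": direction,
                     "p_boot": p, "dropped": False})
    out = pd.DataFrame(rows)
    tested = out[~out["dropped"]].copy()
    if tested.empty:
        raise ValueError("no testable measures")
    bh = benjamini_hochberg(tested["p_boot"].to_numpy(), q=fdr_q)
    tested["bh_critical"] = bh["critical_value"].to_numpy()
    tested["bh_significant"] = bh["significant"].to_numpy()
    out = out.merge(
        tested[["measure", "bh_critical", "bh_significant"]], on="measure", how="left"
    )
    out["bh_significant"] = out["bh_significant"].fillna(False)
    return out.sort_values("cohen_d", ascending=False, ignore_index=True)
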