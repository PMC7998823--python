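"""Measure registry, parameter sweeps and batch pipelines.

Every measure in the package is addressable by a short name plus a
parameter assignment (:class:`MeasureSpec`).  ``run_pipeline`` executes
a list of specs over the epochs of a set of signals, isolating failures
per row; ``run_sweep`` varies exactly one parameter of one measure over
a grid; ``build_battery`` emits the standard battery for 300-s
interval recordings.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import complexity as cx
from . import entropy as ent
from . import linear as lin
from . import multiscale as ms
from .signal import Signal, segment_epochs

__all__ = [
    "MeasureSpec",
    "SweepGrid",
    "MeasureResult",
    "MEASURES",
    "run_pipeline",
    "run_sweep",
    "build_battery",
    "sweep_pivot",
]


@dataclass(frozen=True)
class MeasureDef:
    name: str
    func: Callable  # (x, **params) -> float | dict[str, float]
    defaults: dict
    integer_params: frozenset = frozenset()


def _d(**kw) -> dict:
    return kw


def _hjorth_out(x) -> dict:
    h = lin.hjorth_params(x)
    return {"a": h.activity, "m": h.mobility, "c": h.complexity}


def _dfa_out(x) -> dict:
    r = cx.dfa(x)
    return {"alpha": r.alpha, "alpha1": r.alpha1, "alpha2": r.alpha2}


def _rqa_out(x, m, tau, radius_frac, min_line) -> dict:
    r = cx.rqa_metrics(x, m=m, tau=tau, radius_frac=radius_frac, min_line=min_line)
    return {"rr": r.rr, "det": r.det, "ent": r.ent, "lmax": float(r.lmax),
            "lam": r.lam, "tt": r.tt}


def _pp_out(x, lag) -> dict:
    r = cx.poincare_lagged(x, lags=[lag])[0]
    return {"sd1": r.sd1, "sd2": r.sd2, "ratio": r.ratio, "ccm": r.ccm}


def _tone_out(x) -> dict:
    r = ent.tone_entropy(x)
    return {"tone": r.tone, "ten": r.entropy}


def _de_out(x, m, c, tau) -> dict:
    de, nde = ent.dispersion_entropy(x, m=m, c=c, tau=tau)
    return {"de": de, "norm": nde}


def _scale_curve(func):
    def wrapper(x, scale, **kw):
        return float(func(x, scales=[scale], **kw)[0])

    return wrapper


MEASURES: dict[str, MeasureDef] = {}


def _register(name: str, func: Callable, defaults: dict, integer: Sequence[str] = ()):
    MEASURES[name] = MeasureDef(name, func, defaults, frozenset(integer))


# linear block
_register("mean", lambda x: float(np.mean(x)), _d())
_register("sd", lambda x: float(np.std(x, ddof=1)), _d())
_register("cv", lambda x: lin.descriptive_stats(x).cv, _d())
_register("skew", lambda x: lin.descriptive_stats(x).skewness, _d())
_register("kurt", lambda x: lin.descriptive_stats(x).kurtosis, _d())
_register("slope", lambda x: lin.trend_fit(x)[0], _d())
_register("intercept", lambda x: lin.trend_fit(x)[1], _d())
_register("rmssd", lin.rmssd, _d())
_register("hjorth", _hjorth_out, _d())
_register("hjorth_a", lambda x: lin.hjorth_params(x).activity, _d())
_register("hjorth_m", lambda x: lin.hjorth_params(x).mobility, _d())
_register("hjorth_c", lambda x: lin.hjorth_params(x).complexity, _d())
_register(
    "acov",
    lambda x, lag: float(lin.autocovariance_lags(x, L=lag)[lag - 1]),
    _d(lag=1),
    integer=["lag"],
)

# complexity block
_register("hfd", cx.higuchi_fd, _d(k_max=10), integer=["k_max"])
_register("kfd", cx.katz_fd, _d())
_register("hurst", cx.hurst_rs, _d())
_register("dfa", _dfa_out, _d())
_register(
    "af",
    lambda x, counting_time: float(cx.allan_factor(x, [counting_time])[0]),
    _d(counting_time=10.0),
)
_register(
    "d2",
    lambda x, m, tau, theiler_w: cx.correlation_dimension(
        x, m=m, tau=tau, theiler_w=theiler_w
    ).d2,
    _d(m=2, tau=1, theiler_w=0),
    integer=["m", "tau", "theiler_w"],
)
_register(
    "lle",
    lambda x, m, tau, mean_period: cx.largest_lyapunov(
        x, m=m, tau=tau, mean_period=mean_period
    ).lle,
    _d(m=2, tau=1, mean_period=1),
    integer=["m", "tau", "mean_period"],
)
_register("lzc", cx.lempel_ziv, _d(symbolizer="median_binary"))
_register(
    "mlzc",
    lambda x, scale, symbolizer: float(cx.multiscale_lz(x, [scale], symbolizer)[0]),
    _d(scale=1, symbolizer="median_binary"),
    integer=["scale"],
)
_register("rqa", _rqa_out, _d(m=2, tau=1, radius_frac=0.2, min_line=2),
          integer=["m", "tau", "min_line"])
_register("pp", _pp_out, _d(lag=1), integer=["lag"])

# entropy block
_register("se", lambda x, bins: ent.shannon_like(x, "shannon", bins=bins),
          _d(bins=64), integer=["bins"])
_register("renyi", lambda x, bins, q: ent.shannon_like(x, "renyi", bins=bins, q=q),
          _d(bins=64, q=2.0), integer=["bins"])
_register("tsallis", lambda x, bins, q: ent.shannon_like(x, "tsallis", bins=bins, q=q),
          _d(bins=64, q=2.0), integer=["bins"])
_register("ce", lambda x, m, bins: ent.conditional_entropy(x, m=m, bins=bins),
          _d(m=2, bins=6), integer=["m", "bins"])
_register("cce",
          lambda x, m, bins: ent.conditional_entropy(x, m=m, bins=bins, corrected=True),
          _d(m=2, bins=6), integer=["m", "bins"])
for _kind in ("apen", "sampen", "qse", "cosen"):
    _register(_kind,
              (lambda k: lambda x, m, r: ent.regularity_family(x, k, m=m, r=r))(_kind),
              _d(m=2, r=0.2), integer=["m"])
_register("fuzen",
          lambda x, m, r, fuzzy_exponent: ent.regularity_family(
              x, "fuzzy", m=m, r=r, fuzzy_exponent=fuzzy_exponent),
          _d(m=2, r=0.2, fuzzy_exponent=2.0), integer=["m"])
_register("fsampen",
          lambda x, m, r, envelope_window: ent.regularity_family(
              x, "fsampen", m=m, r=r, envelope_window=envelope_window),
          _d(m=2, r=0.2, envelope_window=16), integer=["m", "envelope_window"])
_register("pe", lambda x, m, tau: ent.ordinal_family(x, "pe", m=m, tau=tau),
          _d(m=3, tau=1), integer=["m", "tau"])
_register("pme", lambda x, m, tau: ent.ordinal_family(x, "pme", m=m, tau=tau),
          _d(m=3, tau=1), integer=["m", "tau"])
_register("aape",
          lambda x, m, tau, A: ent.ordinal_family(x, "aape", m=m, tau=tau, aape_A=A),
          _d(m=3, tau=1, A=0.5), integer=["m", "tau"])
_register("de", _de_out, _d(m=2, c=6, tau=1), integer=["m", "c", "tau"])
_register("be", ent.bubble_entropy, _d(m=10), integer=["m"])
_register("slopen",
          lambda x, m, delta, gamma: ent.slope_entropy(x, m=m, delta=delta, gamma=gamma),
          _d(m=2, delta=0.001, gamma=1.0), integer=["m"])
_register("disten", lambda x, m, bins: ent.distribution_entropy(x, m=m, bins=bins),
          _d(m=2, bins=64), integer=["m", "bins"])
_register("phen", lambda x, k: ent.phase_entropy(x, k_sectors=k),
          _d(k=16), integer=["k"])
_register("tone", _tone_out, _d())
_register("eoe",
          lambda x, window_w, state_levels: ent.entropy_of_entropy(
              x, window_w=window_w, state_levels=state_levels),
          _d(window_w=5, state_levels=4), integer=["window_w", "state_levels"])

# multiscale block (per-scale scalar measures)
_register("mse", _scale_curve(ms.mse), _d(scale=1, m=2, r=0.15), integer=["scale", "m"])
_register("rcmse", _scale_curve(ms.rcmse), _d(scale=1, m=2, r=0.15),
          integer=["scale", "m"])
_register("rcmde", _scale_curve(ms.rcmde), _d(scale=1, m=2, c=6, tau=1),
          integer=["scale", "m", "c", "tau"])
_register("rcmfe", _scale_curve(ms.rcmfe), _d(scale=1, m=2, r=0.2),
          integer=["scale", "m"])
_register("impe", _scale_curve(ms.impe), _d(scale=1, m=3, tau=1),
          integer=["scale", "m", "tau"])


@dataclass(frozen=True)
class MeasureSpec:
    """A measure name plus one concrete value per parameter."""

    name: str
    params: dict = field(default_factory=dict)

    def resolve(self) -> dict:
        if self.name not in MEASURES:
            raise KeyError(f"unknown measure {self.name!r}; known: {sorted(MEASURES)}")
        mdef = MEASURES[self.name]
        params = {**mdef.defaults, **self.params}
        unknown = set(self.params) - set(mdef.defaults)
        if unknown:
            raise ValueError(f"{self.name}: unknown parameters {sorted(unknown)}")
        for p in mdef.integer_params:
            if p in params:
                if params[p] != int(params[p]):
                    raise ValueError(f"{self.name}: parameter {p} must be an integer")
                params[p] = int(params[p])
        return params

    def validate(self) -> "MeasureSpec":
        self.resolve()
        return self


@dataclass(frozen=True)
class MeasureResult:
    file: str
    epoch: int
    measure: str
    params: dict
    values: float | dict
    elapsed_s: float
    status: str  # ok | undefined | error:<msg>


@dataclass(frozen=True)
class SweepGrid:
    """One measure, one swept parameter, an inclusive [min, max] range."""

    measure: str
    param: str
    min: float
    max: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("increment must be positive")
        if self.min > self.max:
            raise ValueError("min must not exceed max")
        mdef = MEASURES.get(self.measure)
        if mdef is None:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.param not in mdef.defaults:
            raise ValueError(
                f"measure {self.measure!r} has no parameter {self.param!r}"
            )

    def values(self) -> np.ndarray:
        mdef = MEASURES[self.measure]
        vals = np.arange(self.min, self.max + self.step / 2, self.step)
        if self.param in mdef.integer_params:
            vals = np.unique(np.round(vals).astype(int))
        return vals


def _evaluate(spec: MeasureSpec, x: np.ndarray, file: str, epoch: int) -> MeasureResult:
    params = spec.resolve()
    mdef = MEASURES[spec.name]
    t0 = time.perf_counter()
    try:
        value = mdef.func(x, **params)
        status = "ok"
        vals = value if isinstance(value, dict) else float(value)
        scalars = vals.values() if isinstance(vals, dict) else [vals]
        if any(isinstance(v, float) and math.isnan(v) for v in scalars):
            status = "undefined"
    except Exception as exc:  # noqa: BLE001 - failures become status rows
        vals = math.nan
        status = f"error:{exc}"
    elapsed = time.perf_counter() - t0
    return MeasureResult(
        file=file, epoch=epoch, measure=spec.name, params=params,
        values=vals, elapsed_s=elapsed, status=status,
    )


def _epoch_arrays(signal: Signal, epoch_length: Optional[float]):
    if epoch_length is None:
        yield 0, signal.values
        return
    es = segment_epochs(signal, epoch_length)
    for i in range(len(es)):
        yield i, es.epoch(i)


def run_pipeline(
    signals: Sequence[Signal],
    specs: Sequence[MeasureSpec],
    epoch_length: Optional[float] = None,
) -> list[MeasureResult]:
    """Run every spec on every epoch of every signal.

    Ordering is deterministic: (file, epoch, spec).  A failing row is
    reported with an error status; it never aborts the batch.
    """
    if not signals:
        raise ValueError("no signals given")
    if not specs:
        raise ValueError("no measure specs given")
    for spec in specs:
        spec.validate()
    results = []
    for sig in signals:
        for epoch_idx, x in _epoch_arrays(sig, epoch_length):
            for spec in specs:
                results.append(_evaluate(spec, x, sig.label, epoch_idx))
    return results


def run_sweep(
    signals: Sequence[Signal],
    grid: SweepGrid,
    epoch_length: Optional[float] = None,
) -> pd.DataFrame:
    """Vary one parameter of one measure over its grid.

    Returns a tidy table with one row per (file, epoch, parameter value,
    output); parameter values violating a measure precondition become
    status rows rather than aborting the sweep.
    """
    if not signals:
        raise ValueError("no signals given")
    rows = []
    for value in grid.values():
        spec = MeasureSpec(grid.measure, {grid.param: value})
        for sig in signals:
            for epoch_idx, x in _epoch_arrays(sig, epoch_length):
                res = _evaluate(spec, x, sig.label, epoch_idx)
                vals = res.values if isinstance(res.values, dict) else {"": res.values}
                for comp, v in vals.items():
                    name = f"{grid.measure}.{comp}" if comp else grid.measure
                    rows.append(
                        {
                            "file": sig.label,
                            "epoch": epoch_idx,
                            "param": grid.param,
                            "param_value": value,
                            "output": name,
                            "value": v,
                            "status": res.status,
                        }
                    )
    return pd.DataFrame(rows)


def sweep_pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a sweep table: parameter on the index, one trace per
    (file, epoch, output) — ready for plotting."""
    return table.pivot_table(
        index="param_value", columns=["file", "epoch", "output"], values="value",
        aggfunc="first",
    )


# measures named in the source battery but without public definitions;
# reported as skipped rather than silently absent
BATTERY_SKIPPED = ("RoCV", "RoSlope", "ACV", "E-MC", "AE", "EoD_m", "KLD_m")


def build_battery(preset: str = "table3_300s") -> tuple[list[MeasureSpec], tuple[str, ...]]:
    """The standard battery for 300-s interval recordings.

    Returns ``(specs, skipped)``: the descriptive/linear block,
    autocovariance lags 1–20, Higuchi FD k_max 5–14, Hurst, the RQA set,
    lagged Poincaré + CCM 1–10, LZC with multiscale LZC 1–9, Shannon
    entropy, entropy of entropy, Tone–Entropy, permutation entropy
    τ 1–10, improved multiscale PE 1–10, permutation min-entropy τ 1–10,
    refined-composite multiscale dispersion entropy 1–10, DistEn,
    SlopeEn, bubble entropy and phase entropy.
    """
    if preset != "table3_300s":
        raise ValueError(f"unknown preset {preset!r}")
    specs: list[MeasureSpec] = []
    for name in ("mean", "sd", "cv", "skew", "kurt", "slope", "intercept",
                 "rmssd", "hjorth_a", "hjorth_m", "hjorth_c"):
        specs.append(MeasureSpec(name))
    specs += [MeasureSpec("acov", {"lag": L}) for L in range(1, 21)]
    specs += [MeasureSpec("hfd", {"k_max": k}) for k in range(5, 15)]
    specs.append(MeasureSpec("hurst"))
    specs.append(MeasureSpec("rqa"))
    specs += [MeasureSpec("pp", {"lag": L}) for L in range(1, 11)]
    specs.append(MeasureSpec("lzc"))
    specs += [MeasureSpec("mlzc", {"scale": s}) for s in range(1, 10)]
    specs.append(MeasureSpec("se"))
    specs.append(MeasureSpec("eoe"))
    specs.append(MeasureSpec("tone"))
    specs += [MeasureSpec("pe", {"tau": t}) for t in range(1, 11)]
    specs += [MeasureSpec("impe", {"scale": s}) for s in range(1, 11)]
    specs += [MeasureSpec("pme", {"tau": t}) for t in range(1, 11)]
    specs += [MeasureSpec("rcmde", {"scale": s}) for s in range(1, 11)]
    specs.append(MeasureSpec("disten"))
    specs.append(MeasureSpec("slopen"))
    specs.append(MeasureSpec("be"))
    specs.append(MeasureSpec("phen"))
    for spec in specs:
        spec.validate()
    return specs, BATTERY_SKIPPED
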