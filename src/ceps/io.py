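"""Reading signal files and writing result tables.

Supported inputs: plain text (one value per line), delimited CSV/TXT
(comma, tab, semicolon or whitespace; sniffed) and XLSX (first sheet).
Decimal separator is ".".  Multi-column files fan out into one
:class:`~ceps.signal.Signal` per column.

Result tables are written as CSV or XLSX, in long ("tidy") or wide
layout, optionally aggregated over epochs.  The parameters used for each
measure are saved alongside the values — on a second sheet for XLSX, in
a sidecar ``<stem>_parameters.csv`` for CSV.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .signal import Signal

__all__ = ["read_signal_files", "write_results", "results_to_frame"]

_SUPPORTED_EXTS = (".txt", ".csv", ".xlsx")
_DELIMS = [",", "\t", ";"]


class SignalParseError(ValueError):
    """A file could not be parsed as numeric signal data."""


def _sniff_delimiter(sample_lines: list[str]) -> Optional[str]:
    # prefer an explicit delimiter that appears on every non-empty line
    for d in _DELIMS:
        if sample_lines and all(d in ln for ln in sample_lines):
            return d
    return None  # whitespace / single column


def _read_delimited(path: Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8-sig") as fh:
        lines = [ln.rstrip("\n\r") for ln in fh]
    content = [ln for ln in lines if ln.strip() != ""]
    if not content:
        raise SignalParseError(f"{path}: file is empty")
    delim = _sniff_delimiter(content[:20])
    rows = []
    for ln in content:
        if delim is None:
            rows.append(ln.split())
        else:
            rows.append([c.strip() for c in ln.split(delim)])
    width = max(len(r) for r in rows)
    # optional single header line of non-numeric labels
    start = 0
    if rows and not _all_numeric(rows[0]):
        if len(rows) == 1 or _all_numeric(rows[1]):
            start = 1
    data = []
    for irow, row in enumerate(rows[start:], start=start):
        vals = []
        for icol, cell in enumerate(row):
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise SignalParseError(
                    f"{path}: non-numeric value {cell!r} at row {irow}, column {icol}"
                ) from None
        vals.extend([np.nan] * (width - len(vals)))
        data.append(vals)
    if not data:
        raise SignalParseError(f"{path}: no numeric rows found")
    return pd.DataFrame(data)


def _all_numeric(cells: Sequence[str]) -> bool:
    for c in cells:
        if c == "":
            continue
        try:
            float(c)
        except ValueError:
            return False
    return True


def _read_xlsx(path: Path) -> pd.DataFrame:
    df = pd.read_excel(path, sheet_name=0, header=None)
    # drop an optional header row of labels
    first = df.iloc[0]
    if first.map(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SignalParseError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, column {col}"
            )
        df[col] = coerced
    return df


def read_signal_files(
    paths: Iterable[str | os.PathLike],
    column: Optional[int] = None,
    sample_rate_hz: Optional[float] = None,
    is_time_series: Optional[bool] = None,
) -> list[Signal]:
    """Read one or more signal files into :class:`Signal` objects.

    When ``column`` is None, every column of a multi-column file yields
    its own Signal; ordering is (file order, column order).  Data are
    treated as a sampled time series when ``sample_rate_hz`` is given
    (or ``is_time_series`` is set explicitly), otherwise as an
    event-interval series.
    """
    if is_time_series is None:
        is_time_series = sample_rate_hz is not None
    signals: list[Signal] = []
    for raw in paths:
        path = Path(raw)
        if not path.exists():
            raise FileNotFoundError(str(path))
        ext = path.suffix.lower()
        if ext not in _SUPPORTED_EXTS:
            raise ValueError(
                f"{path}: unsupported extension {ext!r}; supported: "
                + ", ".join(_SUPPORTED_EXTS)
            )
        df = _read_xlsx(path) if ext == ".xlsx" else _read_delimited(path)
        cols = [column] if column is not None else list(range(df.shape[1]))
        for c in cols:
            if c >= df.shape[1]:
                raise IndexError(f"{path}: column {c} not present ({df.shape[1]} columns)")
            vals = df.iloc[:, c].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                raise SignalParseError(f"{path}: column {c} holds no numeric data")
            label = path.stem if df.shape[1] == 1 else f"{path.stem}[{c}]"
            signals.append(
                Signal(
                    values=vals,
                    sample_rate_hz=sample_rate_hz,
                    is_time_series=is_time_series,
                    label=label,
                    source=(str(path), c),
                )
            )
    return signals


# ---------------------------------------------------------------------------
# result export


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten MeasureResult records to a tidy (long) DataFrame.

    One row per scalar output: multi-output measures (e.g. RQA) emit one
    row per named component, as ``measure.component``.
    """
    rows = []
    for r in results:
        base = {
            "file": r.file,
            "epoch": r.epoch,
            "measure": r.measure,
            "params": _format_params(r.params),
            "elapsed_s": r.elapsed_s,
            "status": r.status,
        }
        vals = r.values if isinstance(r.values, dict) else {"": r.values}
        for comp, v in vals.items():
            name = f"{r.measure}.{comp}" if comp else r.measure
            rows.append({**base, "output": name, "value": v})
    return pd.DataFrame(rows)


def _format_params(params: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(params.items()))


def _column_key(row) -> str:
    p = row["params"]
    return f"{row['output']}({p})" if p else row["output"]


def write_results(
    results: Sequence,
    path: str | os.PathLike,
    layout: str = "long",
    aggregate: str = "none",
) -> Path:
    """Write MeasureResult records to CSV or XLSX.

    layout
        ``long``: one row per (file, epoch, output).  ``wide``: one row
        per (file, epoch), one column per measure+parameter combination.
    aggregate
        ``none``, ``mean_sd`` or ``median_iqr`` — collapse epochs per
        (file, output).  IQR uses linear-interpolation (type-7) quartiles.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise ValueError("layout must be 'long' or 'wide'")
    if aggregate not in ("none", "mean_sd", "median_iqr"):
        raise ValueError("aggregate must be 'none', 'mean_sd' or 'median_iqr'")
    long = results_to_frame(results)
    if long.empty:
        raise ValueError("no results to write")
    long["column"] = long.apply(_column_key, axis=1)

    if aggregate == "none":
        if layout == "long":
            table = long[["file", "epoch", "output", "params", "value",
                          "elapsed_s", "status"]]
        else:
            epochs_per_file = long.groupby("file")["epoch"].nunique()
            if epochs_per_file.nunique() > 1:
                raise ValueError("wide layout requires a common epoch grid across files")
            table = long.pivot_table(
                index=["file", "epoch"], columns="column", values="value",
                aggfunc="first", sort=False,
            ).reset_index()
    else:
        grouped = long.groupby(["file", "column"], sort=False)["value"]
        if aggregate == "mean_sd":
            agg = grouped.agg(center="mean", spread=lambda v: v.std(ddof=1))
            center_name, spread_name = "mean", "sd"
        else:
            agg = grouped.agg(
                center="median",
                spread=lambda v: np.percentile(v, 75) - np.percentile(v, 25),
            )
            center_name, spread_name = "median", "iqr"
        agg = agg.reset_index()
        if layout == "long":
            table = agg.rename(columns={"center": center_name, "spread": spread_name})
        else:
            c = agg.pivot_table(index="file", columns="column", values="center",
                                aggfunc="first", sort=False)
            s = agg.pivot_table(index="file", columns="column", values="spread",
                                aggfunc="first", sort=False)
            c.columns = [f"{col}.{center_name}" for col in c.columns]
            s.columns = [f"{col}.{spread_name}" for col in s.columns]
            table = pd.concat([c, s], axis=1).reset_index()

    params_table = (
        long[["measure", "params"]]
        .drop_duplicates()
        .sort_values(["measure", "params"])
        .reset_index(drop=True)
    )

    ext = path.suffix.lower()
    if ext == ".xlsx":
        with pd.ExcelWriter(path) as writer:
            table.to_excel(writer, sheet_name="results", index=False)
            params_table.to_excel(writer, sheet_name="parameters", index=False)
    elif ext == ".csv":
        table.to_csv(path, index=False, float_format="%.17g")
        params_table.to_csv(path.with_name(path.stem + "_parameters.csv"), index=False)
    else:
        raise ValueError(f"unsupported output extension {ext!r}; use .csv or .xlsx")
    return path
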