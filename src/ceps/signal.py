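"""Core containers: a univariate signal and its epoch segmentation.

A :class:`Signal` is either a *sampled time series* (values on a uniform
time grid, with a sample rate in Hz) or an *event-interval series* such as
beat-to-beat (RRi), pulse-to-pulse (PPi) or breath-to-breath (BBi)
intervals, conventionally in milliseconds or seconds.  Most measures in
this package are agnostic to which it is; epoching and filtering are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["Signal", "EpochSet", "segment_epochs"]


@dataclass(frozen=True)
class Signal:
    """A univariate numeric series plus sampling metadata.

    Parameters
    ----------
    values
        The sample or interval values.  Must be non-empty and finite.
    sample_rate_hz
        Sampling frequency; required when ``is_time_series`` is true.
    is_time_series
        True for uniformly sampled data, False for event-interval
        ("non time series") data such as RRi/BBi.
    label
        Human-readable name, usually derived from the file name.
    source
        ``(path, column)`` provenance, if read from a file.
    """

    values: np.ndarray
    sample_rate_hz: Optional[float] = None
    is_time_series: bool = False
    label: str = ""
    source: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("Signal values must be one-dimensional")
        if arr.size == 0:
            raise ValueError("Signal values must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Signal values must all be finite")
        if self.is_time_series:
            if self.sample_rate_hz is None:
                raise ValueError("sample_rate_hz is required for time-series data")
        if self.sample_rate_hz is not None and self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: Sequence[float], **meta) -> "Signal":
        """Return a copy carrying ``values`` and updated metadata."""
        return replace(self, values=np.asarray(values, dtype=float), **meta)


@dataclass(frozen=True)
class EpochSet:
    """Non-overlapping, equal-length windows tiling a prefix of a signal.

    ``windows`` are half-open 0-based index ranges ``(start, stop)``; a
    trailing remainder shorter than one epoch is dropped.
    """

    parent: Signal
    epoch_length: float  # seconds (time series) or point count
    windows: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        for start, stop in self.windows:
            yield self.parent.values[start:stop]

    def epoch(self, i: int) -> np.ndarray:
        start, stop = self.windows[i]
        return self.parent.values[start:stop]


def segment_epochs(signal: Signal, epoch_length: float) -> EpochSet:
    """Split ``signal`` into non-overlapping epochs.

    ``epoch_length`` is in seconds for time-series data (window point
    count = round(epoch_length × sample_rate)), in points otherwise.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n = len(signal)
    if signal.is_time_series:
        window_points = int(round(epoch_length * signal.sample_rate_hz))
    else:
        window_points = int(round(epoch_length))
    if window_points < 1:
        raise ValueError("epoch_length yields an empty window")
    if window_points > n:
        raise ValueError(
            f"epoch of {window_points} points is longer than the series ({n} points)"
        )
    n_windows = n // window_points
    windows = tuple(
        (i * window_points, (i + 1) * window_points) for i in range(n_windows)
    )
    return EpochSet(parent=signal, epoch_length=epoch_length, windows=windows)
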