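"""Trace detrending and smoothing.

Raw slice luminescence carries a large decaying baseline (luciferin
consumption, tissue rundown).  Detrending subtracts a centred 24-h running
average, which annihilates any drift that is slow relative to the window and
leaves a near-zero-mean oscillation; a centred running median is provided as
the spike-robust smoother used before extrema detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import LuminescenceTrace

__all__ = ["DetrendedTrace", "baseline_subtract", "smooth", "smooth_trace"]


@dataclass
class DetrendedTrace:
    """Baseline-subtracted trace on the same grid as its source."""

    sample_id: str
    times_h: np.ndarray
    values: np.ndarray
    window_h: float
    source: LuminescenceTrace | None = None

    @property
    def sampling_interval_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    def __len__(self) -> int:
        return len(self.times_h)


def _odd_window_samples(window_h: float, dt: float) -> int:
    w = int(round(window_h / dt))
    return max(w + (1 - w % 2), 3)  # odd, >= 3


def baseline_subtract(trace: LuminescenceTrace, window_h: float = 24.0) -> DetrendedTrace:
    """Subtract a centred running average of width ``window_h`` from a trace.

    At the edges the centred window shrinks (truncates) rather than dropping
    samples, so the output grid equals the input grid.  Requires a uniform
    grid spanning at least one window.
    """
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    if trace.duration_h < window_h:
        raise ValueError("trace shorter than the detrending window")
    w = _odd_window_samples(window_h, trace.sampling_interval_h)
    running_mean = (
        pd.Series(trace.values).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )
    return DetrendedTrace(
        sample_id=trace.sample_id,
        times_h=trace.times_h.copy(),
        values=trace.values - running_mean,
        window_h=window_h,
        source=trace,
    )


def smooth(values: np.ndarray, window_h: float, sampling_interval_h: float) -> np.ndarray:
    """Centred running median; idempotent on constants, removes single-sample
    spikes, preserves monotone segments."""
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    w = _odd_window_samples(window_h, sampling_interval_h)
    return (
        pd.Series(np.asarray(values, dtype=float))
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def smooth_trace(detrended: DetrendedTrace, window_h: float = 2.0) -> DetrendedTrace:
    """Convenience wrapper returning a smoothed copy of a detrended trace."""
    return DetrendedTrace(
        sample_id=detrended.sample_id,
        times_h=detrended.times_h.copy(),
        values=smooth(detrended.values, window_h, detrended.sampling_interval_h),
        window_h=detrended.window_h,
        source=detrended.source,
    )
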