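"""Rhythm descriptors for detrended PER2::LUC traces.

Two complementary routes are implemented.  The extrema route finds troughs in
the smoothed detrended signal, defines each peak as the midpoint of two
consecutive troughs, and averages inter-peak intervals over 2-3 consecutive
cycles to obtain the period.  The fit route performs least-squares regression
of a damped sinusoid

    y(t) = A * exp(-lambda * (t - t_start)) * cos(2 pi (t - t_peak) / tau)

over a window, initialised from the extrema estimates.  Phases are expressed
in degrees with the ascending zero crossing at 0/360 and the peak at 90; the
phase of a treatment at time T_p given the preceding fitted peak P_bt and the
period tau is

    ((T_p - P_bt) / tau) * 360 + 90,     reduced mod 360 into [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .preprocessing import DetrendedTrace, smooth

__all__ = [
    "ExtremaSet",
    "RhythmFit",
    "TreatmentPhase",
    "find_troughs",
    "peaks_from_troughs",
    "extrema",
    "estimate_period",
    "fit_sine",
    "treatment_phase_degrees",
    "InsufficientCyclesError",
]

DEFAULT_PERIOD_BOUNDS = (16.0, 32.0)


class InsufficientCyclesError(ValueError):
    """Raised when a trace window does not contain enough oscillation cycles."""


@dataclass(frozen=True)
class ExtremaSet:
    trough_times_h: np.ndarray
    peak_times_h: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.trough_times_h, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("trough times must be strictly increasing")
        if len(self.peak_times_h) != max(len(t) - 1, 0):
            raise ValueError("need exactly one peak per consecutive trough pair")


@dataclass
class RhythmFit:
    """Damped-sine fit over one trace window."""

    window_h: tuple[float, float]
    period_h: float
    amplitude: float
    damping_rate: float
    peak_time_h: float          # fitted peak nearest the window centre
    residual_rms: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def peak_times(self, t_from: float, t_to: float) -> np.ndarray:
        """All fitted/extrapolated peak times in [t_from, t_to]."""
        k_lo = int(np.ceil((t_from - self.peak_time_h) / self.period_h))
        k_hi = int(np.floor((t_to - self.peak_time_h) / self.period_h))
        return self.peak_time_h + self.period_h * np.arange(k_lo, k_hi + 1)

    def peak_before(self, t: float) -> float:
        """Last extrapolated peak at or before time t."""
        k = np.floor((t - self.peak_time_h) / self.period_h)
        return float(self.peak_time_h + k * self.period_h)

    def peak_after(self, t: float) -> float:
        """First extrapolated peak strictly after time t."""
        k = np.floor((t - self.peak_time_h) / self.period_h) + 1
        return float(self.peak_time_h + k * self.period_h)


@dataclass(frozen=True)
class TreatmentPhase:
    """Phase of a treatment in the degree convention (peak = 90)."""

    degrees: float
    raw_degrees: float       # formula output before reduction into [0, 360)
    treatment_time_h: float
    peak_before_h: float
    period_h: float


# ---------------------------------------------------------------------------
# extrema route

def find_troughs(
    detrended: DetrendedTrace,
    min_separation_h: float = 12.0,
    smooth_window_h: float | None = None,
    min_prominence_frac: float = 0.2,
) -> np.ndarray:
    """Trough times of a detrended trace.

    Local minima of the (optionally median-smoothed) signal separated by at
    least ``min_separation_h``, with prominence at least
    ``min_prominence_frac`` of the signal's half peak-to-peak range; trough
    times are refined by parabolic interpolation through the three samples
    around each minimum.  Raises :class:`InsufficientCyclesError` when fewer
    than two troughs are found (e.g. a constant trace).
    """
    y = detrended.values
    dt = detrended.sampling_interval_h
    if smooth_window_h:
        y = smooth(y, smooth_window_h, dt)
    span = np.ptp(y)
    if span == 0:
        raise InsufficientCyclesError("insufficient cycles: flat trace")
    distance = max(int(round(min_separation_h / dt)), 1)
    idx, _ = find_peaks(-y, distance=distance, prominence=min_prominence_frac * span / 2)
    if len(idx) < 2:
        raise InsufficientCyclesError(f"insufficient cycles: {len(idx)} trough(s) found")
    times = detrended.times_h[idx].astype(float)
    # parabolic sub-sample refinement
    for j, i in enumerate(idx):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom > 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                times[j] += np.clip(delta, -1, 1) * dt
    return times


def peaks_from_troughs(trough_times_h: np.ndarray) -> np.ndarray:
    """Peaks as midpoints of consecutive troughs."""
    t = np.asarray(trough_times_h, dtype=float)
    if len(t) < 2:
        raise InsufficientCyclesError("need at least 2 troughs to place a peak")
    return (t[:-1] + t[1:]) / 2.0


def extrema(detrended: DetrendedTrace, **kwargs) -> ExtremaSet:
    troughs = find_troughs(detrended, **kwargs)
    return ExtremaSet(trough_times_h=troughs, peak_times_h=peaks_from_troughs(troughs))


def estimate_period(peak_times_h: np.ndarray, n_cycles: int | None = None) -> float:
    """Mean of the first ``n_cycles`` consecutive inter-peak intervals.

    ``n_cycles`` defaults to 3 when at least 4 peaks are available, else 2.
    """
    p = np.asarray(peak_times_h, dtype=float)
    if n_cycles is None:
        n_cycles = 3 if len(p) >= 4 else 2
    if n_cycles not in (2, 3):
        raise ValueError("n_cycles must be 2 or 3")
    if len(p) < n_cycles + 1:
        raise InsufficientCyclesError(
            f"need {n_cycles + 1} peaks for {n_cycles} cycles, have {len(p)}"
        )
    return float(np.mean(np.diff(p[: n_cycles + 1])))


# ---------------------------------------------------------------------------
# sine-fit route

def _model(t, amp, lam, tau, t_peak, t0):
    return amp * np.exp(-lam * (t - t0)) * np.cos(2 * np.pi * (t - t_peak) / tau)


def fit_sine(
    detrended: DetrendedTrace,
    window_h: tuple[float, float] | None = None,
    damped: bool = True,
    period_bounds: tuple[float, float] = DEFAULT_PERIOD_BOUNDS,
    max_restarts: int = 4,
) -> RhythmFit:
    """Least-squares damped-sine fit over a trace window.

    Initialised from extrema-based period and peak estimates (falling back to
    a 24-h prior when extrema detection fails); the damping rate is bounded
    below by 0, so an undamped sine is nested.  Windows shorter than two
    fitted cycles are rejected; non-convergence after bounded restarts
    returns a flagged fit.
    """
    t_all, y_all = detrended.times_h, detrended.values
    if window_h is None:
        window_h = (float(t_all[0]), float(t_all[-1]))
    lo, hi = window_h
    sel = (t_all >= lo - 1e-9) & (t_all <= hi + 1e-9)
    t, y = t_all[sel], y_all[sel]
    if len(t) < 16:
        raise InsufficientCyclesError("window contains too few samples")
    if (hi - lo) < 2 * period_bounds[0]:
        raise InsufficientCyclesError("window shorter than two plausible cycles")

    # extrema-based initialisation
    tau0, peak0 = 24.0, None
    try:
        sub = DetrendedTrace(
            sample_id=detrended.sample_id,
            times_h=t,
            values=y,
            window_h=detrended.window_h,
        )
        troughs = find_troughs(sub, min_separation_h=period_bounds[0] / 2, smooth_window_h=2.0)
        peaks = peaks_from_troughs(troughs)
        if len(peaks) >= 3:
            tau0 = estimate_period(peaks)
        elif len(peaks) == 2:
            tau0 = float(peaks[1] - peaks[0])
        centre = (lo + hi) / 2
        peak0 = float(peaks[np.argmin(np.abs(peaks - centre))])
    except InsufficientCyclesError:
        peak0 = float(t[np.argmax(smooth(y, 2.0, detrended.sampling_interval_h))])
    tau0 = float(np.clip(tau0, *period_bounds))
    # 5% slack: tau0 is itself a noisy extrema-based estimate
    if (hi - lo) < 1.9 * tau0:
        raise InsufficientCyclesError("window shorter than two cycles at the initial period")

    amp0 = max(float(np.std(y)) * np.sqrt(2), 1e-12)
    lam_hi = 0.5 if damped else 1e-12
    bounds = (
        [1e-12, 0.0, period_bounds[0], lo - tau0],
        [np.inf, lam_hi, period_bounds[1], hi + tau0],
    )

    best = None
    inits = [(amp0, 0.01 if damped else 0.0, tau0, peak0)]
    for k in range(1, max_restarts + 1):
        dtau = tau0 * (1 + 0.05 * (-1) ** k * ((k + 1) // 2))
        inits.append((amp0, 0.01 if damped else 0.0, float(np.clip(dtau, *period_bounds)),
                      peak0 + tau0 / 4 * (-1) ** k))
    for amp_i, lam_i, tau_i, peak_i in inits:
        x0 = [amp_i, min(lam_i, lam_hi), tau_i, float(np.clip(peak_i, lo - tau0, hi + tau0))]
        res = least_squares(
            lambda p: _model(t, p[0], p[1], p[2], p[3], lo) - y,
            x0,
            bounds=bounds,
            method="trf",
        )
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-3 * len(t) * amp0**2:
            break

    amp, lam, tau, t_peak = best.x
    # canonical reference peak: the one nearest the window centre
    centre = (lo + hi) / 2
    t_peak = t_peak + tau * np.round((centre - t_peak) / tau)
    rms = float(np.sqrt(2 * best.cost / len(t)))
    flags = []
    converged = bool(best.success)
    if not converged:
        flags.append("non-convergence")
    if rms > 0.8 * amp:
        flags.append("poor-fit")
    return RhythmFit(
        window_h=(lo, hi),
        period_h=float(tau),
        amplitude=float(amp),
        damping_rate=float(lam),
        peak_time_h=float(t_peak),
        residual_rms=rms,
        converged=converged,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# degree convention

def treatment_phase_degrees(t_p: float, p_bt: float, tau: float) -> TreatmentPhase:
    """Phase (degrees) of a treatment at time ``t_p`` given the preceding
    fitted peak ``p_bt`` and period ``tau``.

    A treatment exactly at a peak maps to 90; three quarters of a cycle after
    a peak (the ascending zero crossing) maps to a raw 360, reduced to 0 in
    the wrapped value.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if t_p < p_bt - 1e-9:
        raise ValueError("treatment time precedes the reference peak")
    raw = ((t_p - p_bt) / tau) * 360.0 + 90.0
    return TreatmentPhase(
        degrees=float(raw % 360.0),
        raw_degrees=float(raw),
        treatment_time_h=float(t_p),
        peak_before_h=float(p_bt),
        period_h=float(tau),
    )
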