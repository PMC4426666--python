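"""Phase-shift estimation, phase-response curves, dose-response statistics.

A phase shift is measured by fitting damped sinusoids to the detrended trace
before and after the treatment and comparing the first post-treatment fitted
peak with the pre-treatment fit extrapolated forward: a later observed peak
is a delay and is signed negative.  Shifts are wrapped to the nearest cycle,
into (-tau/2, tau/2].

The phase-response curve is estimated by ordinary least squares of the
individual shifts on a two-harmonic sinusoidal basis
{1, sin phi, cos phi, sin 2phi, cos 2phi}, and dose-response tables carry
mean +/- SEM per peptide x dose with a one-way ANOVA across dose groups and
Bonferroni-adjusted pairwise comparisons against the vehicle group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import baseline_subtract
from .rhythm import (
    InsufficientCyclesError,
    RhythmFit,
    TreatmentPhase,
    find_troughs,
    fit_sine,
    treatment_phase_degrees,
)
from .traces import LuminescenceTrace, TreatmentEvent

__all__ = [
    "ShiftConfig",
    "PhaseShiftEstimate",
    "PRCModel",
    "PrcExtremum",
    "DoseResponseTable",
    "TestReport",
    "phase_shift",
    "estimate_cohort_shifts",
    "fit_prc",
    "prc_extremum",
    "dose_response",
    "compare_groups",
    "second_peak_time",
]


@dataclass(frozen=True)
class ShiftConfig:
    """Tunable parameters of the phase-shift estimator (hours)."""

    detrend_window_h: float = 24.0
    smooth_window_h: float = 2.0
    min_separation_h: float = 12.0
    edge_trim_h: float | None = None      # defaults to detrend_window_h / 2
    event_exclusion_h: float | None = None  # defaults to detrend_window_h / 2
    damped: bool = True
    period_bounds: tuple[float, float] = (16.0, 32.0)

    @property
    def trim(self) -> float:
        return self.detrend_window_h / 2 if self.edge_trim_h is None else self.edge_trim_h

    @property
    def exclusion(self) -> float:
        # the running average straddles the treatment discontinuity, so the
        # detrended signal within half a window of the event is distorted
        return self.detrend_window_h / 2 if self.event_exclusion_h is None else self.event_exclusion_h


@dataclass
class PhaseShiftEstimate:
    sample_id: str
    shift_h: float                       # signed; delay negative
    treatment_phase: TreatmentPhase
    peptide: str
    dose_nM: float
    pre_fit: RhythmFit
    post_fit: RhythmFit
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def phase_shift(
    trace: LuminescenceTrace,
    event: TreatmentEvent | None = None,
    config: ShiftConfig = ShiftConfig(),
) -> PhaseShiftEstimate:
    """Estimate the signed phase shift caused by one treatment event.

    Requires roughly two oscillation cycles on each side of the event.  The
    pre-treatment window runs from the end of the detrending edge region to
    half a detrending window before the event; the post-treatment window
    starts at the first detected trough at least half a window after the
    event (skipping both the acute transient and the region where the
    running average straddles the treatment discontinuity) and ends before
    the trailing edge region.  The shift is the pre-fit extrapolated peak nearest
    the first post-treatment fitted peak minus that peak, wrapped into
    (-tau/2, tau/2].
    """
    if event is None:
        if not trace.events:
            raise ValueError("trace has no treatment events")
        event = trace.events[0]
    t0, t1 = float(trace.times_h[0]), float(trace.times_h[-1])
    detrended = baseline_subtract(trace, config.detrend_window_h)

    pre_window = (t0 + config.trim, event.time_h - config.exclusion)
    pre_fit = fit_sine(
        detrended, pre_window, damped=config.damped, period_bounds=config.period_bounds
    )
    tau = pre_fit.period_h

    troughs = find_troughs(
        detrended,
        min_separation_h=config.min_separation_h,
        smooth_window_h=config.smooth_window_h,
    )
    after = troughs[troughs >= event.time_h + config.exclusion - 1e-6]
    if len(after) == 0:
        raise InsufficientCyclesError("no trough found after the treatment")
    post_window = (float(after[0]), t1 - config.trim)
    post_fit = fit_sine(
        detrended, post_window, damped=config.damped, period_bounds=config.period_bounds
    )

    post_peak = post_fit.peak_after(event.time_h)
    pre_extrap = pre_fit.peak_time_h + tau * np.round((post_peak - pre_fit.peak_time_h) / tau)
    shift = float(pre_extrap - post_peak)
    # wrap into (-tau/2, tau/2]
    shift = tau / 2 - ((tau / 2 - shift) % tau)

    p_bt = pre_fit.peak_before(event.time_h)
    phase = treatment_phase_degrees(event.time_h, p_bt, tau)
    flags = [f"pre:{f}" for f in pre_fit.flags] + [f"post:{f}" for f in post_fit.flags]
    return PhaseShiftEstimate(
        sample_id=trace.sample_id,
        shift_h=shift,
        treatment_phase=phase,
        peptide=event.peptide,
        dose_nM=event.concentration_nM,
        pre_fit=pre_fit,
        post_fit=post_fit,
        flags=flags,
    )


def estimate_cohort_shifts(
    traces: list[LuminescenceTrace], config: ShiftConfig = ShiftConfig()
) -> list[PhaseShiftEstimate]:
    return [phase_shift(tr, config=config) for tr in traces]


def second_peak_time(trace: LuminescenceTrace, config: ShiftConfig = ShiftConfig()) -> float:
    """Alternative phase metric: time (hours after culture start) of the
    second fitted peak of an untreated recording."""
    detrended = baseline_subtract(trace, config.detrend_window_h)
    t0, t1 = float(trace.times_h[0]), float(trace.times_h[-1])
    fit = fit_sine(detrended, (t0 + config.trim, t1 - config.trim),
                   damped=config.damped, period_bounds=config.period_bounds)
    peaks = fit.peak_times(t0, t1)
    peaks = peaks[peaks >= t0]
    if len(peaks) < 2:
        raise InsufficientCyclesError("fewer than two fitted peaks in the recording")
    return float(peaks[1])


# ---------------------------------------------------------------------------
# phase-response curve

@dataclass
class PRCModel:
    """Two-harmonic regression of shift (hours) on treatment phase (degrees)."""

    coefficients: np.ndarray            # (a0, a1, b1, a2, b2)
    grid_deg: np.ndarray                # 0..359 at 1 degree
    grid_pred_h: np.ndarray
    r_squared: float | None
    n_points: int
    flags: list[str] = field(default_factory=list)

    def predict(self, phase_deg) -> np.ndarray | float:
        X = _harmonic_design(np.atleast_1d(np.asarray(phase_deg, dtype=float)))
        out = X @ self.coefficients
        return float(out[0]) if np.isscalar(phase_deg) else out


@dataclass(frozen=True)
class PrcExtremum:
    phase_deg: float
    shift_h: float
    flat: bool = False


def _harmonic_design(phase_deg: np.ndarray) -> np.ndarray:
    phi = np.deg2rad(phase_deg)
    return np.column_stack(
        [np.ones_like(phi), np.sin(phi), np.cos(phi), np.sin(2 * phi), np.cos(2 * phi)]
    )


def fit_prc(estimates, shifts_h=None) -> PRCModel:
    """Fit the harmonic phase-response regression.

    Accepts either a list of :class:`PhaseShiftEstimate` or two arrays
    (phases in degrees, shifts in hours).  Requires at least 8 points whose
    phases span at least 3 quadrants of the cycle.
    """
    if shifts_h is None:
        phases = np.array([e.treatment_phase.degrees for e in estimates], dtype=float)
        shifts = np.array([e.shift_h for e in estimates], dtype=float)
    else:
        phases = np.asarray(estimates, dtype=float)
        shifts = np.asarray(shifts_h, dtype=float)
    if len(phases) < 8:
        raise ValueError("need at least 8 phase-shift points")
    quadrants = np.unique((phases % 360.0) // 90.0)
    if len(quadrants) < 3:
        raise ValueError("phases must span at least 3 quadrants of the cycle")

    X = _harmonic_design(phases)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: phases too clustered")
    beta, _, _, _ = np.linalg.lstsq(X, shifts, rcond=None)

    flags = []
    ss_res = float(np.sum((shifts - X @ beta) ** 2))
    ss_tot = float(np.sum((shifts - shifts.mean()) ** 2))
    r2: float | None
    if ss_tot == 0:
        r2 = None
        flags.append("zero-variance")
    else:
        r2 = 1.0 - ss_res / ss_tot
    grid = np.arange(360.0)
    return PRCModel(
        coefficients=beta,
        grid_deg=grid,
        grid_pred_h=_harmonic_design(grid) @ beta,
        r_squared=r2,
        n_points=len(phases),
        flags=flags,
    )


def prc_extremum(model: PRCModel, flat_tol_h: float = 0.5) -> PrcExtremum:
    """Grid phase of the largest predicted delay (most negative shift).

    Ties resolve to the smallest phase; a model whose predicted shifts span
    less than ``flat_tol_h`` (default 0.5 h, well below any real resetting
    effect here) is flagged flat and carries no extremum phase.
    """
    pred = model.grid_pred_h
    if np.ptp(pred) < flat_tol_h:
        return PrcExtremum(phase_deg=float("nan"), shift_h=float(pred.mean()), flat=True)
    i = int(np.argmin(pred))
    return PrcExtremum(phase_deg=float(model.grid_deg[i]), shift_h=float(pred[i]), flat=False)


# ---------------------------------------------------------------------------
# dose-response tables and group statistics

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class DoseResponseTable:
    """Mean +/- SEM shift per peptide x dose, with one-way ANOVA across dose
    groups (vehicle included) and Bonferroni post-tests against vehicle."""

    table: pd.DataFrame                 # peptide, dose_nM, mean_shift_h, sem_h, n, p_adj, stars
    anova: dict[str, dict]              # per peptide: F, df, p
    vehicle_label: str


def dose_response(
    estimates: list[PhaseShiftEstimate], vehicle_label: str = "PBS"
) -> DoseResponseTable:
    df = pd.DataFrame(
        {
            "peptide": [e.peptide for e in estimates],
            "dose_nM": [e.dose_nM for e in estimates],
            "shift_h": [e.shift_h for e in estimates],
        }
    )
    vehicle = df.loc[df["peptide"] == vehicle_label, "shift_h"].to_numpy()
    if len(vehicle) == 0:
        raise ValueError(f"no vehicle group {vehicle_label!r} in the estimates")

    rows = [
        {
            "peptide": vehicle_label,
            "dose_nM": 0.0,
            "mean_shift_h": float(vehicle.mean()),
            "sem_h": float(stats.sem(vehicle)) if len(vehicle) > 1 else np.nan,
            "n": len(vehicle),
            "p_adj": np.nan,
            "stars": "",
        }
    ]
    anova: dict[str, dict] = {}
    for peptide, grp in df[df["peptide"] != vehicle_label].groupby("peptide", sort=False):
        groups = [g.to_numpy() for _, g in grp.groupby("dose_nM")["shift_h"]]
        doses = sorted(grp["dose_nM"].unique())
        all_groups = groups + [vehicle]
        if len(all_groups) < 2:
            raise ValueError("one-way ANOVA needs at least two groups")
        if np.ptp(np.concatenate(all_groups)) == 0:
            F, p = 0.0, 1.0  # all observations identical: no between-group variance
        else:
            F, p = stats.f_oneway(*all_groups)
        N = sum(len(g) for g in all_groups)
        k = len(all_groups)
        df_between, df_within = k - 1, N - k
        grand = np.concatenate(all_groups).mean()
        ms_within = (
            sum(((g - g.mean()) ** 2).sum() for g in all_groups) / df_within
        )
        anova[peptide] = {"F": float(F), "df": (df_between, df_within), "p": float(p)}
        n_comp = len(doses)
        for dose, g in zip(doses, groups):
            # Bonferroni post-test vs vehicle with the pooled within-group MS
            se = np.sqrt(ms_within * (1 / len(g) + 1 / len(vehicle)))
            tval = (g.mean() - vehicle.mean()) / se if se > 0 else 0.0
            p_adj = min(2 * stats.t.sf(abs(tval), df_within) * n_comp, 1.0)
            rows.append(
                {
                    "peptide": peptide,
                    "dose_nM": float(dose),
                    "mean_shift_h": float(g.mean()),
                    "sem_h": float(stats.sem(g)) if len(g) > 1 else np.nan,
                    "n": len(g),
                    "p_adj": float(p_adj),
                    "stars": _stars(p_adj),
                }
            )
    return DoseResponseTable(
        table=pd.DataFrame(rows), anova=anova, vehicle_label=vehicle_label
    )


@dataclass
class TestReport:
    method: str
    statistic: float
    p_value: float
    significant: bool
    posttests: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None


def compare_groups(
    values_a,
    values_b,
    method: str = "mann_whitney",
    design: tuple | None = None,
    alpha: float = 0.05,
) -> TestReport:
    """Group comparison in the styles used for slice experiments.

    ``mann_whitney``: two-sided exact/asymptotic Mann-Whitney U.
    ``anova2_bonferroni``: two-way ANOVA (group x block, e.g. treatment x
    timepoint) with Bonferroni-adjusted pooled-t post-tests per block;
    ``design`` must supply the block labels as (blocks_a, blocks_b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestReport(
            method=method,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            significant=bool(res.pvalue < alpha),
        )
    if method == "anova2_bonferroni":
        if design is None:
            raise ValueError("anova2_bonferroni requires design=(blocks_a, blocks_b)")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        blocks_a, blocks_b = design
        long = pd.DataFrame(
            {
                "value": np.concatenate([a, b]),
                "group": ["A"] * len(a) + ["B"] * len(b),
                "block": list(blocks_a) + list(blocks_b),
            }
        )
        model = ols("value ~ C(group) * C(block)", data=long).fit()
        table = sm.stats.anova_lm(model, typ=2)
        ms_resid = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
        df_resid = float(table.loc["Residual", "df"])
        blocks = sorted(long["block"].unique())
        rows = []
        for blk in blocks:
            ga = long.query("group == 'A' and block == @blk")["value"].to_numpy()
            gb = long.query("group == 'B' and block == @blk")["value"].to_numpy()
            if len(ga) == 0 or len(gb) == 0:
                rows.append({"block": blk, "t": np.nan, "p_adj": np.nan, "stars": "na"})
                continue
            se = np.sqrt(ms_resid * (1 / len(ga) + 1 / len(gb)))
            tval = (ga.mean() - gb.mean()) / se if se > 0 else 0.0
            p_adj = min(2 * stats.t.sf(abs(tval), df_resid) * len(blocks), 1.0)
            rows.append({"block": blk, "t": float(tval), "p_adj": float(p_adj),
                         "stars": _stars(p_adj)})
        posttests = pd.DataFrame(rows)
        p_group = float(table.loc["C(group)", "PR(>F)"])
        return TestReport(
            method=method,
            statistic=float(table.loc["C(group)", "F"]),
            p_value=p_group,
            significant=bool(p_group < alpha),
            posttests=posttests,
            anova_table=table,
        )
    raise ValueError(f"unknown method {method!r}")
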