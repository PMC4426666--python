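"""Synthetic PER2::LUC-like trace and qPCR generators.

The trace model is a damped sinusoid riding on a decaying baseline,

    L(t) = b0 * exp(-k t) + A * exp(-lambda t) * cos(2 pi (t - t_peak) / tau) + eps,

which is what explanted liver-slice luminometry looks like: counts decay as
luciferin is consumed, the circadian oscillation damps as cells desynchronise,
and shot noise sits on top.  A treatment at oscillator phase phi (degrees;
ascending zero crossing = 0/360, peak = 90) and dose d shifts the oscillation
instantaneously by

    shift(phi, d) = PRC(phi) * d^n / (d^n + EC50^n)     [hours; delays negative]

where PRC is a two-harmonic sinusoid, and optionally damps the post-treatment
amplitude.  Packaged :class:`TreatmentResponse` configurations reproduce the
published effect sizes of the proglucagon-derived peptides (oxyntomodulin
delays of up to 8 h with a maximum near 180 degrees, glucagon up to 3 h,
GLP-1/GLP-2/GRPP inert) and the biphasic dexamethasone response.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .traces import EventTruth, GroundTruth, LuminescenceTrace, TreatmentEvent

__all__ = [
    "OscillatorParams",
    "TreatmentResponse",
    "CohortSpec",
    "QpcrSimConfig",
    "expected_shift",
    "simulate_trace",
    "generate_cohort",
    "generate_qpcr_timecourse",
    "packaged_response",
    "packaged_cohort_spec",
    "packaged_qpcr_config",
    "PACKAGED_PEPTIDES",
]

VEHICLE = "PBS"


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one simulated slice oscillator.

    Times in hours, luminescence in counts/s, rates in 1/h.
    """

    period_h: float = 24.0
    amplitude: float = 100.0
    damping_rate: float = 0.01
    initial_peak_time_h: float = 4.0
    baseline_level: float = 300.0
    baseline_decay_rate: float = 0.01
    noise_sd: float = 5.0
    sampling_interval_h: float = 1.0 / 6.0
    duration_h: float = 120.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be > 0")
        if self.amplitude < 0 or self.damping_rate < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, damping_rate, noise_sd must be >= 0")
        if not 0 < self.sampling_interval_h < self.period_h / 8:
            raise ValueError("sampling_interval_h must be in (0, period/8)")
        if self.duration_h < 3 * self.period_h:
            raise ValueError("duration_h must cover at least 3 periods")


@dataclass(frozen=True)
class TreatmentResponse:
    """Ground-truth resetting behaviour of one peptide.

    ``prc_coefficients`` = (a0, a1, b1, a2, b2) in hours define
    PRC(phi) = a0 + a1 sin(phi) + b1 cos(phi) + a2 sin(2 phi) + b2 cos(2 phi).
    Dose scaling is a Hill factor d^n / (d^n + EC50^n).  A null peptide has
    all-zero coefficients.  ``amplitude_damping_factor`` multiplies the
    oscillation amplitude after a non-vehicle treatment.
    """

    peptide_name: str
    prc_coefficients: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    ec50_nM: float = 20.0
    hill_n: float = 1.0
    amplitude_damping_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.prc_coefficients) != 5:
            raise ValueError("prc_coefficients must have 5 entries (a0, a1, b1, a2, b2)")
        if self.ec50_nM <= 0 or self.hill_n <= 0:
            raise ValueError("ec50_nM and hill_n must be > 0")
        if not 0 <= self.amplitude_damping_factor <= 1:
            raise ValueError("amplitude_damping_factor must be in [0, 1]")

    @property
    def is_null(self) -> bool:
        return all(c == 0 for c in self.prc_coefficients)

    def prc(self, phase_deg) -> np.ndarray | float:
        a0, a1, b1, a2, b2 = self.prc_coefficients
        phi = np.deg2rad(np.asarray(phase_deg, dtype=float))
        return (
            a0
            + a1 * np.sin(phi)
            + b1 * np.cos(phi)
            + a2 * np.sin(2 * phi)
            + b2 * np.cos(2 * phi)
        )

    def hill(self, dose_nM) -> np.ndarray | float:
        d = np.asarray(dose_nM, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(d > 0, d**self.hill_n / (d**self.hill_n + self.ec50_nM**self.hill_n), 0.0)
        return h


def expected_shift(response: TreatmentResponse, phase_deg: float, dose_nM: float) -> float:
    """Ground-truth signed phase shift (hours; delays negative) for a treatment.

    Zero at zero dose and for null peptides.
    """
    if not (np.isfinite(phase_deg) and np.isfinite(dose_nM)):
        raise ValueError("phase and dose must be finite")
    if not 0 <= phase_deg < 360:
        raise ValueError("phase_deg must be in [0, 360)")
    if dose_nM < 0:
        raise ValueError("dose_nM must be >= 0")
    if dose_nM == 0 or response.is_null:
        return 0.0
    return float(response.prc(phase_deg) * response.hill(dose_nM))


def _phase_deg_at(t: float, peak_time: float, period: float) -> float:
    """Oscillator phase at time t given the current effective peak time."""
    return float((((t - peak_time) / period) * 360.0 + 90.0) % 360.0)


def simulate_trace(
    params: OscillatorParams,
    response: TreatmentResponse | None = None,
    events: list[TreatmentEvent] | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    sample_id: str = "sample",
) -> LuminescenceTrace:
    """Simulate one trace, applying an instantaneous phase shift at each event.

    The injected shift at an event is ``expected_shift`` evaluated at the
    oscillator's phase at the event time; a vehicle event (dose 0) leaves the
    trace untouched.  Identical seeds give identical traces.
    """
    events = sorted(events or [], key=lambda e: e.time_h)
    if response is None:
        response = TreatmentResponse(peptide_name=VEHICLE)
    for ev in events:
        if not 0 <= ev.time_h <= params.duration_h:
            raise ValueError(f"event at {ev.time_h} h outside trace duration")

    n = int(round(params.duration_h / params.sampling_interval_h)) + 1
    t = np.arange(n) * params.sampling_interval_h
    rng = np.random.default_rng(seed)

    peak_time = params.initial_peak_time_h
    amp = params.amplitude
    values = np.empty(n)
    truth_events: list[EventTruth] = []
    bounds = [e.time_h for e in events] + [np.inf]

    start = 0.0
    for ev, end in zip(events + [None], bounds):
        seg = (t >= start) & (t < end)
        values[seg] = amp * np.exp(-params.damping_rate * t[seg]) * np.cos(
            2 * np.pi * (t[seg] - peak_time) / params.period_h
        )
        if ev is not None:
            phi = _phase_deg_at(ev.time_h, peak_time, params.period_h)
            shift = expected_shift(response, phi, ev.concentration_nM)
            truth_events.append(
                EventTruth(
                    time_h=ev.time_h,
                    phase_deg=phi,
                    dose_nM=ev.concentration_nM,
                    injected_shift_h=shift,
                )
            )
            if ev.concentration_nM > 0:
                # a delay (negative shift) moves subsequent peaks later
                peak_time -= shift
                amp *= response.amplitude_damping_factor
            start = ev.time_h

    values += params.baseline_level * np.exp(-params.baseline_decay_rate * t)
    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, size=n)

    return LuminescenceTrace(
        sample_id=sample_id,
        times_h=t,
        values=values,
        events=events,
        ground_truth=GroundTruth(period_h=params.period_h, events=tuple(truth_events)),
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated treatment cohort.

    One trace per peptide x dose x replicate, each treated once inside the
    requested phase window, plus ``vehicle_replicates`` PBS controls.
    """

    responses: dict[str, TreatmentResponse] = field(default_factory=dict)
    doses_nM: tuple[float, ...] = (450.0,)
    replicates: int = 5
    phase_window_deg: tuple[float, float] = (180.0, 200.0)
    params: OscillatorParams = field(default_factory=OscillatorParams)
    vehicle_replicates: int = 5
    peak_time_jitter_h: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = self.phase_window_deg
        if not (0 <= lo <= hi < 360):
            raise ValueError("phase window must lie within [0, 360)")
        if len(self.doses_nM) == 0:
            raise ValueError("dose list must be non-empty")


def _treatment_time_for_phase(
    phase_deg: float, peak_time: float, period: float, min_time: float
) -> float:
    """Earliest time >= min_time at which the oscillator sits at phase_deg."""
    offset = ((phase_deg - 90.0) % 360.0) / 360.0 * period
    t = peak_time + offset
    while t < min_time:
        t += period
    return t


def generate_cohort(spec: CohortSpec) -> list[LuminescenceTrace]:
    """Simulate all traces of a cohort with seeded reproducibility.

    Treatment times are placed so each event's ground-truth phase falls in the
    requested window, with at least two pre-treatment cycles (past the
    detrending edge region) and two post-treatment cycles on the grid.
    """
    root = np.random.SeedSequence(spec.seed)
    designs: list[tuple[str, float]] = [
        (name, dose) for name in spec.responses for dose in spec.doses_nM
    ]
    traces: list[LuminescenceTrace] = []
    vehicle_resp = spec.responses.get(VEHICLE, TreatmentResponse(peptide_name=VEHICLE))

    n_units = len(designs) * spec.replicates + spec.vehicle_replicates
    seeds = root.spawn(n_units)
    unit = 0
    lo, hi = spec.phase_window_deg
    # treatment must sit past 2 cycles + the detrend edge margin
    min_tp = 2 * spec.params.period_h + 26.0

    def one_trace(name: str, resp: TreatmentResponse, dose: float, rep: int) -> LuminescenceTrace:
        nonlocal unit
        ss = seeds[unit]
        unit += 1
        jitter_rng = np.random.default_rng(ss.spawn(1)[0])
        p = replace(
            spec.params,
            initial_peak_time_h=spec.params.initial_peak_time_h
            + jitter_rng.uniform(-spec.peak_time_jitter_h, spec.peak_time_jitter_h),
        )
        phi = jitter_rng.uniform(lo, hi) if hi > lo else lo
        tp = _treatment_time_for_phase(phi, p.initial_peak_time_h, p.period_h, min_tp)
        ev = TreatmentEvent(time_h=tp, peptide=name, concentration_nM=dose)
        sid = f"{name}_{dose:g}nM_r{rep}"
        return simulate_trace(p, resp, [ev], seed=ss, sample_id=sid)

    for name, dose in designs:
        for rep in range(1, spec.replicates + 1):
            traces.append(one_trace(name, spec.responses[name], dose, rep))
    for rep in range(1, spec.vehicle_replicates + 1):
        traces.append(one_trace(VEHICLE, vehicle_resp, 0.0, rep))
    return traces


# ---------------------------------------------------------------------------
# packaged configurations

PACKAGED_PEPTIDES = ("OXM", "GCG", "GLP-1", "GLP-2", "GRPP", "DEX", "PBS")
PAPER_DOSES_NM = (0.5, 1.5, 4.5, 15.0, 45.0, 150.0, 450.0)

_FILE_FOR = {
    "OXM": "oxm.toml",
    "GCG": "gcg.toml",
    "GLP-1": "glp1.toml",
    "GLP-2": "glp2.toml",
    "GRPP": "grpp.toml",
    "DEX": "dex.toml",
    "PBS": "pbs.toml",
}


def packaged_response(peptide: str) -> TreatmentResponse:
    """Load the packaged TreatmentResponse calibration for one peptide."""
    try:
        fname = _FILE_FOR[peptide.upper().replace("GLP1", "GLP-1").replace("GLP2", "GLP-2")]
    except KeyError:
        raise KeyError(f"no packaged response for {peptide!r}; have {PACKAGED_PEPTIDES}")
    data = tomllib.loads(
        resources.files("circaluc.configs").joinpath(fname).read_text()
    )["response"]
    return TreatmentResponse(
        peptide_name=data["peptide_name"],
        prc_coefficients=tuple(data["prc_coefficients"]),
        ec50_nM=data["ec50_nM"],
        hill_n=data["hill_n"],
        amplitude_damping_factor=data["amplitude_damping_factor"],
    )


def packaged_cohort_spec(
    peptides: tuple[str, ...] = ("OXM",),
    doses_nM: tuple[float, ...] = PAPER_DOSES_NM,
    replicates: int = 5,
    phase_window_deg: tuple[float, float] = (180.0, 200.0),
    seed: int = 0,
    noise_frac: float = 0.05,
) -> CohortSpec:
    """Cohort matching the published slice dose-response design.

    n replicates per dose across a 0.5-450 nM ladder, treatments in the
    180-200 degree window, 5% amplitude noise, 8-day recordings.
    """
    params = OscillatorParams(duration_h=192.0, noise_sd=noise_frac * 100.0)
    responses = {p: packaged_response(p) for p in peptides}
    return CohortSpec(
        responses=responses,
        doses_nM=doses_nM,
        replicates=replicates,
        phase_window_deg=phase_window_deg,
        params=params,
        vehicle_replicates=replicates,
        seed=seed,
    )


def packaged_prc_cohort_spec(
    peptide: str = "OXM",
    n_phases: int = 48,
    dose_nM: float = 450.0,
    seed: int = 0,
    noise_frac: float = 0.05,
) -> CohortSpec:
    """Cohort for phase-response-curve estimation: one trace per phase,
    phases spread over the full cycle at a fixed (saturating) dose."""
    params = OscillatorParams(duration_h=204.0, noise_sd=noise_frac * 100.0)
    return CohortSpec(
        responses={peptide: packaged_response(peptide)},
        doses_nM=(dose_nM,),
        replicates=1,
        phase_window_deg=(0.0, 359.999),
        params=params,
        vehicle_replicates=0,
        seed=seed,
    )


def generate_prc_cohort(spec: CohortSpec, n_phases: int = 48) -> list[LuminescenceTrace]:
    """Traces with treatment phases on an evenly spaced grid over the window."""
    (peptide, resp), = spec.responses.items()
    dose = spec.doses_nM[0]
    lo, hi = spec.phase_window_deg
    phases = lo + (hi - lo) * np.arange(n_phases) / n_phases
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(n_phases)
    min_tp = 2 * spec.params.period_h + 26.0
    traces = []
    for i, (phi, ss) in enumerate(zip(phases, seeds)):
        jitter_rng = np.random.default_rng(ss.spawn(1)[0])
        p = replace(
            spec.params,
            initial_peak_time_h=spec.params.initial_peak_time_h
            + jitter_rng.uniform(-spec.peak_time_jitter_h, spec.peak_time_jitter_h),
        )
        tp = _treatment_time_for_phase(phi, p.initial_peak_time_h, p.period_h, min_tp)
        ev = TreatmentEvent(time_h=tp, peptide=peptide, concentration_nM=dose)
        traces.append(
            simulate_trace(p, resp, [ev], seed=ss, sample_id=f"{peptide}_phi{phi:.0f}_i{i}")
        )
    return traces


# ---------------------------------------------------------------------------
# synthetic qPCR panels

@dataclass(frozen=True)
class QpcrSimConfig:
    """Fold-change profiles per gene/timepoint converted to Cq values.

    ``profiles[gene][timepoint_min]`` is the true fold change relative to the
    0-min (untreated) condition; the reference gene is flat by construction.
    Cq for a target is base_cq - log_E(fold) plus Gaussian noise.
    """

    profiles: dict[str, dict[float, float]] = field(default_factory=dict)
    reference_gene: str = "Actb"
    base_cq: dict[str, float] = field(default_factory=dict)
    efficiency: dict[str, float] = field(default_factory=dict)
    default_efficiency: float = 2.0
    default_base_cq: float = 25.0
    reference_base_cq: float = 20.0
    noise_sd: float = 0.0
    replicates: int = 3
    treatment: str = "treated"

    def __post_init__(self) -> None:
        for g, e in self.efficiency.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {g} must be in (1, 2]")
        if not 1.0 < self.default_efficiency <= 2.0:
            raise ValueError("default_efficiency must be in (1, 2]")


def generate_qpcr_timecourse(config: QpcrSimConfig, seed: int | None = 0) -> pd.DataFrame:
    """Simulate a Cq table (sample_id, gene, cq, efficiency, treatment,
    timepoint_min, replicate) realising the configured fold-change profiles."""
    rng = np.random.default_rng(seed)
    timepoints = sorted({tp for prof in config.profiles.values() for tp in prof})
    genes = list(config.profiles) + [config.reference_gene]
    rows = []
    for tp in timepoints:
        for rep in range(1, config.replicates + 1):
            sid = f"{config.treatment}_t{tp:g}_r{rep}"
            for gene in genes:
                eff = config.efficiency.get(gene, config.default_efficiency)
                if gene == config.reference_gene:
                    base = config.reference_base_cq
                    fold = 1.0
                else:
                    base = config.base_cq.get(gene, config.default_base_cq)
                    fold = config.profiles[gene].get(tp, 1.0)
                if fold <= 0:
                    raise ValueError("fold changes must be > 0")
                cq = base - np.log(fold) / np.log(eff)
                if config.noise_sd > 0:
                    cq += rng.normal(0.0, config.noise_sd)
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": gene,
                        "cq": cq,
                        "efficiency": eff,
                        "treatment": config.treatment,
                        "timepoint_min": tp,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def packaged_qpcr_config(name: str = "oxm_180", noise_sd: float = 0.0) -> QpcrSimConfig:
    """Packaged induction profiles after peptide treatment of liver slices.

    ``oxm_180``: treatment on the descending phase transiently induces Per1
    (peak at 60 min, back near baseline by 120 min) and sustainedly induces
    Per2, with Bmal1 flat.  ``oxm_360``: treatment at the ascending crossing
    leaves all three genes flat.
    """
    if name == "oxm_180":
        profiles = {
            "Per1": {0.0: 1.0, 30.0: 2.0, 60.0: 3.5, 120.0: 1.3, 240.0: 1.0},
            "Per2": {0.0: 1.0, 30.0: 1.8, 60.0: 3.0, 120.0: 2.8, 240.0: 2.5},
            "Bmal1": {0.0: 1.0, 30.0: 1.0, 60.0: 1.0, 120.0: 1.0, 240.0: 1.0},
        }
    elif name == "oxm_360":
        profiles = {
            "Per1": {0.0: 1.0, 30.0: 1.0, 60.0: 1.0, 120.0: 1.0, 240.0: 1.0},
            "Per2": {0.0: 1.0, 30.0: 1.0, 60.0: 1.0, 120.0: 1.0, 240.0: 1.0},
            "Bmal1": {0.0: 1.0, 30.0: 1.0, 60.0: 1.0, 120.0: 1.0, 240.0: 1.0},
        }
    else:
        raise KeyError(f"unknown packaged qPCR profile {name!r}")
    return QpcrSimConfig(profiles=profiles, noise_sd=noise_sd, treatment=name)
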