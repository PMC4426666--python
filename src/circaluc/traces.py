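"""Luminescence trace containers and long-format CSV I/O.

A trace is one sample's uniformly sampled bioluminescence time series
(counts/s against hours since the start of recording) together with the
treatment events applied to it.  Synthetic traces additionally carry the
generator's ground truth (injected phase shifts, true period) so parameter
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentEvent",
    "EventTruth",
    "GroundTruth",
    "LuminescenceTrace",
    "read_traces",
    "write_traces",
    "read_events",
    "write_events",
    "attach_events",
]


@dataclass(frozen=True)
class TreatmentEvent:
    """A single treatment applied to a culture at ``time_h`` hours.

    Vehicle treatments are encoded as peptide ``"PBS"`` at concentration 0.
    """

    time_h: float
    peptide: str
    concentration_nM: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_h):
            raise ValueError("event time must be finite")
        if not np.isfinite(self.concentration_nM) or self.concentration_nM < 0:
            raise ValueError("concentration must be finite and >= 0")


@dataclass(frozen=True)
class EventTruth:
    """Generator-side record of what one event actually did to the oscillator."""

    time_h: float
    phase_deg: float        # oscillator phase at the event, degrees in [0, 360)
    dose_nM: float
    injected_shift_h: float  # signed; delays negative


@dataclass(frozen=True)
class GroundTruth:
    period_h: float
    events: tuple[EventTruth, ...] = ()

    @property
    def total_shift_h(self) -> float:
        return float(sum(e.injected_shift_h for e in self.events))


@dataclass
class LuminescenceTrace:
    sample_id: str
    times_h: np.ndarray
    values: np.ndarray
    events: list[TreatmentEvent] = field(default_factory=list)
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(self.times_h) < 2:
            raise ValueError("trace needs at least two samples")
        steps = np.diff(self.times_h)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling grid must be uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("luminescence values must be finite")

    @property
    def sampling_interval_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def duration_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])

    def __len__(self) -> int:
        return len(self.times_h)


# ---------------------------------------------------------------------------
# long-format CSV round trip

def write_traces(traces: list[LuminescenceTrace], path) -> None:
    """Write traces as long CSV: sample_id, time_h, luminescence."""
    frames = [
        pd.DataFrame(
            {"sample_id": t.sample_id, "time_h": t.times_h, "luminescence": t.values}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[LuminescenceTrace]:
    df = pd.read_csv(path)
    required = {"sample_id", "time_h", "luminescence"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV needs columns {sorted(required)}")
    traces = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        traces.append(
            LuminescenceTrace(
                sample_id=str(sid),
                times_h=grp["time_h"].to_numpy(),
                values=grp["luminescence"].to_numpy(),
            )
        )
    return traces


def write_events(traces: list[LuminescenceTrace], path) -> None:
    """Write all traces' events as CSV: sample_id, time_h, peptide, concentration_nM."""
    rows = [
        {
            "sample_id": t.sample_id,
            "time_h": ev.time_h,
            "peptide": ev.peptide,
            "concentration_nM": ev.concentration_nM,
        }
        for t in traces
        for ev in t.events
    ]
    pd.DataFrame(rows, columns=["sample_id", "time_h", "peptide", "concentration_nM"]).to_csv(
        path, index=False
    )


def read_events(path) -> dict[str, list[TreatmentEvent]]:
    df = pd.read_csv(path)
    out: dict[str, list[TreatmentEvent]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), []).append(
            TreatmentEvent(
                time_h=float(row["time_h"]),
                peptide=str(row["peptide"]),
                concentration_nM=float(row["concentration_nM"]),
            )
        )
    for evs in out.values():
        evs.sort(key=lambda e: e.time_h)
    return out


def attach_events(traces: list[LuminescenceTrace], events: dict[str, list[TreatmentEvent]]) -> None:
    for t in traces:
        t.events = list(events.get(t.sample_id, []))
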