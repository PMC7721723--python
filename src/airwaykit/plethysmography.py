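"""Whole-body plethysmography analysis: quiet epochs, breath detection, summary.

The pipeline starts from a calibrated flow/volume trace (the chamber-pressure
to volume conversion lives in the instrument) plus a boolean movement channel
scored from video.  Quiet wakefulness is any movement-free interval of at
least 5 s; breaths are detected inside those epochs only, breaths whose
computed tidal volume falls outside [0.05, 2.0] ml are excluded as baseline
or environmental noise, and seven parameters are reported: tidal volume,
respiratory rate, minute volume, inspiratory and expiratory time, and peak
inspiratory / expiratory flow.  Respiratory rate is the retained breath count
divided by the analyzed (extracted) quiet time; minute volume is tidal volume
times respiratory rate.

Sign convention: inspiration is positive flow.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySummaryError, FormatError

__all__ = [
    "BreathTrace",
    "BreathTable",
    "RespiratorySummary",
    "select_quiet_epochs",
    "detect_breaths",
    "filter_breaths",
    "summarize_respiration",
    "analyze_trace",
]

TV_MIN_ML = 0.05  # inclusive bounds of the tidal-volume plausibility window
TV_MAX_ML = 2.0


@dataclass
class BreathTrace:
    """Uniformly sampled flow/volume/movement time series."""

    time_s: np.ndarray
    flow_ml_s: np.ndarray
    volume_ml: np.ndarray
    movement: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow_ml_s = np.asarray(self.flow_ml_s, dtype=float)
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.movement = np.asarray(self.movement).astype(bool)
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.max(np.abs(dt - dt[0])) > 1e-6:
                raise FormatError("trace sampling is not uniform within 1e-6 s")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.dt

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time_s=self.time_s, flow_ml_s=self.flow_ml_s,
                 volume_ml=self.volume_ml, movement=self.movement.astype(int))
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BreathTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"], df["flow_ml_s"], df["volume_ml"], df["movement"])


@dataclass
class BreathTable:
    """Per-breath measurements; one row per detected breath."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["onset_s", "tidal_volume_ml", "ti_ms", "te_ms",
                     "pif_ml_s", "pef_ml_s", "epoch_id"]
        )
    )

    def __len__(self):
        return len(self.frame)


@dataclass(frozen=True)
class RespiratorySummary:
    """The seven plethysmography parameters over the analyzed quiet time."""

    tidal_volume_ml: float
    rr_per_min: float
    minute_volume_ml_min: float
    ti_ms: float
    te_ms: float
    pif_ml_s: float
    pef_ml_s: float
    extracted_time_s: float
    n_breaths: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def select_quiet_epochs(trace: BreathTrace, min_duration_s: float = 5.0):
    """Maximal movement-free intervals lasting at least ``min_duration_s``.

    The threshold is inclusive: an interval of exactly ``min_duration_s``
    qualifies.  Returns a list of (start_s, end_s) tuples.
    """
    quiet = ~trace.movement
    if not quiet.any():
        return []
    edges = np.diff(quiet.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if quiet[0]:
        starts.insert(0, 0)
    if quiet[-1]:
        ends.append(quiet.size)
    dt = trace.dt
    epochs = []
    for s, e in zip(starts, ends):
        duration = (e - s) * dt
        if duration >= min_duration_s - 1e-9:
            epochs.append((float(trace.time_s[0] + s * dt), float(trace.time_s[0] + e * dt)))
    return epochs


def _detect_in_segment(flow, time, dt, band):
    """Hysteresis-guarded breath segmentation of one quiet segment.

    A breath starts when flow rises through +band after having been below
    -band or near zero, and consists of the positive (inspiratory) lobe
    followed by the negative (expiratory) lobe, ending at the next
    inspiration onset.  Returns a list of (i_on, i_mid, i_end) sample index
    triples (onset, insp->exp transition, breath end).
    """
    onsets = []
    state = 0  # 0 unknown/expiratory, 1 inspiratory
    for i, f in enumerate(flow):
        if state != 1 and f > band:
            onsets.append(i)
            state = 1
        elif state == 1 and f < -band:
            state = 0
    # refine each onset back to the true upward zero crossing: the hysteresis
    # band only guards detection, it must not clip the inspiratory lobe
    refined = []
    for i in onsets:
        while i > 0 and flow[i - 1] > 0.0:
            i -= 1
        refined.append(i)
    onsets = refined
    breaths = []
    for k, i_on in enumerate(onsets):
        i_stop = onsets[k + 1] if k + 1 < len(onsets) else flow.size
        # inspiration ends at the first downward zero crossing after onset
        seg = flow[i_on:i_stop]
        below = np.flatnonzero(seg <= 0.0)
        if below.size == 0:
            continue  # inspiration never completed inside the segment
        i_mid = i_on + int(below[0])
        if k + 1 == len(onsets):
            # last breath: expiration must return near zero to be complete
            tail = flow[i_mid:i_stop]
            if tail.size == 0 or tail.min() > -band:
                continue
            back = np.flatnonzero(tail >= 0.0)
            back = back[back > 0]
            i_stop = i_mid + int(back[0]) if back.size else i_stop
        breaths.append((i_on, i_mid, i_stop))
    return breaths


def detect_breaths(trace: BreathTrace, epochs, hysteresis_fraction: float = 0.05) -> BreathTable:
    """Detect breaths within quiet epochs.

    Breath boundaries are zero crossings of flow guarded by a hysteresis band
    (default 5% of the robust flow amplitude, the 95th percentile of |flow|),
    preventing noise-split breaths.  Breaths crossing an epoch border are
    discarded entirely.  Tidal volume is the integral of the inspiratory
    lobe; PIF/PEF are the lobe extrema magnitudes.
    """
    dt = trace.dt
    rows = []
    for epoch_id, (t0, t1) in enumerate(epochs):
        i0 = int(np.ceil((t0 - trace.time_s[0]) / dt - 1e-9))
        i1 = int(np.floor((t1 - trace.time_s[0]) / dt + 1e-9))
        flow = trace.flow_ml_s[i0:i1]
        if flow.size < 4:
            continue
        amp = np.percentile(np.abs(flow), 95)
        if amp <= 0:
            continue
        band = hysteresis_fraction * amp
        for i_on, i_mid, i_end in _detect_in_segment(flow, trace.time_s[i0:i1], dt, band):
            insp = flow[i_on:i_mid]
            exp = flow[i_mid:i_end]
            if insp.size == 0 or exp.size == 0:
                continue
            # include the zero-crossing boundary samples in the integral so
            # the half-segments at lobe edges are not dropped
            lo = max(i_on - 1, 0)
            tv = float(np.trapezoid(np.maximum(flow[lo:i_mid + 1], 0.0), dx=dt))
            rows.append(
                dict(
                    onset_s=float(trace.time_s[i0 + i_on]),
                    tidal_volume_ml=tv,
                    ti_ms=1e3 * (i_mid - i_on + 1) * dt,
                    te_ms=1e3 * (i_end - i_mid - 1) * dt,
                    pif_ml_s=float(insp.max()),
                    pef_ml_s=float(abs(exp.min())),
                    epoch_id=epoch_id,
                )
            )
    table = BreathTable(pd.DataFrame(rows)) if rows else BreathTable()
    if len(table) >= 3:
        median_period_s = 1e-3 * float(
            (table.frame["ti_ms"] + table.frame["te_ms"]).median()
        )
        if median_period_s > 0 and trace.sampling_hz < 10.0 / median_period_s:
            warnings.warn(
                "sampling rate below 10x the dominant breathing frequency; "
                "breath timing may be unreliable"
            )
    return table


def filter_breaths(table: BreathTable) -> BreathTable:
    """Drop breaths with tidal volume strictly below 0.05 or above 2.0 ml.

    The bounds themselves are retained (strict inequalities), and the filter
    is idempotent.
    """
    if len(table) == 0:
        return BreathTable()
    tv = table.frame["tidal_volume_ml"]
    keep = (tv >= TV_MIN_ML) & (tv <= TV_MAX_ML)
    return BreathTable(table.frame.loc[keep].reset_index(drop=True))


def summarize_respiration(table: BreathTable, extracted_time_s: float) -> RespiratorySummary:
    """Cohort-style parameter means over retained breaths.

    ``extracted_time_s`` is the total quiet-epoch duration actually analyzed;
    respiratory rate is breath count / extracted time (per minute), and
    minute volume is mean tidal volume x rate, exact by construction.
    """
    if len(table) == 0:
        raise EmptySummaryError("no retained breaths to summarize")
    f = table.frame
    tv = float(f["tidal_volume_ml"].mean())
    rr = len(f) / extracted_time_s * 60.0
    return RespiratorySummary(
        tidal_volume_ml=tv,
        rr_per_min=rr,
        minute_volume_ml_min=tv * rr,
        ti_ms=float(f["ti_ms"].mean()),
        te_ms=float(f["te_ms"].mean()),
        pif_ml_s=float(f["pif_ml_s"].mean()),
        pef_ml_s=float(f["pef_ml_s"].mean()),
        extracted_time_s=float(extracted_time_s),
        n_breaths=int(len(f)),
    )


def analyze_trace(trace: BreathTrace, min_quiet_s: float = 5.0,
                  apply_filter: bool = True) -> RespiratorySummary:
    """Full chain: quiet epochs -> detection -> tidal-volume filter -> summary.

    ``apply_filter=False`` skips the [0.05, 2.0] ml plausibility filter —
    useful when characterizing measurement fidelity on waveforms whose true
    tidal volume sits exactly on the exclusion boundary, where quadrature
    error alone decides a strict-inequality comparison.
    """
    epochs = select_quiet_epochs(trace, min_quiet_s)
    if not epochs:
        raise EmptySummaryError("no quiet epochs of sufficient duration")
    table = detect_breaths(trace, epochs)
    if apply_filter:
        table = filter_breaths(table)
    extracted = sum(e - s for s, e in epochs)
    return summarize_respiration(table, extracted)
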