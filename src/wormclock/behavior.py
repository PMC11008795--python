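"""Locomotor-trace containers and preprocessing.

An :class:`ActivityTrace` is the behavioral atom: one individual's distance-moved
time series annotated with the light regime (L/D per sample) and the recording
phase (an entrained light:dark block, LD, followed by constant darkness, DD).
Zeitgeber time (ZT) is hours since lights-on; under DD the same reference
continues as circadian time (CT), so a single ``zt0_offset_s`` anchors both.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTrace",
    "BinnedActivity",
    "Actogram",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "moving_average",
    "bin_activity",
    "qc_filter",
    "build_actogram",
]

MIN_PER_DAY = 1440


class TraceParseError(ValueError):
    """Raised when a trace file violates the format contract."""


@dataclass
class ActivityTrace:
    """One individual's locomotor recording.

    Parameters
    ----------
    individual_id : str
        Stable identifier of the animal.
    time_s : ndarray
        Seconds from recording start, strictly increasing.
    activity : ndarray
        Distance moved per sample (arbitrary units), non-negative.
    light : ndarray of {'L', 'D'}
        Instantaneous light condition.
    phase : ndarray of {'LD', 'DD'}
        Recording phase; LD block precedes the DD block.
    zt0_offset_s : float
        Seconds from recording start to the lights-on (ZT0) reference.
    """

    individual_id: str
    time_s: np.ndarray
    activity: np.ndarray
    light: np.ndarray
    phase: np.ndarray
    zt0_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.light = np.asarray(self.light, dtype=object)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time_s.size
        if not (self.activity.size == self.light.size == self.phase.size == n):
            raise TraceParseError("trace columns have unequal lengths")
        dt = np.diff(self.time_s)
        if n > 1 and not np.all(dt > 0):
            row = int(np.argmin(dt > 0)) + 1
            raise TraceParseError(f"time not strictly increasing at row {row + 1}")
        if np.any(self.activity < 0):
            row = int(np.argmax(self.activity < 0))
            raise TraceParseError(f"negative activity at row {row + 1}")

    @property
    def sampling_dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def zt_hours(self) -> np.ndarray:
        """ZT (LD) / CT (DD) of each sample, in [0, 24)."""
        return ((self.time_s - self.zt0_offset_s) / 3600.0) % 24.0

    def restrict_phase(self, phase: str) -> "ActivityTrace":
        if phase not in ("LD", "DD"):
            raise ValueError(f"unknown phase {phase!r}")
        m = self.phase == phase
        return ActivityTrace(
            self.individual_id,
            self.time_s[m],
            self.activity[m],
            self.light[m],
            self.phase[m],
            self.zt0_offset_s,
        )

    def phase_duration_days(self, phase: str) -> float:
        m = self.phase == phase
        if not m.any():
            return 0.0
        t = self.time_s[m]
        dt = self.sampling_dt_s
        return float((t[-1] - t[0] + dt) / 86400.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "activity": self.activity,
                "light": self.light,
                "phase": self.phase,
            }
        )


@dataclass
class BinnedActivity:
    """Day x bin matrix of summed activity for one recording phase.

    ``bins[d, b]`` is the activity summed over bin ``b`` of day ``d`` (days
    counted from the start of the phase, bins by ZT/CT).  ``complete`` flags
    days with every bin covered by data; pooled statistics use complete days
    only, so each time-of-day bin carries equal weight.
    """

    individual_id: str
    phase: str
    bin_width_min: float
    bins: np.ndarray  # (n_days, n_bins)
    zt_of_bin: np.ndarray  # left edge, hours
    complete: np.ndarray  # (n_days,) bool

    @property
    def n_bins(self) -> int:
        return self.bins.shape[1]

    @property
    def pooled_profile(self) -> np.ndarray:
        """Mean 24-h profile over complete days (all days pooled to one day)."""
        if not self.complete.any():
            raise ValueError("no complete day to pool")
        return self.bins[self.complete].mean(axis=0)

    @property
    def total_activity(self) -> float:
        return float(self.bins.sum())


@dataclass
class Actogram:
    """Raster of daily activity; optionally double-plotted (day d | day d+1)."""

    matrix: np.ndarray
    double_plot: bool
    bin_width_min: float


_REQUIRED_COLUMNS = ("time_s", "activity", "light", "phase")


def read_trace(path, individual_id: str | None = None, dialect: str = "seconds",
               zt0_offset_s: float = 0.0) -> ActivityTrace:
    """Read an activity trace CSV.

    ``dialect='ms'`` accepts a ``time_ms`` column (converted to seconds).
    Raises :class:`TraceParseError` naming the offending row on violations.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect == "ms":
        if "time_ms" not in df.columns:
            raise TraceParseError("dialect 'ms' requires a time_ms column")
        df = df.rename(columns={"time_ms": "time_s"})
        df["time_s"] = df["time_s"] / 1000.0
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"missing required column(s): {', '.join(missing)}")
    if individual_id is None:
        individual_id = str(df["individual_id"].iloc[0]) if "individual_id" in df.columns else "unknown"
    return ActivityTrace(
        individual_id=individual_id,
        time_s=df["time_s"].to_numpy(float),
        activity=df["activity"].to_numpy(float),
        light=df["light"].to_numpy(object),
        phase=df["phase"].to_numpy(object),
        zt0_offset_s=zt0_offset_s,
    )


def write_trace(trace: ActivityTrace, path) -> None:
    df = trace.to_frame()
    df.insert(0, "individual_id", trace.individual_id)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round trip


def moving_average(trace: ActivityTrace, window_s: float = 60.0) -> ActivityTrace:
    """Centered running mean; edge windows shrink to the available samples.

    The 60-s default mirrors standard noise reduction of frame-wise distance
    traces before periodogram analysis.
    """
    dt = trace.sampling_dt_s
    if window_s < dt:
        raise ValueError(f"window_s={window_s} shorter than sampling interval {dt}")
    w = max(1, int(round(window_s / dt)))
    smoothed = (
        pd.Series(trace.activity).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )
    return replace(trace, activity=smoothed)


def bin_activity(trace: ActivityTrace, bin_width_min: float = 30.0,
                 phase: str = "LD") -> BinnedActivity:
    """Sum activity into fixed ZT bins, one row per day of the given phase.

    Bins are half-open ``[a, b)`` in ZT/CT hours.  Days are counted from the
    first sample of the phase, aligned so that each row spans ZT0..24.
    Trailing (or leading) partial days are retained in the matrix but flagged
    incomplete and excluded from :attr:`BinnedActivity.pooled_profile`.
    """
    if MIN_PER_DAY % bin_width_min != 0:
        raise ValueError(f"bin width {bin_width_min} min must divide 1440 min")
    sub = trace.restrict_phase(phase)
    if sub.time_s.size == 0:
        raise ValueError(f"trace has no {phase} samples")
    n_bins = int(MIN_PER_DAY // bin_width_min)
    zt = sub.zt_hours()
    bin_idx = np.floor(zt / (bin_width_min / 60.0)).astype(int) % n_bins
    # absolute day index relative to the ZT0 preceding the phase start
    abs_day = np.floor((sub.time_s - trace.zt0_offset_s) / 86400.0).astype(int)
    abs_day -= abs_day.min()
    n_days = abs_day.max() + 1
    bins = np.zeros((n_days, n_bins))
    np.add.at(bins, (abs_day, bin_idx), sub.activity)
    # a day is complete when every bin received at least one sample
    counts = np.zeros((n_days, n_bins))
    np.add.at(counts, (abs_day, bin_idx), 1.0)
    complete = (counts > 0).all(axis=1)
    zt_of_bin = np.arange(n_bins) * bin_width_min / 60.0
    return BinnedActivity(
        individual_id=trace.individual_id,
        phase=phase,
        bin_width_min=float(bin_width_min),
        bins=bins,
        zt_of_bin=zt_of_bin,
        complete=complete,
    )


@dataclass
class QcDecision:
    individual_id: str
    included_ld: bool
    included_dd: bool
    reasons: list = field(default_factory=list)


def qc_filter(cohort, min_days: float = 3.0, flags: dict | None = None):
    """Partition traces into included/excluded per phase, with reasons.

    ``flags`` maps individual_id to a dict with optional boolean keys
    ``maturing`` and ``escaped``; either excludes the animal everywhere
    (maturation irreversibly changes behavior; escape truncates the record).
    A phase with fewer than ``min_days`` days of data is excluded for that
    phase only.
    """
    flags = flags or {}
    decisions = []
    for trace in cohort:
        f = flags.get(trace.individual_id, {})
        d = QcDecision(trace.individual_id, True, True)
        if f.get("maturing"):
            d.included_ld = d.included_dd = False
            d.reasons.append("matured during or within 1 week after recording")
        if f.get("escaped"):
            d.included_ld = d.included_dd = False
            d.reasons.append("escaped from tracking well")
        for phase, attr in (("LD", "included_ld"), ("DD", "included_dd")):
            if getattr(d, attr) and trace.phase_duration_days(phase) < min_days:
                setattr(d, attr, False)
                d.reasons.append(
                    f"less than {min_days:g} d of data in {phase} "
                    f"({trace.phase_duration_days(phase):.2f} d)"
                )
        decisions.append(d)
    return decisions


def build_actogram(binned: BinnedActivity, double_plot: bool = True) -> Actogram:
    """Lay out daily bins as an actogram matrix.

    Double-plotting appends the following day to each row so rhythms crossing
    midnight stay visually contiguous; the final row's second half has no
    following day and is filled with NaN.
    """
    m = binned.bins
    if not double_plot:
        return Actogram(m.copy(), False, binned.bin_width_min)
    n_days, n_bins = m.shape
    out = np.full((n_days, 2 * n_bins), np.nan)
    out[:, :n_bins] = m
    if n_days > 1:
        out[:-1, n_bins:] = m[1:]
    return Actogram(out, True, binned.bin_width_min)
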