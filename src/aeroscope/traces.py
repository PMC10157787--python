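"""Reading, segmenting and slope-fitting raw dissolved-oxygen traces.

An intermittent-flow respirometry record alternates flush phases (chamber
re-oxygenated toward saturation) with closed measurement phases during which
the O2 decline is proportional to the fish's oxygen uptake.  The
mass-specific uptake for a closed phase is

    MO2 = |dO2/dt| * (v_R - v_F) / m      [mg O2 kg-1 min-1]

where ``v_R`` is the respirometer volume (L), ``v_F`` the volume displaced
by the fish (L, taken equal to its mass assuming 1 kg = 1 L) and ``m`` the
fish mass (kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraceError",
    "O2Trace",
    "CycleSchedule",
    "CycleWindow",
    "SlopeFit",
    "read_trace",
    "write_trace",
    "segment_cycles",
    "fit_slope",
    "compute_mo2",
    "correct_background",
    "process_trace",
]

#: canonical column names for delimited trace files
TRACE_COLUMNS = ("time_s", "o2_mg_per_l", "temp_c", "phase")


class TraceError(ValueError):
    """Raised for malformed trace inputs (bad columns, time order, rows)."""


@dataclass
class O2Trace:
    """A raw O2/temperature time series for one fish in one respirometer.

    Parameters
    ----------
    fish_id : str
        Identifier of the fish.
    data : pandas.DataFrame
        Columns ``time_s`` (strictly increasing, seconds), ``o2_mg_per_l``
        (>= 0), ``temp_c`` and optionally ``phase`` (labels such as
        ``"flush"`` / ``"measure"``).
    respirometer_volume : float
        v_R in litres.
    fish_mass : float
        m in kilograms.
    fish_volume : float, optional
        v_F in litres; defaults to ``fish_mass`` (1 kg displaces 1 L).
    """

    fish_id: str
    data: pd.DataFrame
    respirometer_volume: float
    fish_mass: float
    fish_volume: float | None = None

    def __post_init__(self) -> None:
        if self.fish_volume is None:
            self.fish_volume = float(self.fish_mass)
        if self.fish_mass <= 0:
            raise TraceError("fish_mass must be positive")
        if self.respirometer_volume <= self.fish_volume:
            raise TraceError(
                "respirometer volume must exceed fish volume "
                f"(v_R={self.respirometer_volume}, v_F={self.fish_volume})"
            )
        if self.respirometer_volume / self.fish_mass < 1.0:
            raise TraceError("fish too large for chamber (volume ratio < 1)")
        t = np.asarray(self.data["time_s"], dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise TraceError(f"time not strictly increasing at row {row}")
        if np.any(np.asarray(self.data["o2_mg_per_l"], dtype=float) < 0):
            row = int(np.argmax(np.asarray(self.data["o2_mg_per_l"]) < 0))
            raise TraceError(f"negative O2 reading at row {row}")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data["time_s"], dtype=float)

    @property
    def o2(self) -> np.ndarray:
        return np.asarray(self.data["o2_mg_per_l"], dtype=float)

    @property
    def has_phase(self) -> bool:
        return "phase" in self.data.columns and self.data["phase"].notna().any()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CycleSchedule:
    """Flush/measure timing of the respirometry protocol.

    ``first_measure_minutes`` covers the special first closed window that
    starts the moment the chamber is sealed after a chase (cycle 0); the
    regular cycles of ``flush_minutes`` + ``measure_minutes`` follow.
    """

    flush_minutes: float
    measure_minutes: float
    start_phase: str = "flush"
    first_measure_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.flush_minutes <= 0 or self.measure_minutes <= 0:
            raise TraceError("cycle durations must be positive")
        if self.start_phase not in ("flush", "measure"):
            raise TraceError("start_phase must be 'flush' or 'measure'")


@dataclass(frozen=True)
class CycleWindow:
    """A closed (measurement) window within a trace, in seconds."""

    cycle_index: int
    t_start: float
    t_end: float

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class SlopeFit:
    """OLS slope of O2 on time for one closed window, with validity flags."""

    slope_per_min: float
    r_squared: float
    n_points: int
    negative: bool
    linear: bool
    artifact_free: bool
    valid: bool
    reason: str | None = None


def read_trace(
    path,
    fish_id: str | None = None,
    respirometer_volume: float | None = None,
    fish_mass: float | None = None,
    fish_volume: float | None = None,
    sep: str = ",",
    time_col: str = "time_s",
    o2_col: str = "o2_mg_per_l",
    temp_col: str = "temp_c",
    phase_col: str = "phase",
) -> O2Trace:
    """Read a delimited logger export into a validated :class:`O2Trace`.

    Column names are configurable; units are assumed to be seconds,
    mg O2 L-1 and degrees Celsius.  Raises :class:`TraceError` naming the
    offending (0-based) data row for unparseable values or non-monotone
    time stamps.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in (time_col, o2_col, temp_col) if c not in df.columns]
    if missing:
        raise TraceError(f"missing columns in {path}: {missing}")
    out = pd.DataFrame()
    for src, dst in ((time_col, "time_s"), (o2_col, "o2_mg_per_l"), (temp_col, "temp_c")):
        vals = pd.to_numeric(df[src], errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy()))
            raise TraceError(f"unparseable value in column '{src}' at row {row}")
        out[dst] = vals.astype(float)
    if phase_col in df.columns:
        out["phase"] = df[phase_col].astype(str)
    t = out["time_s"].to_numpy()
    bad = np.diff(t) <= 0
    if bad.any():
        row = int(np.argmax(bad)) + 1
        raise TraceError(f"time column not increasing at row {row}")
    return O2Trace(
        fish_id=fish_id if fish_id is not None else str(path),
        data=out,
        respirometer_volume=respirometer_volume if respirometer_volume is not None else np.inf,
        fish_mass=fish_mass if fish_mass is not None else 1.0,
        fish_volume=fish_volume,
    )


def write_trace(trace: O2Trace, path, sep: str = ",") -> None:
    """Write a trace in the canonical dialect (round-trips with read_trace)."""
    cols = [c for c in TRACE_COLUMNS if c in trace.data.columns]
    trace.data.to_csv(path, sep=sep, index=False, columns=cols)


# ---------------------------------------------------------------------------
# segmentation


def segment_cycles(
    trace: O2Trace,
    schedule: CycleSchedule | None = None,
    auto: bool = False,
    min_fraction: float = 0.6,
    measure_labels: tuple[str, ...] = ("measure", "closed"),
) -> list[CycleWindow]:
    """Locate the closed measurement windows of a trace.

    Precedence: an explicit ``phase`` column in the trace dominates; then an
    explicit :class:`CycleSchedule`; then ``auto`` detection, which treats
    sustained O2 increases (flush re-oxygenation) as phase boundaries.
    Final windows shorter than ``min_fraction`` of the nominal closed
    duration are discarded (slope fits on very short truncated windows are
    unstable).
    """
    t = trace.times
    if trace.has_phase:
        return _segment_by_labels(trace, measure_labels)
    if schedule is not None:
        return _segment_by_schedule(t, schedule, min_fraction)
    if auto:
        return _segment_auto(trace, min_fraction)
    raise TraceError("no phase labels; supply a schedule or enable auto detection")


def _segment_by_labels(trace: O2Trace, measure_labels) -> list[CycleWindow]:
    phases = trace.data["phase"].astype(str).str.lower().to_numpy()
    t = trace.times
    is_meas = np.isin(phases, [m.lower() for m in measure_labels])
    windows: list[CycleWindow] = []
    idx = 0
    start = None
    for i in range(len(t)):
        if is_meas[i] and start is None:
            start = i
        elif not is_meas[i] and start is not None:
            windows.append(CycleWindow(idx, t[start], t[i - 1]))
            idx += 1
            start = None
    if start is not None:
        windows.append(CycleWindow(idx, t[start], t[-1]))
    return windows


def _segment_by_schedule(t: np.ndarray, schedule: CycleSchedule, min_fraction: float) -> list[CycleWindow]:
    t0, t_end = t[0], t[-1]
    if t_end <= t0:
        raise TraceError("empty trace")
    flush_s = schedule.flush_minutes * 60.0
    meas_s = schedule.measure_minutes * 60.0
    first_s = (
        schedule.first_measure_minutes * 60.0
        if schedule.first_measure_minutes is not None
        else meas_s
    )
    windows: list[CycleWindow] = []
    cursor = t0
    idx = 0
    if schedule.start_phase == "measure":
        windows.append(CycleWindow(idx, cursor, min(cursor + first_s, t_end)))
        idx += 1
        cursor += first_s + flush_s
    else:
        cursor += flush_s
    if cursor >= t_end and not windows:
        raise TraceError("schedule longer than trace: no measurement window fits")
    while cursor < t_end:
        windows.append(CycleWindow(idx, cursor, min(cursor + meas_s, t_end)))
        idx += 1
        cursor += meas_s + flush_s
    nominal = {0: first_s if schedule.start_phase == "measure" else meas_s}
    kept = [
        w for w in windows
        if (w.t_end - w.t_start) >= min_fraction * nominal.get(w.cycle_index, meas_s)
    ]
    return [CycleWindow(i, w.t_start, w.t_end) for i, w in enumerate(kept)]


def _segment_auto(trace: O2Trace, min_fraction: float, smooth_s: float = 30.0) -> list[CycleWindow]:
    """Detect closed windows as sustained O2 declines between flush rises."""
    t, o2 = trace.times, trace.o2
    if len(t) < 10:
        raise TraceError("trace too short for auto segmentation")
    # moving-average smoothing over ~smooth_s to suppress probe noise
    dt = float(np.median(np.diff(t)))
    k = max(1, int(round(smooth_s / dt)))
    kernel = np.ones(k) / k
    sm = np.convolve(o2, kernel, mode="same")
    rising = np.gradient(sm, t) > 0
    windows: list[CycleWindow] = []
    start = None
    idx = 0
    for i in range(len(t)):
        if not rising[i] and start is None:
            start = i
        elif rising[i] and start is not None:
            if t[i - 1] - t[start] >= 60.0:  # ignore sub-minute dips
                windows.append(CycleWindow(idx, t[start], t[i - 1]))
                idx += 1
            start = None
    if start is not None and t[-1] - t[start] >= 60.0:
        windows.append(CycleWindow(idx, t[start], t[-1]))
    if not windows:
        raise TraceError("auto segmentation found no measurement cycles")
    return windows


# ---------------------------------------------------------------------------
# slope fitting and MO2 conversion


def fit_slope(
    t_seconds,
    o2,
    r2_threshold: float = 0.9,
    jump_sd_multiple: float = 5.0,
    min_points: int = 5,
) -> SlopeFit:
    """OLS regression of O2 on time over one closed window.

    Fits per second internally and reports the slope per minute.  Three
    programmatic flags stand in for the visual screening applied to such
    regressions: ``negative`` (slope < 0), ``linear`` (r2 >= threshold) and
    ``artifact_free`` (no single-point jump in the residuals larger than
    ``jump_sd_multiple`` residual SDs).  Windows with fewer than
    ``min_points`` samples are marked invalid rather than raising.
    """
    t = np.asarray(t_seconds, dtype=float)
    y = np.asarray(o2, dtype=float)
    n = len(t)
    if n < min_points:
        return SlopeFit(np.nan, np.nan, n, False, False, False, False,
                        reason=f"fewer than {min_points} points")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0:
        return SlopeFit(np.nan, np.nan, n, False, False, False, False,
                        reason="zero time variance")
    slope = float(tc @ (y - y.mean())) / sxx  # mg L-1 s-1
    resid = y - (y.mean() + slope * tc)
    ss_res = float(resid @ resid)
    ss_tot = float((y - y.mean()) @ (y - y.mean()))
    # a perfectly flat window is a perfect fit with zero slope
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    resid_sd = float(np.std(resid))
    if resid_sd > 0 and n > 2:
        jumps = np.abs(np.diff(resid))
        artifact_free = bool(np.max(jumps) <= jump_sd_multiple * resid_sd)
    else:
        artifact_free = True
    return SlopeFit(
        slope_per_min=slope * 60.0,
        r_squared=r2,
        n_points=n,
        negative=bool(slope < 0),
        linear=bool(r2 >= r2_threshold),
        artifact_free=artifact_free,
        valid=True,
    )


def compute_mo2(slope_magnitude: float, v_r: float, v_f: float, m: float) -> float:
    """Convert an O2-decline slope magnitude to mass-specific MO2.

    ``MO2 = |dO2/dt| * (v_R - v_F) / m`` with the slope in mg L-1 min-1,
    volumes in litres and mass in kg, giving mg O2 kg-1 min-1.
    """
    if not (v_r > v_f > 0):
        raise ValueError(f"need v_R > v_F > 0, got v_R={v_r}, v_F={v_f}")
    if m <= 0:
        raise ValueError("fish mass must be positive")
    if slope_magnitude < 0:
        raise ValueError("pass the magnitude of a negative fitted slope")
    return slope_magnitude * (v_r - v_f) / m


def correct_background(
    mo2: np.ndarray,
    t_minutes: np.ndarray | None = None,
    pre_rate: float = 0.0,
    post_rate: float = 0.0,
    v_r: float = 1.0,
    v_f: float = 0.0,
    m: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Optionally subtract microbial background respiration from MO2 entries.

    Background rates (mg O2 L-1 min-1) measured before and after the trial
    are linearly interpolated over the record and converted through the same
    volume term as the fish's MO2.  Both rates default to zero — background
    respiration measured around these trials is typically negligible and
    not incorporated.  Entries driven below zero are clipped and flagged.

    Returns ``(adjusted_mo2, clipped_flags)``.
    """
    mo2 = np.asarray(mo2, dtype=float)
    if pre_rate == 0.0 and post_rate == 0.0:
        return mo2.copy(), np.zeros(len(mo2), dtype=bool)
    if t_minutes is None:
        frac = np.linspace(0.0, 1.0, len(mo2))
    else:
        t = np.asarray(t_minutes, dtype=float)
        span = t[-1] - t[0]
        frac = (t - t[0]) / span if span > 0 else np.zeros_like(t)
    rate = pre_rate + (post_rate - pre_rate) * frac
    adjusted = mo2 - rate * (v_r - v_f) / m
    clipped = adjusted < 0
    return np.where(clipped, 0.0, adjusted), clipped


def process_trace(
    trace: O2Trace,
    schedule: CycleSchedule | None = None,
    auto: bool = False,
    r2_threshold: float = 0.9,
    jump_sd_multiple: float = 5.0,
    min_fraction: float = 0.6,
) -> pd.DataFrame:
    """Segment a trace, fit every closed-window slope and convert to MO2.

    Returns a per-cycle table with columns ``fish_id, cycle, t_start, t_end,
    t_mid_min, slope_per_min, r_squared, n_points, mo2, negative, linear,
    artifact_free, valid``.  ``mo2`` is NaN for windows whose slope is not
    negative (an increasing O2 trend cannot be an uptake rate).
    """
    windows = segment_cycles(trace, schedule=schedule, auto=auto, min_fraction=min_fraction)
    t, o2 = trace.times, trace.o2
    rows = []
    for w in windows:
        sel = (t >= w.t_start) & (t <= w.t_end)
        fit = fit_slope(t[sel], o2[sel], r2_threshold=r2_threshold,
                        jump_sd_multiple=jump_sd_multiple)
        if fit.valid and fit.slope_per_min <= 0:
            mo2 = compute_mo2(abs(fit.slope_per_min), trace.respirometer_volume,
                              trace.fish_volume, trace.fish_mass)
        else:
            mo2 = np.nan
        rows.append({
            "fish_id": trace.fish_id,
            "cycle": w.cycle_index,
            "t_start": w.t_start,
            "t_end": w.t_end,
            "t_mid_min": w.t_mid / 60.0,
            "slope_per_min": fit.slope_per_min,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "mo2": mo2,
            "negative": fit.negative,
            "linear": fit.linear,
            "artifact_free": fit.artifact_free,
            "valid": fit.valid and fit.negative and fit.artifact_free,
        })
    return pd.DataFrame(rows)
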