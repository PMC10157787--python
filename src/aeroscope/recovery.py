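"""Post-exercise recovery metrics: %AAS, %MMR, recMMR50 and EPOC.

Recovery after an exhaustive chase is tracked three ways over the first
50 minutes — the fraction of aerobic scope restored (%AAS, referenced to
the fish's overall MMR), the raw MO2 as a fraction of the stage's chase MMR
(%MMR), and the time to fall to 50% of that chase MMR (recMMR50).  The
oxygen debt (EPOC) is the area between a cubic smoothing spline through the
overnight MO2 record and the resting rate, accumulated until the spline
first returns to RMR and reported in hourly blocks.

Because %AAS is referenced to MMR_overall while the chase itself peaks at
the (possibly lower) stage MMR, %AAS at time 0 generally starts above 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .rates import Estimate

__all__ = [
    "RecoveryProfile",
    "EpocResult",
    "recovery_timecourse",
    "rec_mmr50",
    "compute_epoc",
    "recovery_profile",
]

RECOVERY_BLOCKS_MIN = (0, 10, 20, 30, 40, 50)


def recovery_timecourse(
    t_minutes,
    mo2,
    aas: float,
    mmr_ref: float,
    mmr_overall: float,
    blocks=RECOVERY_BLOCKS_MIN,
) -> pd.DataFrame:
    """%AAS and %MMR pooled into 10-min blocks over early recovery.

    %AAS(t) = 100 * (MMR_overall - MO2(t)) / AAS measures how much of the
    aerobic scope has been restored (100 = fully recovered to RMR);
    %MMR(t) = 100 * MO2(t) / MMR_ref, where ``mmr_ref`` is the chase MMR of
    the stage being analysed.  Measurements are assigned to blocks by their
    midpoint time and averaged within block.

    Raises ``ValueError`` when ``aas`` is not positive (mortalities have no
    recovery profile).
    """
    if aas <= 0 or np.isnan(aas):
        raise ValueError("aas must be positive; mortalities have no recovery profile")
    t = np.asarray(t_minutes, dtype=float)
    y = np.asarray(mo2, dtype=float)
    width = blocks[1] - blocks[0] if len(blocks) > 1 else 10.0
    rows = []
    for b in blocks:
        sel = (t >= b) & (t < b + width)
        if sel.any():
            m = float(np.mean(y[sel]))
            rows.append({
                "block_min": b,
                "pct_aas": 100.0 * (mmr_overall - m) / aas,
                "pct_mmr": 100.0 * m / mmr_ref,
                "n": int(sel.sum()),
            })
        else:
            rows.append({"block_min": b, "pct_aas": np.nan,
                         "pct_mmr": np.nan, "n": 0})
    return pd.DataFrame(rows)


def rec_mmr50(t_minutes, mo2, mmr_ref: float,
              band: tuple[float, float] = (0.48, 0.52)) -> Estimate:
    """Time to recover to 50% of the chase MMR.

    Returns the time (minutes since chase) of the first measurement whose
    MO2 falls within ``band`` (fractions of ``mmr_ref``); fish whose record
    jumps across the band without a distinct measurement inside it are
    excluded (missing-with-reason).
    """
    t = np.asarray(t_minutes, dtype=float)
    y = np.asarray(mo2, dtype=float) / mmr_ref
    inside = (y >= band[0]) & (y <= band[1])
    if not inside.any():
        return Estimate(np.nan, reason=(
            f"no measurement between {band[0]:.0%} and {band[1]:.0%} of MMR"))
    return Estimate(float(t[np.argmax(inside)]))


@dataclass(frozen=True)
class EpocResult:
    cumulative: float          # mg O2 kg-1
    hourly: tuple              # hours 1..5, mg O2 kg-1
    complete: bool             # spline returned to RMR before the horizon
    t_return_min: float | None # time of return to RMR, minutes
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.reason is not None


def compute_epoc(
    t_minutes,
    mo2,
    rmr: float,
    horizon_min: float = 300.0,
    min_measurements: int = 60,
    return_tol: float = 0.02,
    lam: float | None = None,
    grid_dt_min: float = 0.1,
    n_hours: int = 5,
) -> EpocResult:
    """Spline-based excess post-exercise oxygen consumption.

    A cubic smoothing spline (penalty chosen by generalized cross-validation
    unless ``lam`` is given) is fit to the (t, MO2) record starting at the
    chase; EPOC is the integral of max(spline - RMR, 0) from t=0 until the
    spline first drops to within ``return_tol`` of RMR (recovery complete)
    or until ``horizon_min``.  Exact equality with RMR never occurs on
    noisy data, hence the tolerance.  The integral is also split into the
    first ``n_hours`` hourly blocks.  Records with <= ``min_measurements``
    points are ineligible.
    """
    t = np.asarray(t_minutes, dtype=float)
    y = np.asarray(mo2, dtype=float)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if len(t) <= min_measurements:
        return EpocResult(np.nan, (np.nan,) * n_hours, False, None, reason=(
            f"only {len(t)} measurements (> {min_measurements} required)"))
    order = np.argsort(t)
    t, y = t[order], y[order]
    spline = make_smoothing_spline(t, y, lam=lam)
    t_end = min(float(t[-1]), horizon_min)
    grid = np.arange(t[0], t_end + 0.5 * grid_dt_min, grid_dt_min)
    s = spline(grid)

    returned = s <= rmr * (1.0 + return_tol)
    if returned.any():
        i_ret = int(np.argmax(returned))
        t_return = float(grid[i_ret])
        complete = True
    else:
        i_ret = len(grid) - 1
        t_return = None
        complete = False

    excess = np.maximum(s - rmr, 0.0)
    excess[i_ret + 1:] = 0.0  # stop accumulating once recovered
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (excess[1:] + excess[:-1]) * np.diff(grid))])
    cumulative = float(cum[-1])
    hourly = []
    for h in range(1, n_hours + 1):
        lo, hi = (h - 1) * 60.0, h * 60.0
        lo_v = float(np.interp(lo, grid, cum))
        hi_v = float(np.interp(hi, grid, cum)) if hi <= grid[-1] else float(cum[-1])
        hourly.append(max(hi_v - lo_v, 0.0))
    return EpocResult(cumulative, tuple(hourly), complete, t_return)


@dataclass
class RecoveryProfile:
    """Per-fish recovery summary for one chase stage."""

    fish_id: str
    chase_stage: str                      # "MMR_1h" or "MMR_18h"
    timecourse: pd.DataFrame | None       # block table (block_min, pct_aas, pct_mmr)
    rec_mmr50: Estimate
    epoc: EpocResult | None
    reason: str | None = None


def recovery_profile(
    fish_id: str,
    chase_stage: str,
    t_minutes,
    mo2,
    rmr: float,
    aas: float,
    mmr_ref: float,
    mmr_overall: float,
    band: tuple[float, float] = (0.48, 0.52),
    compute_epoc_kwargs: dict | None = None,
    with_epoc: bool = True,
) -> RecoveryProfile:
    """Assemble the full recovery profile for one fish and chase stage.

    EPOC is only meaningful for the overnight record after the first chase;
    pass ``with_epoc=False`` for the short post-18h stage.
    """
    if aas is None or np.isnan(aas) or aas <= 0:
        return RecoveryProfile(fish_id, chase_stage, None,
                               Estimate(np.nan, reason="zero or missing aerobic scope"),
                               None, reason="zero or missing aerobic scope")
    tc = recovery_timecourse(t_minutes, mo2, aas, mmr_ref, mmr_overall)
    r50 = rec_mmr50(t_minutes, mo2, mmr_ref, band=band)
    epoc = None
    if with_epoc:
        epoc = compute_epoc(t_minutes, mo2, rmr, **(compute_epoc_kwargs or {}))
    return RecoveryProfile(fish_id, chase_stage, tc, r50, epoc)
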