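"""Per-fish metabolic-rate estimation.

Maximum metabolic rate (MMR) after an exhaustive chase is the steepest
qualifying O2-decline slope found by a sliding-window search over the first
closed measurement cycle; the overall MMR is the per-fish maximum over the
chase estimates and every validated overnight measurement.  Resting
metabolic rate (RMR) is a low quantile of the validated overnight MO2
record.  Aerobic scope combines the two, with mortalities assigned zero
scope.  Allometric mass adjustment, Q10 temperature coefficients and
scaling-exponent estimation round out the per-fish summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
import pandas as pd

from .traces import compute_mo2

__all__ = [
    "Estimate",
    "MetabolicSummary",
    "estimate_mmr_chase",
    "estimate_mmr_overall",
    "estimate_rmr",
    "aerobic_scope",
    "mass_adjust",
    "compute_q10",
    "estimate_scaling_exponent",
    "summarize_fish",
    "group_summary",
]


@dataclass(frozen=True)
class Estimate:
    """A numeric estimate that may be missing for a stated reason."""

    value: float
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.reason is not None or isnan(self.value)

    def __float__(self) -> float:
        return float(self.value)


def estimate_mmr_chase(
    t_seconds,
    o2,
    v_r: float,
    v_f: float,
    m: float,
    min_window_s: float = 90.0,
    step_s: float = 1.0,
    r2_min: float = 0.9,
) -> Estimate:
    """MMR from a sliding-window slope search over the first closed cycle.

    Every window of duration >= ``min_window_s``, starting at any sample and
    advancing in ``step_s`` increments, is fit by OLS; the steepest negative
    slope with r2 > ``r2_min`` is converted to MO2.  The search maximises
    over window length as well as start position, so "steepest" is taken
    over the full (start, length) space.  Returns a missing estimate with a
    reason when the cycle is shorter than the minimum window or no window
    qualifies.
    """
    t = np.asarray(t_seconds, dtype=float)
    y = np.asarray(o2, dtype=float)
    n = len(t)
    if n < 5 or t[-1] - t[0] < min_window_s:
        return Estimate(np.nan, reason=f"cycle shorter than {min_window_s:g} s")

    # prefix sums for O(1) OLS statistics of any window [i, j]
    S1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    St = np.concatenate([[0.0], np.cumsum(t)])
    Sy = np.concatenate([[0.0], np.cumsum(y)])
    Stt = np.concatenate([[0.0], np.cumsum(t * t)])
    Sty = np.concatenate([[0.0], np.cumsum(t * y)])
    Syy = np.concatenate([[0.0], np.cumsum(y * y)])

    # candidate start indices on the step_s grid
    starts = [0]
    for i in range(1, n):
        if t[i] - t[starts[-1]] >= step_s - 1e-9:
            starts.append(i)
    best_slope = 0.0  # slopes of interest are negative
    found = False
    for i in starts:
        # all window ends j with duration >= min_window_s and >= 5 points
        j_min = int(np.searchsorted(t, t[i] + min_window_s, side="left"))
        j_min = max(j_min, i + 4)
        if j_min >= n:
            continue
        js = np.arange(j_min, n)
        cnt = S1[js + 1] - S1[i]
        st = St[js + 1] - St[i]
        sy = Sy[js + 1] - Sy[i]
        stt = Stt[js + 1] - Stt[i]
        sty = Sty[js + 1] - Sty[i]
        syy = Syy[js + 1] - Syy[i]
        sxx = stt - st * st / cnt
        sxy = sty - st * sy / cnt
        syy_c = syy - sy * sy / cnt
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            r2 = np.where(syy_c > 0, (sxy * sxy) / (sxx * syy_c), 0.0)
        ok = (slope < 0) & (r2 > r2_min) & (sxx > 0)
        if ok.any():
            cand = slope[ok].min()
            if cand < best_slope:
                best_slope = cand
                found = True
    if not found:
        return Estimate(np.nan, reason=f"no window with r2 > {r2_min:g}")
    slope_per_min = abs(best_slope) * 60.0
    return Estimate(compute_mo2(slope_per_min, v_r, v_f, m))


def estimate_mmr_overall(
    overnight_mo2,
    mmr_1h: float | None = None,
    mmr_18h: float | None = None,
    min_measurements: int = 60,
) -> Estimate:
    """Per-fish maximum MO2 over chase estimates and overnight record.

    Requires strictly more than ``min_measurements`` validated overnight MO2
    values (fish with sparse records cannot support a credible maximum);
    otherwise returns missing-with-reason.
    """
    mo2 = np.asarray(overnight_mo2, dtype=float)
    mo2 = mo2[~np.isnan(mo2)]
    if len(mo2) <= min_measurements:
        return Estimate(np.nan, reason=(
            f"only {len(mo2)} overnight measurements (> {min_measurements} required)"))
    candidates = [float(np.max(mo2))]
    for v in (mmr_1h, mmr_18h):
        if v is not None and not isnan(v):
            candidates.append(float(v))
    return Estimate(max(candidates))


def estimate_rmr(
    mo2,
    r_squared=None,
    r2_min: float = 0.85,
    quantile: float = 0.10,
    min_measurements: int = 60,
    method: str = "quantile",
) -> Estimate:
    """Resting metabolic rate as a low quantile of validated overnight MO2.

    ``method="quantile"`` (default) takes the 0.10 quantile of the
    validated values under numpy's linear-interpolation convention;
    ``method="decile_mean"`` averages the values at or below that quantile
    instead.  Entries with r2 <= ``r2_min`` are dropped when an ``r_squared``
    array is supplied.  Fewer than ``min_measurements`` validated entries
    gives missing-with-reason.
    """
    mo2 = np.asarray(mo2, dtype=float)
    if r_squared is not None:
        r2 = np.asarray(r_squared, dtype=float)
        mo2 = mo2[r2 > r2_min]
    mo2 = mo2[~np.isnan(mo2)]
    if len(mo2) < min_measurements:
        return Estimate(np.nan, reason=(
            f"only {len(mo2)} validated measurements (>= {min_measurements} required)"))
    q = float(np.quantile(mo2, quantile))
    if method == "quantile":
        return Estimate(q)
    if method == "decile_mean":
        low = mo2[mo2 <= q]
        return Estimate(float(low.mean()))
    raise ValueError(f"unknown RMR method {method!r}")


@dataclass(frozen=True)
class ScopeResult:
    aas: float
    fas: float
    flagged: bool = False   # survivor with rmr >= mmr_overall


def aerobic_scope(mmr_overall: float, rmr: float, survived: bool) -> ScopeResult:
    """Absolute and factorial aerobic scope with the mortality-as-zero rule.

    Survivors: AAS = MMR_overall - RMR and FAS = MMR_overall / RMR.  A fish
    that died during the trial has, by definition, zero aerobic scope, so
    both are 0 regardless of any measured rates.  A survivor whose RMR
    reaches its MMR is computed as-is but flagged.
    """
    if not survived:
        return ScopeResult(0.0, 0.0)
    if mmr_overall is None or rmr is None or isnan(mmr_overall) or isnan(rmr):
        raise ValueError("survivor requires both mmr_overall and rmr")
    flagged = rmr >= mmr_overall
    return ScopeResult(mmr_overall - rmr, mmr_overall / rmr, flagged)


def mass_adjust(mo2: float, mass: float, exponent: float,
                reference_mass: float = 3.5) -> float:
    """Adjust a mass-specific rate to a common reference body mass.

    Whole-animal metabolism scales as mass**b, so the mass-specific rate
    scales as mass**(b-1) and the adjustment to ``reference_mass`` is
    ``mo2 * (mass / reference_mass)**(1 - b)``.  Exponents of 0.58 (MMR)
    and 0.67 (RMR) are the package defaults elsewhere.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if not 0 < exponent < 1.5:
        raise ValueError("scaling exponent outside the plausible range (0, 1.5)")
    return mo2 * (mass / reference_mass) ** (1.0 - exponent)


def compute_q10(r12: float, t12: float, rx: float, tx: float) -> float:
    """Temperature coefficient Q10 = (RX / R12) ** (10 / (TX - T12))."""
    if r12 <= 0 or rx <= 0:
        raise ValueError("rates must be positive")
    if tx == t12:
        raise ValueError("temperatures must differ")
    return (rx / r12) ** (10.0 / (tx - t12))


def estimate_scaling_exponent(mass, whole_animal_mo2, groups=None):
    """Allometric scaling exponent b from log10-log10 least squares.

    Fits log10(MO2_whole) = a + b*log10(mass); with ``groups`` given, each
    group gets its own intercept while the slope b is shared.  Returns
    ``(b, intercepts)`` where intercepts maps group label (or None) to a.
    """
    mass = np.asarray(mass, dtype=float)
    mo2 = np.asarray(whole_animal_mo2, dtype=float)
    if len(mass) < 3:
        raise ValueError("need at least 3 fish")
    lx = np.log10(mass)
    ly = np.log10(mo2)
    if np.ptp(lx) == 0:
        raise ValueError("zero mass variance")
    if groups is None:
        X = np.column_stack([np.ones(len(lx)), lx])
        coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
        return float(coef[1]), {None: float(coef[0])}
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    X = np.zeros((len(lx), len(labels) + 1))
    for j, g in enumerate(labels):
        X[groups == g, j] = 1.0
    X[:, -1] = lx
    coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
    return float(coef[-1]), {g: float(coef[j]) for j, g in enumerate(labels)}


# ---------------------------------------------------------------------------
# per-fish summary


@dataclass
class MetabolicSummary:
    """Per-fish metabolic phenotype with mass-adjusted variants."""

    fish_id: str
    population: str | None
    test_temperature: float | None
    body_mass: float
    survived: bool
    rmr: Estimate
    mmr_1h: Estimate
    mmr_18h: Estimate
    mmr_overall: Estimate
    aas: float
    fas: float
    n_validated_mo2: int
    rmr_adj: float = np.nan
    mmr_overall_adj: float = np.nan
    aas_adj: float = np.nan
    fas_adj: float = np.nan
    flagged: bool = False

    def to_dict(self) -> dict:
        d = {
            "fish_id": self.fish_id,
            "population": self.population,
            "test_temperature": self.test_temperature,
            "body_mass": self.body_mass,
            "survived": self.survived,
            "rmr": self.rmr.value, "rmr_reason": self.rmr.reason,
            "mmr_1h": self.mmr_1h.value, "mmr_1h_reason": self.mmr_1h.reason,
            "mmr_18h": self.mmr_18h.value, "mmr_18h_reason": self.mmr_18h.reason,
            "mmr_overall": self.mmr_overall.value,
            "mmr_overall_reason": self.mmr_overall.reason,
            "aas": self.aas, "fas": self.fas,
            "n_validated_mo2": self.n_validated_mo2,
            "rmr_adj": self.rmr_adj, "mmr_overall_adj": self.mmr_overall_adj,
            "aas_adj": self.aas_adj, "fas_adj": self.fas_adj,
            "flagged": self.flagged,
        }
        return d


def summarize_fish(
    cycles_1h: pd.DataFrame,
    trace_meta: dict,
    survived: bool,
    cycles_18h: pd.DataFrame | None = None,
    fish_id: str = "",
    population: str | None = None,
    test_temperature: float | None = None,
    r2_mmr: float = 0.9,
    r2_rmr: float = 0.85,
    rmr_quantile: float = 0.10,
    min_measurements: int = 60,
    min_window_s: float = 90.0,
    exponent_mmr: float = 0.58,
    exponent_rmr: float = 0.67,
    reference_mass: float = 3.5,
    raw_cycle0_1h: tuple | None = None,
    raw_cycle0_18h: tuple | None = None,
) -> MetabolicSummary:
    """Combine per-cycle MO2 tables into a fish-level metabolic summary.

    ``cycles_1h`` / ``cycles_18h`` are per-cycle tables from
    :func:`aeroscope.traces.process_trace` for the overnight record after
    the first chase and the short record after the second.
    ``raw_cycle0_*`` optionally provide ``(t_seconds, o2)`` raw samples of
    the first closed window for the sliding-window MMR search; when absent
    the chase MMR falls back to the cycle-0 whole-window estimate.
    ``trace_meta`` needs keys ``v_r``, ``v_f``, ``m``.
    """
    v_r, v_f, m = trace_meta["v_r"], trace_meta["v_f"], trace_meta["m"]

    def chase_mmr(raw, cycles):
        if raw is not None:
            return estimate_mmr_chase(raw[0], raw[1], v_r, v_f, m,
                                      min_window_s=min_window_s, r2_min=r2_mmr)
        if cycles is not None and len(cycles) and (cycles["cycle"] == 0).any():
            row = cycles[cycles["cycle"] == 0].iloc[0]
            if row["valid"] and row["r_squared"] > r2_mmr:
                return Estimate(float(row["mo2"]))
        return Estimate(np.nan, reason="no qualifying chase cycle")

    mmr_1h = chase_mmr(raw_cycle0_1h, cycles_1h)
    mmr_18h = chase_mmr(raw_cycle0_18h, cycles_18h)

    overnight = cycles_1h[(cycles_1h["cycle"] > 0) & cycles_1h["valid"]]
    overnight_mo2 = overnight["mo2"].to_numpy()
    overnight_r2 = overnight["r_squared"].to_numpy()

    rmr = estimate_rmr(overnight_mo2, overnight_r2, r2_min=r2_rmr,
                       quantile=rmr_quantile, min_measurements=min_measurements)
    validated = overnight_mo2[overnight_r2 > r2_rmr]
    mmr_overall = estimate_mmr_overall(
        validated,
        mmr_1h=None if mmr_1h.is_missing else mmr_1h.value,
        mmr_18h=None if mmr_18h.is_missing else mmr_18h.value,
        min_measurements=min_measurements,
    )

    if survived and not rmr.is_missing and not mmr_overall.is_missing:
        scope = aerobic_scope(mmr_overall.value, rmr.value, survived=True)
        aas, fas, flagged = scope.aas, scope.fas, scope.flagged
    elif not survived:
        scope = aerobic_scope(np.nan, np.nan, survived=False)
        aas, fas, flagged = scope.aas, scope.fas, False
    else:
        aas, fas, flagged = np.nan, np.nan, False

    summary = MetabolicSummary(
        fish_id=fish_id, population=population,
        test_temperature=test_temperature, body_mass=m, survived=survived,
        rmr=rmr, mmr_1h=mmr_1h, mmr_18h=mmr_18h, mmr_overall=mmr_overall,
        aas=aas, fas=fas, n_validated_mo2=int(len(validated)), flagged=flagged,
    )
    if not rmr.is_missing:
        summary.rmr_adj = mass_adjust(rmr.value, m, exponent_rmr, reference_mass)
    if not mmr_overall.is_missing:
        summary.mmr_overall_adj = mass_adjust(mmr_overall.value, m,
                                              exponent_mmr, reference_mass)
    if survived and not rmr.is_missing and not mmr_overall.is_missing:
        summary.aas_adj = summary.mmr_overall_adj - summary.rmr_adj
        summary.fas_adj = summary.mmr_overall_adj / summary.rmr_adj
    elif not survived:
        summary.aas_adj = 0.0
        summary.fas_adj = 0.0
    return summary


def group_summary(summaries: pd.DataFrame,
                  metrics=("rmr", "mmr_overall", "aas", "fas"),
                  by=("population", "test_temperature")) -> pd.DataFrame:
    """Mean and SEM of per-fish metrics by population x temperature.

    Computed per individual first and then averaged, so the group FAS is the
    mean of individual ratios, not the ratio of group means.
    """
    rows = []
    for keys, grp in summaries.groupby(list(by)):
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        for mcol in metrics:
            vals = pd.to_numeric(grp[mcol], errors="coerce").dropna()
            rec[f"{mcol}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{mcol}_sem"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                  if len(vals) > 1 else np.nan)
            rec[f"{mcol}_n"] = len(vals)
        rows.append(rec)
    return pd.DataFrame(rows)
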