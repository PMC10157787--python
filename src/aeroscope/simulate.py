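"""Synthetic respirometry cohorts with a ground-truth ledger.

The generator emulates the raw material of an acute thermal-challenge
respirometry study on adult salmon: per-fish dissolved-oxygen traces from
intermittent-flow respirometers, a cohort table (morphometrics, test
temperature, survival), and Bernoulli survival outcomes governed by a
log-logistic dose-response in temperature.  Every simulated quantity is
recorded in a ledger so the downstream estimators can be checked against
truth.

The generative model for oxygen uptake after an exhaustive chase is
mono-exponential recovery toward the temperature-dependent resting rate:

    MO2(t) = RMR(T) + (MMR - RMR(T)) * exp(-k t)
    RMR(T) = rmr12 * q10**((T - 12) / 10)

which has the closed-form oxygen debt EPOC = (MMR - RMR)/k used as an
oracle in tests.  Spontaneous activity during overnight recovery is
modelled as rectangular MO2 excursions with a per-cycle probability, which
is how a fish's overall maximum MO2 can exceed its post-chase maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traces import CycleSchedule, O2Trace

__all__ = [
    "FishPhenotype",
    "SimConfig",
    "Burst",
    "CohortSim",
    "rmr_at_temperature",
    "simulate_mo2_trajectory",
    "simulate_o2_trace",
    "simulate_survival_outcomes",
    "simulate_cohort",
]


def rmr_at_temperature(rmr12: float, q10: float, temperature: float,
                       t_ref: float = 12.0) -> float:
    """Resting metabolic rate at ``temperature`` given the rate at 12 C."""
    return rmr12 * q10 ** ((temperature - t_ref) / 10.0)


@dataclass
class FishPhenotype:
    """Ground-truth physiological parameters for one simulated fish.

    ``rmr12`` and ``mmr_true`` are mass-specific rates in mg O2 kg-1 min-1;
    ``epoc_rate_k`` is the mono-exponential recovery rate (min-1);
    ``burst_prob`` is the per-measurement-cycle probability of a spontaneous
    activity excursion during overnight recovery.
    """

    fish_id: str
    population: str
    sex: str
    body_mass: float            # kg
    fork_length: float          # mm
    rmr12: float                # mg O2 kg-1 min-1 at 12 C
    q10_true: float
    mmr_true: float             # mg O2 kg-1 min-1
    epoc_rate_k: float          # min-1
    burst_prob: float = 0.0
    organ_masses: dict = field(default_factory=dict)   # g
    hematocrit: float = 50.0    # %

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.rmr12 <= 0:
            raise ValueError("rmr12 must be positive")
        if self.mmr_true <= self.rmr12:
            raise ValueError("mmr_true must exceed rmr12")
        if self.q10_true <= 0:
            raise ValueError("q10_true must be positive")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must be a probability")

    def rmr_at(self, temperature: float) -> float:
        return rmr_at_temperature(self.rmr12, self.q10_true, temperature)


@dataclass(frozen=True)
class Burst:
    """A rectangular spontaneous-activity excursion added to MO2."""

    t_start: float   # minutes since chase
    duration: float  # minutes
    height: float    # mg O2 kg-1 min-1 added on top of the recovery curve


@dataclass
class SimConfig:
    """Protocol and noise settings for the simulator.

    Defaults mirror a large-salmon intermittent-flow protocol: 54.5 or 98 L
    chambers, 15-min cycles of 9 min flushing + 6 min closed, a special
    5-min closed window immediately after each chase, ~18 h of overnight
    recording, and weekly-calibrated optode noise.  ``seed`` fixes all
    randomness.
    """

    respirometer_volume: float = 98.0      # L
    flush_minutes: float = 9.0
    measure_minutes: float = 6.0
    first_measure_minutes: float = 5.0     # special post-chase closed window
    cycle_count: int = 72                  # regular cycles after cycle 0
    test_temperature: float = 12.0         # C
    noise_sd: float = 0.02                 # mg L-1 on each O2 reading
    background_rate: float = 0.0           # mg O2 L-1 min-1
    o2_saturation: float = 10.0            # mg L-1
    sample_dt_s: float = 1.0
    flush_tau_s: float = 30.0              # re-oxygenation time constant
    drift_per_hour: float = 0.0            # optional linear probe drift, mg L-1 h-1
    seed: int = 0
    survival_m50: float = 21.0             # C
    survival_slope: float = 25.0
    n_per_temperature: int = 10

    def __post_init__(self) -> None:
        if self.respirometer_volume <= 0:
            raise ValueError("respirometer_volume must be positive")
        for name in ("flush_minutes", "measure_minutes", "first_measure_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def schedule(self) -> CycleSchedule:
        return CycleSchedule(
            flush_minutes=self.flush_minutes,
            measure_minutes=self.measure_minutes,
            start_phase="measure",
            first_measure_minutes=self.first_measure_minutes,
        )


def simulate_mo2_trajectory(
    phenotype: FishPhenotype,
    temperature: float,
    t_grid,
    bursts: list[Burst] | None = None,
) -> np.ndarray:
    """True mass-specific MO2 on ``t_grid`` (minutes since chase).

    MO2(0) equals the fish's true MMR and decays mono-exponentially toward
    the temperature-dependent RMR; optional rectangular bursts are added on
    top.  Strictly decreasing when no bursts are present.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("t_grid must be a non-empty 1-d array")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not 0.0 <= temperature <= 30.0:
        raise ValueError("temperature outside the supported range [0, 30] C")
    rmr = phenotype.rmr_at(temperature)
    mo2 = rmr + (phenotype.mmr_true - rmr) * np.exp(-phenotype.epoc_rate_k * t)
    if bursts:
        for b in bursts:
            mo2 = mo2 + np.where((t >= b.t_start) & (t < b.t_start + b.duration),
                                 b.height, 0.0)
    return mo2


def _closed_windows(config: SimConfig, duration_min: float) -> list[tuple[int, float, float]]:
    """(cycle_index, t_start_min, t_end_min) of every closed window."""
    windows = []
    t = 0.0
    idx = 0
    end = min(config.first_measure_minutes, duration_min)
    if end > 0:
        windows.append((idx, 0.0, end))
        idx += 1
    t = config.first_measure_minutes + config.flush_minutes
    while t < duration_min and idx <= config.cycle_count:
        windows.append((idx, t, min(t + config.measure_minutes, duration_min)))
        idx += 1
        t += config.measure_minutes + config.flush_minutes
    return windows


def simulate_o2_trace(
    phenotype: FishPhenotype,
    config: SimConfig,
    duration_minutes: float | None = None,
    bursts: list[Burst] | None = None,
    rng: np.random.Generator | None = None,
    mo2_override: float | None = None,
) -> tuple[O2Trace, pd.DataFrame]:
    """Generate a raw O2 trace by inverting the MO2 equation.

    During each closed window the oxygen concentration declines with slope
    ``-(MO2 * m)/(v_R - v_F) - background`` and during flush phases it
    relaxes exponentially back to saturation.  The fish's MO2 is held
    constant within each (short) closed window at its value at the moment
    the chamber seals — a zero-order hold that makes the generative model
    exactly invertible by the slope-fitting pipeline and gives the ledger a
    well-defined per-cycle truth.

    ``mo2_override`` freezes MO2 at a constant value for the whole trace
    (useful for arithmetic checks).  Returns ``(trace, truth)`` where
    ``truth`` has one row per closed window with the held MO2 value and the
    implied noise-free slope.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if duration_minutes is None:
        duration_minutes = (
            config.first_measure_minutes
            + config.cycle_count * (config.flush_minutes + config.measure_minutes)
        )
    m = phenotype.body_mass
    v_r = config.respirometer_volume
    v_f = m  # 1 kg displaces 1 L
    if v_r / m < 1.0:
        raise ValueError("fish too large for chamber (volume ratio < 1)")
    windows = _closed_windows(config, duration_minutes)
    dt = config.sample_dt_s
    t_s = np.arange(0.0, duration_minutes * 60.0 + 0.5 * dt, dt)
    t_min = t_s / 60.0
    phase = np.full(len(t_s), "flush", dtype=object)
    o2 = np.empty(len(t_s))

    truth_rows = []
    level = config.o2_saturation
    prev_end_idx = 0
    for (idx, w0, w1) in windows:
        i0 = int(np.searchsorted(t_min, w0, side="left"))
        i1 = int(np.searchsorted(t_min, w1, side="right"))
        if i1 <= i0:
            continue
        # flush segment between previous window end and this window start
        if i0 > prev_end_idx:
            seg = slice(prev_end_idx, i0)
            tt = t_s[seg] - t_s[prev_end_idx]
            sat = config.o2_saturation
            o2[seg] = sat + (level - sat) * np.exp(-tt / config.flush_tau_s)
            # O2 level at the moment the chamber seals again
            level = sat + (level - sat) * np.exp(
                -(t_s[i0] - t_s[prev_end_idx]) / config.flush_tau_s)
        if mo2_override is not None:
            mo2_here = mo2_override
        else:
            mo2_here = float(simulate_mo2_trajectory(
                phenotype, config.test_temperature, np.array([w0]), bursts=bursts)[0])
        slope = -(mo2_here * m) / (v_r - v_f) - config.background_rate  # mg L-1 min-1
        seg = slice(i0, i1)
        o2[seg] = level + slope * (t_min[seg] - t_min[i0])
        phase[seg] = "measure"
        level = o2[i1 - 1] if i1 > i0 else level
        prev_end_idx = i1
        truth_rows.append({
            "cycle": idx, "t_start_min": w0, "t_end_min": w1,
            "mo2_true": mo2_here, "slope_true_per_min": slope,
        })
    if prev_end_idx < len(t_s):
        seg = slice(prev_end_idx, len(t_s))
        tt = t_s[seg] - t_s[prev_end_idx]
        o2[seg] = config.o2_saturation + (level - config.o2_saturation) * np.exp(-tt / config.flush_tau_s)

    if config.drift_per_hour:
        o2 = o2 + config.drift_per_hour * t_s / 3600.0
    if config.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.noise_sd, size=len(o2))
    o2 = np.maximum(o2, 0.0)

    data = pd.DataFrame({
        "time_s": t_s,
        "o2_mg_per_l": o2,
        "temp_c": config.test_temperature,
        "phase": phase,
    })
    trace = O2Trace(
        fish_id=phenotype.fish_id,
        data=data,
        respirometer_volume=v_r,
        fish_mass=m,
        fish_volume=v_f,
    )
    return trace, pd.DataFrame(truth_rows)


def survival_probability(temperature, m50: float, slope: float):
    """P(survive | T) = 1 / (1 + exp(slope * (ln T - ln m50)))."""
    T = np.asarray(temperature, dtype=float)
    return 1.0 / (1.0 + np.exp(slope * (np.log(T) - np.log(m50))))


def simulate_survival_outcomes(
    temperatures,
    n_per_temperature: int,
    m50: float,
    slope: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bernoulli survival draws under the log-logistic dose-response.

    Returns one row per fish with columns ``temperature`` and ``survived``.
    Reproducible for a fixed seed; empirical survival converges on
    P(survive|T) as the group size grows.
    """
    if m50 <= 0:
        raise ValueError("m50 must be positive")
    if n_per_temperature < 1:
        raise ValueError("need at least one fish per temperature")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for T in np.asarray(temperatures, dtype=float):
        p = float(survival_probability(T, m50, slope))
        survived = rng.random(n_per_temperature) < p
        for s in survived:
            rows.append({"temperature": T, "survived": bool(s)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generation

#: default two-population design: (m50 C, log-logistic slope)
DEFAULT_POPULATIONS = {
    "coastal": (21.0, 25.0),
    "interior": (23.6, 14.0),
}

DEFAULT_TEMPERATURES = (12.0, 18.0, 21.0, 24.0)


@dataclass
class CohortSim:
    """Output bundle of :func:`simulate_cohort`."""

    cohort: pd.DataFrame
    traces: dict            # fish_id -> {"post_chase_1h": (O2Trace, truth), ...}
    ledger: pd.DataFrame    # per-fish ground truth
    config: SimConfig


def _draw_phenotype(rng: np.random.Generator, fish_id: str, population: str,
                    burst_prob: float) -> FishPhenotype:
    sex = "male" if rng.random() < 0.75 else "female"
    body_mass = float(np.clip(rng.lognormal(np.log(3.4), 0.28), 1.4, 7.2))
    fork_length = float(640.0 + 60.0 * (body_mass - 3.4) + rng.normal(0, 25))
    rmr12 = float(np.clip(rng.normal(2.4, 0.30), 1.2, 4.0))
    q10 = float(np.clip(rng.normal(1.7, 0.15), 1.2, 2.3))
    mmr = float(np.clip(rng.normal(11.3, 1.4), rmr12 * 2.5 + 1.0, 18.0))
    k = float(np.clip(rng.normal(0.05, 0.008), 0.02, 0.09))
    gsi_pct = rng.normal(20.0, 2.5) if sex == "female" else rng.normal(6.0, 1.0)
    organ = {
        "gonads": max(float(rng.normal(gsi_pct, 0.5)), 0.5) / 100 * body_mass * 1000,
        "ventricle": max(float(rng.normal(0.19, 0.02)), 0.05) / 100 * body_mass * 1000,
        "spleen": max(float(rng.normal(0.18, 0.04)), 0.02) / 100 * body_mass * 1000,
        "liver": max(float(rng.normal(1.65, 0.25)), 0.3) / 100 * body_mass * 1000,
    }
    hct = float(np.clip(rng.normal(55.0, 8.0), 10.0, 75.0))
    return FishPhenotype(
        fish_id=fish_id, population=population, sex=sex,
        body_mass=body_mass, fork_length=fork_length,
        rmr12=rmr12, q10_true=q10, mmr_true=mmr, epoc_rate_k=k,
        burst_prob=burst_prob, organ_masses=organ, hematocrit=hct,
    )


def _draw_bursts(rng: np.random.Generator, phenotype: FishPhenotype,
                 config: SimConfig, temperature: float,
                 duration_min: float) -> list[Burst]:
    """Per-cycle Bernoulli bursts during overnight recovery (after hour 2)."""
    if phenotype.burst_prob <= 0:
        return []
    bursts = []
    rmr = phenotype.rmr_at(temperature)
    scope = phenotype.mmr_true - rmr
    for (idx, w0, w1) in _closed_windows(config, duration_min):
        if w0 < 120.0:  # leave the chase-recovery decay unperturbed
            continue
        if rng.random() < phenotype.burst_prob:
            height = float(rng.uniform(0.6, 1.3)) * scope
            bursts.append(Burst(t_start=w0, duration=w1 - w0, height=height))
    return bursts


def simulate_cohort(
    config: SimConfig,
    populations: dict | None = None,
    temperatures=DEFAULT_TEMPERATURES,
    n_per_temperature: int | None = None,
    burst_prob: float = 0.006,
    low_hematocrit_prob: float = 0.05,
    overnight_hours: float = 18.0,
    post_18h_minutes: float = 65.0,
    make_traces: bool = True,
) -> CohortSim:
    """Simulate a full two-population thermal-challenge cohort.

    Each fish is acclimated at 12 C and tested at one of the given
    temperatures; survival is Bernoulli under the population's log-logistic
    curve.  Survivors get two traces (an ~18 h overnight record after the
    first chase and a ~1 h record after the second); mortalities die at a
    random time during the overnight record, which truncates their trace.
    The ledger records every fish's true RMR at its test temperature, true
    MMR, recovery rate k and closed-form EPOC.
    """
    if populations is None:
        populations = DEFAULT_POPULATIONS
    if n_per_temperature is None:
        n_per_temperature = config.n_per_temperature
    temperatures = tuple(float(T) for T in temperatures)
    if len(temperatures) == 0:
        raise ValueError("need at least one temperature group")
    rng = np.random.default_rng(config.seed)

    cohort_rows, ledger_rows = [], []
    traces: dict = {}
    fish_counter = 0
    for pop, (m50, slope) in populations.items():
        for T in temperatures:
            for _ in range(n_per_temperature):
                fish_counter += 1
                fid = f"{pop[:2]}{fish_counter:03d}"
                ph = _draw_phenotype(rng, fid, pop, burst_prob)
                if rng.random() < low_hematocrit_prob:
                    ph.hematocrit = float(rng.uniform(12.0, 19.5))
                p_surv = float(survival_probability(T, m50, slope))
                survived = bool(rng.random() < p_surv)
                death_time_min = None if survived else float(rng.uniform(30.0, overnight_hours * 60.0))
                cfg = replace(config, test_temperature=T, seed=int(rng.integers(2**31 - 1)))
                rmr_T = ph.rmr_at(T)
                ledger_rows.append({
                    "fish_id": fid, "population": pop, "temperature": T,
                    "body_mass": ph.body_mass,
                    "rmr_true": rmr_T, "mmr_true": ph.mmr_true,
                    "q10_true": ph.q10_true, "epoc_rate_k": ph.epoc_rate_k,
                    "epoc_true": (ph.mmr_true - rmr_T) / ph.epoc_rate_k,
                    "survived": survived, "m50": m50, "survival_slope": slope,
                    "p_survive": p_surv,
                })
                cohort_rows.append({
                    "fish_id": fid, "population": pop, "sex": ph.sex,
                    "body_mass": ph.body_mass, "fork_length": ph.fork_length,
                    "test_temperature": T, "survived": survived,
                    "gonad_mass_g": ph.organ_masses["gonads"],
                    "ventricle_mass_g": ph.organ_masses["ventricle"],
                    "spleen_mass_g": ph.organ_masses["spleen"],
                    "liver_mass_g": ph.organ_masses["liver"],
                    "hematocrit": ph.hematocrit,
                })
                if not make_traces:
                    continue
                dur = overnight_hours * 60.0 if survived else death_time_min
                bursts = _draw_bursts(rng, ph, cfg, T, dur)
                trace1, truth1 = simulate_o2_trace(
                    ph, cfg, duration_minutes=dur, bursts=bursts,
                    rng=np.random.default_rng(cfg.seed))
                entry = {"post_chase_1h": (trace1, truth1)}
                if survived:
                    cfg2 = replace(cfg, seed=int(rng.integers(2**31 - 1)),
                                   cycle_count=max(1, int(post_18h_minutes // (config.flush_minutes + config.measure_minutes))))
                    trace2, truth2 = simulate_o2_trace(
                        ph, cfg2, duration_minutes=post_18h_minutes,
                        rng=np.random.default_rng(cfg2.seed))
                    entry["post_chase_18h"] = (trace2, truth2)
                traces[fid] = entry
    cohort = pd.DataFrame(cohort_rows)
    ledger = pd.DataFrame(ledger_rows)
    return CohortSim(cohort=cohort, traces=traces, ledger=ledger, config=config)
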