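"""Population-level thermal performance of aerobic scope.

Aerobic scope across acute test temperatures is summarised by a quadratic
thermal performance curve AAS(T) = c0 + c1*T + c2*T^2 fit over all fish,
with mortalities entered as zero scope.  The vertex gives the optimal
temperature Topt and peak scope AAS_max; the upper pejus temperature is the
highest temperature at which the curve still delivers a set fraction
(default 80%) of AAS_max, which for a quadratic has the closed form

    T_pejus_upper = Topt + sqrt((1 - threshold) * AAS_max / (-c2)).

Uncertainty on both summaries comes from a bootstrap over fish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThermalPerformanceModel",
    "TPCResults",
    "thermal_thresholds",
    "percent_max_curve",
    "warming_tolerance",
]


def thermal_thresholds(c0: float, c1: float, c2: float,
                       threshold: float = 0.80) -> tuple[float, float, float]:
    """Closed-form (Topt, AAS_max, T_pejus_upper) of a concave quadratic.

    Requires c2 < 0 and 0 < threshold <= 1.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if c2 >= 0:
        raise ValueError("no peak: quadratic coefficient must be negative")
    topt = -c1 / (2.0 * c2)
    aas_max = c0 + c1 * topt + c2 * topt * topt
    t_pejus = topt + np.sqrt((1.0 - threshold) * aas_max / (-c2))
    return float(topt), float(aas_max), float(t_pejus)


def percent_max_curve(coeffs, temperatures, aas_max: float | None = None) -> np.ndarray:
    """AAS as percent of the curve's maximum, clipped at 0."""
    c0, c1, c2 = coeffs
    T = np.asarray(temperatures, dtype=float)
    if aas_max is None:
        _, aas_max, _ = thermal_thresholds(c0, c1, c2, threshold=0.8)
    vals = c0 + c1 * T + c2 * T * T
    return np.clip(100.0 * vals / aas_max, 0.0, None)


def warming_tolerance(max_env_temperature: float, t_pejus_upper: float) -> float:
    """Functional warming tolerance: maximum environmental temperature minus
    the upper pejus temperature.  Negative when the environment already
    exceeds the population's near-optimal range."""
    return max_env_temperature - t_pejus_upper


class ThermalPerformanceModel:
    """Quadratic thermal-performance model for per-fish aerobic scope.

    Parameters
    ----------
    temperature, aas : array-like
        One entry per fish: acute test temperature (C) and absolute aerobic
        scope (mg O2 kg-1 min-1), with mortalities included as zeros unless
        the analysis is restricted to survivors upstream.
    population : str, optional
        Label carried through to the results.
    """

    def __init__(self, temperature, aas, population: str | None = None):
        self.temperature = np.asarray(temperature, dtype=float)
        self.aas = np.asarray(aas, dtype=float)
        if len(self.temperature) != len(self.aas):
            raise ValueError("temperature and aas must have equal length")
        keep = ~np.isnan(self.aas) & ~np.isnan(self.temperature)
        self.temperature, self.aas = self.temperature[keep], self.aas[keep]
        if len(np.unique(self.temperature)) < 3:
            raise ValueError("need at least 3 distinct temperatures for a quadratic")
        self.population = population

    @classmethod
    def from_summaries(cls, summaries: pd.DataFrame, population: str | None = None,
                       metric: str = "aas", survivors_only: bool = False):
        """Build from a per-fish metabolic summary table.

        By default all fish enter the fit with mortalities as zero scope;
        ``survivors_only=True`` mirrors the survivor-restricted view (which
        can greatly overestimate a population's capacity at lethal
        temperatures).
        """
        df = summaries
        if population is not None:
            df = df[df["population"] == population]
        if survivors_only:
            df = df[df["survived"].astype(bool)]
        return cls(df["test_temperature"].to_numpy(),
                   pd.to_numeric(df[metric], errors="coerce").to_numpy(),
                   population=population)

    def fit(self, threshold: float = 0.80, bootstrap: int = 0,
            seed: int | None = None, vertex_margin: float = 3.0) -> "TPCResults":
        """Least-squares quadratic fit with optional bootstrap over fish.

        Peak diagnostics (Topt, AAS_max, T_pejus) are populated only when
        the fitted curve is concave and its vertex lies within the observed
        temperature range widened by ``vertex_margin`` C; otherwise they are
        missing with a reason (extrapolated vertices are meaningless).
        """
        c2, c1, c0 = np.polyfit(self.temperature, self.aas, 2)
        res = TPCResults(self, (float(c0), float(c1), float(c2)), threshold,
                         vertex_margin)
        if bootstrap > 0:
            rng = np.random.default_rng(seed)
            n = len(self.aas)
            topts, pejus = [], []
            failures = 0
            for _ in range(bootstrap):
                idx = rng.integers(0, n, size=n)
                Tb, yb = self.temperature[idx], self.aas[idx]
                if len(np.unique(Tb)) < 3:
                    failures += 1
                    continue
                b2, b1, b0 = np.polyfit(Tb, yb, 2)
                if b2 >= 0:
                    failures += 1
                    continue
                try:
                    to, _, tp = thermal_thresholds(b0, b1, b2, threshold)
                except ValueError:
                    failures += 1
                    continue
                topts.append(to)
                pejus.append(tp)
            if topts:
                res.topt_sd = float(np.std(topts, ddof=1))
                res.t_pejus_sd = float(np.std(pejus, ddof=1))
                res.bootstrap_mean_topt = float(np.mean(topts))
                res.bootstrap_mean_t_pejus = float(np.mean(pejus))
            res.n_bootstrap = bootstrap
            res.n_bootstrap_failed = failures
        return res


@dataclass
class TPCResults:
    """Fitted thermal performance curve with peak diagnostics."""

    model: ThermalPerformanceModel
    coefficients: tuple      # (c0, c1, c2)
    threshold: float
    vertex_margin: float
    topt: float = np.nan
    aas_max: float = np.nan
    t_pejus_upper: float = np.nan
    peak_reason: str | None = None
    topt_sd: float = np.nan
    t_pejus_sd: float = np.nan
    bootstrap_mean_topt: float = np.nan
    bootstrap_mean_t_pejus: float = np.nan
    n_bootstrap: int = 0
    n_bootstrap_failed: int = 0

    def __post_init__(self):
        c0, c1, c2 = self.coefficients
        T = self.model.temperature
        if c2 >= 0:
            self.peak_reason = "fitted quadratic is not concave (c2 >= 0)"
            return
        topt, aas_max, t_pejus = thermal_thresholds(c0, c1, c2, self.threshold)
        lo, hi = T.min() - self.vertex_margin, T.max() + self.vertex_margin
        if not lo <= topt <= hi:
            self.peak_reason = (
                f"vertex {topt:.2f} C outside observed range [{lo:.1f}, {hi:.1f}]")
            return
        self.topt, self.aas_max, self.t_pejus_upper = topt, aas_max, t_pejus

    @property
    def has_peak(self) -> bool:
        return self.peak_reason is None

    def predict(self, temperatures) -> np.ndarray:
        c0, c1, c2 = self.coefficients
        T = np.asarray(temperatures, dtype=float)
        return c0 + c1 * T + c2 * T * T

    def percent_max(self, temperatures) -> np.ndarray:
        if not self.has_peak:
            raise ValueError(f"no valid peak: {self.peak_reason}")
        return percent_max_curve(self.coefficients, temperatures, self.aas_max)

    def warming_tolerance(self, max_env_temperature: float) -> float:
        if not self.has_peak:
            raise ValueError(f"no valid peak: {self.peak_reason}")
        return warming_tolerance(max_env_temperature, self.t_pejus_upper)

    def summary(self) -> str:
        c0, c1, c2 = self.coefficients
        lines = [
            "Thermal performance curve (quadratic, mortalities as zero scope)",
            f"  population:     {self.model.population or '-'}",
            f"  n fish:         {len(self.model.aas)}",
            f"  AAS(T) =        {c0:.4f} + {c1:.4f} T + {c2:.5f} T^2",
        ]
        if self.has_peak:
            lines += [
                f"  Topt:           {self.topt:.2f} C"
                + (f" (bootstrap SD {self.topt_sd:.2f})" if self.n_bootstrap else ""),
                f"  AAS max:        {self.aas_max:.2f} mg O2 kg-1 min-1",
                f"  upper T_pejus:  {self.t_pejus_upper:.2f} C at {self.threshold:.0%} of max"
                + (f" (bootstrap SD {self.t_pejus_sd:.2f})" if self.n_bootstrap else ""),
            ]
        else:
            lines.append(f"  peak:           missing ({self.peak_reason})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        c0, c1, c2 = self.coefficients
        return {
            "population": self.model.population, "n": len(self.model.aas),
            "c0": c0, "c1": c1, "c2": c2, "threshold": self.threshold,
            "topt": self.topt, "aas_max": self.aas_max,
            "t_pejus_upper": self.t_pejus_upper,
            "topt_sd": self.topt_sd, "t_pejus_sd": self.t_pejus_sd,
            "peak_reason": self.peak_reason,
        }

    def plot(self, ax=None, grid=None):
        """Percent-of-maximum curve with the pejus threshold line."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        T = self.model.temperature
        if grid is None:
            grid = np.linspace(T.min() - 1, T.max() + 1, 200)
        ax.plot(grid, self.percent_max(grid), label=self.model.population)
        ax.axhline(100 * self.threshold, ls="--", color="grey")
        if self.has_peak:
            ax.axvline(self.t_pejus_upper, ls=":", color="grey")
        ax.scatter(T, 100 * self.model.aas / self.aas_max, s=12, alpha=0.5)
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel("% of maximum AAS")
        return ax
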