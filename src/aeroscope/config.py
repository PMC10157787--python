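"""Run configuration for the end-to-end pipeline.

Every analysis threshold lives here with its standard default: r2 cutoffs
of 0.9 (MMR windows) and 0.85 (RMR validation), the 0.10 RMR quantile, the
90 s minimum sliding window, the 60-measurement eligibility floor, the
48-52% recMMR50 band, the 80% pejus threshold, scaling exponents 0.58
(MMR) / 0.67 (RMR) and the 3.5 kg reference mass.  A config plus the seed
fully determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .simulate import SimConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "aeroscope_run"
    log_level: str = "INFO"

    # trace processing
    r2_mmr: float = 0.9
    r2_rmr: float = 0.85
    jump_sd_multiple: float = 5.0
    min_cycle_fraction: float = 0.6

    # metabolic rates
    rmr_quantile: float = 0.10
    min_measurements: int = 60
    min_window_s: float = 90.0
    exponent_mmr: float = 0.58
    exponent_rmr: float = 0.67
    reference_mass: float = 3.5

    # recovery
    recovery_band: tuple = (0.48, 0.52)
    epoc_horizon_min: float = 300.0
    epoc_return_tol: float = 0.02

    # thermal performance
    pejus_threshold: float = 0.80
    tpc_bootstrap: int = 200

    # survival
    hematocrit_min: float = 20.0

    # simulation block (None -> analyze external inputs)
    simulation: dict = field(default_factory=dict)
    input_cohort: str | None = None
    input_trace_dir: str | None = None
    make_plots: bool = False

    def sim_config(self) -> SimConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        known = {f.name for f in fields(SimConfig)}
        extra = {k: v for k, v in sim.items() if k in known}
        return SimConfig(**extra)

    def sim_extras(self) -> dict:
        """Simulation keys routed to simulate_cohort rather than SimConfig."""
        known = {f.name for f in fields(SimConfig)}
        return {k: v for k, v in self.simulation.items() if k not in known}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.recovery_band, list):
            cfg.recovery_band = tuple(cfg.recovery_band)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["recovery_band"] = list(self.recovery_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recovery_band"] = list(self.recovery_band)
        return d
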