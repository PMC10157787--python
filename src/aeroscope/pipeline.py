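"""End-to-end orchestration: simulate/load, process, summarise, report.

A run is deterministic given (inputs, config, seed).  Each stage writes a
delimited table into the run directory and the run closes with a
machine-readable ``summary.json`` recording the package version, a config
hash, per-stage record counts and an exclusion ledger (every fish is either
analysed or excluded for a named reason, so counts always reconcile).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .rates import group_summary, summarize_fish
from .recovery import recovery_profile
from .simulate import simulate_cohort
from .survival import SurvivalModel, lrt_population, organ_indices
from .thermal import ThermalPerformanceModel
from .traces import process_trace

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("aeroscope")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the run directory."""


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _cycle0_raw(trace):
    """Raw (t, o2) samples of the first closed window, for the MMR search."""
    data = trace.data
    phases = data["phase"].astype(str).str.lower().to_numpy()
    t = trace.times
    is_meas = phases == "measure"
    if not is_meas.any():
        return None
    i0 = int(np.argmax(is_meas))
    i1 = i0
    while i1 < len(t) and is_meas[i1]:
        i1 += 1
    return t[i0:i1], trace.o2[i0:i1]


def run_pipeline(config: RunConfig, sim=None):
    """Run the full analysis and write all tables under the run directory.

    ``sim`` may carry a pre-built :class:`aeroscope.simulate.CohortSim`;
    otherwise one is generated from the config's simulation block.  Returns
    the summary dictionary that is also written to ``summary.json``.
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "exclusions": {},
    }

    stage = "simulate"
    try:
        if sim is None:
            sim = simulate_cohort(config.sim_config(), **config.sim_extras())
        cohort = sim.cohort
        cohort.to_csv(out / "cohort.csv", index=False)
        if len(sim.ledger):
            sim.ledger.to_csv(out / "ground_truth.csv", index=False)
        summary["stages"]["simulate"] = {"n_fish": int(len(cohort))}
        if cohort.empty:
            summary["status"] = "no eligible fish"
            (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
            log.warning("empty cohort: nothing to analyze")
            return summary

        # ------------------------------------------------------------------
        stage = "morphometrics"
        morpho_rows, ineligible = [], []
        for _, row in cohort.iterrows():
            rec = organ_indices(
                row["body_mass"], row["gonad_mass_g"], row["ventricle_mass_g"],
                row["spleen_mass_g"], row["liver_mass_g"], row["hematocrit"],
                fish_id=row["fish_id"], hematocrit_min=config.hematocrit_min)
            morpho_rows.append(rec.__dict__)
            if not rec.eligible:
                ineligible.append(row["fish_id"])
        pd.DataFrame(morpho_rows).to_csv(out / "morphometrics.csv", index=False)
        summary["exclusions"]["low_hematocrit"] = len(ineligible)
        eligible = cohort[~cohort["fish_id"].isin(ineligible)].reset_index(drop=True)
        summary["stages"]["morphometrics"] = {
            "n_input": int(len(cohort)), "n_eligible": int(len(eligible))}

        # ------------------------------------------------------------------
        stage = "trace_processing"
        all_cycles, summaries, recovery_blocks, epoc_rows, rec50_rows = [], [], [], [], []
        excl = {"no_trace": 0, "sparse_record": 0, "no_rec50_band": 0,
                "epoc_ineligible": 0, "epoc_incomplete": 0}
        for _, row in eligible.iterrows():
            fid = row["fish_id"]
            entry = sim.traces.get(fid)
            if entry is None:
                excl["no_trace"] += 1
                continue
            trace1, _ = entry["post_chase_1h"]
            cycles1 = process_trace(trace1, r2_threshold=config.r2_mmr,
                                    jump_sd_multiple=config.jump_sd_multiple,
                                    min_fraction=config.min_cycle_fraction)
            cycles1["stage"] = "post_chase_1h"
            all_cycles.append(cycles1)
            cycles18 = None
            raw18 = None
            if "post_chase_18h" in entry:
                trace2, _ = entry["post_chase_18h"]
                cycles18 = process_trace(trace2, r2_threshold=config.r2_mmr,
                                         jump_sd_multiple=config.jump_sd_multiple,
                                         min_fraction=config.min_cycle_fraction)
                cycles18["stage"] = "post_chase_18h"
                all_cycles.append(cycles18)
                raw18 = _cycle0_raw(trace2)

            stage = "metabolic_rates"
            summ = summarize_fish(
                cycles1,
                trace_meta={"v_r": trace1.respirometer_volume,
                            "v_f": trace1.fish_volume, "m": trace1.fish_mass},
                survived=bool(row["survived"]),
                cycles_18h=cycles18,
                fish_id=fid, population=row["population"],
                test_temperature=row["test_temperature"],
                r2_mmr=config.r2_mmr, r2_rmr=config.r2_rmr,
                rmr_quantile=config.rmr_quantile,
                min_measurements=config.min_measurements,
                min_window_s=config.min_window_s,
                exponent_mmr=config.exponent_mmr,
                exponent_rmr=config.exponent_rmr,
                reference_mass=config.reference_mass,
                raw_cycle0_1h=_cycle0_raw(trace1),
                raw_cycle0_18h=raw18,
            )
            summaries.append(summ.to_dict())
            if summ.rmr.is_missing and bool(row["survived"]):
                excl["sparse_record"] += 1
                continue

            stage = "recovery"
            valid = cycles1[cycles1["valid"]]
            prof = recovery_profile(
                fid, "MMR_1h",
                valid["t_mid_min"].to_numpy(), valid["mo2"].to_numpy(),
                rmr=summ.rmr.value, aas=summ.aas,
                mmr_ref=summ.mmr_1h.value, mmr_overall=summ.mmr_overall.value,
                band=tuple(config.recovery_band),
                compute_epoc_kwargs={
                    "horizon_min": config.epoc_horizon_min,
                    "min_measurements": config.min_measurements,
                    "return_tol": config.epoc_return_tol,
                })
            if prof.timecourse is not None:
                tc = prof.timecourse.copy()
                tc.insert(0, "fish_id", fid)
                tc.insert(1, "stage", "MMR_1h")
                recovery_blocks.append(tc)
            rec50_rows.append({"fish_id": fid, "stage": "MMR_1h",
                               "rec_mmr50_min": prof.rec_mmr50.value,
                               "reason": prof.rec_mmr50.reason})
            if prof.rec_mmr50.is_missing and prof.reason is None:
                excl["no_rec50_band"] += 1
            if prof.epoc is not None:
                if prof.epoc.is_missing:
                    excl["epoc_ineligible"] += 1
                elif not prof.epoc.complete:
                    excl["epoc_incomplete"] += 1
                else:
                    rowd = {"fish_id": fid, "epoc_cumulative": prof.epoc.cumulative,
                            "t_return_min": prof.epoc.t_return_min}
                    for h, v in enumerate(prof.epoc.hourly, start=1):
                        rowd[f"epoc_hour_{h}"] = v
                    epoc_rows.append(rowd)

        if all_cycles:
            pd.concat(all_cycles, ignore_index=True).to_csv(out / "cycles.csv", index=False)
        summaries_df = pd.DataFrame(summaries)
        summaries_df.to_csv(out / "metabolic_summaries.csv", index=False)
        if recovery_blocks:
            pd.concat(recovery_blocks, ignore_index=True).to_csv(
                out / "recovery_blocks.csv", index=False)
        pd.DataFrame(rec50_rows).to_csv(out / "rec_mmr50.csv", index=False)
        pd.DataFrame(epoc_rows).to_csv(out / "epoc.csv", index=False)
        summary["exclusions"].update(excl)
        summary["stages"]["metabolic_rates"] = {
            "n_summaries": int(len(summaries_df)),
            "n_with_rmr": int(summaries_df["rmr"].notna().sum()) if len(summaries_df) else 0,
        }

        stage = "group_summary"
        if len(summaries_df):
            group_summary(summaries_df).to_csv(out / "group_summary.csv", index=False)

        # ------------------------------------------------------------------
        stage = "thermal_performance"
        tpc_rows = []
        if len(summaries_df):
            usable = summaries_df[summaries_df["aas"].notna()]
            for pop in sorted(usable["population"].dropna().unique()):
                sub = usable[usable["population"] == pop]
                try:
                    model = ThermalPerformanceModel(
                        sub["test_temperature"], sub["aas"], population=pop)
                except ValueError as e:
                    log.warning("TPC for %s skipped: %s", pop, e)
                    continue
                res = model.fit(threshold=config.pejus_threshold,
                                bootstrap=config.tpc_bootstrap, seed=config.seed)
                tpc_rows.append(res.to_dict())
                if config.make_plots:
                    ax = res.plot()
                    ax.figure.savefig(out / f"tpc_{pop}.png", dpi=120)
        pd.DataFrame(tpc_rows).to_csv(out / "tpc_report.csv", index=False)
        summary["stages"]["thermal_performance"] = {"n_populations": len(tpc_rows)}

        # ------------------------------------------------------------------
        stage = "survival"
        surv_rows = []
        pops = sorted(cohort["population"].dropna().unique())
        per_group = []
        for pop in pops:
            res = SurvivalModel.from_cohort(cohort, population=pop).fit()
            per_group.append(res)
            surv_rows.append(res.to_dict())
            if config.make_plots and not res.boundary:
                ax = res.plot()
                ax.figure.savefig(out / f"survival_{pop}.png", dpi=120)
        if len(pops) > 1:
            pooled = SurvivalModel.from_cohort(cohort).fit()
            if not pooled.boundary and all(not r.boundary for r in per_group):
                lrt = lrt_population(pooled, per_group)
                summary["survival_lrt"] = {
                    "statistic": lrt.statistic, "df": lrt.df, "p_value": lrt.p_value}
        pd.DataFrame(surv_rows).to_csv(out / "survival_report.csv", index=False)
        summary["stages"]["survival"] = {"n_populations": len(surv_rows)}

    except Exception as e:  # pragma: no cover - error path
        summary["status"] = "failed"
        summary["failed_stage"] = stage
        summary["error"] = str(e)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        log.error("pipeline failed at stage %s: %s", stage, e)
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    summary["status"] = "ok"
    # conservation check: every eligible fish is analysed or excluded
    n_eligible = summary["stages"]["morphometrics"]["n_eligible"]
    summary["accounting"] = {
        "n_input": int(len(cohort)),
        "n_eligible": n_eligible,
        "n_excluded_low_hematocrit": summary["exclusions"]["low_hematocrit"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
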