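"""Trace IO, cycle segmentation, slope fitting and MO2 conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aeroscope as a
from aeroscope.traces import TraceError


def make_trace(t, o2, phase=None, v_r=98.0, m=3.5):
    data = pd.DataFrame({"time_s": t, "o2_mg_per_l": o2, "temp_c": 12.0})
    if phase is not None:
        data["phase"] = phase
    return a.O2Trace("fx", data, respirometer_volume=v_r, fish_mass=m)


class TestReadWrite:
    def test_round_trip(self, tmp_path, phenotype, quiet_config):
        trace, _ = a.simulate_o2_trace(phenotype, quiet_config,
                                       duration_minutes=30.0)
        p = tmp_path / "t.csv"
        a.write_trace(trace, p)
        back = a.read_trace(p, fish_id="f1", respirometer_volume=98.0,
                            fish_mass=3.5)
        pd.testing.assert_frame_equal(back.data, trace.data)
        p2 = tmp_path / "t2.csv"
        a.write_trace(back, p2)
        assert p.read_text() == p2.read_text()

    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "ok.csv"
        p.write_text("time_s,o2_mg_per_l,temp_c\n" + "\n".join(
            f"{i},{10 - 0.001 * i},12.0" for i in range(20)))
        trace = a.read_trace(p, fish_mass=2.0, respirometer_volume=50.0)
        assert len(trace) == 20

    def test_decreasing_time_cites_row(self, tmp_path):
        t = list(range(100))
        t[57] = 10  # decreasing at data row 57
        p = tmp_path / "bad.csv"
        p.write_text("time_s,o2_mg_per_l,temp_c\n" + "\n".join(
            f"{ti},9.5,12.0" for ti in t))
        with pytest.raises(TraceError, match="row 57"):
            a.read_trace(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("time_s,temp_c\n0,12\n1,12\n")
        with pytest.raises(TraceError, match="missing columns"):
            a.read_trace(p)

    def test_unparseable_row_cited(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text("time_s,o2_mg_per_l,temp_c\n0,9.5,12\n1,oops,12\n2,9.4,12\n")
        with pytest.raises(TraceError, match="row 1"):
            a.read_trace(p)


class TestSegmentation:
    def test_schedule_arithmetic_four_windows(self):
        # 60 min trace, flush 9 + measure 6, starting in flush
        t = np.arange(0, 3601.0)
        trace = make_trace(t, np.full(len(t), 9.0))
        sched = a.CycleSchedule(flush_minutes=9, measure_minutes=6)
        wins = a.segment_cycles(trace, schedule=sched)
        assert len(wins) == 4
        assert wins[0].t_start == pytest.approx(540.0)
        assert wins[0].t_end == pytest.approx(900.0)
        assert wins[-1].t_start == pytest.approx(3240.0)

    def test_short_trace_truncation_policy(self):
        # trace ends 4 min into the first 6-min window: 67% of nominal, kept
        t = np.arange(0, 9 * 60 + 240.0)
        trace = make_trace(t, np.full(len(t), 9.0))
        sched = a.CycleSchedule(flush_minutes=9, measure_minutes=6)
        wins = a.segment_cycles(trace, schedule=sched)
        assert len(wins) == 1
        # ends 3 min in: 50% of nominal, dropped
        t = np.arange(0, 9 * 60 + 180.0)
        wins = a.segment_cycles(make_trace(t, np.full(len(t), 9.0)),
                                schedule=sched)
        assert len(wins) == 0

    def test_phase_labels_dominate(self, phenotype, quiet_config):
        trace, truth = a.simulate_o2_trace(phenotype, quiet_config,
                                           duration_minutes=60.0)
        wins = a.segment_cycles(trace)  # labels present in simulated traces
        assert len(wins) == len(truth)
        for w, (_, row) in zip(wins, truth.iterrows()):
            assert w.t_start / 60.0 == pytest.approx(row["t_start_min"], abs=0.05)

    def test_auto_detection_matches_labels(self, phenotype):
        cfg = a.SimConfig(noise_sd=0.005, cycle_count=4, seed=3)
        trace, truth = a.simulate_o2_trace(phenotype, cfg)
        labelled = a.segment_cycles(trace)
        trace.data = trace.data.drop(columns=["phase"])
        auto = a.segment_cycles(trace, auto=True)
        assert len(auto) == len(labelled)
        for wa, wl in zip(auto, labelled):
            assert abs(wa.t_start - wl.t_start) < 45.0
            assert abs(wa.t_end - wl.t_end) < 45.0

    def test_auto_zero_cycles_raises(self):
        t = np.arange(0, 600.0)
        o2 = 8.0 + 0.001 * t  # monotone rise: pure flush, no closed windows
        with pytest.raises(TraceError, match="no measurement cycles"):
            a.segment_cycles(make_trace(t, o2), auto=True)


class TestFitSlope:
    def test_exact_line(self):
        t = np.arange(0, 300.0)
        fit = a.fit_slope(t, 10.0 - 0.001 * t)
        assert fit.slope_per_min == pytest.approx(-0.06, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.negative and fit.linear and fit.artifact_free

    def test_constant_o2_flagged_non_negative(self):
        fit = a.fit_slope(np.arange(10.0), np.full(10, 8.0))
        assert fit.slope_per_min == pytest.approx(0.0)
        assert not fit.negative

    def test_spike_sets_artifact_flag(self):
        t = np.arange(0, 300.0)
        o2 = 10.0 - 0.001 * t
        o2[150] += 0.5
        fit = a.fit_slope(t, o2)
        assert not fit.artifact_free
        clean = a.fit_slope(t, 10.0 - 0.001 * t + 0.001 * np.sin(t / 20))
        assert clean.artifact_free

    def test_too_few_points_invalid_not_exception(self):
        fit = a.fit_slope([0, 1, 2], [9, 8, 7])
        assert not fit.valid and "5 points" in fit.reason


class TestComputeMO2:
    def test_arithmetic(self):
        assert a.compute_mo2(0.12, 54.5, 2.5, 2.5) == pytest.approx(2.496)

    def test_zero_slope(self):
        assert a.compute_mo2(0.0, 98.0, 3.5, 3.5) == 0.0

    def test_simulator_inverse(self):
        # slope 0.1111... recovers MO2 = 3.0 for the 98 L / 3.5 kg setup
        slope = 3.0 * 3.5 / (98.0 - 3.5)
        assert a.compute_mo2(slope, 98.0, 3.5, 3.5) == pytest.approx(3.0)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            a.compute_mo2(0.1, 2.0, 3.0, 3.0)   # v_R <= v_F
        with pytest.raises(ValueError):
            a.compute_mo2(-0.1, 98.0, 3.5, 3.5)  # signed positive-trend slope

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(slope=st.floats(0.001, 1.0), vf=st.floats(1.0, 8.0),
           net=st.floats(5.0, 200.0), m=st.floats(0.5, 8.0),
           c=st.floats(0.1, 5.0))
    def test_linearity_properties(self, slope, vf, net, m, c):
        vr = vf + net
        base = a.compute_mo2(slope, vr, vf, m)
        # linear in slope magnitude
        assert a.compute_mo2(c * slope, vr, vf, m) == pytest.approx(c * base)
        # linear in net volume v_R - v_F
        assert a.compute_mo2(slope, vf + c * net, vf, m) == pytest.approx(c * base)
        # inverse in fish mass
        assert a.compute_mo2(slope, vr, vf, c * m) == pytest.approx(base / c)


class TestBackground:
    def test_zero_rates_identity(self):
        mo2 = np.array([3.0, 2.5, 2.0])
        adj, flags = a.correct_background(mo2)
        assert np.array_equal(adj, mo2) and not flags.any()

    def test_constant_background_shifts_by_volume_term(self):
        mo2 = np.full(5, 3.0)
        adj, _ = a.correct_background(mo2, pre_rate=0.01, post_rate=0.01,
                                      v_r=98.0, v_f=3.5, m=3.5)
        assert adj == pytest.approx(3.0 - 0.01 * 94.5 / 3.5)

    def test_excess_background_clips_to_zero_with_flag(self):
        adj, flags = a.correct_background(np.array([0.1]), pre_rate=1.0,
                                          post_rate=1.0, v_r=98.0, v_f=3.5, m=3.5)
        assert adj[0] == 0.0 and flags[0]


class TestProcessTrace:
    def test_noise_free_round_trip_every_cycle(self, phenotype, quiet_config):
        trace, truth = a.simulate_o2_trace(phenotype, quiet_config,
                                           duration_minutes=120.0)
        cycles = a.process_trace(trace)
        assert len(cycles) == len(truth)
        rel = np.abs(cycles["mo2"].to_numpy() - truth["mo2_true"].to_numpy()) \
            / truth["mo2_true"].to_numpy()
        assert rel.max() < 1e-6

    def test_r2_threshold_monotonicity(self, phenotype):
        cfg = a.SimConfig(noise_sd=0.03, cycle_count=12, seed=8)
        trace, _ = a.simulate_o2_trace(phenotype, cfg)
        counts = []
        for thr in (0.5, 0.7, 0.9, 0.99):
            cycles = a.process_trace(trace, r2_threshold=thr)
            counts.append(int((cycles["valid"] & cycles["linear"]).sum()))
        assert counts == sorted(counts, reverse=True)
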