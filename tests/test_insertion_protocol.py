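"""The stepped measurement protocol: baseline, full position, sweep."""
import numpy as np
import pytest

import ffrwire as fw

_FAST = dict(n_steps=24)


@pytest.fixture(scope="module")
def moderate_reports(moderate_case, blood):
    geom, wf, cfg = moderate_case
    base = fw.run_baseline(geom, wf, blood, **_FAST)
    full = fw.run_full_position(geom, wf, blood, **_FAST)
    sweep = fw.run_insertion_sweep(geom, wf, blood,
                                   schedule=cfg.wire_schedule, **_FAST)
    return base, full, sweep


class TestBaseline:
    def test_healthy_artery_against_itself(self, scenarios, blood):
        cfg = scenarios["healthy"]
        geom = fw.build_idealized_rca(cfg)
        wf = fw.waveform_for(cfg)
        rep = fw.run_baseline(geom, wf, blood, **_FAST)
        assert rep.ffr_flow == pytest.approx(1.0, abs=1e-12)
        assert rep.ffr_pressure == pytest.approx(1.0, abs=1e-12)
        assert rep.flow_reduction_vs_healthy == pytest.approx(0.0, abs=1e-9)

    def test_ffr_decreases_with_severity(self, scenarios, blood):
        values = []
        for name in ("mild", "moderate", "severe"):
            cfg = scenarios[name]
            geom = fw.build_idealized_rca(cfg)
            wf = fw.waveform_for(cfg)
            values.append(fw.run_baseline(geom, wf, blood, **_FAST).ffr_flow)
        assert values[0] > values[1] > values[2]

    def test_rejects_geometry_with_wire(self, moderate_case, blood):
        geom, wf, _ = moderate_case
        with pytest.raises(ValueError):
            fw.run_baseline(geom.with_wire(0.35e-3, 24e-3), wf, blood)


class TestFullPosition:
    def test_zero_diameter_wire_equals_baseline(self, moderate_case, blood):
        geom, wf, _ = moderate_case
        base = fw.run_baseline(geom, wf, blood,
                               station_x=float(geom.trunk.stations[-1]),
                               **_FAST)
        rep = fw.run_full_position(geom, wf, blood, wire_diameter=0.0, **_FAST)
        assert rep.ffr_flow == pytest.approx(base.ffr_flow, rel=1e-12)
        assert rep.pd_mean == pytest.approx(base.pd_mean, rel=1e-12)

    def test_wire_reduces_flow_below_baseline(self, moderate_reports):
        base, full, _ = moderate_reports
        assert full.ffr_flow < base.ffr_flow
        assert full.flow_reduction_vs_healthy > base.flow_reduction_vs_healthy

    def test_occluding_wire_flagged(self, moderate_case, blood):
        geom, wf, _ = moderate_case
        rep = fw.run_full_position(geom, wf, blood, wire_diameter=1.3e-3,
                                   **_FAST)
        assert rep.occluded
        assert rep.ffr_flow == 0.0


class TestInsertionSweep:
    def test_per_position_keys_match_schedule(self, moderate_reports,
                                              moderate_case):
        _, _, sweep = moderate_reports
        _, _, cfg = moderate_case
        assert tuple(sweep.per_position) == tuple(cfg.wire_schedule)

    def test_assembled_profile_strictly_increasing_in_x(self, moderate_reports):
        _, _, sweep = moderate_reports
        assert np.all(np.diff(sweep.assembled_profile[:, 0]) > 0)

    def test_flow_non_increasing_with_tip_advance(self, moderate_reports):
        _, _, sweep = moderate_reports
        flows = [r.trunk_flow_m3s for r in sweep.per_position.values()]
        assert np.all(np.diff(flows) <= 0)

    def test_aggregate_ffr_at_most_baseline(self, moderate_reports):
        base, _, sweep = moderate_reports
        assert sweep.aggregate.ffr_pressure <= base.ffr_pressure

    def test_aggregate_velocity_at_least_full_position(self, moderate_reports):
        base, full, sweep = moderate_reports
        assert sweep.aggregate.u_e_mean >= full.u_e_mean

    def test_aggregate_shares_distal_reading_with_full_position(
            self, moderate_reports):
        _, full, sweep = moderate_reports
        assert sweep.aggregate.pd_mean == pytest.approx(full.pd_mean,
                                                        rel=1e-9)
        assert sweep.aggregate.dp_mean == pytest.approx(full.dp_mean,
                                                        rel=1e-9)

    def test_single_position_schedule_degenerates_to_full(self, moderate_case,
                                                          blood):
        geom, wf, _ = moderate_case
        tip = float(geom.trunk.stations[-1])
        sweep = fw.run_insertion_sweep(geom, wf, blood, schedule=(tip,),
                                       **_FAST)
        full = fw.run_full_position(geom, wf, blood, tip_x=tip, **_FAST)
        assert sweep.aggregate.pd_mean == pytest.approx(full.pd_mean,
                                                        rel=1e-12)
        assert sweep.aggregate.ffr_pressure == pytest.approx(
            full.ffr_pressure, rel=1e-12)

    def test_zero_wire_profile_matches_baseline_pressures(self, moderate_case,
                                                          blood):
        geom, wf, cfg = moderate_case
        sweep = fw.run_insertion_sweep(geom, wf, blood,
                                       schedule=cfg.wire_schedule,
                                       wire_diameter=0.0, **_FAST)
        sol = fw.solve_quasi_steady(geom, wf, blood, **_FAST)
        for tip, reading in sweep.per_position.items():
            expected = fw.pa_to_mmhg(sol.mean_station_pressure(tip))
            assert reading.tip_pressure_mmhg == pytest.approx(expected,
                                                              rel=1e-12)

    def test_sweep_is_deterministic(self, moderate_case, blood):
        geom, wf, cfg = moderate_case
        s1 = fw.run_insertion_sweep(geom, wf, blood,
                                    schedule=cfg.wire_schedule, **_FAST)
        s2 = fw.run_insertion_sweep(geom, wf, blood,
                                    schedule=cfg.wire_schedule, **_FAST)
        assert np.array_equal(s1.assembled_profile, s2.assembled_profile)
        assert s1.aggregate == s2.aggregate

    def test_unsorted_schedule_rejected(self, moderate_case, blood):
        geom, wf, _ = moderate_case
        with pytest.raises(ValueError):
            fw.run_insertion_sweep(geom, wf, blood,
                                   schedule=(10e-3, 5e-3), **_FAST)


def test_distal_station_sits_between_lesion_and_bifurcation(moderate_case):
    geom, _, _ = moderate_case
    x_d = fw.distal_measurement_station(geom)
    assert geom.stenosis_window[1] < x_d <= geom.trunk.stations[-1]
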