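"""Resistance primitives and the quasi-steady network solver."""
import dataclasses
import math

import numpy as np
import pytest

import ffrwire as fw
from ffrwire.hemodynamics import (annulus_resistance, expansion_loss,
                                  poiseuille_resistance, reynolds_number,
                                  stenosis_loss, solve_quasi_steady)


class TestPoiseuilleResistance:
    def test_reference_value(self):
        r = poiseuille_resistance(0.0035, 0.01, 0.003)
        assert r == pytest.approx(1.760e7, rel=1e-3)

    def test_linear_in_length_and_d4_scaling(self):
        r = poiseuille_resistance(0.0035, 0.01, 0.003)
        assert poiseuille_resistance(0.0035, 0.02, 0.003) == \
            pytest.approx(2 * r, rel=1e-14)
        assert poiseuille_resistance(0.0035, 0.01, 0.0015) == \
            pytest.approx(16 * r, rel=1e-14)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            poiseuille_resistance(0.0035, 0.01, 0.0)


class TestAnnulusResistance:
    def test_zero_inner_radius_equals_tube_exactly(self):
        rt = poiseuille_resistance(0.0035, 0.01, 0.003)
        ra = annulus_resistance(0.0035, 0.01, 0.0015, 0.0)
        assert ra == rt

    def test_monotone_divergence_toward_blockage(self):
        R = 0.225e-3
        ratios = np.linspace(0.05, 0.999, 40)
        vals = [annulus_resistance(0.0035, 4e-3, R, t * R) for t in ratios]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 1e6 * vals[0]

    def test_severe_throat_tight_fit_dominates(self):
        """0.35-mm wire in the 0.45-mm throat: annular resistance nearly two
        orders of magnitude above the wire-free throat (factor ~77)."""
        r_free = poiseuille_resistance(0.0035, 4e-3, 0.45e-3)
        r_wire = annulus_resistance(0.0035, 4e-3, 0.225e-3, 0.175e-3)
        assert r_wire > 50 * r_free
        assert np.isfinite(r_wire)

    def test_inner_radius_at_wall_is_occlusion(self):
        with pytest.raises(fw.OcclusionError):
            annulus_resistance(0.0035, 0.01, 1e-3, 1e-3)


class TestStenosisLoss:
    def test_equal_areas_reduce_to_viscous_drop(self):
        dp = stenosis_loss(1e-6, throat_resistance=1e8, throat_area=1e-6,
                           upstream_area=1e-6, density=1050.0)
        assert dp == pytest.approx(1e8 * 1e-6, rel=1e-14)

    def test_zero_flow_zero_drop(self):
        assert stenosis_loss(0.0, throat_resistance=1e8, throat_area=1e-6,
                             upstream_area=7e-6, density=1050.0) == 0.0

    def test_matches_direct_formula(self):
        # independent one-line evaluation of the stated composition
        q, rt, a_t, a_u, rho, kt = 1e-6, 2.0e8, 1.13e-6, 7.07e-6, 1050.0, 1.0
        expected = rt * q + kt * 0.5 * rho * q * abs(q) * (1/a_t - 1/a_u) ** 2
        got = stenosis_loss(q, throat_resistance=rt, throat_area=a_t,
                            upstream_area=a_u, density=rho,
                            loss_coefficient=kt)
        assert got == pytest.approx(expected, rel=1e-14)

    def test_expansion_loss_odd_in_flow(self):
        dp_fwd = expansion_loss(1e-6, 1e-6, 7e-6, 1050.0)
        dp_rev = expansion_loss(-1e-6, 1e-6, 7e-6, 1050.0)
        assert dp_rev == -dp_fwd


class TestReynoldsNumber:
    def test_zero_flow(self):
        assert reynolds_number(0.0, 3e-3, 0.0035, 1050.0) == 0.0

    def test_reference_proximal_value(self):
        # 0.62 m/s section-mean velocity in a 3-mm vessel
        q = 0.62 * math.pi * (1.5e-3) ** 2
        assert reynolds_number(q, 3e-3, 0.0035, 1050.0) == \
            pytest.approx(558.0, rel=1e-2)

    def test_linear_in_flow(self):
        r1 = reynolds_number(1e-6, 3e-3, 0.0035, 1050.0)
        assert reynolds_number(2e-6, 3e-3, 0.0035, 1050.0) == \
            pytest.approx(2 * r1, rel=1e-14)

    def test_warns_above_laminar_guard(self):
        with pytest.warns(UserWarning):
            reynolds_number(1e-3, 3e-3, 0.0035, 1050.0)


class TestQuasiSteadySolver:
    def test_newtonian_tube_matches_poiseuille(self, single_tube,
                                               constant_waveform,
                                               newtonian_blood):
        cfg_d, cfg_l = 3.0e-3, 84.0e-3
        r_exact = poiseuille_resistance(0.0035, cfg_l, cfg_d)
        sol = solve_quasi_steady(single_tube, constant_waveform,
                                 newtonian_blood, n_steps=8)
        q_exact = 1.0e4 / r_exact
        assert sol.trunk_flow[0] == pytest.approx(q_exact, rel=1e-10)

    def test_quadratic_loss_matches_root_formula(self, scenarios,
                                                 constant_waveform,
                                                 newtonian_blood):
        geom = dataclasses.replace(
            fw.build_idealized_rca(scenarios["moderate"]), branches=None)
        x = geom.trunk.stations
        d = geom.trunk.hydraulic_diameters()
        r_lin = np.trapezoid(128 * 0.0035 / (math.pi * d ** 4), x)
        w0, _ = geom.stenosis_window
        mask = (x >= w0) & (x <= geom.stenosis_window[1])
        a_th = geom.trunk.areas[mask].min()
        a_up = geom.trunk.areas[np.flatnonzero(x <= w0 + 1e-12)[-1]]
        k = 0.5 * 1050.0 * (1 / a_th - 1 / a_up) ** 2
        p = 1.0e4
        q_exact = (-r_lin + math.sqrt(r_lin ** 2 + 4 * k * p)) / (2 * k)
        sol = solve_quasi_steady(geom, constant_waveform, newtonian_blood,
                                 n_steps=8)
        assert sol.trunk_flow[0] == pytest.approx(q_exact, rel=1e-10)

    def test_linear_mode_homogeneity(self, single_tube, newtonian_blood):
        wf1 = fw.synth_waveform(mean_pressure=8e3, pulse_amplitude=2e3)
        wf2 = fw.synth_waveform(mean_pressure=2.4e4, pulse_amplitude=6e3)
        s1 = solve_quasi_steady(single_tube, wf1, newtonian_blood, n_steps=32)
        s2 = solve_quasi_steady(single_tube, wf2, newtonian_blood, n_steps=32)
        assert np.allclose(s2.trunk_flow, 3.0 * s1.trunk_flow, rtol=1e-9)

    def test_mass_conservation_at_bifurcation(self, moderate_case, blood):
        geom, wf, _ = moderate_case
        sol = solve_quasi_steady(geom, wf, blood, n_steps=32)
        imbalance = np.abs(sol.trunk_flow - sol.branch_flows.sum(axis=0))
        assert np.all(imbalance <= 1e-10 * np.abs(sol.trunk_flow))

    def test_station_pressures_non_increasing_downstream(self, moderate_case,
                                                         blood):
        geom, wf, _ = moderate_case
        sol = solve_quasi_steady(geom, wf, blood, n_steps=16)
        drops = np.diff(sol.station_pressures, axis=0)
        assert np.all(drops <= 1e-9)

    def test_wire_strictly_reduces_cycle_mean_flow(self, scenarios, blood):
        for name in ("mild", "moderate", "severe"):
            cfg = scenarios[name]
            geom = fw.build_idealized_rca(cfg)
            wf = fw.waveform_for(cfg)
            q0 = solve_quasi_steady(geom, wf, blood, n_steps=24).mean_trunk_flow()
            qw = solve_quasi_steady(geom.with_wire(0.35e-3, 24e-3), wf, blood,
                                    n_steps=24).mean_trunk_flow()
            assert qw < q0

    def test_advancing_tip_monotonically_reduces_flow(self, moderate_case,
                                                      blood):
        geom, wf, cfg = moderate_case
        flows = []
        for tip in cfg.wire_schedule:
            sol = solve_quasi_steady(geom.with_wire(0.35e-3, tip), wf, blood,
                                     n_steps=16)
            flows.append(sol.mean_trunk_flow())
        assert np.all(np.diff(flows) < 0)

    def test_occluding_wire_yields_flagged_zero_flow(self, moderate_case,
                                                     blood):
        geom, wf, _ = moderate_case
        sol = solve_quasi_steady(geom.with_wire(1.3e-3, 24e-3), wf, blood,
                                 n_steps=8)
        assert sol.occluded
        assert np.all(sol.trunk_flow == 0.0)

    def test_total_drop_strictly_increasing_in_flow(self, moderate_case,
                                                    blood):
        geom, _, _ = moderate_case
        net = fw.ResistanceNetwork(geom, blood)
        qs = np.linspace(-2e-5, 2e-5, 41)
        dps = [net.total_drop(q) for q in qs]
        assert np.all(np.diff(dps) > 0)


class TestSegmentResistance:
    def test_pressure_drop_monotone(self):
        seg = fw.SegmentResistance(0.0, 0.01, resistance=1e8,
                                   loss_coefficient=1e13, kind="stenosis")
        qs = np.linspace(-1e-5, 1e-5, 21)
        dps = [seg.pressure_drop(q) for q in qs]
        assert np.all(np.diff(dps) > 0)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            fw.SegmentResistance(0.0, 0.01, resistance=-1.0)


def test_solution_frame_has_unit_suffixed_columns(moderate_case, blood):
    geom, wf, _ = moderate_case
    sol = solve_quasi_steady(geom, wf, blood, n_steps=8)
    frame = fw.hemodynamics.solution_to_frame(sol)
    assert "time_s" in frame.columns
    assert "trunk_flow_m3s" in frame.columns
    assert any(c.startswith("pressure_") and c.endswith("_mmHg")
               for c in frame.columns)
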