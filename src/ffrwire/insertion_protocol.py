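"""The invasive measurement procedure as an orchestrated protocol.

Three configurations are simulated per lesion:

* ``run_baseline`` — no wire, the reference the clinical estimate is judged
  against;
* ``run_full_position`` — the wire spans inlet to its most distal station
  for the whole simulation (the usual modelling simplification);
* ``run_insertion_sweep`` — one quasi-steady run per scheduled tip
  position, imitating the stepwise advance of the wire. The "during
  insertion" pressure at station x is the tip reading of the run whose tip
  sits at x, and the aggregate CDP uses the across-position mean proximal
  velocity.

Every diagnostic is referenced to the matching healthy artery (same trunk
at its reference diameter, same branches), which provides both the healthy
flow Q_H and the calibration constant C at the distal measurement station.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diagnostics as dg
from .geometry import ArteryGeometry, classify_severity
from .hemodynamics import FlowSolution, solve_quasi_steady
from .rheology import BloodModel
from .synthetic_data import PressureWaveform
from .units import mmhg_to_pa, pa_to_mmhg

__all__ = [
    "PositionReading",
    "SweepResult",
    "distal_measurement_station",
    "run_baseline",
    "run_full_position",
    "run_insertion_sweep",
]


def distal_measurement_station(geometry: ArteryGeometry) -> float:
    """Default P_d station: first station downstream of the lesion and at or
    before the bifurcation. For a lesion-free geometry the bifurcation
    station itself is used."""
    x = geometry.trunk.stations
    if geometry.stenosis_window is None:
        return float(x[-1])
    w1 = geometry.stenosis_window[1]
    after = x[x > w1 + 1e-12]
    if after.size == 0:
        return float(x[-1])
    return float(after[0])


def _solve_pair(geometry: ArteryGeometry, waveform: PressureWaveform,
                blood: BloodModel, **solver_kw) -> tuple[FlowSolution, FlowSolution]:
    """Solve the given geometry and its healthy counterpart."""
    healthy = geometry.without_stenosis()
    sol = solve_quasi_steady(geometry, waveform, blood, **solver_kw)
    sol_h = solve_quasi_steady(healthy, waveform, blood, **solver_kw)
    return sol, sol_h


def _report(sol: FlowSolution, sol_h: FlowSolution, geometry: ArteryGeometry,
            blood: BloodModel, station_x: float, wire_state: str,
            pd_mean_pa: float | None = None,
            u_e_mean: float | None = None) -> dg.DiagnosticReport:
    """Assemble a DiagnosticReport from a solved case and its healthy twin."""
    pa_pa = dg.time_average(sol.station_pressures[0], sol.times, sol.period)
    if pd_mean_pa is None:
        pd_mean_pa = sol.mean_station_pressure(station_x)
    pa_h = dg.time_average(sol_h.station_pressures[0], sol_h.times, sol_h.period)
    pd_prime = sol_h.mean_station_pressure(station_x)
    c = dg.calibrate_c(pa_h, pd_prime)

    q_s = sol.mean_trunk_flow()
    q_h = sol_h.mean_trunk_flow()
    if u_e_mean is None:
        u_e_mean = sol.mean_inlet_velocity()
    dp_pa = pa_pa - pd_mean_pa
    cdp_val = (dg.cdp(dp_pa, blood.density, u_e_mean)
               if u_e_mean > 0 else float("inf"))
    return dg.DiagnosticReport(
        pa_mean=pa_to_mmhg(pa_pa),
        pd_mean=pa_to_mmhg(pd_mean_pa),
        dp_mean=pa_to_mmhg(dp_pa),
        u_e_mean=u_e_mean,
        cdp=cdp_val,
        c_constant=c,
        ffr_pressure=dg.ffr_pressure(pd_mean_pa, pa_pa, c),
        ffr_flow=dg.ffr_flow(q_s, q_h),
        flow_reduction_vs_healthy=dg.flow_reduction(q_h, q_s),
        severity_class=classify_severity(geometry.severity),
        wire_state=wire_state,
        measurement_station=station_x,
        occluded=sol.occluded,
    )


def run_baseline(geometry: ArteryGeometry, waveform: PressureWaveform,
                 blood: BloodModel, station_x: float | None = None,
                 **solver_kw) -> dg.DiagnosticReport:
    """Wire-free reference diagnostics for a (possibly healthy) geometry."""
    if geometry.wire is not None:
        raise ValueError("baseline geometry must not carry a wire")
    if station_x is None:
        station_x = distal_measurement_station(geometry)
    sol, sol_h = _solve_pair(geometry, waveform, blood, **solver_kw)
    return _report(sol, sol_h, geometry, blood, station_x, "none")


def run_full_position(geometry: ArteryGeometry, waveform: PressureWaveform,
                      blood: BloodModel, tip_x: float | None = None,
                      wire_diameter: float = 0.35e-3,
                      **solver_kw) -> dg.DiagnosticReport:
    """Diagnostics with the wire held at its most distal position.

    The distal pressure is read at the wire tip (default: the last trunk
    station). A zero-diameter wire reproduces the baseline exactly.
    """
    if geometry.wire is not None:
        raise ValueError("pass a wire-free geometry; the wire is attached here")
    if tip_x is None:
        tip_x = float(geometry.trunk.stations[-1])
    geom_w = (geometry.with_wire(wire_diameter, tip_x)
              if wire_diameter > 0 else geometry)
    sol, sol_h = _solve_pair(geom_w, waveform, blood, **solver_kw)
    return _report(sol, sol_h, geometry, blood, tip_x, "full_position")


@dataclass(frozen=True)
class PositionReading:
    """Cycle-mean readings of one wire-tip position."""

    tip_pressure_mmhg: float
    trunk_flow_m3s: float
    inlet_velocity_ms: float
    occluded: bool


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Stepped-insertion outcome: per-position readings, the assembled
    tip-pressure profile, and the aggregate during-insertion diagnostics."""

    per_position: dict[float, PositionReading]
    assembled_profile: np.ndarray      # (n, 2): x (m), mean tip pressure (mmHg)
    aggregate: dg.DiagnosticReport


def run_insertion_sweep(geometry: ArteryGeometry, waveform: PressureWaveform,
                        blood: BloodModel,
                        schedule: tuple[float, ...] | None = None,
                        wire_diameter: float = 0.35e-3,
                        **solver_kw) -> SweepResult:
    """Simulate the stepwise wire advance over ``schedule`` tip positions.

    Aggregate diagnostics follow the clinical bookkeeping: P_d (and the
    trans-lesion drop) come from the most distal tip reading, while the CDP
    velocity is the mean proximal velocity across all positions. Positions
    where the wire occludes the lumen are flagged and the sweep continues.
    """
    if geometry.wire is not None:
        raise ValueError("pass a wire-free geometry; wires are attached per position")
    if schedule is None:
        schedule = tuple(float(x) for x in geometry.trunk.stations[-1:])
    schedule = tuple(float(x) for x in schedule)
    if len(schedule) == 0 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be a non-empty strictly increasing sequence")
    x = geometry.trunk.stations
    if schedule[0] < x[0] - 1e-12 or schedule[-1] > x[-1] + 1e-12:
        raise ValueError("schedule positions must lie within the trunk")

    healthy = geometry.without_stenosis()
    sol_h = solve_quasi_steady(healthy, waveform, blood, **solver_kw)

    per_position: dict[float, PositionReading] = {}
    last_sol: FlowSolution | None = None
    velocities = []
    for tip in schedule:
        geom_w = (geometry.with_wire(wire_diameter, tip)
                  if wire_diameter > 0 else geometry)
        sol = solve_quasi_steady(geom_w, waveform, blood, **solver_kw)
        u = sol.mean_inlet_velocity()
        per_position[tip] = PositionReading(
            tip_pressure_mmhg=pa_to_mmhg(sol.mean_station_pressure(tip)),
            trunk_flow_m3s=sol.mean_trunk_flow(),
            inlet_velocity_ms=u,
            occluded=sol.occluded,
        )
        velocities.append(u)
        last_sol = sol

    profile = np.asarray(
        [[tip, per_position[tip].tip_pressure_mmhg] for tip in schedule])
    u_mean_across = float(np.mean(velocities))
    tip_last = schedule[-1]
    pd_last_pa = mmhg_to_pa(per_position[tip_last].tip_pressure_mmhg)

    aggregate = _report(
        last_sol, sol_h, geometry, blood, tip_last, "during_insertion",
        pd_mean_pa=pd_last_pa, u_e_mean=u_mean_across)
    return SweepResult(per_position=per_position,
                       assembled_profile=profile,
                       aggregate=aggregate)
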