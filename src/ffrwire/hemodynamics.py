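"""Quasi-steady reduced-order flow solver.

The pulsatile problem is treated as a sequence of independent steady solves:
at each sample of the inlet pressure waveform the trunk flow Q satisfies

    p_in(t) = sum_segments dp_segment(Q) + dp_parallel_branches(Q),

with both outlets at zero gauge. Each trunk segment contributes a viscous
Poiseuille drop (tube or concentric-annulus closed form, viscosity from the
Carreau law at the segment's wall shear rate) and the lesion adds a
Borda-Carnot expansion loss quadratic in Q. The map Q -> dp is strictly
monotone (losses use Q|Q|), so the per-step solve is a safeguarded
one-dimensional root find on a guaranteed bracket. Fluid inertia and wall
compliance are neglected — the diagnostics of interest are cycle averages,
for which a resistive network is the standard reduced-order frame.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, OcclusionError
from .geometry import ArteryGeometry
from .rheology import BloodModel, apparent_viscosity
from .synthetic_data import PressureWaveform
from .units import pa_to_mmhg

__all__ = [
    "SegmentResistance",
    "FlowSolution",
    "poiseuille_resistance",
    "annulus_resistance",
    "stenosis_loss",
    "expansion_loss",
    "reynolds_number",
    "ResistanceNetwork",
    "solve_quasi_steady",
    "solution_to_frame",
]

#: Laminarity guard: wall-bounded blood flow is taken laminar below this.
REYNOLDS_LAMINAR_LIMIT = 2000.0


def poiseuille_resistance(viscosity: float, length: float,
                          diameter: float) -> float:
    """Linear resistance 128*mu*l/(pi*d^4) of a circular tube (Pa.s/m^3)."""
    if viscosity <= 0 or length <= 0 or diameter <= 0:
        raise ValueError("viscosity, length and diameter must be positive")
    return 128.0 * viscosity * length / (math.pi * diameter ** 4)


def _annulus_geom_factor(outer_radius: float, inner_radius: float) -> float:
    """Per-unit-length resistance divided by viscosity, 8/(pi*K), for a
    concentric annulus; K = R^4 - r^4 - (R^2-r^2)^2/ln(R/r)."""
    R, r = outer_radius, inner_radius
    if r == 0.0:
        return 8.0 / (math.pi * R ** 4)
    K = R ** 4 - r ** 4 - (R ** 2 - r ** 2) ** 2 / math.log(R / r)
    if K <= 0.0:
        raise OcclusionError("annular gap numerically closed")
    return 8.0 / (math.pi * K)


def annulus_resistance(viscosity: float, length: float, outer_radius: float,
                       inner_radius: float) -> float:
    """Closed-form Poiseuille resistance of a concentric annulus.

    ``inner_radius = 0`` returns the open-tube value exactly; the resistance
    grows without bound (logarithmically slowly at first) as the inner
    radius approaches the outer one, and an inner radius at or beyond the
    outer wall is a complete occlusion.
    """
    if viscosity <= 0 or length <= 0 or outer_radius <= 0:
        raise ValueError("viscosity, length and outer_radius must be positive")
    if inner_radius < 0:
        raise ValueError("inner_radius must be non-negative")
    if inner_radius >= outer_radius:
        raise OcclusionError("inner_radius >= outer_radius: flow area closed")
    return viscosity * length * _annulus_geom_factor(outer_radius, inner_radius)


def expansion_loss(flow: float, throat_area: float, upstream_area: float,
                   density: float, loss_coefficient: float = 1.0) -> float:
    """Borda-Carnot irreversible expansion loss (Pa), quadratic in Q.

    dp = K_t * (rho/2) * Q|Q| * (1/A_throat - 1/A_upstream)^2. Odd in Q so
    the total pressure-drop map stays monotone under backflow.
    """
    if throat_area <= 0 or upstream_area <= 0 or density <= 0:
        raise ValueError("areas and density must be positive")
    dv = 1.0 / throat_area - 1.0 / upstream_area
    return loss_coefficient * 0.5 * density * flow * abs(flow) * dv * dv


def stenosis_loss(flow: float, *, throat_resistance: float,
                  throat_area: float, upstream_area: float, density: float,
                  loss_coefficient: float = 1.0) -> float:
    """Trans-lesion pressure drop: viscous throat term plus expansion loss.

    ``throat_resistance`` is the tube/annulus viscous resistance of the
    throat segment at the current viscosity.
    """
    if throat_resistance < 0:
        raise ValueError("throat_resistance must be non-negative")
    return throat_resistance * flow + expansion_loss(
        flow, throat_area, upstream_area, density, loss_coefficient)


def reynolds_number(flow: float, diameter: float, viscosity: float,
                    density: float) -> float:
    """Tube Reynolds number rho*v*d/mu with v = 4|Q|/(pi d^2)."""
    if diameter <= 0 or viscosity <= 0 or density <= 0:
        raise ValueError("diameter, viscosity and density must be positive")
    v = 4.0 * abs(flow) / (math.pi * diameter ** 2)
    re = density * v * diameter / viscosity
    if re > REYNOLDS_LAMINAR_LIMIT:
        warnings.warn(
            f"Reynolds number {re:.0f} exceeds the laminar guard "
            f"({REYNOLDS_LAMINAR_LIMIT:.0f}); the resistive model assumes "
            "laminar flow", stacklevel=2)
    return re


@dataclass(frozen=True)
class SegmentResistance:
    """Lumped segment: dp(Q) = R*Q + k*Q|Q| over [x_start, x_end].

    ``kind`` records the geometry the coefficients came from
    ({tube | annulus | stenosis}).
    """

    x_start: float
    x_end: float
    resistance: float
    loss_coefficient: float = 0.0
    kind: str = "tube"

    def __post_init__(self) -> None:
        if self.resistance < 0 or self.loss_coefficient < 0:
            raise ValueError("resistance coefficients must be non-negative")

    def pressure_drop(self, flow: float) -> float:
        return self.resistance * flow + self.loss_coefficient * flow * abs(flow)


@dataclass(frozen=True, eq=False)
class FlowSolution:
    """Per-time-step flows and station pressures of a quasi-steady run."""

    times: np.ndarray                 # s, spans one period
    period: float
    trunk_flow: np.ndarray            # m^3/s
    branch_flows: np.ndarray          # (2, nt) m^3/s; zeros if no branches
    station_pressures: np.ndarray     # (n_stations, nt) Pa gauge
    stations: np.ndarray              # m
    inlet_velocity: np.ndarray        # m/s, section-mean at the inlet
    converged: np.ndarray             # bool per step
    occluded: bool = False
    max_reynolds: float = 0.0

    def _mean(self, series: np.ndarray) -> float:
        return float(np.trapezoid(series, self.times) / self.period)

    def mean_trunk_flow(self) -> float:
        return self._mean(self.trunk_flow)

    def mean_inlet_velocity(self) -> float:
        return self._mean(self.inlet_velocity)

    def mean_branch_flows(self) -> tuple[float, float]:
        return self._mean(self.branch_flows[0]), self._mean(self.branch_flows[1])

    def station_pressure_series(self, x: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.stations - x)))
        if abs(self.stations[i] - x) > 1e-9:
            raise ValueError(f"no station at x = {x!r}")
        return self.station_pressures[i]

    def mean_station_pressure(self, x: float) -> float:
        return self._mean(self.station_pressure_series(x))


class ResistanceNetwork:
    """Precomputed nonlinear resistance chain for one geometry and blood.

    Exposes the monotone total pressure-drop map and the per-station drop
    profile; `solve_quasi_steady` drives it over a waveform.
    """

    def __init__(self, geometry: ArteryGeometry, blood: BloodModel,
                 expansion_loss_coefficient: float = 1.0):
        self.geometry = geometry
        self.blood = blood
        trunk = geometry.trunk
        self.x = trunk.stations
        lumen_area = trunk.areas
        lumen_perim = trunk.perimeters
        wire = geometry.wire

        in_wire = np.zeros(self.x.size, dtype=bool)
        flow_area = lumen_area.copy()
        flow_perim = lumen_perim.copy()
        self.occluded = False
        if wire is not None and wire.diameter > 0:
            in_wire = (self.x >= wire.entry_position - 1e-12) & (
                self.x <= wire.tip_position + 1e-12)
            wire_area = math.pi * (wire.diameter / 2.0) ** 2
            flow_area[in_wire] -= wire_area
            flow_perim[in_wire] += math.pi * wire.diameter
            if np.any(flow_area[in_wire] <= 0):
                self.occluded = True
                self._first_blocked = int(np.argmax(flow_area <= 0))
        self.in_wire = in_wire
        self.flow_area = flow_area
        self.flow_perim = flow_perim

        if not self.occluded:
            self.d_h = 4.0 * flow_area / flow_perim
            # per-unit-length viscous factor g: R'(x) = mu(x) * g(x)
            lumen_radius = 2.0 * lumen_area / lumen_perim  # = d/2 for circles
            g = np.empty_like(lumen_area)
            tube = ~in_wire
            g[tube] = 8.0 / (math.pi * lumen_radius[tube] ** 4)
            if in_wire.any():
                r_w = wire.diameter / 2.0
                g[in_wire] = np.asarray([
                    _annulus_geom_factor(R, r_w) for R in lumen_radius[in_wire]
                ])
            self.g = g
            self.dx = np.diff(self.x)

        # Borda-Carnot expansion loss, lumped at the lesion's divergent end
        self.k_quad = 0.0
        self.i_loss = None
        if geometry.stenosis_window is not None and not self.occluded:
            w0, w1 = geometry.stenosis_window
            in_window = (self.x >= w0 - 1e-12) & (self.x <= w1 + 1e-12)
            idx_window = np.flatnonzero(in_window)
            i_throat = idx_window[int(np.argmin(flow_area[idx_window]))]
            i_up = int(np.flatnonzero(self.x <= w0 + 1e-12)[-1])
            a_th = flow_area[i_throat]
            a_up = flow_area[i_up]
            dv = 1.0 / a_th - 1.0 / a_up
            self.k_quad = expansion_loss_coefficient * 0.5 * blood.density * dv * dv
            self.i_loss = int(np.flatnonzero(self.x >= w1 - 1e-12)[0])

        self.branches = geometry.branches

        # guaranteed bracket: resistance floor at the infinite-shear viscosity
        if not self.occluded:
            rp_floor = blood.mu_inf * self.g
            r_trunk_floor = float(
                np.sum(0.5 * (rp_floor[:-1] + rp_floor[1:]) * self.dx))
            if self.branches is not None:
                rb = [poiseuille_resistance(blood.mu_inf, b.length, b.diameter)
                      for b in self.branches]
                r_branch_floor = rb[0] * rb[1] / (rb[0] + rb[1])
            else:
                r_branch_floor = 0.0
            self._r_floor = r_trunk_floor + r_branch_floor

    # -- trunk --------------------------------------------------------------

    def _segment_viscosity(self, flow: float) -> np.ndarray:
        gamma = 32.0 * abs(flow) / (math.pi * self.d_h ** 3)
        return np.asarray(apparent_viscosity(self.blood, gamma))

    def trunk_drop_profile(self, flow: float) -> np.ndarray:
        """Cumulative pressure drop (Pa) from the inlet to every station."""
        mu = self._segment_viscosity(flow)
        rp = mu * self.g
        seg = 0.5 * (rp[:-1] + rp[1:]) * self.dx * flow
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        if self.k_quad:
            cum[self.i_loss:] += self.k_quad * flow * abs(flow)
        return cum

    # -- branches -----------------------------------------------------------

    def branch_split(self, flow: float) -> tuple[tuple[float, float], float]:
        """Partition trunk flow between the daughters so both see the same
        bifurcation pressure; returns ((q_main, q_side), dp_branch).

        Viscosity is updated by fixed-point iteration on each branch's wall
        shear rate (tolerance 1e-14 relative, cap 100 iterations)."""
        if self.branches is None:
            return (0.0, 0.0), 0.0
        if flow == 0.0:
            return (0.0, 0.0), 0.0
        (bm, bs) = self.branches
        q = 0.5 * flow
        r_main = r_side = 0.0
        for _ in range(100):
            mu_m = apparent_viscosity(
                self.blood, 32.0 * abs(q) / (math.pi * bm.diameter ** 3))
            mu_s = apparent_viscosity(
                self.blood, 32.0 * abs(flow - q) / (math.pi * bs.diameter ** 3))
            r_main = poiseuille_resistance(mu_m, bm.length, bm.diameter)
            r_side = poiseuille_resistance(mu_s, bs.length, bs.diameter)
            q_new = flow * r_side / (r_main + r_side)
            done = abs(q_new - q) <= 1e-14 * abs(flow)
            q = q_new
            if done:
                break
        return (q, flow - q), r_main * q

    # -- assembled map ------------------------------------------------------

    def total_drop(self, flow: float) -> float:
        drop = float(self.trunk_drop_profile(flow)[-1])
        _, dp_branch = self.branch_split(flow)
        return drop + dp_branch

    def solve_flow(self, inlet_pressure: float, *, time: float | None = None) -> float:
        """Trunk flow balancing the inlet pressure against the network."""
        p = inlet_pressure
        if self.occluded or p == 0.0:
            return 0.0
        q_ub = 10.0 * abs(p) / self._r_floor
        lo, hi = (0.0, q_ub) if p > 0 else (-q_ub, 0.0)
        f = lambda q: self.total_drop(q) - p
        try:
            return brentq(f, lo, hi, xtol=1e-24,
                          rtol=4.0 * np.finfo(float).eps, maxiter=200)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            raise ConvergenceError(
                f"flow solve failed at p = {p:.6g} Pa: {exc}",
                time=time, residual=float(f(q_ub))) from exc


def solve_quasi_steady(geometry: ArteryGeometry, waveform: PressureWaveform,
                       blood: BloodModel, n_steps: int = 200,
                       expansion_loss_coefficient: float = 1.0,
                       time_grid: np.ndarray | None = None) -> FlowSolution:
    """Drive the resistance network over one cardiac cycle.

    One period is simulated on a uniform grid of ``n_steps`` intervals
    (endpoint included, so cycle averages close exactly). A completely
    occluded wire yields the zero-flow solution with the ``occluded`` flag
    set rather than an error.
    """
    net = ResistanceNetwork(geometry, blood,
                            expansion_loss_coefficient=expansion_loss_coefficient)
    if time_grid is not None:
        times = np.asarray(time_grid, dtype=float)
    else:
        times = np.linspace(0.0, waveform.period, n_steps + 1)
    nt = times.size
    ns = net.x.size
    q_trunk = np.zeros(nt)
    q_branch = np.zeros((2, nt))
    pressures = np.empty((ns, nt))
    converged = np.ones(nt, dtype=bool)
    max_re = 0.0

    p_in = waveform.pressure_at(times)
    for j in range(nt):
        p = float(p_in[j])
        if net.occluded:
            blocked = net._first_blocked
            pressures[:blocked, j] = p
            pressures[blocked:, j] = 0.0
            continue
        q = net.solve_flow(p, time=float(times[j]))
        q_trunk[j] = q
        pressures[:, j] = p - net.trunk_drop_profile(q)
        (qm, qs), _ = net.branch_split(q)
        q_branch[0, j] = qm
        q_branch[1, j] = qs
        re = reynolds_number(q, float(net.d_h[0]), blood.mu_inf, blood.density)
        max_re = max(max_re, re)

    if not net.occluded:
        inlet_velocity = q_trunk / net.flow_area[0]
    else:
        inlet_velocity = np.zeros(nt)

    return FlowSolution(
        times=times,
        period=waveform.period,
        trunk_flow=q_trunk,
        branch_flows=q_branch,
        station_pressures=pressures,
        stations=net.x.copy(),
        inlet_velocity=inlet_velocity,
        converged=converged,
        occluded=net.occluded,
        max_reynolds=max_re,
    )


def solution_to_frame(sol: FlowSolution, station_labels=None):
    """Tabular export: time, flows and one gauge-pressure column (mmHg) per
    station. ``station_labels`` defaults to the station coordinate in mm."""
    import pandas as pd

    data = {
        "time_s": sol.times,
        "trunk_flow_m3s": sol.trunk_flow,
        "main_branch_flow_m3s": sol.branch_flows[0],
        "side_branch_flow_m3s": sol.branch_flows[1],
    }
    if station_labels is None:
        station_labels = [f"x{1000.0 * x:+.3f}mm" for x in sol.stations]
    for label, row in zip(station_labels, sol.station_pressures):
        data[f"pressure_{label}_mmHg"] = pa_to_mmhg(1.0) * row
    return pd.DataFrame(data)
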