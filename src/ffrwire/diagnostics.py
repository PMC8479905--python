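"""Diagnostic quantities for stenosis severity assessment.

Clinically, only time-averaged pressures are available during an invasive
FFR procedure. This module implements the cycle averaging, the pressure
drop coefficient

    CDP = dp_mean / (0.5 * rho * u_e_mean^2),

the fractional flow reserve both as the actual flow ratio FFR = Q_s/Q_H and
as its pressure-based clinical estimate FFR = C * P_d/P_a (with the
calibration constant C = P_a/P_d' taken from the healthy artery), and the
flow-reduction and percent-error metrics used to quantify how much the
guidewire distorts the measurement.

Conventions: CDP is strict SI (Pa, kg/m^3, m/s). Pressures in reports are
mmHg; the calibration and FFR formulas are ratios, so the unit cancels.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "DiagnosticReport",
    "time_average",
    "cdp",
    "calibrate_c",
    "ffr_pressure",
    "ffr_flow",
    "flow_reduction",
    "percent_error",
]


def time_average(samples, times, period: float | None = None) -> float:
    """Trapezoid-rule cycle mean of a sampled series over one period.

    ``times`` must span exactly one period (to 1e-9 relative) when
    ``period`` is given; otherwise the sampled span is used as the period.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(samples, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("samples and times must have equal length >= 2")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("times must be increasing")
    if period is None:
        period = span
    elif abs(span - period) > 1e-9 * period:
        raise ValueError(
            f"samples span {span:.9g} s but the period is {period:.9g} s")
    return float(np.trapezoid(y, t) / period)


def cdp(dp_mean: float, density: float, u_e_mean: float) -> float:
    """Pressure drop coefficient dp/(0.5*rho*u^2), strict SI inputs."""
    if density <= 0:
        raise ValueError("density must be positive")
    if u_e_mean <= 0:
        raise ValueError(
            "CDP is undefined for a vanishing proximal velocity")
    return dp_mean / (0.5 * density * u_e_mean ** 2)


def calibrate_c(pa_mean: float, pd_prime_mean: float) -> float:
    """Calibration constant C = P_a / P_d' from the healthy artery.

    ``pd_prime_mean`` is the healthy-run pressure at the same station where
    the stenotic case measures its distal pressure; with C in hand the
    stenotic pressure ratio P_d/P_a converts to a flow ratio.
    """
    if pd_prime_mean <= 0:
        raise ValueError("healthy distal pressure must be positive")
    return pa_mean / pd_prime_mean


def ffr_pressure(pd_mean: float, pa_mean: float, c: float) -> float:
    """Pressure-derived FFR estimate C * P_d / P_a."""
    if pa_mean <= 0:
        raise ValueError("aortic pressure must be positive")
    return c * pd_mean / pa_mean


def ffr_flow(q_stenosed_mean: float, q_healthy_mean: float) -> float:
    """Actual flow ratio Q_s / Q_H — the quantity FFR is meant to estimate."""
    if q_healthy_mean <= 0:
        raise ValueError("healthy flow must be positive")
    return q_stenosed_mean / q_healthy_mean


def flow_reduction(q_healthy: float, q: float) -> float:
    """Percent flow reduction (Q_H - Q)/Q_H * 100 relative to healthy."""
    if q_healthy <= 0:
        raise ValueError("healthy flow must be positive")
    return (q_healthy - q) / q_healthy * 100.0


def percent_error(reference: float, estimate: float) -> float:
    """Unsigned relative error 100*|reference - estimate|/reference (%)."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * abs(reference - estimate) / reference


@dataclass(frozen=True)
class DiagnosticReport:
    """Cycle-averaged diagnostics of one simulated configuration.

    ``ffr_pressure`` is the clinical estimate C*P_d/P_a; ``ffr_flow`` the
    actual flow ratio against the matching healthy artery. ``wire_state``
    is one of {none | full_position | during_insertion}.
    """

    pa_mean: float                 # mmHg, time-averaged inlet pressure
    pd_mean: float                 # mmHg, time-averaged distal pressure
    dp_mean: float                 # mmHg, inlet-to-distal drop
    u_e_mean: float                # m/s, cycle-mean proximal velocity
    cdp: float                     # dimensionless, SI convention
    c_constant: float              # dimensionless calibration P_a/P_d'
    ffr_pressure: float            # dimensionless
    ffr_flow: float                # dimensionless
    flow_reduction_vs_healthy: float   # %
    severity_class: str
    wire_state: str
    measurement_station: float     # m, axial position of P_d
    occluded: bool = False

    def to_dict(self) -> dict:
        return asdict(self)
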