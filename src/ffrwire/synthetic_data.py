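"""Synthetic study fixtures: idealized stenotic RCA geometries, a pulsatile
aortic inlet waveform, and guidewire position schedules.

These generators stand in for the raw inputs a patient study would provide
(CT-derived lumen geometry, catheter-lab pressure recordings). The idealized
right coronary artery is a straight circular trunk of 3.0 mm diameter running
from the inlet at x = -60 mm to a bifurcation at x = +24 mm, with a smooth
axisymmetric constriction whose throat hydraulic diameter realizes a target
percent reduction (1.8 / 1.2 / 0.45 mm for the 40 / 60 / 85% reference
stenoses). The throat is centred at x = 10.05 mm, midway between the two
"at the throat" wire-tip stations (9.4 and 10.7 mm).

The daughter branches are lumped straight tubes sized at build time so that
(a) the healthy artery carries a design flow of 10 mL/s at the cycle-mean
inlet pressure — placing the proximal velocity near 1.4 m/s, consistent with
the reference study's reported inlet velocities — and (b) the flow split to
the main branch equals the configured target (63.2% by default, the
experimentally measured healthy split). Daughter diameters follow Murray's
law (d_i proportional to the cube root of the flow fraction) so that both
branches operate at the same wall shear rate: the split target is then
realized exactly under shear-thinning rheology, not just in the Newtonian
limit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ArteryGeometry, AxialProfile, Branch
from .units import MMHG_PA

__all__ = [
    "ScenarioConfig",
    "PressureWaveform",
    "build_idealized_rca",
    "synth_waveform",
    "reference_scenarios",
    "REFERENCE_WIRE_SCHEDULE_MM",
]

#: Wire-tip stations of the stepped insertion protocol (mm): one proximal
#: reference, two before the throat, two at the throat, two beyond it.
REFERENCE_WIRE_SCHEDULE_MM: tuple[float, ...] = (0.0, 5.3, 8.0, 9.4, 10.7, 13.5, 24.0)

#: Reference viscosity (Pa.s) used only for sizing the lumped branch tubes.
REFERENCE_VISCOSITY = 3.5e-3

#: Design cycle-mean flow of the healthy artery (m^3/s) at the mean inlet
#: pressure; sets the absolute resistance level of the branch network.
DESIGN_HEALTHY_FLOW = 1.0e-5


@dataclass(frozen=True)
class PressureWaveform:
    """Periodic inlet gauge-pressure samples over one cardiac cycle.

    ``times`` spans [0, period] strictly increasing; the first and last
    samples agree (periodic closure) so cycle averages are well defined.
    """

    times: np.ndarray
    pressures: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if t.size != p.size or t.size < 2:
            raise ValueError("times and pressures must have equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < -1e-12 or t[-1] > self.period * (1 + 1e-12):
            raise ValueError("times must lie in [0, period]")
        if not np.all(np.isfinite(p)):
            raise ValueError("pressures must be finite")
        scale = max(abs(p[0]), abs(p[-1]), 1.0)
        if abs(p[0] - p[-1]) > 1e-9 * scale:
            raise ValueError("waveform is not periodically closed")

    def pressure_at(self, t):
        """Linear interpolation with periodic wrap-around (Pa)."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        out = np.interp(tt, self.times, self.pressures)
        return float(out) if out.ndim == 0 else out

    def cycle_mean(self) -> float:
        return float(np.trapezoid(self.pressures, self.times) / self.period)


@dataclass(frozen=True)
class ScenarioConfig:
    """One study condition: stenosis severity, wire protocol and inlet drive.

    ``severity_percent = 0`` (or ``None``) is the healthy artery. Reference
    fixtures use 40 / 60 / 85.
    """

    severity_percent: float = 0.0
    trunk_diameter: float = 3.0e-3
    trunk_length: float = 84.0e-3          # inlet (-60 mm) to bifurcation (+24 mm)
    stenosis_length: float = 4.0e-3
    taper_shape: str = "cosine"            # {"cosine", "trapezoid"}
    branch_split_target: float = 0.632
    wire_diameter: float = 0.35e-3
    wire_schedule: tuple[float, ...] = tuple(
        x * 1e-3 for x in REFERENCE_WIRE_SCHEDULE_MM
    )
    mean_pressure: float = 85.89 * MMHG_PA
    period: float = 0.8
    systolic_fraction: float = 0.35
    pulse_amplitude: float = 40.0 * MMHG_PA
    n_samples: int = 201
    noise_std: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        s = self.severity_percent
        if s is None:
            object.__setattr__(self, "severity_percent", 0.0)
            s = 0.0
        if not 0.0 <= s < 100.0:
            raise ValueError("severity_percent must lie in [0, 100)")
        if self.stenosis_length <= 0:
            raise ValueError("stenosis_length must be positive")
        if not 0.0 < self.branch_split_target < 1.0:
            raise ValueError("branch_split_target must lie in (0, 1)")
        if len(self.wire_schedule) and np.any(np.diff(self.wire_schedule) <= 0):
            raise ValueError("wire_schedule must be strictly increasing")
        if self.taper_shape not in ("cosine", "trapezoid"):
            raise ValueError("taper_shape must be 'cosine' or 'trapezoid'")


# throat centred between the two "at the throat" wire stations
_THROAT_CENTER = 0.5 * (9.4e-3 + 10.7e-3)
_X_INLET_OFFSET = 60.0e-3   # inlet sits 60 mm upstream of x = 0


def _throat_profile(x: np.ndarray, d0: float, d_throat: float,
                    window: tuple[float, float], center: float,
                    shape: str) -> np.ndarray:
    """Diameter along the trunk: d0 outside the lesion, tapering to
    d_throat at its centre."""
    w0, w1 = window
    length = w1 - w0
    d = np.full_like(x, d0)
    mask = (x >= w0) & (x <= w1)
    if shape == "cosine":
        # raised-cosine constriction: smooth, "sharp" convergence/divergence
        bump = 0.5 * (1.0 + np.cos(2.0 * np.pi * (x[mask] - center) / length))
    else:  # trapezoid: linear ramps with a flat throat over the middle half
        rel = np.abs(x[mask] - center) / (length / 2.0)
        bump = np.clip(2.0 * (1.0 - rel), 0.0, 1.0)
    d[mask] = d0 - (d0 - d_throat) * bump
    return d


def _station_grid(config: ScenarioConfig,
                  window: tuple[float, float] | None) -> np.ndarray:
    x_in = -_X_INLET_OFFSET
    x_bif = x_in + config.trunk_length
    coarse = np.arange(x_in, x_bif + 1e-9, 2.0e-3)
    pieces = [coarse, np.asarray([x_in, x_bif, 0.0])]
    if window is not None:
        w0, w1 = window
        pieces.append(np.arange(w0, w1 + 1e-9, (w1 - w0) / 40.0))
        pieces.append(np.asarray([w0, w1, _THROAT_CENTER]))
    pieces.append(np.asarray(config.wire_schedule, dtype=float))
    x = np.concatenate(pieces)
    x = x[(x >= x_in - 1e-12) & (x <= x_bif + 1e-12)]
    # dedup on a 1-nm grid to avoid float-noise near-duplicates
    x = np.unique(np.round(x, 12))
    return x


def _design_branches(config: ScenarioConfig,
                     trunk_resistance: float) -> tuple[Branch, Branch]:
    """Size the two lumped daughter tubes.

    Total healthy resistance is set by the design flow at the cycle-mean
    inlet pressure; the parallel pair is then partitioned so the main branch
    takes ``branch_split_target`` of the flow. Murray's-law diameters give
    both branches identical wall shear at that split.
    """
    f = config.branch_split_target
    r_total = config.mean_pressure / DESIGN_HEALTHY_FLOW
    r_parallel = r_total - trunk_resistance
    if r_parallel <= 0:
        raise ValueError("trunk resistance exceeds the design total; "
                         "increase trunk_diameter or the design flow")
    r_main = r_parallel / f
    r_side = r_parallel / (1.0 - f)
    d_main = config.trunk_diameter * f ** (1.0 / 3.0)
    d_side = config.trunk_diameter * (1.0 - f) ** (1.0 / 3.0)
    mu = REFERENCE_VISCOSITY
    l_main = r_main * math.pi * d_main ** 4 / (128.0 * mu)
    l_side = r_side * math.pi * d_side ** 4 / (128.0 * mu)
    return Branch(l_main, d_main), Branch(l_side, d_side)


def build_idealized_rca(config: ScenarioConfig) -> ArteryGeometry:
    """Deterministic idealized stenotic RCA for one scenario.

    Circular trunk of ``trunk_diameter`` with a smooth constriction whose
    throat hydraulic diameter equals ``trunk_diameter * (1 - severity/100)``
    exactly (a station is placed at the throat). Severity 0 yields a uniform
    tube. The returned geometry carries no wire; the insertion protocol
    attaches one per tip position.
    """
    d0 = config.trunk_diameter
    s = config.severity_percent
    if s > 0:
        d_throat = d0 * (1.0 - s / 100.0)
        half = config.stenosis_length / 2.0
        window = (_THROAT_CENTER - half, _THROAT_CENTER + half)
    else:
        d_throat = d0
        window = None

    x = _station_grid(config, window)
    if window is not None:
        d = _throat_profile(x, d0, d_throat, window, _THROAT_CENTER,
                            config.taper_shape)
    else:
        d = np.full_like(x, d0)
    areas = np.pi * (d / 2.0) ** 2
    perimeters = np.pi * d
    trunk = AxialProfile(stations=x, areas=areas, perimeters=perimeters)

    # healthy-trunk resistance at the reference viscosity, for branch sizing
    r_trunk = 128.0 * REFERENCE_VISCOSITY * config.trunk_length / (
        math.pi * d0 ** 4)
    branches = _design_branches(config, r_trunk)

    return ArteryGeometry(
        trunk=trunk,
        stenosis_window=window,
        throat_position=_THROAT_CENTER if window is not None else None,
        branches=branches,
        wire=None,
    )


def synth_waveform(mean_pressure: float = 85.89 * MMHG_PA,
                   period: float = 0.8,
                   systolic_fraction: float = 0.35,
                   pulse_amplitude: float = 40.0 * MMHG_PA,
                   n_samples: int = 201,
                   noise_std: float = 0.0,
                   random_seed: int = 0) -> PressureWaveform:
    """Parameterized aortic pressure waveform with an exact cycle mean.

    Shape: a half-sine systolic rise/fall over ``systolic_fraction * period``
    riding on a baseline that ramps up during systole and decays
    exponentially back during diastole (time constant one third of the
    diastolic interval). The whole curve is shifted so its trapezoid-rule
    cycle mean equals ``mean_pressure`` exactly; the samples stay positive
    whenever ``pulse_amplitude < 2 * mean_pressure``.
    """
    if mean_pressure <= 0:
        raise ValueError("mean_pressure must be positive")
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if pulse_amplitude < 0:
        raise ValueError("pulse_amplitude must be non-negative")

    t = np.linspace(0.0, period, n_samples)
    ts = systolic_fraction * period
    tau = (period - ts) / 3.0
    systole = t <= ts

    pulse = np.zeros_like(t)
    pulse[systole] = pulse_amplitude * np.sin(np.pi * t[systole] / ts)

    # diastolic run-off: baseline rises by 0.3*amplitude across systole and
    # decays exactly back to its start-of-cycle value by t = period
    rise = 0.3 * pulse_amplitude
    base = np.zeros_like(t)
    base[systole] = rise * t[systole] / ts
    td = t[~systole]
    decay = (np.exp(-(td - ts) / tau) - np.exp(-(period - ts) / tau)) / (
        1.0 - np.exp(-(period - ts) / tau))
    base[~systole] = rise * decay

    p = pulse + base
    if noise_std > 0:
        rng = np.random.default_rng(random_seed)
        p[1:-1] += rng.normal(0.0, noise_std, size=n_samples - 2)
    p += mean_pressure - np.trapezoid(p, t) / period
    return PressureWaveform(times=t, pressures=p, period=period)


def waveform_for(config: ScenarioConfig) -> PressureWaveform:
    """The inlet waveform of a scenario (deterministic given its seed)."""
    return synth_waveform(
        mean_pressure=config.mean_pressure,
        period=config.period,
        systolic_fraction=config.systolic_fraction,
        pulse_amplitude=config.pulse_amplitude,
        n_samples=config.n_samples,
        noise_std=config.noise_std,
        random_seed=config.random_seed,
    )


def reference_scenarios() -> dict[str, ScenarioConfig]:
    """The four study conditions: healthy plus 40 / 60 / 85% stenoses,
    each with the 0.35-mm wire and the seven-position insertion schedule."""
    return {
        "healthy": ScenarioConfig(severity_percent=0.0),
        "mild": ScenarioConfig(severity_percent=40.0),
        "moderate": ScenarioConfig(severity_percent=60.0),
        "severe": ScenarioConfig(severity_percent=85.0),
    }
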