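"""Lumen geometry data model for a stenotic coronary artery.

The artery trunk is described station-wise: strictly increasing axial
coordinates with the lumen cross-section area and wetted perimeter at each
station. All derived quantities (hydraulic diameter, stenosis severity,
annular wire sections) come from these two fields, so the model is agnostic
to the actual cross-section shape.

Axial convention: x = 0 at the first guidewire tip station, 60 mm downstream
of the inlet; the inlet therefore sits at x = -60 mm and the bifurcation of
the reference fixtures at x = +24 mm.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import OcclusionError

__all__ = [
    "AxialProfile",
    "Guidewire",
    "Branch",
    "ArteryGeometry",
    "hydraulic_diameter",
    "severity_percent",
    "annular_section",
    "classify_severity",
    "save_geometry",
    "load_geometry",
]


def hydraulic_diameter(area, perimeter):
    """d = 4 * area / wetted perimeter (m). Reduces to the geometric
    diameter for circles and to 2(R - r) for a concentric annulus."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be positive")
    d = 4.0 * area / perimeter
    return float(d) if d.ndim == 0 else d


def severity_percent(d_artery: float, d_throat: float) -> float:
    """Percent reduction in hydraulic diameter, (d_a - d_t)/d_a * 100."""
    if d_throat <= 0 or d_artery <= 0:
        raise ValueError("diameters must be positive")
    if d_throat > d_artery:
        raise ValueError("throat diameter exceeds reference diameter")
    return (d_artery - d_throat) / d_artery * 100.0


def annular_section(lumen_area: float, lumen_perimeter: float,
                    wire_diameter: float) -> tuple[float, float]:
    """Flow section (area, perimeter) left by a concentric wire.

    The wire removes its own cross-section from the lumen area and adds its
    circumference to the wetted perimeter. A wire at least as large as the
    lumen is a complete occlusion.
    """
    if wire_diameter < 0:
        raise ValueError("wire_diameter must be non-negative")
    if wire_diameter == 0.0:
        return float(lumen_area), float(lumen_perimeter)
    wire_area = math.pi * (wire_diameter / 2.0) ** 2
    if wire_area >= lumen_area:
        raise OcclusionError(
            f"wire area {wire_area:.3e} m^2 >= lumen area {lumen_area:.3e} m^2"
        )
    return (lumen_area - wire_area,
            lumen_perimeter + math.pi * wire_diameter)


#: Default class bin edges (% hydraulic-diameter reduction). The guideline
#: classes place 40% in "mild", 60% in "moderate" and 85% in "severe";
#: reductions below the mild edge are reported as "minimal".
DEFAULT_SEVERITY_EDGES: dict[str, float] = {
    "mild": 25.0,
    "moderate": 50.0,
    "severe": 70.0,
}


def classify_severity(percent: float,
                      edges: dict[str, float] | None = None) -> str:
    """Map a % hydraulic-diameter reduction to a named severity class."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    e = DEFAULT_SEVERITY_EDGES if edges is None else edges
    if percent >= e["severe"]:
        return "severe"
    if percent >= e["moderate"]:
        return "moderate"
    if percent >= e["mild"]:
        return "mild"
    return "minimal"


@dataclass(frozen=True, eq=False)
class AxialProfile:
    """Station-wise lumen description: x (m), area (m^2), wetted perimeter (m)."""

    stations: np.ndarray
    areas: np.ndarray
    perimeters: np.ndarray

    def __post_init__(self) -> None:
        for name in ("stations", "areas", "perimeters"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.stations.size
        if n < 2 or self.areas.size != n or self.perimeters.size != n:
            raise ValueError("profile arrays must have equal length >= 2")
        if np.any(np.diff(self.stations) <= 0):
            raise ValueError("stations must be strictly increasing")
        if np.any(self.areas <= 0) or np.any(self.perimeters <= 0):
            raise ValueError("areas and perimeters must be positive")

    def hydraulic_diameters(self) -> np.ndarray:
        return hydraulic_diameter(self.areas, self.perimeters)

    def station_index(self, x: float, tol: float = 1e-9) -> int:
        """Index of the station at axial position x (must exist)."""
        i = int(np.argmin(np.abs(self.stations - x)))
        if abs(self.stations[i] - x) > tol:
            raise ValueError(f"no station at x = {x!r}")
        return i


@dataclass(frozen=True)
class Guidewire:
    """Concentric pressure wire occupying the lumen from entry to tip."""

    diameter: float = 0.35e-3
    tip_position: float = 24.0e-3
    entry_position: float = -60.0e-3

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("wire diameter must be positive")
        if self.tip_position < self.entry_position:
            raise ValueError("tip_position must be >= entry_position")


@dataclass(frozen=True)
class Branch:
    """Daughter vessel lumped as a straight tube (length, diameter in m)."""

    length: float
    diameter: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("branch length and diameter must be positive")


@dataclass(frozen=True, eq=False)
class ArteryGeometry:
    """Stenotic trunk with optional daughter branches and guidewire.

    ``branches is None`` means the trunk discharges directly to the
    zero-gauge outlet (useful for single-tube verification cases); the
    reference fixtures bifurcate at the last trunk station.
    """

    trunk: AxialProfile
    stenosis_window: tuple[float, float] | None = None
    throat_position: float | None = None
    branches: tuple[Branch, Branch] | None = None
    wire: Guidewire | None = None

    def __post_init__(self) -> None:
        x = self.trunk.stations
        if self.stenosis_window is not None:
            w0, w1 = self.stenosis_window
            if not (x[0] <= w0 < w1 <= x[-1]):
                raise ValueError("stenosis_window outside trunk extent")
            if self.throat_position is None:
                raise ValueError("stenosed geometry needs a throat_position")
            if not (w0 <= self.throat_position <= w1):
                raise ValueError("throat_position outside stenosis_window")
        if self.wire is not None and self.wire.tip_position > x[-1] + 1e-12:
            raise ValueError("wire tip beyond trunk extent")

    # -- derived quantities -------------------------------------------------

    @property
    def reference_diameter(self) -> float:
        """Healthy-lumen hydraulic diameter, taken at the inlet station."""
        return float(self.trunk.hydraulic_diameters()[0])

    @property
    def throat_diameter(self) -> float:
        """Minimum hydraulic diameter (within the lesion if one exists)."""
        d = self.trunk.hydraulic_diameters()
        if self.stenosis_window is None:
            return float(d.min())
        w0, w1 = self.stenosis_window
        mask = (self.trunk.stations >= w0) & (self.trunk.stations <= w1)
        return float(d[mask].min())

    @property
    def severity(self) -> float:
        if self.stenosis_window is None:
            return 0.0
        return severity_percent(self.reference_diameter, self.throat_diameter)

    @property
    def wire_occludes(self) -> bool:
        """True when the wire leaves no open flow area somewhere in its span."""
        if self.wire is None:
            return False
        x = self.trunk.stations
        mask = (x >= self.wire.entry_position) & (x <= self.wire.tip_position + 1e-12)
        wire_area = math.pi * (self.wire.diameter / 2.0) ** 2
        return bool(np.any(self.trunk.areas[mask] <= wire_area))

    # -- structural edits ---------------------------------------------------

    def with_wire(self, diameter: float, tip_position: float,
                  entry_position: float | None = None) -> "ArteryGeometry":
        entry = self.trunk.stations[0] if entry_position is None else entry_position
        wire = Guidewire(diameter=diameter, tip_position=tip_position,
                         entry_position=float(entry))
        return replace(self, wire=wire)

    def without_wire(self) -> "ArteryGeometry":
        return replace(self, wire=None)

    def without_stenosis(self) -> "ArteryGeometry":
        """Healthy counterpart: uniform trunk at the reference section,
        same stations and branches, no lesion, no wire."""
        a0 = float(self.trunk.areas[0])
        p0 = float(self.trunk.perimeters[0])
        trunk = AxialProfile(
            stations=self.trunk.stations.copy(),
            areas=np.full_like(self.trunk.areas, a0),
            perimeters=np.full_like(self.trunk.perimeters, p0),
        )
        return ArteryGeometry(trunk=trunk, stenosis_window=None,
                              throat_position=None, branches=self.branches,
                              wire=None)


# -- structured-text round trip ---------------------------------------------
# JSON with shortest-round-trip float repr: numeric fields are bit-stable.

def geometry_to_dict(geom: ArteryGeometry) -> dict:
    d: dict = {
        "trunk": {
            "stations_m": geom.trunk.stations.tolist(),
            "areas_m2": geom.trunk.areas.tolist(),
            "perimeters_m": geom.trunk.perimeters.tolist(),
        },
        "stenosis_window_m": list(geom.stenosis_window)
        if geom.stenosis_window else None,
        "throat_position_m": geom.throat_position,
        "branches": [
            {"length_m": b.length, "diameter_m": b.diameter}
            for b in geom.branches
        ] if geom.branches else None,
        "wire": {
            "diameter_m": geom.wire.diameter,
            "tip_position_m": geom.wire.tip_position,
            "entry_position_m": geom.wire.entry_position,
        } if geom.wire else None,
    }
    return d


def geometry_from_dict(d: dict) -> ArteryGeometry:
    trunk = AxialProfile(
        stations=np.asarray(d["trunk"]["stations_m"], dtype=float),
        areas=np.asarray(d["trunk"]["areas_m2"], dtype=float),
        perimeters=np.asarray(d["trunk"]["perimeters_m"], dtype=float),
    )
    window = d.get("stenosis_window_m")
    branches = d.get("branches")
    wire = d.get("wire")
    return ArteryGeometry(
        trunk=trunk,
        stenosis_window=tuple(window) if window else None,
        throat_position=d.get("throat_position_m"),
        branches=tuple(Branch(b["length_m"], b["diameter_m"]) for b in branches)
        if branches else None,
        wire=Guidewire(wire["diameter_m"], wire["tip_position_m"],
                       wire["entry_position_m"]) if wire else None,
    )


def save_geometry(geom: ArteryGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps(geometry_to_dict(geom), indent=2))


def load_geometry(path: str | Path) -> ArteryGeometry:
    return geometry_from_dict(json.loads(Path(path).read_text()))
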