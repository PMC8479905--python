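"""End-to-end pipeline and reference-arithmetic verification.

``run_pipeline`` chains the whole measurement protocol for one scenario —
healthy baseline (calibrating C), wire-free stenotic baseline, full-position
wire, stepped insertion sweep — and writes the diagnostic table plus a
provenance/metadata block.

``verify_reference_arithmetic`` recomputes every derived cell of a bundled
table of reference diagnostic readings (published values from a
patient-specific CFD study of guidewire insertion: FFR/CDP error
percentages, flow-ratio and composed-reduction identities, and the
area-to-hydraulic-diameter identity of the severe throat) from its printed
inputs and checks agreement at the printed precision. This validates the
diagnostic formulas independently of any flow solve.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import DiagnosticReport, percent_error
from .errors import OcclusionError
from .insertion_protocol import (SweepResult, run_baseline, run_full_position,
                                 run_insertion_sweep)
from .rheology import BloodModel, CARREAU_HUMAN_BLOOD
from .synthetic_data import (ScenarioConfig, build_idealized_rca,
                             reference_scenarios, waveform_for)
from .units import MMHG_PA

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "verify_reference_arithmetic",
]


@dataclass(frozen=True)
class RunConfig:
    """One pipeline invocation: scenario, rheology, solver and output."""

    scenario: str | ScenarioConfig = "moderate"
    blood: BloodModel = CARREAU_HUMAN_BLOOD
    n_steps: int = 200
    expansion_loss_coefficient: float = 1.0
    schedule: tuple[float, ...] | None = None   # m; None = scenario default
    wire_diameter: float | None = None          # m; None = scenario default
    out_dir: str | None = None
    seed: int = 0

    def resolve_scenario(self) -> ScenarioConfig:
        if isinstance(self.scenario, ScenarioConfig):
            return self.scenario
        presets = reference_scenarios()
        if self.scenario not in presets:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; "
                f"choose from {sorted(presets)}")
        base = presets[self.scenario]
        from dataclasses import replace
        return replace(base, random_seed=self.seed)


@dataclass(frozen=True, eq=False)
class PipelineResult:
    reports: dict[str, DiagnosticReport]
    sweep: SweepResult | None
    table: pd.DataFrame
    metadata: dict


def _table_row(name: str, rep: DiagnosticReport,
               baseline: DiagnosticReport) -> dict:
    return {
        "case": name,
        "pa_mmHg": rep.pa_mean,
        "pd_mmHg": rep.pd_mean,
        "dp_mmHg": rep.dp_mean,
        "u_inlet_ms": rep.u_e_mean,
        "cdp": rep.cdp,
        "cdp_error_pct": (percent_error(baseline.cdp, rep.cdp)
                          if rep is not baseline and math.isfinite(rep.cdp)
                          and math.isfinite(baseline.cdp) else float("nan")),
        "ffr": rep.ffr_pressure,
        "ffr_error_pct": (percent_error(baseline.ffr_flow, rep.ffr_pressure)
                          if rep is not baseline else float("nan")),
        "occluded": rep.occluded,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Healthy calibration -> baseline -> full position -> insertion sweep.

    Emits (when ``out_dir`` is set) a diagnostics table CSV mirroring the
    without / during-insertion / full-position layout, a per-position sweep
    CSV, and a JSON metadata block recording C, unit conventions and the
    generator assumptions so no number is separable from them.
    """
    scen = config.resolve_scenario()
    geometry = build_idealized_rca(scen)
    waveform = waveform_for(scen)
    blood = config.blood
    solver_kw = dict(n_steps=config.n_steps,
                     expansion_loss_coefficient=config.expansion_loss_coefficient)
    wire_d = scen.wire_diameter if config.wire_diameter is None else config.wire_diameter
    schedule = scen.wire_schedule if config.schedule is None else config.schedule

    reports: dict[str, DiagnosticReport] = {}
    reports["without"] = run_baseline(geometry, waveform, blood, **solver_kw)
    sweep = None
    if geometry.stenosis_window is not None:
        sweep = run_insertion_sweep(geometry, waveform, blood,
                                    schedule=schedule, wire_diameter=wire_d,
                                    **solver_kw)
        reports["during_insertion"] = sweep.aggregate
        reports["full_position"] = run_full_position(
            geometry, waveform, blood, wire_diameter=wire_d, **solver_kw)

    base = reports["without"]
    table = pd.DataFrame([_table_row(k, r, base) for k, r in reports.items()])

    scen_dict = asdict(scen)
    config_hash = hashlib.sha256(
        json.dumps(scen_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    metadata = {
        "ffrwire_version": __version__,
        "config_sha256_16": config_hash,
        "scenario": scen_dict,
        "c_constant": base.c_constant,
        "conventions": {
            "pressure_unit_io": "mmHg (1 mmHg = 133.322 Pa)",
            "cdp": "strict SI: dp_Pa / (0.5 * rho_kg_m3 * u_ms^2)",
            "gauge": "all pressures gauge; outlets at 0",
        },
        "assumptions": {
            "cardiac_period_s": scen.period,
            "systolic_fraction": scen.systolic_fraction,
            "pulse_amplitude_mmHg": scen.pulse_amplitude / MMHG_PA,
            "trunk_diameter_mm": scen.trunk_diameter * 1e3,
            "stenosis_length_mm": scen.stenosis_length * 1e3,
            "expansion_loss_coefficient": config.expansion_loss_coefficient,
            "branch_split_target": scen.branch_split_target,
            "quasi_steady": True,
            "rigid_walls": True,
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "diagnostics.csv", index=False,
                     float_format="%.10g")
        if sweep is not None:
            rows = [{"tip_position_mm": 1e3 * tip,
                     "tip_pressure_mmHg": r.tip_pressure_mmhg,
                     "trunk_flow_m3s": r.trunk_flow_m3s,
                     "inlet_velocity_ms": r.inlet_velocity_ms,
                     "occluded": r.occluded}
                    for tip, r in sweep.per_position.items()]
            pd.DataFrame(rows).to_csv(out / "sweep_positions.csv",
                                      index=False, float_format="%.10g")
        (out / "metadata.json").write_text(json.dumps(metadata, indent=2))

    return PipelineResult(reports=reports, sweep=sweep, table=table,
                          metadata=metadata)


# ---------------------------------------------------------------------------
# Reference-arithmetic verification
# ---------------------------------------------------------------------------

def _ratio_from_reduction(reduction_pct: float) -> float:
    return 1.0 - reduction_pct / 100.0


def _compose_reduction(first_pct: float, further_pct: float) -> float:
    """Total % reduction after a further reduction of the remainder."""
    remaining = (1.0 - first_pct / 100.0) * (1.0 - further_pct / 100.0)
    return 100.0 * (1.0 - remaining)


def _circle_diameter_mm_from_area(area_mm2: float) -> float:
    return 2.0 * math.sqrt(area_mm2 / math.pi)


#: Bundled reference readings (printed inputs -> printed derived value).
#: Each row: check name, callable kind, inputs, printed value, printed
#: decimal places. "printed precision" match = within one unit of the last
#: printed digit (the source mixes round-half-away and truncation).
_REFERENCE_CHECKS: list[dict] = [
    # mild lesion table: CDP 1.38 -> 1.56 / 1.62, FFR 0.83 -> 0.82
    dict(name="mild_cdp_error_during_pct", kind="err", inputs=(1.38, 1.56),
         printed=13.0, decimals=0),
    dict(name="mild_cdp_error_full_pct", kind="err", inputs=(1.38, 1.62),
         printed=17.4, decimals=1),
    dict(name="mild_ffr_error_pct", kind="err", inputs=(0.83, 0.82),
         printed=1.2, decimals=1),
    # moderate lesion table: CDP 5.31 -> 7.2 / 6.48, FFR 0.43 -> 0.33
    dict(name="moderate_cdp_error_during_pct", kind="err", inputs=(5.31, 7.2),
         printed=35.6, decimals=1),
    dict(name="moderate_cdp_error_full_pct", kind="err", inputs=(5.31, 6.48),
         printed=22.0, decimals=0),
    dict(name="moderate_ffr_error_pct", kind="err", inputs=(0.43, 0.33),
         printed=23.2, decimals=1),
    # headline error statements (two decimal places)
    dict(name="headline_ffr_error_pct", kind="err", inputs=(0.43, 0.33),
         printed=23.26, decimals=2),
    dict(name="headline_cdp_error_pct", kind="err", inputs=(5.31, 7.2),
         printed=35.6, decimals=1),
    # flow-ratio identities from the stated % reductions vs healthy
    dict(name="mild_flow_ratio", kind="ratio", inputs=(16.79,),
         printed=0.83, decimals=2),
    dict(name="moderate_flow_ratio", kind="ratio", inputs=(55.45,),
         printed=0.44, decimals=2),
    dict(name="severe_flow_ratio", kind="ratio", inputs=(92.18,),
         printed=0.078, decimals=3),
    # severe case: 92.18% reduction, then a further 43.37% with the wire
    dict(name="severe_total_reduction_pct", kind="compose",
         inputs=(92.18, 43.37), printed=95.57, decimals=2),
    # severe throat: 0.159 mm^2 circular section -> 0.45 mm hydraulic diameter
    dict(name="severe_throat_diameter_mm", kind="circle_d", inputs=(0.159,),
         printed=0.45, decimals=2),
]

_KIND_FN = {
    "err": lambda a, b: percent_error(a, b),
    "ratio": lambda r: _ratio_from_reduction(r),
    "compose": lambda a, b: _compose_reduction(a, b),
    "circle_d": lambda a: _circle_diameter_mm_from_area(a),
}


def verify_reference_arithmetic() -> pd.DataFrame:
    """Recompute every derived reference cell from its printed inputs.

    Returns a frame with columns (check, computed, printed, decimals,
    match); mismatches are reported, never raised.
    """
    rows = []
    for chk in _REFERENCE_CHECKS:
        computed = _KIND_FN[chk["kind"]](*chk["inputs"])
        tol = 10.0 ** (-chk["decimals"])
        rows.append({
            "check": chk["name"],
            "computed": computed,
            "printed": chk["printed"],
            "decimals": chk["decimals"],
            "match": bool(abs(computed - chk["printed"]) < tol),
        })
    return pd.DataFrame(rows)
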