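"""High-level drivers: one knife setting -> converged fields -> report."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

from .config import RunConfig
from .empirical import make_source_spec
from .exposure import ExposureReport, build_report, fit_H_smoke_curve
from .scene import Mesh
from .solver import FieldState, solve_steady

__all__ = ["CaseResult", "run_case", "run_sweep"]

log = logging.getLogger("theatresmoke")


@dataclass
class CaseResult:
    tip_temp: float
    state: FieldState
    report: ExposureReport


def run_case(config: RunConfig, tip_temp: float,
             mesh: Mesh | None = None) -> CaseResult:
    """Simulate one tip-temperature case end to end.

    Builds the mesh (unless given), assembles the smoke source from the
    calibration polynomials at the published power for this temperature,
    runs the steady buoyant solve and assembles the exposure report.
    """
    mesh = mesh or config.build_mesh()
    spec = make_source_spec(tip_temp, config.calibration, config.composition,
                            position=config.scene.incision_point)
    log.info("case %.0f degC: power %.0f W, waste gas %.3e m3/s",
             tip_temp, spec.power, spec.volume_flow)
    state = solve_steady(mesh, config.boundary, spec, config.settings,
                         config.constants, config.gas)
    log.info("case %.0f degC: converged=%s after %d iterations",
             tip_temp, state.converged,
             len(next(iter(state.residual_history.values()), [])))
    report = build_report(state, tip_temp, thresholds=config.thresholds)
    return CaseResult(tip_temp=tip_temp, state=state, report=report)


def run_sweep(config: RunConfig, tip_temps=None, out_dir=None,
              resume: bool = True) -> dict:
    """Run the canonical temperature sweep and fit H_smoke(T).

    With ``out_dir`` set, per-case reports are written as JSON and cases
    whose report file already exists are skipped on rerun (resumable).
    Returns ``{"cases": {T: report-dict}, "h_smoke_fit": ... or None}``.
    """
    temps = tuple(tip_temps if tip_temps is not None else config.tip_temps)
    mesh = config.build_mesh()
    reports: dict[float, dict] = {}
    for t in temps:
        path = os.path.join(out_dir, f"report_T{int(t)}.json") if out_dir else None
        if path and resume and os.path.exists(path):
            with open(path) as fh:
                reports[t] = json.load(fh)
            log.info("case %.0f degC: found existing report, skipping", t)
            continue
        result = run_case(config, t, mesh=mesh)
        if path:
            os.makedirs(out_dir, exist_ok=True)
            result.report.to_json(path)
        reports[t] = json.loads(result.report.to_json())
    points = [(t, r["h_smoke"]) for t, r in reports.items()
              if r["h_smoke_status"] != "undefined"]
    fit = None
    if len({t for t, _ in points}) >= 3:
        fit = fit_H_smoke_curve(points)
    out = {"cases": reports,
           "h_smoke": {t: r["h_smoke"] for t, r in reports.items()},
           "h_smoke_fit": None if fit is None else
           {"coeffs": list(fit.coeffs), "residuals": fit.residuals}}
    if out_dir:
        with open(os.path.join(out_dir, "sweep_summary.json"), "w") as fh:
            json.dump(out, fh, indent=2)
    return out
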