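"""Case and sweep drivers: mesh -> flow -> drug transport -> metrics.

``run_case`` executes the full pipeline for one Reynolds number and returns
a flat summary row (plus the field objects); ``run_sweep`` repeats it over
the Reynolds list, warm-starting each flow solve from the previous case,
and attaches trend diagnostics (monotonicity of the low-WSS fraction and of
the wall-line concentration mean).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dean_secondary import classify_dean_regime, dean_number
from .drug_transport import drug_flux_balance, solve_drug
from .flow_solver import (FlowField, InletSpec, SolverError, solve_flow,
                          velocity_for_reynolds)
from .geometry import build_geometry
from .metrics import (LINE_IDS, compute_wss, concentration_ratios,
                      line_profile, low_wss_fraction, segment_stats)
from .vtkio import write_mesh_vtk

log = logging.getLogger("stentflow")

__all__ = ["CaseResult", "SweepResult", "run_case", "run_sweep"]


@dataclass
class CaseResult:
    """Summary of one Reynolds case; ``row`` is the flat machine-readable
    record, the field objects allow further analysis."""

    Re: float
    row: dict
    flow: FlowField | None = None
    concentration: object = None
    wss: object = None
    profiles: dict = field(default_factory=dict)


@dataclass
class SweepResult:
    table: pd.DataFrame
    diagnostics: dict
    cases: list[CaseResult]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_case(config: RunConfig, Re: float, out_dir: str | Path | None = None,
             initial: FlowField | None = None, mesh=None) -> CaseResult:
    """Run one Reynolds case; optionally write VTK/CSV/JSON outputs."""
    g = config.geometry
    v = velocity_for_reynolds(config.fluid, Re, g.lumen_diameter)
    if mesh is None:
        log.info("building mesh at %.3g cells/mm", config.resolution)
        mesh = build_geometry(g, resolution=config.resolution)
    Dn = dean_number(Re, g.lumen_diameter / 2, g.bend_radius) if g.bend_angle > 0 else 0.0
    regime = classify_dean_regime(Dn)

    log.info("Re=%g: solving flow (v=%.4g m/s)", Re, v)
    inlet = InletSpec(v_char=v, lumen_half_width=g.lumen_diameter / 2)
    flow = solve_flow(mesh, config.fluid, inlet, config.solver, initial=initial)
    log.info("Re=%g: flow converged in %d iterations", Re, len(flow.history))

    wss = compute_wss(flow, mesh, config.fluid)
    low = low_wss_fraction(wss, config.wss_threshold,
                           restrict_to_stent=config.restrict_low_wss_to_stent)

    log.info("Re=%g: solving drug transport", Re)
    conc = solve_drug(mesh, flow, config.transport, config.solver)
    balance = drug_flux_balance(conc, mesh, flow, config.transport, config.solver)

    profiles = {lid: line_profile(conc, mesh, lid, offset=config.line_offset)
                for lid in LINE_IDS}
    ratios = concentration_ratios(profiles)
    segs = {lid: segment_stats(profiles[lid], mesh.stent_span)
            for lid in ("B_inner", "B_outer")}

    # peak velocity magnitude on the mid-bend cross-section
    i_mid = int(np.argmin(np.abs(mesh.s_c - 0.5 * sum(mesh.bend_span))))
    speed = np.hypot(flow.u_cell[i_mid], flow.v_cell[i_mid])
    peak_mid = float(speed[mesh.fluid[i_mid]].max())

    row = {
        "Re": Re, "v_char": v, "Dn": Dn, "regime": regime,
        "low_wss_total": low.total, "low_wss_inner": low.inner,
        "low_wss_outer": low.outer,
        "peak_midbend_velocity": peak_mid,
        "flux_residual": balance.residual,
        "b_mean_pooled": float(np.concatenate(
            [profiles["B_inner"].concentration,
             profiles["B_outer"].concentration]).mean()),
        "peak_ratio_A": ratios.peak_ratio_A, "mean_ratio_A": ratios.mean_ratio_A,
        "peak_ratio_B": ratios.peak_ratio_B, "mean_ratio_B": ratios.mean_ratio_B,
        "config_hash": config.config_hash, "version": __version__,
    }
    for lid, p in profiles.items():
        row[f"{lid}_mean"] = p.mean
        row[f"{lid}_peak"] = p.peak
    for lid, st in segs.items():
        for seg, val in st.means.items():
            row[f"{lid}_{seg}_mean"] = val

    case = CaseResult(Re=Re, row=row, flow=flow)
    case.concentration = conc
    case.wss = wss
    case.profiles = profiles

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"re{Re:g}"
        write_mesh_vtk(out / f"{tag}.vtk", mesh, {
            "u": flow.u_cell, "v": flow.v_cell, "p": flow.p,
            "concentration": conc.phi,
        })
        pd.DataFrame(wss.to_table()).to_csv(out / f"{tag}_wss.csv", index=False)
        prof_tab = pd.concat([
            pd.DataFrame({"line": lid, "s": p.s, "concentration": p.concentration})
            for lid, p in profiles.items()])
        prof_tab.to_csv(out / f"{tag}_lines.csv", index=False)
        (out / f"{tag}_summary.json").write_text(json.dumps(row, indent=2))
    return case


def run_sweep(config: RunConfig, reynolds: list[float] | None = None,
              out_dir: str | Path | None = None) -> SweepResult:
    """Run the Reynolds sweep; per-case failures are recorded, not raised."""
    re_list = list(reynolds if reynolds is not None else config.reynolds_numbers)
    mesh = build_geometry(config.geometry, resolution=config.resolution) \
        if re_list else None
    rows, cases = [], []
    prev_flow = None
    for Re in re_list:
        try:
            case = run_case(config, Re, out_dir=out_dir,
                            initial=prev_flow, mesh=mesh)
            prev_flow = case.flow
            rows.append(case.row)
            cases.append(case)
        except (SolverError, ValueError) as exc:   # keep sweeping
            log.error("Re=%g failed: %s", Re, exc)
            rows.append({"Re": Re, "error": str(exc),
                         "config_hash": config.config_hash,
                         "version": __version__})
    table = pd.DataFrame(rows)
    diagnostics = {}
    ok = table[table["error"].isna()] if "error" in table.columns else table
    if len(ok) >= 2:
        lw = ok["low_wss_total"].to_numpy()
        bm = ok["b_mean_pooled"].to_numpy()
        pk = ok["peak_midbend_velocity"].to_numpy()
        re_arr = ok["Re"].to_numpy()
        diagnostics["low_wss_non_increasing"] = bool(np.all(np.diff(lw) <= 1e-12))
        diagnostics["b_mean_non_increasing"] = bool(np.all(np.diff(bm) <= 1e-12))
        if len(ok) >= 3:
            fit = np.polyfit(re_arr, pk, 1)
            resid = pk - np.polyval(fit, re_arr)
            ss = 1 - resid @ resid / ((pk - pk.mean()) @ (pk - pk.mean()))
            diagnostics["peak_velocity_linear_r2"] = float(ss)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep.csv", index=False)
        (out / "sweep_diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    return SweepResult(table=table, diagnostics=diagnostics, cases=cases)
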