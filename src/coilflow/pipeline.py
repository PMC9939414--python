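"""Study orchestration: the HCT x porosity sweep, grid convergence, writers.

The default study runs six conditions on the shared bilobed geometry and
waveform — hematocrit 0.35 and 0.45, each uncoiled and with coil porosities
0.89 and 0.79 — computes per-condition index reports, tabulates all pairwise
contrasts, and writes a deterministic bundle (JSON reports, CSV tables, VTK
snapshots).  Two runs of the same configuration produce byte-identical
summaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import AneurysmGeometry, GeometryParams, build_geometry, coil_mask
from .indices import (
    PHASE_NAMES,
    ComparisonReport,
    IndexReport,
    compare_conditions,
    export_wall_loads,
    osi,
    phase_metrics,
    tawss,
)
from .io import config_to_yaml, load_json, save_json, write_vtk_structured_points, write_waveform_csv
from .rheology import RheologyParams
from .solver import CoilModel, RunResult, SolverConfig, run_cycles, run_to_steady
from .waveform import Waveform, synth_waveform

__all__ = [
    "Condition",
    "WaveformParams",
    "StudyConfig",
    "StudyResult",
    "default_study_config",
    "run_study",
    "grid_convergence",
    "write_bundle",
    "read_bundle_reports",
]


@dataclass(frozen=True)
class Condition:
    label: str
    H: float
    porosity: float | None = None


@dataclass(frozen=True)
class WaveformParams:
    period: float = 0.8
    u_dia: float = 0.15
    u_peak: float = 0.55
    systole_fraction: float = 0.35
    n_samples: int = 256

    def build(self) -> Waveform:
        return synth_waveform(**dataclasses.asdict(self))


def _default_conditions() -> list:
    return [
        Condition("hct35_uncoiled", 0.35, None),
        Condition("hct45_uncoiled", 0.45, None),
        Condition("hct35_phi089", 0.35, 0.89),
        Condition("hct35_phi079", 0.35, 0.79),
        Condition("hct45_phi089", 0.45, 0.89),
        Condition("hct45_phi079", 0.45, 0.79),
    ]


@dataclass(frozen=True)
class StudyConfig:
    """Full study description; serialisable to/from YAML."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    conditions: list = field(default_factory=_default_conditions)
    eta: float = 0.035
    m: float = 100.0
    rho: float = 1060.0
    wire_diameter: float = 2.5e-4
    coil_fill_fraction: float = 1.0
    # multiples of 13 keep the parent-wall line y = W grid-aligned across
    # refinement levels (avoids O(1-cell) wall re-alignment noise)
    resolutions: list = field(default_factory=lambda: [52, 65, 91, 117])

    def validate(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        self.geometry.validate()
        self.solver.validate()

    def rheology_for(self, cond: Condition) -> RheologyParams:
        return RheologyParams(H=cond.H, eta=self.eta, m=self.m, rho=self.rho)


def default_study_config(ny: int = 96, **overrides) -> StudyConfig:
    """The default six-condition study at a ny x 2*ny resolution.

    The 13 mm domain height is fixed; the grid refines with ``ny``.
    """
    height = 13.0e-3
    geo = GeometryParams(grid_nx=2 * ny, grid_ny=ny, dx=height / ny)
    return StudyConfig(geometry=geo, **overrides)


@dataclass
class StudyResult:
    config: StudyConfig
    geometry: AneurysmGeometry
    waveform: Waveform
    reports: dict            # label -> IndexReport
    comparisons: ComparisonReport | None
    results: dict            # label -> RunResult
    summary: pd.DataFrame


def _summary_table(reports: dict) -> pd.DataFrame:
    """Phases x conditions layout, one block per metric, straight from the
    reports (no recomputation)."""
    labels = list(reports)
    rows = []
    metrics = ("max_wss", "osi_windowed_max", "wall_pressure_max", "neck_avg_velocity")
    for metric in metrics:
        for phase in PHASE_NAMES:
            row = {"metric": metric, "phase": phase}
            for lbl in labels:
                row[lbl] = getattr(reports[lbl], metric)[phase]
            rows.append(row)
    for metric in ("max_osi", "tawss_max", "ke_sac_mean"):
        row = {"metric": metric, "phase": "cycle"}
        for lbl in labels:
            row[lbl] = getattr(reports[lbl], metric)
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig | None = None, progress: bool = False) -> StudyResult:
    """Run every condition on the shared geometry/waveform and compare.

    Deterministic: no randomness anywhere in the pipeline, so repeated runs
    of the same configuration give identical reports.
    """
    config = config or default_study_config()
    config.validate()
    geometry = build_geometry(config.geometry)
    waveform = config.waveform.build()

    reports: dict = {}
    results: dict = {}
    coil_geos: dict = {}
    for cond in config.conditions:
        if progress:
            print(f"[coilflow] condition {cond.label} (H={cond.H}, phi={cond.porosity})")
        rheo = config.rheology_for(cond)
        if cond.porosity is not None:
            if cond.porosity not in coil_geos:
                coil_geos[cond.porosity] = coil_mask(geometry, config.coil_fill_fraction)
            geo_c = coil_geos[cond.porosity]
            coil = CoilModel(porosity=cond.porosity, wire_diameter=config.wire_diameter)
        else:
            geo_c, coil = geometry, None
        res = run_cycles(geo_c, waveform, rheo, coil=coil, config=config.solver,
                         progress=progress)
        series = res.final_cycle_series
        report = phase_metrics(
            series, res.snapshots, waveform.phases, geo_c, rheo,
            label=cond.label, porosity=cond.porosity,
            ke_sac_mean=float(res.ke_sac[-1]),
            cycle_peak_wss=res.cycle_peak_systolic_max_wss(),
        )
        reports[cond.label] = report
        results[cond.label] = res

    comparisons = compare_conditions(reports) if len(reports) >= 2 else None
    return StudyResult(
        config=config,
        geometry=geometry,
        waveform=waveform,
        reports=reports,
        comparisons=comparisons,
        results=results,
        summary=_summary_table(reports),
    )


# ---------------------------------------------------------------------------
# grid convergence


_GRID_LABELS = ["coarse", "medium", "fine", "very fine"]


def grid_convergence(
    config: StudyConfig | None = None,
    resolutions=None,
    H: float = 0.45,
) -> pd.DataFrame:
    """Neck-plane average velocity across grid refinement levels.

    Solves frozen-inflow steady states at the maximum-acceleration and
    peak-systolic inflow levels of the study waveform on each grid (domain
    fixed, dx refined with ny) and reports the neck average velocity.  The
    ``converged`` column flags levels within 1% of the finest grid on both
    inflow levels.
    """
    config = config or default_study_config()
    resolutions = sorted(resolutions or config.resolutions)
    if len(resolutions) < 3:
        raise ValueError("grid convergence needs at least 3 resolutions")
    wf = config.waveform.build()
    u_ma = float(wf.u_at(wf.phases["max_accel"]))
    u_ps = float(wf.u_at(wf.phases["peak_systole"]))
    rheo = RheologyParams(H=H, eta=config.eta, m=config.m, rho=config.rho)
    height = config.geometry.grid_ny * config.geometry.dx

    rows = []
    for ny in resolutions:
        geo = build_geometry(
            dataclasses.replace(config.geometry, grid_nx=2 * ny, grid_ny=ny, dx=height / ny)
        )
        _, v_ma = run_to_steady(geo, rheo, u_ma, config=config.solver)
        _, v_ps = run_to_steady(geo, rheo, u_ps, config=config.solver)
        rows.append({"cells": geo.nx * geo.ny, "ny": ny,
                     "v_neck_max_accel": v_ma, "v_neck_peak_systole": v_ps})
    table = pd.DataFrame(rows).sort_values("cells", ignore_index=True)
    n = len(table)
    labels = _GRID_LABELS[:n] if n <= 4 else [f"level{i}" for i in range(n)]
    table.insert(0, "grid", labels)
    ref_ma = table["v_neck_max_accel"].iloc[-1]
    ref_ps = table["v_neck_peak_systole"].iloc[-1]
    table["converged"] = (
        (np.abs(table["v_neck_max_accel"] - ref_ma) <= 0.01 * abs(ref_ma))
        & (np.abs(table["v_neck_peak_systole"] - ref_ps) <= 0.01 * abs(ref_ps))
    )
    return table


# ---------------------------------------------------------------------------
# bundle writer


def write_bundle(study: StudyResult, outdir, force: bool = False) -> dict:
    """Write the study bundle: JSON reports, CSV tables, VTK snapshots.

    Refuses to write into an existing non-empty directory unless ``force``.
    All outputs are deterministic (no timestamps).
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass force=True (--force) to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"outdir": str(outdir)}

    summary_path = outdir / "study_summary.csv"
    study.summary.to_csv(summary_path, index=False, float_format="%.9e")
    paths["summary"] = str(summary_path)

    write_waveform_csv(outdir / "waveform.csv", study.waveform)
    write_vtk_structured_points(
        outdir / "geometry.vtk",
        study.geometry,
        {"sdf": study.geometry.sdf, "lumen": study.geometry.lumen_mask,
         "coil": study.geometry.coil_mask},
    )

    for label, report in study.reports.items():
        cdir = outdir / label
        cdir.mkdir(exist_ok=True)
        save_json(cdir / "report.json", report.to_dict())
        res = study.results.get(label)
        if res is None:
            continue
        series = res.final_cycle_series
        profile = pd.DataFrame({"s": series.s, "valid": series.valid,
                                "tawss": tawss(series), "osi": osi(series)})
        for name in PHASE_NAMES:
            k = int(np.argmin(np.abs(series.t - study.waveform.phases[name])))
            profile[f"tau_w_{name}"] = series.tau_w[k]
            profile[f"p_w_{name}"] = series.p_w[k]
        profile.to_csv(cdir / "wall_profile.csv", index=False, float_format="%.9e")
        export_wall_loads(series, study.waveform.phases).to_csv(
            cdir / "wall_loads.csv", index=False, float_format="%.9e"
        )
        for name, snap in res.snapshots.items():
            uc, vc = snap.cell_velocity()
            write_vtk_structured_points(
                cdir / f"fields_{name}.vtk",
                res.geometry,
                {"p": snap.p, "mu": snap.mu, "u": uc, "v": vc,
                 "lumen": res.geometry.lumen_mask, "coil": res.geometry.coil_mask},
            )

    if study.comparisons is not None:
        save_json(outdir / "comparisons.json", study.comparisons.to_dict())
        study.comparisons.to_dataframe().to_csv(
            outdir / "comparisons.csv", index=False, float_format="%.9e"
        )

    log = [
        f"coilflow {__version__}",
        f"conditions: {', '.join(study.reports)}",
        "config:",
        config_to_yaml(study.config),
    ]
    (outdir / "run_log.txt").write_text("\n".join(log))
    return paths


def read_bundle_reports(outdir) -> dict:
    """Re-read every per-condition IndexReport from a written bundle."""
    outdir = Path(outdir)
    reports = {}
    for rp in sorted(outdir.glob("*/report.json")):
        d = load_json(rp)
        reports[d["label"]] = IndexReport.from_dict(d)
    return reports
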