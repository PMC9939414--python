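"""Writers and readers: legacy VTK, CSV/JSON reports, YAML run configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

SCHEMA_VERSION = 1


def write_vtk_structured_points(path, geometry, cell_fields: dict) -> None:
    """Write cell data on the uniform grid as a legacy ASCII VTK file.

    ``cell_fields`` maps field names to (nx, ny) arrays; boolean masks are
    written as 0/1 integers.  The file uses STRUCTURED_POINTS with CELL_DATA,
    which every VTK-aware viewer reads without extra dependencies.
    """
    nx, ny, dx = geometry.nx, geometry.ny, geometry.dx
    lines = [
        "# vtk DataFile Version 3.0",
        "coilflow field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        "ORIGIN 0.0 0.0 0.0",
        f"SPACING {dx:.9e} {dx:.9e} {dx:.9e}",
        f"CELL_DATA {nx * ny}",
    ]
    for name, f in cell_fields.items():
        f = np.asarray(f)
        if f.dtype == bool:
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            vals = f.astype(int)
            fmt = "{:d}"
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            vals = f.astype(float)
            fmt = "{:.9e}"
        # VTK cell data is x-fastest: iterate j outer, i inner
        lines.extend(
            " ".join(fmt.format(v) for v in vals[:, j]) for j in range(ny)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_waveform_csv(path, waveform) -> None:
    """Two-column CSV (time, inlet mean velocity)."""
    with open(path, "w") as fh:
        fh.write("time_s,u_mean_m_per_s\n")
        for t, u in zip(waveform.times, waveform.u_mean):
            fh.write(f"{t:.9e},{u:.9e}\n")


def save_json(path, payload: dict) -> None:
    payload = dict(payload)
    payload.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def config_to_yaml(config) -> str:
    """Serialise a StudyConfig (nested dataclasses) to YAML."""

    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [conv(x) for x in obj]
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    return yaml.safe_dump(conv(config), sort_keys=False)


def config_from_yaml(text: str):
    """Parse a YAML study configuration (sections mirror StudyConfig)."""
    from .geometry import GeometryParams
    from .pipeline import Condition, StudyConfig, WaveformParams
    from .solver import SolverConfig

    raw = yaml.safe_load(text) or {}
    kw = {}
    if "geometry" in raw:
        kw["geometry"] = GeometryParams(**raw["geometry"])
    if "waveform" in raw:
        kw["waveform"] = WaveformParams(**raw["waveform"])
    if "solver" in raw:
        kw["solver"] = SolverConfig(**raw["solver"])
    if "conditions" in raw:
        kw["conditions"] = [Condition(**c) for c in raw["conditions"]]
    for key in ("eta", "m", "rho", "wire_diameter", "coil_fill_fraction", "resolutions"):
        if key in raw:
            kw[key] = raw[key]
    return StudyConfig(**kw)
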