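"""Exporters and run manifests.

CSV files carry 6 significant digits by default; field frames on plane or
volume grids can additionally be written as legacy-ASCII VTK structured
points (readable by ParaView and friends).  Every CLI run writes a JSON
manifest with the full parameter set and seeds so that a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import MCStats, SpectrumCurve
from .field import FieldFrame

FLOAT_FORMAT = "%.6g"


def write_dipole_csv(model, path: str | Path) -> Path:
    """Write the full dipole table (positions, axes, kinds, xi) as CSV."""
    path = Path(path)
    model.dipole_table().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def model_summary(model) -> dict:
    """JSON-serialisable summary of a spindle model (metadata + per-MT rows)."""
    return {
        "seed": model.seed,
        "cell_nm": {"a": model.cell.a, "b": model.cell.b,
                    "R_equiv": model.cell.R_equiv, "c": model.cell.c,
                    "rho": model.cell.rho},
        "scenario": model.params.scenario,
        "mtoc_centers_nm": model.mtoc_centers.tolist(),
        "counts": model.count_by_class(),
        "microtubules": [
            {"index": mt.index, "class": mt.mt_class,
             "boundary_condition": mt.boundary_condition.value,
             "length_nm": mt.length,
             "principal_frequency_hz": mt.principal_frequency,
             "n_rings": len(mt.rings), "phase_rad": mt.phase}
            for mt in model.microtubules],
    }


def write_model_json(model, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model_summary(model), indent=1))
    return path


def write_spectrum_csv(spectrum: SpectrumCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"frequency_hz": spectrum.frequency,
                  "amplitude": spectrum.amplitude}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_field_csv(frame: FieldFrame, path: str | Path) -> Path:
    """Field frame as CSV point probes (position, E vector, |E|, clamps)."""
    path = Path(path)
    g = frame.grid
    df = pd.DataFrame({
        "x_nm": g.points[:, 0], "y_nm": g.points[:, 1], "z_nm": g.points[:, 2],
        "Ex_v_m": frame.E_real[:, 0], "Ey_v_m": frame.E_real[:, 1],
        "Ez_v_m": frame.E_real[:, 2], "mag_v_m": frame.magnitude,
        "clamped": frame.clamped_mask.astype(int),
    })
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_mc_csv(stats: MCStats, path: str | Path) -> Path:
    path = Path(path)
    g = stats.grid
    pd.DataFrame({
        "x_nm": g.points[:, 0], "y_nm": g.points[:, 1], "z_nm": g.points[:, 2],
        "max_v_m": stats.max, "mean_v_m": stats.mean, "min_v_m": stats.min,
    }).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_vtk(frame: FieldFrame, path: str | Path,
              title: str = "spindle electric field") -> Path:
    """Legacy-ASCII VTK structured points with |E| scalars and E vectors.

    Requires a plane or volume grid (regular spacing).
    """
    g = frame.grid
    if g.kind not in ("plane", "volume") or not g.voxel_edge:
        raise ValueError("VTK export requires a regular plane or volume grid")
    if g.kind == "plane":
        free = [i for i in range(3) if i != g.plane_axis]
        dims = [1, 1, 1]
        dims[free[0]], dims[free[1]] = g.shape
    else:
        dims = list(g.shape)
    origin = g.points.min(axis=0)
    sp = g.voxel_edge
    # VTK x-fastest ordering; our meshgrid ravels last axis fastest on 'ij',
    # so reorder point data accordingly
    n = len(g.points)
    order = np.lexsort((g.points[:, 0], g.points[:, 1], g.points[:, 2]))
    mag = frame.magnitude[order]
    vec = frame.E_real[order]
    lines = [
        "# vtk DataFile Version 3.0", title, "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        f"ORIGIN {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}",
        f"SPACING {sp:.6g} {sp:.6g} {sp:.6g}",
        f"POINT_DATA {n}",
        "SCALARS E_magnitude float 1", "LOOKUP_TABLE default",
    ]
    lines += [f"{v:.6g}" for v in mag]
    lines.append("VECTORS E_field float")
    lines += [f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in vec]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest(path: str | Path, config: dict, seed: int,
                   extras: dict | None = None) -> Path:
    """JSON manifest of one run: full config, seed and derived quantities."""
    path = Path(path)
    payload = {"config": config, "seed": seed}
    payload.update(extras or {})
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)!r}")
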