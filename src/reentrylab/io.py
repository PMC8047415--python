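"""Readers/writers: HDF5 Vm movies, legacy-VTK spatial fields, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import TissueGeometry

__all__ = [
    "write_movie",
    "read_movie",
    "write_vtk_geometry",
    "write_vtk_frame",
    "write_activation_csv",
    "write_geometry_sidecar",
]

MOVIE_FORMAT_VERSION = 1


def write_movie(
    path: str | Path,
    vm: np.ndarray,
    times: np.ndarray,
    dt: float,
    h_mm: float,
    attrs: dict | None = None,
) -> None:
    """Lossless Vm-movie container (HDF5): (frames, ny, nx) plus metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MOVIE_FORMAT_VERSION
        f.attrs["dt_ms"] = dt
        f.attrs["h_mm"] = h_mm
        f.attrs["units_vm"] = "mV"
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        f.create_dataset("vm", data=vm, compression="gzip", compression_opts=1)
        f.create_dataset("times_ms", data=np.asarray(times, float))


def read_movie(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a Vm movie; returns ``(vm, times_ms, attrs)``."""
    with h5py.File(path, "r") as f:
        if "vm" not in f or "times_ms" not in f:
            raise ValueError(f"{path}: not a Vm-movie container (missing datasets)")
        version = int(f.attrs.get("format_version", -1))
        if version != MOVIE_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported movie format version {version}"
            )
        vm = f["vm"][...]
        times = f["times_ms"][...]
        attrs = dict(f.attrs)
    if vm.shape[0] != times.shape[0]:
        raise ValueError(f"{path}: truncated movie (frames != times)")
    return vm, times, attrs


# ---------------------------------------------------------------------------
# legacy VTK (ASCII structured points; fine for rectangular grids)


def _vtk_header(title: str, nx: int, ny: int, h: float) -> list[str]:
    return [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {h} {h} 1",
    ]


def write_vtk_geometry(path: str | Path, geom: TissueGeometry) -> None:
    """Geometry as legacy-VTK structured points with cell data
    (region label, conductivity) and a JSON sidecar for regions/segments."""
    ny, nx = geom.shape
    lines = _vtk_header("tissue geometry", nx, ny, geom.h)
    n_cells = geom.labels.size
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS region_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(v)) for v in geom.labels.ravel())
    lines.append("SCALARS sigma_s_per_m float 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.8g}" for v in geom.sigma.ravel())
    Path(path).write_text("\n".join(lines) + "\n")


def write_geometry_sidecar(path: str | Path, geom: TissueGeometry, **meta) -> None:
    """JSON sidecar: named regions and segments as element index lists."""
    payload = {
        "kind": geom.kind,
        "h_mm": geom.h,
        "shape_nodes": list(geom.shape),
        "named_regions": {
            k: np.flatnonzero(v.ravel()).tolist()
            for k, v in geom.named_regions.items()
        },
        "segments": geom.segments.ravel().tolist(),
        **meta,
    }
    Path(path).write_text(json.dumps(payload))


def write_vtk_frame(
    path: str | Path, field: np.ndarray, h: float, name: str = "vm_mv"
) -> None:
    """One nodal scalar field (e.g. a Vm snapshot or activation map)."""
    ny, nx = field.shape
    lines = _vtk_header(name, nx, ny, h)
    lines.append(f"POINT_DATA {field.size}")
    lines.append(f"SCALARS {name} float 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.6g}" for v in np.nan_to_num(field, nan=-1.0).ravel())
    Path(path).write_text("\n".join(lines) + "\n")


def write_activation_csv(path: str | Path, at: np.ndarray, h: float) -> None:
    """Activation-time map as CSV rows (x_mm, y_mm, t_ms; NaN = never)."""
    ny, nx = at.shape
    with open(path, "w") as f:
        f.write("x_mm,y_mm,activation_ms\n")
        for i in range(ny):
            for j in range(nx):
                f.write(f"{j * h},{i * h},{at[i, j]}\n")
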