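"""Minimal legacy ASCII VTK PolyData export for wall meshes and maps.

Only what downstream visualization (ParaView and friends) needs: a point
cloud with per-point scalars and vectors.  Writing the legacy ASCII
format directly avoids a heavyweight VTK dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_polydata"]


def write_polydata(
    path: str | Path,
    points_m: np.ndarray,
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
    title: str = "aortaflow",
) -> Path:
    """Write points (given in metres, stored in mm) with point data."""
    path = Path(path)
    pts = np.asarray(points_m, dtype=float) * 1000.0
    n = len(pts)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}" for p in pts]
    lines.append(f"VERTICES {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    if scalars or vectors:
        lines.append(f"POINT_DATA {n}")
    for name, vals in (scalars or {}).items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) != n:
            raise ValueError(f"scalar '{name}' length {len(vals)} != {n} points")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.nan_to_num(vals, nan=-1.0)]
    for name, vals in (vectors or {}).items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (n, 3):
            raise ValueError(f"vector '{name}' shape {vals.shape} != ({n}, 3)")
        lines.append(f"VECTORS {name} float")
        lines += [
            f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in np.nan_to_num(vals, nan=0.0)
        ]
    path.write_text("\n".join(lines) + "\n")
    return path
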