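"""Containers and I/O for 4D phase-contrast ("4D flow") MRI datasets.

A 4D flow acquisition yields a three-component velocity field sampled on a
regular 3D grid over the cardiac cycle, together with a signal magnitude
image.  This module holds the in-memory model (:class:`VelocityField`,
:class:`Segmentation`), the derived scalar images used for lumen
segmentation (the PC-MRA), peak-systole detection, and NIfTI + JSON-sidecar
round-trip I/O.

Conventions
-----------
* Velocities are stored in m/s; voxel spacing in mm.  Spacing is converted
  to metres only at the point where a spatial derivative or a world
  coordinate is formed, so WSS comes out directly in Pa and PWV in m/s.
* Voxel indexing is 0-based and the grid is axis aligned: the world
  coordinate of voxel ``(i, j, k)`` is ``(i, j, k) * spacing`` (mm).  No
  orientation matrix is carried; phantoms are generated on this grid and
  scanner-frame orientation handling is out of scope.
* Background phase-offset correction is a scanner-side step and is not
  reimplemented here; the synthetic generator can add a constant offset so
  downstream robustness can be probed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VelocityField",
    "Segmentation",
    "compute_pcmra",
    "peak_systole_index",
    "read_dataset",
    "write_dataset",
]

SIDECAR_NAME = "dataset.json"
SIDECAR_KEYS = ("spacing_mm", "dt_ms", "venc_ms")
COMPONENT_FILES = {
    "vx": "velocity_x.nii.gz",
    "vy": "velocity_y.nii.gz",
    "vz": "velocity_z.nii.gz",
    "mag": "magnitude.nii.gz",
}
MASK_FILE = "mask.nii.gz"


@dataclass
class VelocityField:
    """Three-component velocity (m/s) plus magnitude on a 4D grid.

    Arrays are indexed ``[x, y, z, t]`` and share one shape.  ``spacing``
    is the voxel size in mm, ``dt`` the temporal resolution in ms and
    ``venc`` the velocity encoding (m/s, metadata only).
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    mag: np.ndarray
    spacing: np.ndarray
    dt: float
    venc: float = 2.0

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        shapes = {a.shape for a in (self.vx, self.vy, self.vz, self.mag)}
        if len(shapes) != 1:
            raise ValueError(f"velocity/magnitude arrays differ in shape: {shapes}")
        if self.vx.ndim != 4:
            raise ValueError("velocity arrays must be 4D [nx, ny, nz, nt]")
        if self.vx.shape[3] < 1:
            raise ValueError("need at least one timeframe")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values (mm)")
        if self.dt <= 0:
            raise ValueError("dt must be positive (ms)")
        if np.any(self.mag < 0):
            raise ValueError("magnitude image must be non-negative")

    @property
    def nt(self) -> int:
        return self.vx.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vx.shape[:3]

    @property
    def period_s(self) -> float:
        """Duration of the (periodic) cardiac cycle covered by the frames."""
        return self.nt * self.dt / 1000.0

    def speed(self) -> np.ndarray:
        """Per-voxel velocity magnitude ||v||, shape [nx, ny, nz, nt]."""
        return np.sqrt(self.vx**2 + self.vy**2 + self.vz**2)

    def velocity_at(self, frame: int) -> np.ndarray:
        """Velocity vectors at one timeframe, shape [nx, ny, nz, 3]."""
        return np.stack(
            [self.vx[..., frame], self.vy[..., frame], self.vz[..., frame]], axis=-1
        )


@dataclass
class Segmentation:
    """Binary lumen mask on the same spatial grid as its velocity field."""

    mask: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values (mm)")
        if not self.mask.any():
            raise ValueError("segmentation has no foreground voxels")
        closed = ndimage.binary_closing(self.mask)
        # closing with the default structuring element can drop 1-voxel masks
        closed |= self.mask
        _, n_comp = ndimage.label(closed)
        if n_comp != 1:
            raise ValueError(
                f"segmentation must be a single connected component after closing "
                f"(found {n_comp})"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_centers_m(self) -> np.ndarray:
        """World coordinates (m) of the foreground voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.mask)
        return idx * self.spacing / 1000.0


def _check_same_grid(field: VelocityField, seg: Segmentation) -> None:
    if seg.mask.shape != field.grid_shape:
        raise ValueError(
            f"segmentation grid {seg.mask.shape} does not match velocity grid "
            f"{field.grid_shape}"
        )


def compute_pcmra(field: VelocityField) -> np.ndarray:
    """Phase-contrast MR angiogram: time-averaged magnitude x speed.

    Returns a non-negative 3D image; bright where there is both signal and
    flow, which is what the lumen is segmented on.
    """
    return (field.mag * field.speed()).mean(axis=3)


def peak_systole_index(field: VelocityField, seg: Segmentation) -> int:
    """Timeframe with the highest spatially averaged speed inside the lumen.

    Ties are broken toward the earliest frame.
    """
    _check_same_grid(field, seg)
    mean_speed = field.speed()[seg.mask].mean(axis=0)
    return int(np.argmax(mean_speed))


def _affine(spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _save_nifti(path: Path, arr: np.ndarray, spacing: np.ndarray) -> None:
    img = nib.Nifti1Image(arr, _affine(spacing))
    img.header.set_data_dtype(arr.dtype)
    nib.save(img, str(path))


def _load_array(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing dataset file: {path.name}")
    return np.asanyarray(nib.load(str(path)).dataobj)


def write_dataset(path: str | Path, field: VelocityField, seg: Segmentation) -> Path:
    """Write a dataset directory: per-component NIfTI volumes + JSON sidecar."""
    _check_same_grid(field, seg)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for attr, fname in COMPONENT_FILES.items():
        _save_nifti(path / fname, np.asarray(getattr(field, attr), dtype=np.float64),
                    field.spacing)
    _save_nifti(path / MASK_FILE, seg.mask.astype(np.uint8), field.spacing)
    sidecar = {
        "spacing_mm": [float(s) for s in field.spacing],
        "dt_ms": float(field.dt),
        "venc_ms": float(field.venc),
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_dataset(path: str | Path) -> tuple[VelocityField, Segmentation]:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {SIDECAR_NAME} in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in SIDECAR_KEYS:
        if key not in sidecar:
            raise KeyError(f"sidecar {SIDECAR_NAME} is missing required key '{key}'")
    arrays = {attr: _load_array(path / fname) for attr, fname in COMPONENT_FILES.items()}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent component shapes on disk: {shapes}")
    mask = _load_array(path / MASK_FILE).astype(bool)
    spacing = np.asarray(sidecar["spacing_mm"], dtype=float)
    field = VelocityField(
        vx=arrays["vx"], vy=arrays["vy"], vz=arrays["vz"], mag=arrays["mag"],
        spacing=spacing, dt=float(sidecar["dt_ms"]), venc=float(sidecar["venc_ms"]),
    )
    if mask.shape != field.grid_shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match velocity grid {field.grid_shape}"
        )
    return field, Segmentation(mask=mask, spacing=spacing)
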