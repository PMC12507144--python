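"""Normative hemodynamic atlases and abnormality / incidence maps.

A healthy cohort is projected onto one shared aortic geometry; at every
lumen voxel (velocity) and wall point (WSS) the atlas stores the mean
vector, the mean magnitude and the sample SD of the magnitude.  The 95%
normal band is ``mean +/- 1.96 * SD``; a patient location is *elevated*
when its magnitude exceeds the upper bound (one-sided: only "elevated"
maps are clinically reported), and *abnormally directed* when its vector
deviates from the atlas mean vector by more than 120 degrees.  Direction
is not evaluated where either vector is near zero (< 0.01 m/s or
< 0.01 Pa) -- the angle is unstable there.

A patient is flagged per region when at least one of its locations is
abnormal; incidence maps give, per location, the percentage of patients
flagged among those whose geometry covers the location.

Mapping dialect: subjects and patients are brought onto the shared
geometry by (optional) rigid transform plus nearest-neighbour /
trilinear lookup; atlas locations need contributions from at least 80%
of the cohort (and never fewer than 2 subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .flow_dataset import Segmentation, VelocityField, peak_systole_index
from .geometry import REGIONS, RigidTransform, WallMesh
from .wss import WSSField, _sample_velocity

__all__ = [
    "SubjectSample",
    "Atlas",
    "AbnormalityMap",
    "sample_subject",
    "build_atlas",
    "flag_elevated",
    "flag_misdirected",
    "compare_patient",
    "patient_region_flags",
    "incidence_map",
]

VELOCITY_FLOOR = 0.01  # m/s
WSS_FLOOR = 0.01       # Pa
METRICS = (
    "elevated_velocity",
    "elevated_wss",
    "misdirected_velocity",
    "misdirected_wss",
)


@dataclass
class SubjectSample:
    """One subject's peak-systolic vectors on the shared geometry.

    NaN rows mark shared locations the subject's own lumen/wall does not
    cover.
    """

    vel_vec: np.ndarray  # (n_vox, 3) m/s at the shared lumen voxels
    wss_vec: np.ndarray  # (n_pts, 3) Pa at the shared wall points


@dataclass
class Atlas:
    """Voxelwise / pointwise normative statistics on a shared geometry."""

    seg: Segmentation
    mesh: WallMesh
    vel_mean_vec: np.ndarray   # (n_vox, 3)
    vel_mean_mag: np.ndarray   # (n_vox,)
    vel_sd_mag: np.ndarray     # (n_vox,)
    wss_mean_vec: np.ndarray   # (n_pts, 3)
    wss_mean_mag: np.ndarray   # (n_pts,)
    wss_sd_mag: np.ndarray     # (n_pts,)
    n_subjects: int
    vel_n: np.ndarray          # contributing subjects per voxel
    wss_n: np.ndarray          # contributing subjects per wall point

    @property
    def lumen_indices(self) -> np.ndarray:
        return np.argwhere(self.seg.mask)


@dataclass
class AbnormalityMap:
    """Boolean abnormality flags on the shared geometry for one patient.

    ``evaluated_*`` marks locations where both the patient and the atlas
    were defined; flags are only meaningful there.
    """

    elevated_velocity: np.ndarray
    misdirected_velocity: np.ndarray
    elevated_wss: np.ndarray
    misdirected_wss: np.ndarray
    evaluated_velocity: np.ndarray
    evaluated_wss: np.ndarray

    def flags(self, metric: str) -> np.ndarray:
        return getattr(self, metric)

    def evaluated(self, metric: str) -> np.ndarray:
        return self.evaluated_velocity if metric.endswith("velocity") else self.evaluated_wss


def sample_subject(
    field: VelocityField,
    seg: Segmentation,
    wss: WSSField,
    mesh: WallMesh,
    shared_seg: Segmentation,
    shared_mesh: WallMesh,
    transform: RigidTransform | None = None,
    frame: int | None = None,
    wall_match_tol_factor: float = 2.0,
) -> SubjectSample:
    """Project one subject's peak-systolic hemodynamics onto the shared geometry.

    Velocity is sampled trilinearly at the shared lumen voxel centers
    (after mapping them into the subject's frame when a rigid transform
    is given); coverage requires the mapped point to fall inside the
    subject's own lumen.  WSS is matched to the nearest subject wall
    point within ``wall_match_tol_factor`` voxels.
    """
    if frame is None:
        frame = peak_systole_index(field, seg)
    vox_m = shared_seg.voxel_centers_m()
    pts_m = shared_mesh.points
    if transform is not None:
        vox_m = transform.apply_points_mm(vox_m * 1000.0) / 1000.0
        pts_m = transform.apply_points_mm(pts_m * 1000.0) / 1000.0

    vel = _sample_velocity(field, frame, vox_m)
    vox_idx = np.rint(vox_m * 1000.0 / seg.spacing).astype(int)
    shape = np.asarray(seg.mask.shape)
    inb = np.all((vox_idx >= 0) & (vox_idx < shape), axis=1)
    covered = np.zeros(len(vox_m), dtype=bool)
    covered[inb] = seg.mask[tuple(vox_idx[inb].T)]
    vel[~covered] = np.nan

    tol = wall_match_tol_factor * float(seg.spacing.mean()) / 1000.0
    tree = cKDTree(mesh.points)
    dist, widx = tree.query(pts_m, workers=-1)
    wssv = np.full((len(pts_m), 3), np.nan)
    ok = (dist <= tol) & wss.valid[widx]
    wssv[ok] = wss.vectors[widx[ok]]
    return SubjectSample(vel_vec=vel, wss_vec=wssv)


def _stats(vectors: np.ndarray, min_n: int) -> tuple[np.ndarray, ...]:
    """Mean vector, mean magnitude, SD of magnitude, n, over subjects (axis 0)."""
    finite = np.isfinite(vectors).all(axis=2)
    n = finite.sum(axis=0)
    defined = n >= min_n
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty/short slices
        mean_vec = np.nanmean(vectors, axis=0)
        mags = np.linalg.norm(vectors, axis=2)
        mean_mag = np.nanmean(mags, axis=0)
        sd_mag = np.nanstd(mags, axis=0, ddof=1)
    mean_vec[~defined] = np.nan
    mean_mag[~defined] = np.nan
    sd_mag[~defined] = np.nan
    return mean_vec, mean_mag, sd_mag, n


def build_atlas(
    samples: list[SubjectSample],
    shared_seg: Segmentation,
    shared_mesh: WallMesh,
    min_coverage: float = 0.8,
) -> Atlas:
    """Voxelwise/pointwise mean vectors and magnitude SDs over a cohort.

    Locations contributed by fewer than ``min_coverage`` of the cohort
    (never fewer than 2 subjects) are left undefined (NaN).
    """
    if len(samples) < 2:
        raise ValueError("an atlas needs at least 2 subjects")
    ns = len(samples)
    min_n = max(2, int(np.ceil(min_coverage * ns)))
    vel = np.stack([s.vel_vec for s in samples])
    wssv = np.stack([s.wss_vec for s in samples])
    v_mean, v_mag, v_sd, v_n = _stats(vel, min_n)
    w_mean, w_mag, w_sd, w_n = _stats(wssv, min_n)
    return Atlas(
        seg=shared_seg, mesh=shared_mesh,
        vel_mean_vec=v_mean, vel_mean_mag=v_mag, vel_sd_mag=v_sd,
        wss_mean_vec=w_mean, wss_mean_mag=w_mag, wss_sd_mag=w_sd,
        n_subjects=ns, vel_n=v_n, wss_n=w_n,
    )


def flag_elevated(
    values: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    z: float = 1.96,
) -> tuple[np.ndarray, np.ndarray]:
    """Elevated = strictly above the upper 95% bound ``mean + z * SD``.

    One-sided by design: decreased values are not flagged.  Returns
    (flags, evaluated); locations undefined on either side are not
    flagged and count as uncovered.
    """
    evaluated = np.isfinite(values) & np.isfinite(mean) & np.isfinite(sd)
    flags = np.zeros_like(evaluated)
    flags[evaluated] = values[evaluated] > mean[evaluated] + z * sd[evaluated]
    return flags, evaluated


def flag_misdirected(
    vectors: np.ndarray,
    ref_vectors: np.ndarray,
    angle_deg: float = 120.0,
    floor: float = VELOCITY_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Misdirected = angle(patient vector, atlas mean vector) > threshold.

    Locations where either vector's magnitude is below ``floor`` are not
    evaluated (arccos is unstable near zero vectors).
    """
    vmag = np.linalg.norm(vectors, axis=1)
    rmag = np.linalg.norm(ref_vectors, axis=1)
    finite = np.isfinite(vmag) & np.isfinite(rmag)
    evaluated = finite & (vmag >= floor) & (rmag >= floor)
    flags = np.zeros(len(vectors), dtype=bool)
    if evaluated.any():
        cosang = np.einsum("ij,ij->i", vectors[evaluated], ref_vectors[evaluated])
        cosang /= vmag[evaluated] * rmag[evaluated]
        flags[evaluated] = cosang < np.cos(np.radians(angle_deg))
    return flags, evaluated


def compare_patient(
    atlas: Atlas,
    patient: SubjectSample,
    z: float = 1.96,
    angle_deg: float = 120.0,
) -> AbnormalityMap:
    """All four abnormality maps for one patient on the shared geometry."""
    vmag = np.linalg.norm(patient.vel_vec, axis=1)
    wmag = np.linalg.norm(patient.wss_vec, axis=1)
    ev, eval_v = flag_elevated(vmag, atlas.vel_mean_mag, atlas.vel_sd_mag, z=z)
    ew, eval_w = flag_elevated(wmag, atlas.wss_mean_mag, atlas.wss_sd_mag, z=z)
    mv, _ = flag_misdirected(
        patient.vel_vec, atlas.vel_mean_vec, angle_deg=angle_deg, floor=VELOCITY_FLOOR
    )
    mw, _ = flag_misdirected(
        patient.wss_vec, atlas.wss_mean_vec, angle_deg=angle_deg, floor=WSS_FLOOR
    )
    return AbnormalityMap(
        elevated_velocity=ev, misdirected_velocity=mv,
        elevated_wss=ew, misdirected_wss=mw,
        evaluated_velocity=eval_v, evaluated_wss=eval_w,
    )


def patient_region_flags(
    abmap: AbnormalityMap,
    shared_mesh: WallMesh,
    voxel_regions: np.ndarray,
) -> pd.DataFrame:
    """Per-region booleans: abnormal if at least one location is flagged.

    ``voxel_regions`` are the region labels of the shared lumen voxels
    (see :func:`aortaflow.geometry.label_points`); wall metrics use the
    shared mesh's own labels.  Empty regions come back as NA.
    """
    rows = {}
    wall_regions = np.asarray(shared_mesh.region, dtype=object)
    for metric in METRICS:
        flags = abmap.flags(metric)
        regions = wall_regions if metric.endswith("wss") else np.asarray(voxel_regions)
        row = {}
        for region in REGIONS:
            sel = regions == region
            row[region] = bool(flags[sel].any()) if sel.any() else pd.NA
        rows[metric] = row
    return pd.DataFrame.from_dict(rows, orient="index").reindex(list(METRICS))


def incidence_map(maps: list[AbnormalityMap]) -> dict[str, np.ndarray]:
    """Per-location % of patients abnormal, per metric.

    The denominator is the number of patients whose geometry covers
    (evaluates) the location; locations covered by no patient are NaN.
    """
    if not maps:
        raise ValueError("incidence_map needs at least one patient map")
    out = {}
    for metric in METRICS:
        flags = np.stack([m.flags(metric) for m in maps])
        cover = np.stack([m.evaluated(metric) for m in maps])
        n = cover.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            inc = 100.0 * flags.sum(axis=0) / n
        inc[n == 0] = np.nan
        out[metric] = inc
    return out
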