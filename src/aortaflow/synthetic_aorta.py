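"""Synthetic 4D flow phantoms with analytic ground truth.

Real aortic 4D flow MRI data cannot be redistributed, so every downstream
stage (wall shear stress, regional partition, normative atlas, pulse wave
velocity, cohort statistics) is validated against pulsatile laminar tube
phantoms generated here.  The stated world:

* straight or U-bend tubes at ~2.5 mm isotropic resolution, ~30 cardiac
  timeframes (dt ~32 ms), lumen radius ~10 mm;
* a parabolic (Poiseuille) axial profile
  ``v(r, t, s) = vmax * w(t - s / PWV) * (1 - r^2 / R^2)``
  where ``s`` is centerline arc length, ``w`` a periodic waveform with
  max 1 (linear interpolation between its samples) and ``PWV`` the exact
  wave speed -- the flow pulse propagates along the vessel with zero
  dispersion, so the PWV estimator error is isolated;
* additive Gaussian velocity noise inside AND outside the lumen
  (magnitude image is identically 1: magnitude weighting is not exercised
  by any downstream result);
* healthy-cohort variability as log-normal multipliers on peak velocity
  and lumen radius, all subjects sharing the template grid so voxelwise
  atlas statistics are defined without registration error.

Poiseuille profiles are used instead of full Womersley solutions because
they give closed-form wall shear rate ``2*vmax/R`` and flow rate
``pi*R^2*vmax/2`` -- the oracles every estimator is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .flow_dataset import Segmentation, VelocityField

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "default_waveform",
    "make_phantom",
    "make_cohort",
]

_POLYLINE_STEP_MM = 0.5


def default_waveform(nt: int = 30) -> np.ndarray:
    """A physiological-looking periodic flow waveform with max 1.

    Raised-cosine systolic pulse over the first ~45% of the cycle (peak
    near frame 7 of 30 at 32 ms resolution) on top of a small diastolic
    baseline, normalized to max 1.
    """
    if nt < 4:
        raise ValueError("waveform needs at least 4 samples")
    t = np.arange(nt) / nt
    systole = 0.45
    w = np.where(t < systole, 0.5 * (1.0 - np.cos(2.0 * np.pi * t / systole)), 0.0)
    w = w + 0.05
    return w / w.max()


@dataclass
class PhantomSpec:
    """Geometry, waveform and noise description of one tube phantom."""

    geometry: Literal["straight", "u-bend"] = "straight"
    radius_mm: float = 10.0
    length_mm: float = 100.0          # straight tube length, or per-limb length
    bend_radius_mm: float = 35.0      # U-bend centerline radius
    vmax_peak: float = 1.0            # peak centerline velocity, m/s
    waveform: np.ndarray | None = None
    nt: int = 30
    dt_ms: float = 32.0
    pwv_mps: float = 8.0
    noise_sd: float = 0.0             # Gaussian velocity noise SD, m/s
    spacing_mm: float = 2.5
    seed: int = 0
    margin_mm: float = 7.5
    landmarks_mm: tuple[float, float, float] | None = None
    phase_offset_mps: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.geometry not in ("straight", "u-bend"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.radius_mm <= 2.0 * self.spacing_mm:
            raise ValueError("radius must exceed twice the voxel spacing")
        if self.pwv_mps <= 0:
            raise ValueError("pwv must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=float)
            if not np.isclose(self.waveform.max(), 1.0):
                raise ValueError("waveform must be normalized to max 1")

    @property
    def period_s(self) -> float:
        return self.nt * self.dt_ms / 1000.0

    def resolved_waveform(self) -> np.ndarray:
        if self.waveform is not None:
            return self.waveform
        return default_waveform(self.nt)


@dataclass
class CohortSpec:
    """A cohort of phantoms sharing one grid, with between-subject variability."""

    template: PhantomSpec
    n_subjects: int = 25
    sd_vmax: float = 0.10    # log-normal sigma on peak velocity
    sd_radius: float = 0.05  # log-normal sigma on lumen radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.sd_vmax < 0 or self.sd_radius < 0:
            raise ValueError("between-subject SD multipliers must be >= 0")


@dataclass
class GroundTruth:
    """Analytic truth stored alongside a phantom for oracle tests."""

    spec: PhantomSpec
    peak_frame: int
    centerline_mm: np.ndarray       # fine polyline, (n, 3)
    arclength_mm: np.ndarray        # (n,)
    tangents: np.ndarray            # (n, 3) unit
    landmarks_mm: tuple[float, float, float]
    inlet_mm: np.ndarray            # first centerline point
    apex_normal: np.ndarray         # inner-side direction for straight tubes

    @property
    def radius_m(self) -> float:
        return self.spec.radius_mm / 1000.0

    def delay_s(self, arclength_mm: float | np.ndarray) -> np.ndarray:
        """Exact waveform arrival delay at centerline position s."""
        return np.asarray(arclength_mm, dtype=float) / 1000.0 / self.spec.pwv_mps

    def wall_shear_rate_peak(self) -> float:
        """Analytic peak wall shear rate 2*vmax/R, 1/s."""
        return 2.0 * self.spec.vmax_peak / self.radius_m

    def wall_shear_stress_peak(self, mu: float = 3.2e-3) -> float:
        """Analytic peak WSS magnitude mu * 2*vmax/R, Pa."""
        return mu * self.wall_shear_rate_peak()

    def flow_rate_peak_mlps(self) -> float:
        """Analytic peak flow rate pi*R^2*vmax/2, ml/s."""
        return 0.5 * np.pi * self.radius_m**2 * self.spec.vmax_peak * 1e6

    def true_side(self, points_m: np.ndarray, margin_frac: float = 0.2) -> np.ndarray:
        """Analytic inner/outer labels for wall points.

        Returns an object array of 'inner' / 'outer' / 'ambiguous'; points
        whose signed offset from the centerline toward the curvature center
        is within ``margin_frac * R`` are 'ambiguous' (e.g. the top/bottom
        of the tube, where the inner/outer notion degenerates).
        """
        p = np.asarray(points_m) * 1000.0  # mm
        spec = self.spec
        m, R, L = spec.margin_mm, spec.radius_mm, spec.length_mm
        if spec.geometry == "straight":
            c_perp = m + R
            signed = (p - np.array([c_perp, c_perp, 0.0])) @ self.apex_normal
        else:
            x0 = m + R
            cx, cz = x0 + spec.bend_radius_mm, m + L
            signed = np.empty(len(p))
            in_bend = p[:, 2] >= cz
            r_bend = np.hypot(p[in_bend, 0] - cx, p[in_bend, 2] - cz)
            signed[in_bend] = spec.bend_radius_mm - r_bend
            limb1 = (~in_bend) & (p[:, 0] < cx)
            limb2 = (~in_bend) & (p[:, 0] >= cx)
            signed[limb1] = p[limb1, 0] - x0
            signed[limb2] = (x0 + 2.0 * spec.bend_radius_mm) - p[limb2, 0]
        out = np.where(signed > margin_frac * R, "inner", "outer").astype(object)
        out[np.abs(signed) <= margin_frac * R] = "ambiguous"
        return out


def _centerline_polyline(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fine centerline polyline (mm), cumulative arclength and unit tangents."""
    m, R, L = spec.margin_mm, spec.radius_mm, spec.length_mm
    step = _POLYLINE_STEP_MM
    c_perp = m + R
    if spec.geometry == "straight":
        s = np.arange(0.0, L + step / 2, step)
        pts = np.column_stack([np.full_like(s, c_perp), np.full_like(s, c_perp), s])
    else:
        Rc = spec.bend_radius_mm
        x0, y0 = c_perp, c_perp
        s1 = np.arange(0.0, L, step)
        limb1 = np.column_stack([np.full_like(s1, x0), np.full_like(s1, y0), s1])
        theta = np.arange(np.pi, 0.0, -step / Rc)
        bend = np.column_stack([
            x0 + Rc + Rc * np.cos(theta),
            np.full_like(theta, y0),
            L + Rc * np.sin(theta),
        ])
        s2 = np.arange(L, -step / 2, -step)
        limb2 = np.column_stack(
            [np.full_like(s2, x0 + 2 * Rc), np.full_like(s2, y0), s2]
        )
        pts = np.vstack([limb1, bend, limb2])
    # shift so the tube starts margin_mm away from the z=0 face
    pts = pts + np.array([0.0, 0.0, m])
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seglen)])
    tangents = np.gradient(pts, arclength, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return pts, arclength, tangents


def grid_shape_for(spec: PhantomSpec, radius_mm: float | None = None) -> tuple[int, int, int]:
    """Grid shape (voxels) that contains the tube plus its margins."""
    R = spec.radius_mm if radius_mm is None else radius_mm
    pts, _, _ = _centerline_polyline(spec)
    hi = pts.max(axis=0) + R + spec.margin_mm
    return tuple(int(np.floor(h / spec.spacing_mm)) + 1 for h in hi)


def _default_landmarks(spec: PhantomSpec, total_mm: float) -> tuple[float, float, float]:
    if spec.geometry == "u-bend":
        bend_len = np.pi * spec.bend_radius_mm
        return (spec.length_mm, spec.length_mm + bend_len, total_mm)
    return (total_mm / 3.0, 2.0 * total_mm / 3.0, total_mm)


def make_phantom(
    spec: PhantomSpec, grid_shape: tuple[int, int, int] | None = None
) -> tuple[VelocityField, Segmentation, GroundTruth]:
    """Generate one pulsatile tube phantom.

    All randomness flows from ``spec.seed``; the same spec yields a
    bit-identical dataset.  Raises if the tube (plus margins) does not fit
    inside the grid.
    """
    sp = spec.spacing_mm
    pts, arclength, tangents = _centerline_polyline(spec)
    shape = grid_shape if grid_shape is not None else grid_shape_for(spec)
    ax = [np.arange(n) * sp for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    vox = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tree = cKDTree(pts)
    _, idx = tree.query(vox, workers=-1)
    rel = vox - pts[idx]
    tan = tangents[idx]
    axial = np.einsum("ij,ij->i", rel, tan)
    s_vox = arclength[idx] + axial
    r_vox = np.linalg.norm(rel - axial[:, None] * tan, axis=1)
    inside = (r_vox <= spec.radius_mm) & (s_vox >= 0.0) & (s_vox <= arclength[-1])

    mask = inside.reshape(shape)
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
            or mask[:, :, 0].any() or mask[:, :, -1].any()):
        raise ValueError(
            "tube does not fit: lumen touches the grid boundary "
            f"(grid {shape}, radius {spec.radius_mm} mm, margin {spec.margin_mm} mm)"
        )
    nt = spec.nt
    T = spec.period_s
    w = spec.resolved_waveform()
    wf_t = np.arange(len(w) + 1) * (T / len(w))
    wf_v = np.concatenate([w, w[:1]])

    lum = np.flatnonzero(inside)
    t_frames = np.arange(nt) * spec.dt_ms / 1000.0
    delay = s_vox[lum] / 1000.0 / spec.pwv_mps
    phase = (t_frames[None, :] - delay[:, None]) % T
    w_eval = np.interp(phase, wf_t, wf_v)
    profile = 1.0 - (r_vox[lum] / spec.radius_mm) ** 2
    speed = spec.vmax_peak * w_eval * profile[:, None]  # (n_lumen, nt)
    peak_frame = int(np.argmax(speed.mean(axis=0)))

    comps = []
    for a in range(3):
        v = np.zeros((vox.shape[0], nt))
        v[lum] = speed * tan[lum, a][:, None]
        comps.append(v.reshape(shape + (nt,)))
    vx, vy, vz = comps

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        vx += rng.normal(0.0, spec.noise_sd, vx.shape)
        vy += rng.normal(0.0, spec.noise_sd, vy.shape)
        vz += rng.normal(0.0, spec.noise_sd, vz.shape)
    off = np.asarray(spec.phase_offset_mps, dtype=float)
    if np.any(off != 0):
        vx += off[0]
        vy += off[1]
        vz += off[2]

    field = VelocityField(
        vx=vx, vy=vy, vz=vz, mag=np.ones_like(vx),
        spacing=np.full(3, sp), dt=spec.dt_ms, venc=2.0,
    )
    seg = Segmentation(mask=mask, spacing=np.full(3, sp))
    landmarks = spec.landmarks_mm or _default_landmarks(spec, float(arclength[-1]))
    if not (0 < landmarks[0] < landmarks[1] < landmarks[2] <= arclength[-1] + 1e-6):
        raise ValueError("landmarks must be strictly increasing within the centerline")
    gt = GroundTruth(
        spec=spec,
        peak_frame=peak_frame,
        centerline_mm=pts,
        arclength_mm=arclength,
        tangents=tangents,
        landmarks_mm=tuple(float(v) for v in landmarks),
        inlet_mm=pts[0].copy(),
        apex_normal=np.array([1.0, 0.0, 0.0]),
    )
    return field, seg, gt


def make_cohort(
    cohort: CohortSpec,
) -> list[tuple[VelocityField, Segmentation, GroundTruth]]:
    """Generate a cohort of phantoms on the template grid.

    Subject ``i`` draws its peak velocity and radius from log-normal
    perturbations of the template (``x_i = x * exp(sigma * z_i)``); all
    subjects share the template grid so voxelwise statistics line up
    without registration.
    """
    tpl = cohort.template
    children = np.random.SeedSequence(cohort.seed).spawn(cohort.n_subjects + 1)
    draw_rng = np.random.default_rng(children[0])
    z = draw_rng.standard_normal((cohort.n_subjects, 2))
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[1:]]
    # fixed grid sized for the largest plausible radius draw
    r_max = tpl.radius_mm * np.exp(4.0 * cohort.sd_radius)
    shape = grid_shape_for(tpl, radius_mm=r_max)
    out = []
    for i in range(cohort.n_subjects):
        spec_i = replace(
            tpl,
            vmax_peak=tpl.vmax_peak * float(np.exp(cohort.sd_vmax * z[i, 0])),
            radius_mm=tpl.radius_mm * float(np.exp(cohort.sd_radius * z[i, 1])),
            seed=child_seeds[i],
        )
        out.append(make_phantom(spec_i, grid_shape=shape))
    return out
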