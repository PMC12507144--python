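"""Shared phantom fixtures.

Expensive phantoms are session-scoped; tests must not mutate them (make
copies when a test needs to edit a field or mesh).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from aortaflow.atlas import sample_subject
from aortaflow.flow_dataset import Segmentation
from aortaflow.geometry import (
    extract_centerline,
    extract_wall,
    local_lumen_diameter,
    partition_regions,
)
from aortaflow.synthetic_aorta import CohortSpec, PhantomSpec, grid_shape_for, make_cohort, make_phantom
from aortaflow.wss import estimate_wss


STEADY_WAVEFORM = np.array([1.0])


def analyze(field, seg, gt, mu=3.2e-3):
    """Geometry + WSS for one phantom dataset (test-side convenience)."""
    from aortaflow.flow_dataset import peak_systole_index

    peak = peak_systole_index(field, seg)
    centerline = extract_centerline(seg, inlet_mm=gt.inlet_mm)
    mesh = extract_wall(seg)
    local_lumen_diameter(mesh, seg)
    lm = tuple(min(v / 1000.0, centerline.length) for v in gt.landmarks_mm)
    partition_regions(mesh, centerline, lm, apex_normal=gt.apex_normal)
    wss = estimate_wss(field, mesh, peak, mu=mu)
    return peak, centerline, mesh, lm, wss


@pytest.fixture(scope="session")
def steady_cylinder():
    """Steady Poiseuille cylinder: R=10 mm, vmax=1 m/s, 2.5 mm voxels."""
    spec = PhantomSpec(
        geometry="straight", radius_mm=10.0, length_mm=60.0, nt=1,
        waveform=STEADY_WAVEFORM, spacing_mm=2.5, seed=0,
    )
    field, seg, gt = make_phantom(spec)
    return spec, field, seg, gt


@pytest.fixture(scope="session")
def steady_cylinder_mesh(steady_cylinder):
    _, field, seg, gt = steady_cylinder
    mesh = extract_wall(seg)
    local_lumen_diameter(mesh, seg)
    return mesh


@pytest.fixture(scope="session")
def ubend_phantom():
    """Pulsatile U-bend phantom with mild noise (SNR 20 at peak)."""
    spec = PhantomSpec(
        geometry="u-bend", radius_mm=10.0, length_mm=80.0, bend_radius_mm=35.0,
        spacing_mm=2.5, nt=30, dt_ms=32.0, noise_sd=0.05, seed=7,
    )
    return (spec,) + make_phantom(spec)


@pytest.fixture(scope="session")
def atlas_world():
    """Shared template + 30 healthy subjects sampled onto it (25 atlas + 5 held out)."""
    tpl = PhantomSpec(
        geometry="u-bend", radius_mm=10.0, length_mm=80.0, bend_radius_mm=35.0,
        spacing_mm=2.5, nt=30, dt_ms=32.0, noise_sd=0.05, seed=0,
    )
    grid = grid_shape_for(tpl, radius_mm=tpl.radius_mm * np.exp(4 * 0.05))
    t_field, t_seg, t_gt = make_phantom(
        dataclasses.replace(tpl, noise_sd=0.0), grid_shape=grid
    )
    _, t_centerline, t_mesh, t_lm, _ = analyze(t_field, t_seg, t_gt)
    cohort = make_cohort(
        CohortSpec(template=tpl, n_subjects=30, sd_vmax=0.10, sd_radius=0.05, seed=42)
    )
    samples = []
    for field, seg, gt in cohort:
        peak, _, mesh, _, wss = analyze(field, seg, gt)
        samples.append(sample_subject(field, seg, wss, mesh, t_seg, t_mesh, frame=peak))
    return {
        "template": (t_field, t_seg, t_gt),
        "centerline": t_centerline,
        "mesh": t_mesh,
        "landmarks_m": t_lm,
        "samples": samples,
    }


@pytest.fixture()
def asymmetric_mask():
    """Ellipsoid + offset sphere (no rotational symmetry), 1 mm spacing."""
    shape = (48, 40, 44)
    idx = np.indices(shape).astype(float)
    c1, c2 = np.array([22, 20, 20]), np.array([34, 20, 30])
    ell = (((idx[0] - c1[0]) / 14) ** 2 + ((idx[1] - c1[1]) / 8) ** 2
           + ((idx[2] - c1[2]) / 10) ** 2) <= 1
    sph = (((idx[0] - c2[0]) / 6) ** 2 + ((idx[1] - c2[1]) / 6) ** 2
           + ((idx[2] - c2[2]) / 6) ** 2) <= 1
    return Segmentation(mask=ell | sph, spacing=np.ones(3))
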