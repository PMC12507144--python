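"""End-to-end orchestration: simulate -> geometry -> WSS -> atlas -> PWV -> stats.

A run generates a healthy phantom cohort, builds the normative velocity
and WSS atlases on the shared template geometry, simulates a patient
cohort (two sessions each, with elevated peak velocities and stiffer
walls), maps each patient against the atlases, estimates PWV, registers
follow-up to baseline segmentations, aggregates incidence maps and
writes the table1-4 style reports.

Every source of randomness descends from the single configured seed, so
a rerun with the same config is bit-identical for all deterministic
outputs (CSV/JSON).  Outputs carry provenance metadata (config hash,
seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as _field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    METRICS,
    build_atlas,
    compare_patient,
    incidence_map,
    patient_region_flags,
    sample_subject,
)
from .cohort_stats import build_reports
from .flow_dataset import Segmentation, VelocityField, peak_systole_index
from .geometry import (
    REGIONS,
    extract_centerline,
    extract_wall,
    local_lumen_diameter,
    partition_regions,
    rigid_register,
)
from .pwv import estimate_pwv
from .synthetic_aorta import CohortSpec, PhantomSpec, grid_shape_for, make_cohort, make_phantom
from .vtkio import write_polydata
from .wss import DEFAULT_VISCOSITY, assign_voxel_regions, estimate_wss, region_means

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger("aortaflow")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    n_healthy: int = 25
    n_patients: int = 6
    template: PhantomSpec = _field(
        default_factory=lambda: PhantomSpec(
            geometry="u-bend", radius_mm=10.0, length_mm=80.0, bend_radius_mm=35.0,
            noise_sd=0.05,
        )
    )
    cohort_sd_vmax: float = 0.10
    cohort_sd_radius: float = 0.05
    patient_vmax_factor: float = 1.35
    patient_session_sd: float = 0.03
    patient_pwv_mean: float = 8.5
    patient_pwv_sd: float = 1.5
    mu: float = DEFAULT_VISCOSITY
    z_threshold: float = 1.96
    angle_threshold_deg: float = 120.0
    dt_target_ms: float = 20.0
    section_spacing_mm: float = 10.0
    register_followup: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory: the pipeline has stochastic stages")
        for name in ("mu", "z_threshold", "angle_threshold_deg", "dt_target_ms",
                     "section_spacing_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_healthy < 2:
            raise ConfigError("n_healthy must be at least 2 (atlas needs >= 2 subjects)")
        if self.n_patients < 2:
            raise ConfigError("n_patients must be at least 2")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ConfigError("config is missing the mandatory 'seed'")
        tpl_raw = raw.pop("template", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            if tpl_raw is not None:
                raw["template"] = PhantomSpec(**tpl_raw)
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} did not parse to a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        tpl = d["template"]
        if tpl.get("waveform") is not None:
            tpl["waveform"] = list(map(float, tpl["waveform"]))
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _save_volume(path: Path, data: np.ndarray, spacing: np.ndarray) -> None:
    aff = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), aff), str(path))


def _analyze_subject(field, seg, gt, mu):
    """Geometry + peak-systole WSS for one dataset."""
    peak = peak_systole_index(field, seg)
    centerline = extract_centerline(seg, inlet_mm=gt.inlet_mm)
    mesh = extract_wall(seg)
    local_lumen_diameter(mesh, seg)
    landmarks_m = tuple(v / 1000.0 for v in gt.landmarks_mm)
    landmarks_m = (
        landmarks_m[0], landmarks_m[1], min(landmarks_m[2], centerline.length)
    )
    partition_regions(mesh, centerline, landmarks_m, apex_normal=gt.apex_normal)
    wss = estimate_wss(field, mesh, peak, mu=mu)
    return peak, centerline, mesh, landmarks_m, wss


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns a small summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_patients, s_clinical = ss.spawn(3)

    # --- shared template geometry -----------------------------------------
    log.info("stage geometry: shared template")
    tpl = config.template
    r_max = tpl.radius_mm * float(np.exp(4.0 * config.cohort_sd_radius))
    grid = grid_shape_for(tpl, radius_mm=r_max)
    tpl_clean = dataclasses.replace(tpl, noise_sd=0.0, seed=0)
    t_field, t_seg, t_gt = make_phantom(tpl_clean, grid_shape=grid)
    t_peak, t_centerline, t_mesh, landmarks_m, _ = _analyze_subject(
        t_field, t_seg, t_gt, config.mu
    )
    vox_regions = assign_voxel_regions(
        t_seg.voxel_centers_m(), t_mesh, t_centerline, t_gt.apex_normal
    )

    # --- healthy cohort and atlases ---------------------------------------
    log.info("stage atlas: %d healthy subjects", config.n_healthy)
    cohort_seed = int(s_cohort.generate_state(1)[0] % (2**31))
    healthy = make_cohort(CohortSpec(
        template=tpl, n_subjects=config.n_healthy,
        sd_vmax=config.cohort_sd_vmax, sd_radius=config.cohort_sd_radius,
        seed=cohort_seed,
    ))
    samples = []
    for field, seg, gt in healthy:
        peak, _, mesh, _, wss = _analyze_subject(field, seg, gt, config.mu)
        samples.append(
            sample_subject(field, seg, wss, mesh, t_seg, t_mesh, frame=peak)
        )
    atl = build_atlas(samples, t_seg, t_mesh)

    # --- patients: two sessions each ---------------------------------------
    log.info("stage patients: %d patients x 2 sessions", config.n_patients)
    groups = ["native", "rr"]
    pat_rng = np.random.default_rng(s_patients)
    clin_rng = np.random.default_rng(s_clinical)
    rows, pwv_rows, regmean_rows, reg_rows = [], [], [], []
    abmaps: dict[str, dict[str, list]] = {
        s: {g: [] for g in groups} for s in ("baseline", "follow_up")
    }
    for p in range(config.n_patients):
        sid = f"P{p:02d}"
        group = groups[p % 2]
        z_vmax, z_rad = pat_rng.standard_normal(2)
        pwv_p = float(np.clip(
            pat_rng.normal(config.patient_pwv_mean, config.patient_pwv_sd), 4.0, 13.0
        ))
        vmax_base = tpl.vmax_peak * config.patient_vmax_factor * float(
            np.exp(config.cohort_sd_vmax * z_vmax)
        )
        radius_p = tpl.radius_mm * float(
            np.exp(config.cohort_sd_radius * np.clip(z_rad, -3.5, 3.5))
        )
        sbp0 = float(clin_rng.normal(115.0, 13.0))
        dbp0 = min(float(clin_rng.normal(66.0, 9.0)), sbp0 - 20.0)
        hr0 = float(clin_rng.normal(61.0, 9.0))
        female = bool(clin_rng.random() < 0.5)

        session_segs = {}
        for session in ("baseline", "follow_up"):
            jitter = float(np.exp(config.patient_session_sd * pat_rng.standard_normal()))
            spec_ps = dataclasses.replace(
                tpl,
                vmax_peak=vmax_base * jitter,
                radius_mm=radius_p,
                pwv_mps=pwv_p,
                seed=int(pat_rng.integers(2**31)),
            )
            field, seg, gt = make_phantom(spec_ps, grid_shape=grid)
            session_segs[session] = seg
            peak, centerline, mesh, lm_m, wss = _analyze_subject(
                field, seg, gt, config.mu
            )
            means = region_means(
                field, wss, mesh, seg, peak, centerline, gt.apex_normal
            )
            pwv_res, _ = estimate_pwv(
                field, seg, centerline,
                dt_target_ms=config.dt_target_ms,
                section_spacing_mm=config.section_spacing_mm,
            )
            sample = sample_subject(field, seg, wss, mesh, t_seg, t_mesh, frame=peak)
            abmap = compare_patient(
                atl, sample, z=config.z_threshold, angle_deg=config.angle_threshold_deg
            )
            abmaps[session][group].append(abmap)
            flags = patient_region_flags(abmap, t_mesh, vox_regions)

            row = {
                "subject": sid, "session": session, "group": group,
                "sbp": round(sbp0 + float(clin_rng.normal(0, 3.0)), 1),
                "dbp": round(dbp0 + float(clin_rng.normal(0, 3.0)), 1),
                "hr": round(hr0 + float(clin_rng.normal(0, 4.0)), 1),
                "female": female,
                "pwv": pwv_res.pwv_mps if pwv_res.valid else np.nan,
            }
            for region in REGIONS:
                row[f"vel_{region}"] = means.loc[region, "velocity_mps"]
                row[f"wss_{region}"] = means.loc[region, "wss_pa"]
                for metric in METRICS:
                    val = flags.loc[metric, region]
                    row[f"flag_{metric}_{region}"] = bool(val) if val is not pd.NA else False
                regmean_rows.append({
                    "subject": sid, "session": session, "region": region,
                    "velocity_mps": means.loc[region, "velocity_mps"],
                    "wss_pa": means.loc[region, "wss_pa"],
                })
            rows.append(row)
            pwv_rows.append({
                "subject": sid, "session": session, "group": group,
                "pwv_mps": pwv_res.pwv_mps, "pwv_true_mps": pwv_p,
                "r2": pwv_res.r2, "n_sections": pwv_res.n_sections,
                "valid": pwv_res.valid,
            })

        if config.register_followup:
            tr = rigid_register(session_segs["follow_up"], session_segs["baseline"])
            reg_rows.append({
                "subject": sid, "dice": round(tr.dice, 4),
                "rotation_deg": round(tr.rotation_angle_deg(), 3),
                "translation_mm": round(float(np.linalg.norm(tr.translation_mm)), 3),
                "ok": tr.ok,
            })

    # --- incidence maps -----------------------------------------------------
    log.info("stage incidence maps")
    for session, by_group in abmaps.items():
        for group, maps in by_group.items():
            if not maps:
                continue
            inc = incidence_map(maps)
            wall = {m: inc[m] for m in METRICS if m.endswith("wss")}
            write_polydata(
                outdir / f"incidence_wall_{group}_{session}.vtk",
                t_mesh.points, scalars=wall,
            )
            vol = np.full(t_seg.mask.shape, -1.0, dtype=np.float32)
            lum = t_seg.mask
            for m in METRICS:
                if m.endswith("wss"):
                    continue
                v = vol.copy()
                v[lum] = np.nan_to_num(inc[m], nan=-1.0)
                _save_volume(
                    outdir / f"incidence_{m}_{group}_{session}.nii.gz", v, t_seg.spacing
                )

    # --- atlas export -------------------------------------------------------
    for name, arr in (("vel_mean", atl.vel_mean_mag), ("vel_sd", atl.vel_sd_mag)):
        vol = np.full(t_seg.mask.shape, -1.0, dtype=np.float32)
        vol[t_seg.mask] = np.nan_to_num(arr, nan=-1.0)
        _save_volume(outdir / f"atlas_{name}.nii.gz", vol, t_seg.spacing)
    write_polydata(
        outdir / "atlas_wall.vtk", t_mesh.points,
        scalars={"wss_mean": atl.wss_mean_mag, "wss_sd": atl.wss_sd_mag},
        vectors={"wss_mean_vec": atl.wss_mean_vec},
    )

    # --- reports ------------------------------------------------------------
    log.info("stage statistics and reports")
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "cohort_table.csv", index=False)
    pd.DataFrame(pwv_rows).to_csv(outdir / "pwv.csv", index=False)
    pd.DataFrame(regmean_rows).to_csv(outdir / "region_means.csv", index=False)
    if reg_rows:
        pd.DataFrame(reg_rows).to_csv(outdir / "registration.csv", index=False)
    build_reports(table, outdir)

    provenance = {
        "package": "aortaflow",
        "version": __version__,
        "seed": int(config.seed),
        "config_sha256": config.digest(),
        "n_healthy": config.n_healthy,
        "n_patients": config.n_patients,
        "atlas_n_subjects": atl.n_subjects,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    log.info("pipeline complete: %s", outdir)
    return provenance
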