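"""End-to-end elastography workflow.

Order of stages: displacement tracking (with reference redefinition),
Savitzky-Golay strain, per-frame Love (or plane) stress from the
resampled force, performance gating, modulus / Poisson / shear-wave
maps, ROI summaries.  Because cumulative displacement fields live on
the frame-0 grid, all per-frame maps are natively in the reference
configuration and the multi-frame mean needs no extra warping.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as _flow
from . import strain as _strain
from .io import ForceLog, RunConfig, resample_force_to_frames, write_map_tiff
from .materials import Frame
from .materials import poisson_2d_to_3d
from .modulus import (
    ModulusResult,
    ROI,
    frame_modulus_map,
    frame_nu_prime_map,
    mean_map,
    roi_summary,
    shear_speed_map,
)
from .performance import build_records, gate_frames, records_to_frame, winsorize
from .stress import StressField, love_stress_map, plane_stress_field

__all__ = ["run_pipeline", "default_rois"]


def default_rois(has_inclusion: bool, inclusion_center=(0.0, 12.5e-3),
                 inclusion_radius: float = 4e-3) -> list[ROI]:
    """Region-of-interest layout used for reporting.

    Homogeneous specimens get one large central region; inclusion
    specimens get a circle inside the inclusion (region 2) plus two
    flanking body rectangles (regions 3a/3b) at the same depth.
    """
    if not has_inclusion:
        return [ROI("region1", "rect", (-8e-3, 6e-3, 8e-3, 19e-3))]
    cx, cz = inclusion_center
    r_in = max(inclusion_radius - 1e-3, 1e-3)
    dz = inclusion_radius
    return [
        ROI("region2_inclusion", "circle", (cx, cz, r_in)),
        ROI("region3a_body", "rect", (cx - 11e-3, cz - dz, cx - 6e-3, cz + dz)),
        ROI("region3b_body", "rect", (cx + 6e-3, cz - dz, cx + 11e-3, cz + dz)),
    ]


def _stress_for_frame(phi: StressField, pressure: float) -> StressField:
    """Scale a unit-pressure stress shape by the frame pressure (linearity)."""
    return StressField(sigma_zz=phi.sigma_zz * pressure, pressure_p=pressure,
                       geometry=phi.geometry, model=phi.model)


def run_pipeline(
    frames: list[Frame],
    force_log: ForceLog,
    config: RunConfig,
    outdir=None,
) -> ModulusResult:
    """Run the full elastography workflow on a CINE sequence + force log."""
    t_start = _time.perf_counter()
    timings: dict[str, float] = {}
    geo = config.geometry
    shape = frames[0].shape
    forces = resample_force_to_frames(force_log, [f.time for f in frames])

    # 1. displacement tracking
    t0 = _time.perf_counter()
    fields, tlog = _flow.track_sequence(
        frames, rho_min=config.rho_min, backend=config.flow_backend,
        blur_sigma=config.blur_sigma,
    )
    timings["tracking_s"] = _time.perf_counter() - t0

    # exclude the bottom band traversed by the rising base-plate interface
    if config.bottom_exclusion_m > 0:
        keep_rows = int(round(
            (geo.specimen_height - config.bottom_exclusion_m) / frames[0].pixel_size
        ))
        for f in fields:
            f.valid[keep_rows:, :] = False

    # 2. strain from the cumulative fields (total strain feeds the modulus)
    t0 = _time.perf_counter()
    GS = frames[0].pixel_size
    M = config.filter_half_width_M
    cum_strains = _strain.strain_sequence(fields, "cumulative", M, GS)
    timings["strain_s"] = _time.perf_counter() - t0

    # 3. stress: unit-pressure shape scaled per frame (linear in p)
    t0 = _time.perf_counter()
    if config.stress_model == "love":
        phi = love_stress_map(geo, shape, force=geo.footprint_area)  # p = 1 Pa
    else:
        phi = plane_stress_field(geo.footprint_area, geo, shape)
    pressures = forces[1:] / geo.footprint_area
    stresses = [_stress_for_frame(phi, p) for p in pressures]
    timings["stress_s"] = _time.perf_counter() - t0

    # 4. per-frame maps (reference configuration)
    t0 = _time.perf_counter()
    E_maps = [
        frame_modulus_map(s, st, gamma=config.gamma, strain_floor=config.strain_floor)
        for s, st in zip(cum_strains, stresses)
    ]
    nu_maps = [frame_nu_prime_map(s, config.strain_floor) for s in cum_strains]
    timings["modulus_s"] = _time.perf_counter() - t0

    # 5. performance descriptors on (k-1, k) pairings; the first tracked
    # frame has no predecessor maps, so gating starts at the second.
    # rho_i uses the same preprocessed frames the tracking correlation sees.
    t0 = _time.perf_counter()
    pre = [_flow.preprocess(f, config.blur_sigma) for f in frames]
    aligned = [np.where(v, w, np.nan) for w, v in
               (_flow.warp_image(pre[k + 1].image, fields[k])
                for k in range(len(fields)))]
    # rho_s compares the strain data each frame contributes downstream,
    # i.e. consecutive *cumulative* ezz maps on the common reference grid
    # (consecutive incremental maps share the middle field's noise with
    # opposite sign and would anticorrelate at small per-frame strains).
    cum_maps = [np.where(s.valid_mask, s.ezz, np.nan) for s in cum_strains]
    E_maps_w = [winsorize(m) for m in E_maps]
    frame_indices = [f.target_index for f in fields]
    records = build_records(aligned, cum_maps, E_maps_w,
                            frame_indices[1:]) if len(fields) > 1 else []
    perf = records_to_frame(records, config.p_min) if records else pd.DataFrame()
    accepted = gate_frames(records, config.p_min, "strain") if records else frame_indices
    accepted = [i for i in gate_frames(records, config.p_min, "elastography")
                if i in set(accepted)] if records else frame_indices
    timings["performance_s"] = _time.perf_counter() - t0

    # 6. mean maps over accepted frames
    t0 = _time.perf_counter()
    by_index = {idx: j for j, idx in enumerate(frame_indices)}
    sel = [by_index[i] for i in accepted]
    E_mean, count = mean_map([E_maps[j] for j in sel])
    # average the raw 2D ratio, convert and clip once (the generating value
    # sits near the clip boundary; clipping per frame would bias it down)
    nu_prime_mean, _ = mean_map([nu_maps[j] for j in sel])
    with np.errstate(invalid="ignore"):
        nu_mean = np.clip(poisson_2d_to_3d(nu_prime_mean), 0.0, 0.5)
    ct = shear_speed_map(E_mean, nu_mean, rho=config.density)
    timings["mean_s"] = _time.perf_counter() - t0

    rois = config.rois or default_rois(False)
    summary = roi_summary(E_mean, rois, GS)
    summary.insert(0, "n_frames_used", len(sel))

    track_df = pd.DataFrame(
        {
            "frame": [r.frame_index for r in tlog],
            "rho": [r.rho for r in tlog],
            "switched": [r.switched for r in tlog],
            "reference": [r.reference_index for r in tlog],
        }
    )
    timings["total_s"] = _time.perf_counter() - t_start
    result = ModulusResult(
        E_map=E_mean, nu_map=nu_mean, ct_map=ct, count_map=count,
        frames_used=accepted, roi_summaries=summary, performance=perf,
        track_log=track_df, backend=config.flow_backend,
        extras={
            "per_frame_E": E_maps, "per_frame_nu": nu_maps,
            "cum_strains": cum_strains, "fields": fields,
            "forces": forces, "timings": timings, "stress_shape": phi,
        },
    )
    if outdir is not None:
        _write_outputs(Path(outdir), result, config, frames, timings)
    return result


def _write_outputs(outdir: Path, result: ModulusResult, config: RunConfig,
                   frames: list[Frame], timings: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_map_tiff(outdir / "young_modulus_Pa.tiff", result.E_map)
    write_map_tiff(outdir / "poisson_ratio.tiff", result.nu_map)
    write_map_tiff(outdir / "shear_wave_speed_mps.tiff", result.ct_map)
    result.roi_summaries.to_csv(outdir / "roi_report.csv", index=False)
    if len(result.performance):
        result.performance.to_csv(outdir / "performance.csv", index=False)
    result.track_log.to_csv(outdir / "tracking.csv", index=False)
    config.to_yaml(outdir / "config.yaml")

    h = hashlib.sha256()
    for f in frames:
        h.update(np.ascontiguousarray(f.image).tobytes())
    manifest = {
        "config": _config_dict(config),
        "input_sha256": h.hexdigest(),
        "backend": result.backend,
        "seed": config.seed,
        "frames_used": result.frames_used,
        "timings_s": timings,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
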