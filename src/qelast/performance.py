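"""Per-frame trustability descriptors and frame gating.

Three frame-to-frame correlations are combined multiplicatively:

* rho_i  - correlation of consecutive image frames (both warped to the
  common reference configuration by their displacement fields),
* rho_s  - correlation of consecutive incremental-strain maps,
* rho_e  - correlation of consecutive Young's-modulus maps.

The strain-stage descriptor is p_S = rho_i * rho_s; the elastography
descriptor p_E = rho_i * rho_s * rho_e.  Frames whose descriptor falls
below p_min (default 0.9) are discarded from the corresponding stage.
Negative correlations are kept as-is; they simply fail the gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import frame_correlation

__all__ = ["PerformanceRecord", "stage_correlation", "build_records", "gate_frames"]


@dataclass
class PerformanceRecord:
    frame_index: int
    rho_i: float
    rho_s: float
    rho_e: float

    @property
    def p_S(self) -> float:
        return self.rho_i * self.rho_s

    @property
    def p_E(self) -> float:
        return self.rho_i * self.rho_s * self.rho_e


def winsorize(map2d: np.ndarray, lo: float = 1.0, hi: float = 99.0) -> np.ndarray:
    """Clip a map to its [lo, hi] percentile band (NaNs preserved).

    Pixelwise modulus maps are ratios and carry a heavy-tailed noise
    component (near-floor strains); a few extreme pixels would otherwise
    dominate the variance in the correlation and mask the map's real
    structure.  Correlations of modulus maps are computed on the
    winsorized maps.
    """
    a, b = np.nanpercentile(map2d, [lo, hi])
    return np.clip(map2d, a, b)


def stage_correlation(prev_map: np.ndarray, curr_map_warped: np.ndarray) -> float:
    """Correlation between two maps already living on a common grid.

    NaN pixels are excluded; an empty intersection is undefined and the
    frame is meant to be rejected by the caller.
    """
    return frame_correlation(prev_map, curr_map_warped)


def modulus_stage_correlation(prev_map: np.ndarray, curr_map_warped: np.ndarray) -> float:
    """Uncentered normalized cross-correlation for quantitative maps.

    The image- and strain-stage descriptors correlate *patterns*
    (Pearson).  A quantitative modulus map of a homogeneous target is,
    when correctly recovered, structureless: Pearson then degenerates to
    the correlation of residual noise and *drops* as the estimator
    improves.  Agreement between consecutive elastograms must therefore
    include the maps' level, which the uncentered cosine similarity
    sum(AB) / sqrt(sum(A^2) sum(B^2)) retains.  A frame whose map
    deviates in level or pattern still scores low.
    """
    a = np.asarray(prev_map, dtype=float)
    b = np.asarray(curr_map_warped, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    sel = np.isfinite(a) & np.isfinite(b)
    if not np.any(sel):
        raise ValueError("empty valid overlap between maps")
    denom = np.sqrt(np.sum(a[sel] ** 2) * np.sum(b[sel] ** 2))
    if denom == 0:
        raise ValueError("zero-energy map: correlation undefined")
    return float(np.sum(a[sel] * b[sel]) / denom)


def _safe_corr(a: np.ndarray, b: np.ndarray, fn=None) -> float:
    try:
        return (fn or stage_correlation)(a, b)
    except ValueError:
        return float("nan")


def build_records(
    ref_warped_images: list[np.ndarray],
    strain_maps: list[np.ndarray],
    modulus_maps: list[np.ndarray],
    frame_indices: list[int],
) -> list[PerformanceRecord]:
    """Assemble per-frame records from consecutive-pair correlations.

    Each list holds per-frame maps on the common reference grid with a
    baseline element prepended (the undeformed image / the first strain
    or modulus map), so list ``j`` vs ``j+1`` is the (k-1, k) pairing of
    frame ``frame_indices[j]``.  Lists must be one longer than
    ``frame_indices``.
    """
    n = len(frame_indices)
    for name, lst in (
        ("ref_warped_images", ref_warped_images),
        ("strain_maps", strain_maps),
        ("modulus_maps", modulus_maps),
    ):
        if len(lst) != n + 1:
            raise ValueError(f"{name} must have len(frame_indices)+1 entries")
    records = []
    for j, idx in enumerate(frame_indices):
        rho_i = _safe_corr(ref_warped_images[j], ref_warped_images[j + 1])
        rho_s = _safe_corr(strain_maps[j], strain_maps[j + 1])
        rho_e = _safe_corr(modulus_maps[j], modulus_maps[j + 1],
                           fn=modulus_stage_correlation)
        records.append(PerformanceRecord(idx, rho_i, rho_s, rho_e))
    return records


def gate_frames(records: list[PerformanceRecord], p_min: float, stage: str) -> list[int]:
    """Indices of frames whose descriptor meets p_min for the given stage.

    ``stage`` is 'strain' (gates on p_S) or 'elastography' (gates on p_E).
    NaN descriptors never pass.  Zero accepted frames is a pipeline
    error: nothing downstream could be computed.
    """
    if stage == "strain":
        vals = [(r.frame_index, r.p_S) for r in records]
    elif stage == "elastography":
        vals = [(r.frame_index, r.p_E) for r in records]
    else:
        raise ValueError("stage must be 'strain' or 'elastography'")
    accepted = [idx for idx, p in vals if np.isfinite(p) and p >= p_min]
    if not accepted:
        raise RuntimeError(
            f"no frame passed the {stage} gate at p_min={p_min}; "
            f"descriptors: {[(i, round(p, 4)) if np.isfinite(p) else (i, 'nan') for i, p in vals]}"
        )
    return accepted


def records_to_frame(records: list[PerformanceRecord], p_min: float) -> pd.DataFrame:
    """Performance log table (the data behind the trustability plot)."""
    return pd.DataFrame(
        {
            "frame": [r.frame_index for r in records],
            "rho_i": [r.rho_i for r in records],
            "rho_s": [r.rho_s for r in records],
            "rho_e": [r.rho_e for r in records],
            "p_S": [r.p_S for r in records],
            "p_E": [r.p_E for r in records],
            "accepted": [bool(np.isfinite(r.p_E) and r.p_E >= p_min) for r in records],
        }
    )
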