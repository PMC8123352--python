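"""Young's-modulus, Poisson's-ratio and shear-wave-speed maps plus ROI stats.

Per frame, the axial compressive strain (from the cumulative
displacement field) divides the axial stress magnitude pixelwise:
E = sigma0 / eps0.  If a non-linearity gamma is configured, the apparent
modulus is corrected back to the linear modulus by dividing out
exp(3 * gamma * eps0**2).  Frame maps live on the frame-0 (reference)
configuration, so the multi-frame mean is a plain masked pixelwise mean.

ROI summaries report the median as the headline statistic, plus mean and
standard deviation over valid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import (
    DEFAULT_STRAIN_FLOOR,
    modulus_from_stress_strain,
    poisson_2d_to_3d,
    shear_wave_speed,
)
from .strain import StrainField
from .stress import StressField

__all__ = [
    "ROI",
    "ModulusResult",
    "frame_modulus_map",
    "frame_poisson_map",
    "mean_map",
    "roi_summary",
    "spatial_cov",
]


@dataclass(frozen=True)
class ROI:
    """Named region of interest in physical coordinates (metres).

    Rectangle: (x0, z0, x1, z1) with x measured from the lateral image
    centre and z from the transducer face.  Circle: (cx, cz, r).
    """

    name: str
    shape: str  # "rect" | "circle"
    params: tuple

    def mask(self, image_shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        nrows, ncols = image_shape
        x = (np.arange(ncols) - (ncols - 1) / 2.0) * pixel_size
        z = np.arange(nrows) * pixel_size
        xg, zg = np.meshgrid(x, z)
        if self.shape == "rect":
            x0, z0, x1, z1 = self.params
            m = (xg >= x0) & (xg <= x1) & (zg >= z0) & (zg <= z1)
        elif self.shape == "circle":
            cx, cz, r = self.params
            m = (xg - cx) ** 2 + (zg - cz) ** 2 <= r**2
        else:
            raise ValueError(f"unknown ROI shape '{self.shape}'")
        if not m.any():
            raise ValueError(f"ROI '{self.name}' lies outside the image bounds")
        return m


@dataclass
class ModulusResult:
    """Bundle of output maps and bookkeeping for one elastography run."""

    E_map: np.ndarray
    nu_map: np.ndarray
    ct_map: np.ndarray
    count_map: np.ndarray
    frames_used: list[int]
    roi_summaries: pd.DataFrame
    performance: pd.DataFrame
    track_log: pd.DataFrame
    backend: str = ""
    extras: dict = field(default_factory=dict)


def frame_modulus_map(
    strain: StrainField,
    stress: StressField,
    gamma: float = 0.0,
    strain_floor: float = DEFAULT_STRAIN_FLOOR,
) -> np.ndarray:
    """Pixelwise linear Young's modulus for one frame.

    Compressive strain eps0 = -ezz (positive in compression); pixels with
    |eps0| below the floor, or invalid strain, are NaN.
    """
    eps0 = -strain.ezz
    E_app = modulus_from_stress_strain(stress.sigma_zz, eps0, strain_floor)
    if gamma > 0:
        with np.errstate(invalid="ignore"):
            E_app = E_app / np.exp(3.0 * gamma * np.square(eps0))
    return np.where(strain.valid_mask, E_app, np.nan)


def frame_nu_prime_map(
    strain: StrainField,
    strain_floor: float = DEFAULT_STRAIN_FLOOR,
) -> np.ndarray:
    """Pixelwise in-plane (2D) Poisson's ratio nu' = -exx / ezz, unclipped.

    Pixels with axial strain below the floor are NaN.  Kept unclipped so
    multi-frame averaging sees symmetric noise; conversion and report
    clipping happen once on the aggregated map.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        nu_prime = -strain.exx / strain.ezz
    nu_prime = np.where(np.abs(strain.ezz) >= strain_floor, nu_prime, np.nan)
    return np.where(strain.valid_mask, nu_prime, np.nan)


def frame_poisson_map(
    strain: StrainField,
    strain_floor: float = DEFAULT_STRAIN_FLOOR,
) -> np.ndarray:
    """Pixelwise 3D Poisson's ratio from the lateral/axial strain ratio.

    nu' = -exx / ezz, converted by nu = nu' / (1 - nu'); the reported map
    is clipped to the physically meaningful range [0, 0.5].  Pixels with
    axial strain below the floor are NaN.
    """
    nu_prime = frame_nu_prime_map(strain, strain_floor)
    nu = poisson_2d_to_3d(nu_prime)
    return np.clip(nu, 0.0, 0.5)


def mean_map(per_frame_maps: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Masked pixelwise mean over frames; returns (mean, per-pixel count)."""
    if not per_frame_maps:
        raise ValueError("no frame maps to average")
    stack = np.stack(per_frame_maps)
    count = np.sum(np.isfinite(stack), axis=0)
    total = np.nansum(stack, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    return mean, count


def roi_summary(
    map2d: np.ndarray,
    rois: list[ROI],
    pixel_size: float,
) -> pd.DataFrame:
    """Median / mean / std / pixel count of a map over each ROI."""
    rows = []
    for roi in rois:
        m = roi.mask(map2d.shape, pixel_size)
        vals = map2d[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI '{roi.name}' contains no valid pixels")
        rows.append(
            {
                "roi": roi.name,
                "median": float(np.median(vals)),
                "mean": float(np.mean(vals)),
                "std": float(np.std(vals)),
                "n_pixels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def spatial_cov(map2d: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Spatial coefficient of variation (std/mean) over valid pixels."""
    vals = map2d if mask is None else map2d[mask]
    vals = np.asarray(vals)[np.isfinite(np.asarray(vals))]
    if vals.size == 0:
        raise ValueError("no valid pixels")
    return float(np.std(vals) / np.mean(vals))


def shear_speed_map(E_map: np.ndarray, nu_map: np.ndarray, rho: float = 1000.0) -> np.ndarray:
    """c_t map from the modulus and Poisson maps (NaN-propagating)."""
    with np.errstate(invalid="ignore"):
        return shear_wave_speed(E_map, np.where(np.isfinite(nu_map), nu_map, 0.495), rho)
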