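"""Internal axial stress under a uniformly loaded rectangle (Love's solution).

A rigid rectangular compressor of footprint 2a x 2b pressing with uniform
pressure p on an elastic half-space produces, at an interior point
(x, y, z > 0), the axial stress

    sigma_zz = (1 / 2 pi) * (dV/dz - z * d2V/dz2)

where V is the Newtonian potential of the loaded area.  dV/dz = -p * Omega
with Omega the solid angle the rectangle subtends at the point, written as
2 pi minus four arccos corner terms; d2V/dz2 collects corner-distance
terms.  Directly under the load as z -> 0 the solid angle tends to 2 pi
and |sigma_zz| -> p.

The finite specimen resting on a rigid base is approximated by
superposing a second ("bottom") compressor the size of the base plate,
mirrored to press upward, scaled by the area ratio A1/A2:

    sigma_total = sigma_top + (A1 / A2) * sigma_bottom.

A plane-stress baseline (uniform sigma_zz = F / A1 everywhere) is
provided for comparison.  All formulas are cross-checked against adaptive
quadrature of the Boussinesq point-load kernel.

Sign convention: the map-building functions return *compressive
magnitudes* (positive Pa); the low-level ``love_sigma_zz`` keeps the
natural negative sign of compression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import dblquad

from .materials import Geometry

__all__ = [
    "StressField",
    "love_omega",
    "love_sigma_zz",
    "boussinesq_oracle",
    "love_stress_map",
    "superpose_compressors",
    "plane_stress_field",
]

#: Depth floor (m) used to evaluate nominal z = 0 "surface" pixels.
Z_FLOOR = 1e-9


@dataclass
class StressField:
    """Axial stress magnitude per image pixel (Pa), with its provenance."""

    sigma_zz: np.ndarray
    pressure_p: float
    geometry: Geometry
    model: str = "love"


def _check_z(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("Love's solution requires z > 0; use Z_FLOOR for surface pixels")
    return z


def love_omega(x, y, z, a: float, b: float) -> np.ndarray:
    """Solid angle subtended by the rectangle [-a,a]x[-b,b] at (x, y, z).

    The arccos arguments are clamped to [-1, 1] against rounding.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = _check_z(z)
    total = 2.0 * np.pi
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            ax = a + sx * x
            by = b + sy * y
            arg = ax * by / np.sqrt((ax * ax + z * z) * (by * by + z * z))
            total = total - np.arccos(np.clip(arg, -1.0, 1.0))
    return total


def _d2v_dz2(x, y, z, a: float, b: float, p: float) -> np.ndarray:
    """Second depth derivative of the Newtonian potential, times p.

    a1, b2, c3, d4 are the distances from the observation point to the
    four footprint corners A=(a, b), B=(-a, b), C=(-a, -b), D=(a, -b);
    the pairing below is fixed by agreement with the Boussinesq
    quadrature oracle to machine precision.
    """
    am = a - x
    ap = a + x
    bm = b - y
    bp = b + y
    z2 = z * z
    a1 = np.sqrt(am * am + bm * bm + z2)
    b2 = np.sqrt(ap * ap + bm * bm + z2)
    c3 = np.sqrt(ap * ap + bp * bp + z2)
    d4 = np.sqrt(am * am + bp * bp + z2)
    t = (
        am / (am * am + z2) * (bm / a1 + bp / d4)
        + ap / (ap * ap + z2) * (bm / b2 + bp / c3)
        + bm / (bm * bm + z2) * (am / a1 + ap / b2)
        + bp / (bp * bp + z2) * (am / d4 + ap / c3)
    )
    return p * t


def love_sigma_zz(x, y, z, a: float, b: float, p: float) -> np.ndarray:
    """Signed axial stress (negative = compressive) at (x, y, z)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = _check_z(z)
    dv_dz = -p * love_omega(x, y, z, a, b)
    d2v = _d2v_dz2(x, y, z, a, b, p)
    return (dv_dz - z * d2v) / (2.0 * np.pi)


def boussinesq_oracle(x: float, y: float, z: float, a: float, b: float, p: float) -> float:
    """Axial stress magnitude by adaptive quadrature of the point-load kernel.

    Integrates 3 p z^3 / (2 pi R^5) over the loaded rectangle; serves as
    the independent numerical truth for :func:`love_sigma_zz`.
    """
    if z <= 0:
        raise ValueError("z must be > 0")

    def integrand(ys: float, xs: float) -> float:
        r2 = (x - xs) ** 2 + (y - ys) ** 2 + z * z
        return 3.0 * z**3 / (2.0 * np.pi * r2**2.5)

    val, err = dblquad(integrand, -a, a, -b, b, epsabs=1e-13, epsrel=1e-10)
    if not np.isfinite(val) or (val > 1e-6 and err > 1e-4 * val):
        raise RuntimeError(f"quadrature did not converge (value {val}, err {err})")
    return p * val


def _image_grid(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, z) coordinates of image pixels: x centred laterally,
    z = depth from the transducer face, floored at Z_FLOOR."""
    nrows, ncols = shape
    xs = (np.arange(ncols) - (ncols - 1) / 2.0) * pixel_size
    zs = np.arange(nrows) * pixel_size
    zs = np.maximum(zs, Z_FLOOR)
    return np.meshgrid(xs, zs)


def love_stress_map(
    geometry: Geometry,
    shape: tuple[int, int],
    force: float,
    superpose: bool = True,
) -> StressField:
    """Compressive |sigma_zz| on the image plane (y = 0) for applied force F.

    The image plane passes through the transducer's long axis; the
    pressure is p = F / A1.  With ``superpose`` the bottom-plate mirror
    compressor is added per the A1/A2 superposition rule.
    """
    p = force / geometry.footprint_area
    xg, zg = _image_grid(shape, geometry.pixel_size)
    top = -love_sigma_zz(xg, 0.0, zg, geometry.half_width_a, geometry.half_depth_b, p)
    sigma = top
    if superpose:
        z_from_bottom = np.maximum(geometry.specimen_height - zg, Z_FLOOR)
        bottom = -love_sigma_zz(
            xg, 0.0, z_from_bottom, geometry.base_width / 2.0,
            geometry.base_depth / 2.0, p,
        )
        sigma = top + (geometry.footprint_area / geometry.base_area) * bottom
    return StressField(sigma_zz=sigma, pressure_p=p, geometry=geometry, model="love")


def superpose_compressors(sigma_top: StressField, force: float, geometry: Geometry) -> StressField:
    """Add the mirrored base-plate compressor to a top-only stress field.

    The bottom field is Love's solution for a base-sized rectangle with
    the same pressure p = F / A1, evaluated at the depth measured upward
    from the specimen bottom, scaled by A1/A2 so the bottom compressor
    carries the full reaction force.
    """
    p = force / geometry.footprint_area
    xg, zg = _image_grid(sigma_top.sigma_zz.shape, geometry.pixel_size)
    z_from_bottom = np.maximum(geometry.specimen_height - zg, Z_FLOOR)
    bottom = -love_sigma_zz(
        xg, 0.0, z_from_bottom, geometry.base_width / 2.0, geometry.base_depth / 2.0, p
    )
    total = sigma_top.sigma_zz + (geometry.footprint_area / geometry.base_area) * bottom
    return StressField(sigma_zz=total, pressure_p=p, geometry=geometry, model="love")


def plane_stress_field(force: float, geometry: Geometry, shape: tuple[int, int]) -> StressField:
    """Uniform-stress baseline: sigma_zz = F / A1 everywhere."""
    p = force / geometry.footprint_area
    return StressField(
        sigma_zz=np.full(shape, p, dtype=float), pressure_p=p,
        geometry=geometry, model="plane",
    )
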