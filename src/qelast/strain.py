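"""Strain from displacement fields via a 2D Savitzky-Golay differentiator.

The strain tensor components are the raw displacement-gradient entries
(no symmetrization): exx = dux/dx, exz = dux/dz, ezx = duz/dx and
ezz = duz/dz.  Differentiation uses a separable least-squares
first-derivative kernel of half-width M: within each (2M+1) x (2M+1)
window a plane is fitted to the displacement component and its slope
along the derivative axis is returned.  This simultaneously smooths
(averaging across the perpendicular axis) and differentiates, and is
*exact* for displacement fields linear along the derivative axis.

The kernel entry at offset x from the centre column is

    h(x) = 3 x / ((2M+1)^2 M (M+1) GS)

identical in every row; GS is the grid step (pixel size in metres when
physical strains are wanted).  Only the "valid" part of the convolution
is kept: an M-pixel border is cropped and masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d, map_coordinates

from .flow import DisplacementField

__all__ = [
    "StrainField",
    "sg_kernel",
    "strain_component",
    "strain_from_displacement",
    "strain_sequence",
    "warp_field_to_reference",
]


@dataclass
class StrainField:
    """Four displacement-gradient components on the full frame grid.

    Entries outside ``valid_mask`` (an M-pixel filter-support border, plus
    any invalid displacement pixels) are NaN.
    """

    exx: np.ndarray
    exz: np.ndarray
    ezx: np.ndarray
    ezz: np.ndarray
    valid_mask: np.ndarray
    frame_pair: tuple[int, int] = (0, 0)


def sg_kernel(M: int, GS: float = 1.0) -> np.ndarray:
    """(2M+1) x (2M+1) least-squares first-derivative kernel (column axis).

    Correlating a field with this kernel estimates d/dx (x = column
    offset) averaged over 2M+1 rows.  Entries sum to zero; correlation
    with a linear ramp c*x returns c exactly.
    """
    M = int(M)
    if M < 1:
        raise ValueError("filter half-width M must be >= 1")
    if GS <= 0:
        raise ValueError("grid step GS must be > 0")
    x = np.arange(-M, M + 1, dtype=float)
    row = 3.0 * x / ((2 * M + 1) ** 2 * M * (M + 1) * GS)
    return np.tile(row, (2 * M + 1, 1))


def strain_component(u: np.ndarray, axis: str, M: int, GS: float = 1.0) -> np.ndarray:
    """Differentiate one displacement component along ``axis`` ('x' or 'z').

    Returns a full-size array with the M-pixel border NaN-masked (valid
    convolution only).  Rows are z (axial), columns x (lateral).
    """
    u = np.asarray(u, dtype=float)
    M = int(M)
    if axis == "x":
        deriv_ax, avg_ax = 1, 0
    elif axis == "z":
        deriv_ax, avg_ax = 0, 1
    else:
        raise ValueError("axis must be 'x' or 'z'")
    if u.shape[0] < 2 * M + 1 or u.shape[1] < 2 * M + 1:
        raise ValueError(f"field shape {u.shape} smaller than kernel width {2 * M + 1}")
    # The 2D kernel is separable: derivative row (already fully normalized,
    # including the 1/(2M+1) row averaging) along one axis, plain summation
    # along the other.  ndimage.correlate1d applies weights unflipped, which
    # is exactly the correlation sum of the estimator.
    row = sg_kernel(M, GS)[0]
    core = correlate1d(u, row, axis=deriv_ax, mode="constant")
    core = correlate1d(core, np.ones(2 * M + 1), axis=avg_ax, mode="constant")
    out = np.full(u.shape, np.nan)
    out[M:-M, M:-M] = core[M:-M, M:-M]
    return out


def strain_from_displacement(u: DisplacementField, M: int, GS: float) -> StrainField:
    """All four gradient components of a displacement field.

    ``GS`` is the physical grid step (m); displacement pixel values are
    converted to metres with the same step, so the output is a
    dimensionless strain.
    """
    M = int(M)
    ux_m = u.ux * GS
    uz_m = u.uz * GS
    exx = strain_component(ux_m, "x", M, GS)
    exz = strain_component(ux_m, "z", M, GS)
    ezx = strain_component(uz_m, "x", M, GS)
    ezz = strain_component(uz_m, "z", M, GS)
    mask = np.isfinite(ezz) & u.valid
    for comp in (exx, exz, ezx):
        mask &= np.isfinite(comp)
    for comp in (exx, exz, ezx, ezz):
        comp[~mask] = np.nan
    return StrainField(exx=exx, exz=exz, ezx=ezx, ezz=ezz, valid_mask=mask,
                       frame_pair=(u.reference_index, u.target_index))


def strain_sequence(
    displacements: list[DisplacementField],
    pairing: str = "cumulative",
    M: int = 5,
    GS: float = 1.0,
) -> list[StrainField]:
    """Differentiate a sequence of cumulative displacement fields.

    ``pairing='cumulative'`` differentiates each frame-0 -> k field
    directly (total strain, fed to the modulus stage).
    ``pairing='incremental'`` differentiates the per-frame increments
    u_k - u_{k-1}; since both cumulative fields live on the frame-0
    material grid, their difference is exactly the incremental
    displacement of each material point (used by the performance
    descriptor's frame pairing).
    """
    if not displacements:
        raise ValueError("need at least one displacement field")
    if pairing == "cumulative":
        return [strain_from_displacement(u, M, GS) for u in displacements]
    if pairing != "incremental":
        raise ValueError("pairing must be 'cumulative' or 'incremental'")
    out = []
    prev_ux = np.zeros_like(displacements[0].ux)
    prev_uz = np.zeros_like(displacements[0].uz)
    prev_idx = displacements[0].reference_index
    for u in displacements:
        du = DisplacementField(
            ux=u.ux - prev_ux, uz=u.uz - prev_uz,
            reference_index=prev_idx, target_index=u.target_index,
            cumulative=False, valid=u.valid,
        )
        s = strain_from_displacement(du, M, GS)
        s.frame_pair = (prev_idx, u.target_index)
        out.append(s)
        prev_ux, prev_uz, prev_idx = u.ux, u.uz, u.target_index
    return out


def warp_field_to_reference(field: np.ndarray, u: DisplacementField) -> np.ndarray:
    """Transport a per-pixel map into the reference configuration.

    Samples ``field`` at the displaced positions ``x + u(x)`` of each
    reference pixel; out-of-domain or NaN-adjacent samples become NaN.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != u.shape:
        raise ValueError("field and displacement must share a shape")
    rows, cols = np.mgrid[0 : field.shape[0], 0 : field.shape[1]].astype(float)
    rr = rows + u.uz
    cc = cols + u.ux
    nan_mask = ~np.isfinite(field)
    filled = np.where(nan_mask, 0.0, field)
    out = map_coordinates(filled, [rr, cc], order=1, mode="nearest")
    # a sample is invalid if it draws on any NaN neighbour or leaves the domain
    bad = map_coordinates(nan_mask.astype(float), [rr, cc], order=1, mode="nearest") > 0
    inside = (rr >= 0) & (rr <= field.shape[0] - 1) & (cc >= 0) & (cc <= field.shape[1] - 1)
    out[bad | ~inside | ~u.valid] = np.nan
    return out
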