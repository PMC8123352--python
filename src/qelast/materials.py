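"""Material model, geometry and the scalar elasticity relations.

The package treats the specimen as an isotropic, nearly incompressible,
linear-elastic solid described by its Young's modulus ``E`` and Poisson's
ratio ``nu`` (shear modulus ``G = E / (2 (1 + nu))``).  Mild strain
hardening of gelatin-like materials is modelled through an exponential
apparent modulus ``E_NL = E * exp(3 * gamma * eps0**2)`` controlled by a
dimensionless non-linearity parameter ``gamma``.

Sign convention
---------------
Compressive axial stress and compressive axial strain are handled as
*positive* scalars in the modulus formulas; raw displacement-gradient
fields keep their natural (negative-in-compression) signs.

Units are SI throughout: metres, pascals, newtons, seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElasticMaterial",
    "Geometry",
    "Frame",
    "modulus_from_stress_strain",
    "nonlinear_modulus",
    "poisson_2d_to_3d",
    "poisson_3d_to_2d",
    "shear_wave_speed",
    "DEFAULT_STRAIN_FLOOR",
]

#: Below this compressive-strain magnitude, modulus pixels are masked
#: (returned as NaN) instead of dividing by a near-zero strain.
DEFAULT_STRAIN_FLOOR = 1e-4


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic material with optional strain hardening.

    Parameters
    ----------
    young_modulus : float
        Young's modulus E in Pa, > 0.
    poisson_ratio : float
        Three-dimensional Poisson's ratio, in [0, 0.5).
    nonlinearity_gamma : float
        Exponential hardening parameter, >= 0.  0 means purely linear.
    density : float
        Mass density in kg/m^3 (used for shear-wave-speed conversion).
    """

    young_modulus: float
    poisson_ratio: float = 0.495
    nonlinearity_gamma: float = 0.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.young_modulus) or self.young_modulus <= 0:
            raise ValueError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError(
                f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}"
            )
        if self.nonlinearity_gamma < 0:
            raise ValueError("nonlinearity_gamma must be >= 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def shear_modulus(self) -> float:
        """G = E / (2 (1 + nu)), always positive for valid parameters."""
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))


@dataclass(frozen=True)
class Geometry:
    """Specimen / transducer geometry.

    All lengths in metres.  ``transducer_width`` x ``transducer_depth`` is
    the full rectangular footprint (2a x 2b in the stress solution);
    ``base_width`` x ``base_depth`` the specimen's base plate contact.
    """

    transducer_width: float = 0.038
    transducer_depth: float = 0.008
    base_width: float = 0.045
    base_depth: float = 0.025
    specimen_height: float = 0.025
    pixel_size: float = 0.045e-3

    def __post_init__(self) -> None:
        for name in (
            "transducer_width",
            "transducer_depth",
            "base_width",
            "base_depth",
            "specimen_height",
            "pixel_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.footprint_area > self.base_area:
            raise ValueError("transducer footprint exceeds base area")

    @property
    def half_width_a(self) -> float:
        return self.transducer_width / 2.0

    @property
    def half_depth_b(self) -> float:
        return self.transducer_depth / 2.0

    @property
    def footprint_area(self) -> float:
        """Compressing area A1 = 2a * 2b."""
        return self.transducer_width * self.transducer_depth

    @property
    def base_area(self) -> float:
        """Base contact area A2."""
        return self.base_width * self.base_depth


@dataclass
class Frame:
    """One grayscale B-mode frame of a CINE sequence.

    ``image`` rows run along the axial (depth, z) direction increasing
    downward from the transducer face; columns along the lateral (x)
    direction.  Physical coordinates are ``index * pixel_size`` (pixel
    centres, 0-based).
    """

    image: np.ndarray
    pixel_size: float
    time: float
    index: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"frame image must be 2D, got ndim={self.image.ndim}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError(f"frame {self.index} contains non-finite intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def modulus_from_stress_strain(sigma0, eps0, strain_floor: float = DEFAULT_STRAIN_FLOOR):
    """Young's modulus E = sigma0 / eps0 (compressive-positive scalars).

    Elementwise over arrays.  Where ``|eps0| < strain_floor`` the result is
    masked with NaN rather than allowed to blow up.
    """
    sigma0 = np.asarray(sigma0, dtype=float)
    eps0 = np.asarray(eps0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sigma0 / eps0
    out = np.where(np.abs(eps0) >= strain_floor, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def nonlinear_modulus(E, eps0, gamma):
    """Apparent (strain-hardened) modulus E * exp(3 * gamma * eps0**2).

    Valid for small strains (|eps0| << 1); for gamma = 0 or eps0 = 0 it
    reduces to E.
    """
    E = np.asarray(E, dtype=float)
    out = E * np.exp(3.0 * gamma * np.square(np.asarray(eps0, dtype=float)))
    if out.ndim == 0:
        return float(out)
    return out


def poisson_2d_to_3d(nu_prime):
    """Convert the in-plane (2D) Poisson's ratio to the 3D one.

    nu = nu' / (1 - nu').  The in-plane ratio observable in a single image
    plane underestimates the volumetric ratio; nu' = 1/3 maps to the
    incompressible limit nu = 0.5.  Scalars with nu' >= 1 raise; arrays
    mask such entries with NaN.
    """
    arr = np.asarray(nu_prime, dtype=float)
    if arr.ndim == 0:
        if arr >= 1.0:
            raise ValueError(f"nu_prime must be < 1, got {float(arr)}")
        return float(arr / (1.0 - arr))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = arr / (1.0 - arr)
    return np.where(arr < 1.0, out, np.nan)


def poisson_3d_to_2d(nu):
    """Inverse conversion: nu' = nu / (1 + nu)."""
    arr = np.asarray(nu, dtype=float)
    out = arr / (1.0 + arr)
    if out.ndim == 0:
        return float(out)
    return out


def shear_wave_speed(E, nu, rho: float = 1000.0):
    """Shear wave speed c_t = sqrt(E / (2 rho (1 + nu))) = sqrt(G / rho).

    Converts the quasi-static modulus into the clinically familiar
    shear-wave velocity under the same material model.
    """
    E = np.asarray(E, dtype=float)
    out = np.sqrt(E / (2.0 * rho * (1.0 + np.asarray(nu, dtype=float))))
    if out.ndim == 0:
        return float(out)
    return out
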