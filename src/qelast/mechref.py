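"""Mechanical reference estimators: bonded-block compression and indentation.

Compression test: a plate larger than the specimen compresses a bonded
rubber-like block.  With stretch ratio lambda = (H - delta) / H and
engineering stress sigma = F / A, the modulus of a block bonded on one
loaded surface follows

    E = 3 sigma / ((lambda^-2 - lambda) * Z),      Z = 1 + 2 S^2,

where S is the ratio of one bonded surface to the force-free surface.

Indentation test: the (rectangular) ultrasound transducer acts as the
indenter.  The contact stiffness dF/d(delta) of the post-contact linear
region gives the indentation modulus via the generalized
Bulychev-Alekhin-Shorshorov relation

    dF/d(delta) = (2 / sqrt(pi)) * phi_c * sqrt(A) * M3',

with contact area A and shape factor phi_c (1.016 for a rectangular
indenter); the Young's modulus is E = M3' * (1 - nu^2).

Both estimators detect the contact point as the first sample whose force
reaches a threshold (default 0.1 N), re-zero displacements there, and
fit the post-contact region (strains up to 15 %) by least squares
through the contact point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LoadCurve",
    "IndenterSpec",
    "detect_contact",
    "compression_modulus",
    "indentation_modulus",
    "make_compression_curve",
    "make_indentation_curve",
]

DEFAULT_CONTACT_FORCE = 0.1  # N
MAX_COMPRESSION_STRAIN = 0.15


@dataclass(frozen=True)
class LoadCurve:
    """Step positions (m, strictly increasing) and measured forces (N)."""

    displacements: np.ndarray
    forces: np.ndarray
    contact_threshold: float = DEFAULT_CONTACT_FORCE

    def __post_init__(self) -> None:
        object.__setattr__(self, "displacements",
                           np.asarray(self.displacements, dtype=float))
        object.__setattr__(self, "forces", np.asarray(self.forces, dtype=float))
        if self.displacements.size != self.forces.size:
            raise ValueError("displacements and forces must match in length")
        if not np.all(np.diff(self.displacements) > 0):
            raise ValueError("displacements must be strictly increasing")
        if np.any(self.forces < 0):
            raise ValueError("forces must be >= 0")


@dataclass(frozen=True)
class IndenterSpec:
    """Indenter contact area (m^2) and shape factor phi_c."""

    contact_area: float
    shape_factor_phi_c: float = 1.016

    def __post_init__(self) -> None:
        if self.contact_area <= 0:
            raise ValueError("contact_area must be > 0")
        if not 1.0 <= self.shape_factor_phi_c <= 1.1:
            raise ValueError("phi_c expected in [1.0, 1.1]")


def detect_contact(curve: LoadCurve) -> int:
    """First sample index whose force reaches the contact threshold."""
    hits = np.nonzero(curve.forces >= curve.contact_threshold)[0]
    if hits.size == 0:
        raise ValueError(
            f"force never reaches contact threshold {curve.contact_threshold} N "
            f"(max {curve.forces.max()} N)"
        )
    return int(hits[0])


def compression_modulus(
    curve: LoadCurve,
    height: float,
    area: float,
    S: float,
) -> float:
    """Bonded-block Young's modulus from a stepwise compression curve.

    Post-contact samples with stretch lambda in (1 - 15%, 1) are fitted
    by ordinary least squares through the contact point: the model
    predicts F = E * area * (lambda^-2 - lambda) * Z / 3, linear in E.
    """
    i0 = detect_contact(curve)
    delta = curve.displacements[i0:] - curve.displacements[i0]
    force = curve.forces[i0:] - curve.forces[i0]
    lam = (height - delta) / height
    keep = (lam < 1.0) & (lam >= 1.0 - MAX_COMPRESSION_STRAIN)
    if not np.any(keep):
        raise ValueError("no post-contact compressive points within the 15% strain range")
    Z = 1.0 + 2.0 * S * S
    g = area * (lam[keep] ** -2 - lam[keep]) * Z / 3.0  # dF/dE per point
    f = force[keep]
    E = float(np.sum(f * g) / np.sum(g * g))
    if E <= 0:
        raise ValueError("non-positive modulus estimate; check the load curve")
    return E


def indentation_modulus(
    curve: LoadCurve,
    spec: IndenterSpec,
    nu: float = 0.495,
    max_indent_strain: float | None = None,
    height: float | None = None,
) -> float:
    """Young's modulus from an indentation load curve via the BASh relation.

    The contact stiffness is the OLS slope of (F - F_contact) against
    (delta - delta_contact) through the origin over the post-contact
    region (optionally restricted to delta/height <= max_indent_strain).
    """
    i0 = detect_contact(curve)
    delta = curve.displacements[i0:] - curve.displacements[i0]
    force = curve.forces[i0:] - curve.forces[i0]
    if max_indent_strain is not None and height is not None:
        keep = delta / height <= max_indent_strain
        delta, force = delta[keep], force[keep]
    if np.count_nonzero(delta > 0) < 2:
        raise ValueError("need >= 3 post-contact points for the stiffness fit")
    slope = float(np.sum(force * delta) / np.sum(delta * delta))
    if slope <= 0:
        raise ValueError("non-positive contact stiffness")
    m3 = slope * np.sqrt(np.pi) / (2.0 * spec.shape_factor_phi_c * np.sqrt(spec.contact_area))
    return float(m3 * (1.0 - nu * nu))


def make_compression_curve(
    E: float,
    height: float,
    area: float,
    S: float,
    step: float = 0.2e-3,
    n_steps: int = 20,
    pre_travel: float = 0.4e-3,
    contact_threshold: float = DEFAULT_CONTACT_FORCE,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LoadCurve:
    """Synthetic compression load curve generated from the block model.

    ``pre_travel`` adds zero-force approach samples before contact; at
    contact the curve is offset by exactly the contact threshold so the
    detected contact point is the model origin.
    """
    rng = rng or np.random.default_rng()
    Z = 1.0 + 2.0 * S * S
    pre = np.arange(0.0, pre_travel, step)
    post = pre_travel + np.arange(0, n_steps + 1) * step
    lam = (height - (post - pre_travel)) / height
    f_model = E * area * (lam**-2 - lam) * Z / 3.0
    forces = np.concatenate([np.zeros_like(pre), contact_threshold + f_model])
    if noise_sigma > 0:
        forces = np.clip(forces + rng.normal(0, noise_sigma, forces.shape), 0, None)
        forces[: pre.size] = 0.0
        forces[pre.size] = contact_threshold  # keep the contact sample detectable
    return LoadCurve(np.concatenate([pre, post]), forces,
                     contact_threshold=contact_threshold)


def make_indentation_curve(
    M3_prime: float,
    spec: IndenterSpec,
    step: float = 0.2e-3,
    n_steps: int = 15,
    pre_travel: float = 0.4e-3,
    contact_threshold: float = DEFAULT_CONTACT_FORCE,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LoadCurve:
    """Synthetic indentation curve with stiffness set by the BASh relation."""
    rng = rng or np.random.default_rng()
    stiffness = 2.0 / np.sqrt(np.pi) * spec.shape_factor_phi_c * np.sqrt(spec.contact_area) * M3_prime
    pre = np.arange(0.0, pre_travel, step)
    post = pre_travel + np.arange(0, n_steps + 1) * step
    forces = np.concatenate(
        [np.zeros_like(pre), contact_threshold + stiffness * (post - pre_travel)]
    )
    if noise_sigma > 0:
        forces = np.clip(forces + rng.normal(0, noise_sigma, forces.shape), 0, None)
        forces[: pre.size] = 0.0
        forces[pre.size] = contact_threshold
    return LoadCurve(np.concatenate([pre, post]), forces,
                     contact_threshold=contact_threshold)
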