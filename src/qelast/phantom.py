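"""Synthetic tissue-mimicking phantom sequences with known ground truth.

Emulates the study conditions of a gelatin phantom under quasi-static
transducer compression: a speckle texture (point scatterers convolved
with a Gaussian point-spread function), compressed at 1 mm/s to 3 mm
depth on a 25 mm specimen, imaged at 43 frames/s, with a force log
consistent with the phantom's modulus field.  Homogeneous soft/hard
phantoms and an 8 mm cylindrical inclusion are supported.

Forward deformation model
-------------------------
Each image column behaves as a chain of springs in series carrying an
axial stress profile sigma(x, z) = p * phi(x, z):

* ``stress_model="love"`` (default): phi is the two-compressor Love
  stress shape the reconstruction stage also models, so the synthetic
  truth exercises the full depth-dependent stress physics and parameter
  recovery is well-posed; residual pipeline error is attributable to
  tracking and differentiation.
* ``stress_model="uniform"``: phi = 1 (the idealized uniform-axial-
  stress textbook case); useful for closed-form column-spring checks.

The compressive strain is eps(x, z) = sigma / E(x, z); the axial
displacement integrates eps upward from the fixed bottom, and the
lateral displacement integrates the in-plane expansion
-nu' * ezz outward from the image centre line (nu' = nu / (1 + nu)).
Strain fields are laterally smoothed over ~1 mm so inclusion edges do
not introduce displacement kinks sharper than real gelatin interfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates

from .flow import DisplacementField
from .io import ForceLog, write_cine, write_force_csv, write_map_tiff
from .materials import ElasticMaterial, Frame, Geometry
from .stress import love_stress_map

__all__ = ["PhantomSpec", "PhantomDataset", "make_speckle",
           "phantom_displacement_field", "render_sequence",
           "hard_phantom", "soft_phantom", "inclusion_phantom",
           "HARD_MODULUS_PA", "SOFT_MODULUS_PA"]

#: Lateral smoothing length (m) applied to the ground-truth strain field.
EDGE_SMOOTHING_M = 1e-3

#: Reference Young's moduli of the emulated stiff and soft gelatin
#: mixtures (medians of the mechanical reference measurements).
HARD_MODULUS_PA = 18.9e3
SOFT_MODULUS_PA = 6.92e3


@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition parameters of one synthetic phantom."""

    body: ElasticMaterial
    inclusion: ElasticMaterial | None = None
    inclusion_center: tuple[float, float] = (0.0, 12.5e-3)  # (x from centre, z) m
    inclusion_radius: float = 4e-3
    image_size_px: int = 556
    image_extent: float = 25e-3  # square image, width = height = specimen height
    compression_depth: float = 3e-3
    compression_speed: float = 1e-3
    frame_rate: float = 43.0
    n_frames: int | None = None
    scatterer_density: float = 0.05  # scatterers per pixel
    psf_sigma: float = 1.2  # px
    noise_level: float = 0.01
    stress_model: str = "love"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compression_depth > 0.15 * self.image_extent:
            raise ValueError("compression exceeds 15% of the specimen height")
        if self.inclusion is not None:
            cx, cz = self.inclusion_center
            half = self.image_extent / 2.0
            if (abs(cx) + self.inclusion_radius > half
                    or cz - self.inclusion_radius < 0
                    or cz + self.inclusion_radius > self.image_extent):
                raise ValueError("inclusion must lie inside the image")
        if self.stress_model not in ("love", "uniform"):
            raise ValueError("stress_model must be 'love' or 'uniform'")

    @property
    def pixel_size(self) -> float:
        return self.image_extent / self.image_size_px

    @property
    def geometry(self) -> Geometry:
        return Geometry(specimen_height=self.image_extent, pixel_size=self.pixel_size)

    @property
    def frame_times(self) -> np.ndarray:
        duration = self.compression_depth / self.compression_speed
        if self.n_frames is not None:
            if self.n_frames < 2:
                raise ValueError("n_frames must be >= 2")
            return np.linspace(0.0, duration, self.n_frames)
        n = int(np.floor(duration * self.frame_rate)) + 1
        return np.arange(n) / self.frame_rate

    def modulus_map(self) -> np.ndarray:
        """Ground-truth Young's modulus per pixel (Pa)."""
        n = self.image_size_px
        E = np.full((n, n), self.body.young_modulus)
        if self.inclusion is not None:
            x = (np.arange(n) - (n - 1) / 2.0) * self.pixel_size
            z = np.arange(n) * self.pixel_size
            xg, zg = np.meshgrid(x, z)
            cx, cz = self.inclusion_center
            inside = (xg - cx) ** 2 + (zg - cz) ** 2 <= self.inclusion_radius**2
            E[inside] = self.inclusion.young_modulus
        return E

    def fast(self, **overrides) -> "PhantomSpec":
        """256 x 256 preset with a ~2-of-8 temporal frame subsample."""
        duration = self.compression_depth / self.compression_speed
        kw = dict(image_size_px=256,
                  n_frames=max(2, int(np.floor(duration * self.frame_rate / 4))))
        kw.update(overrides)
        return self.replace(**kw)

    def replace(self, **kw) -> "PhantomSpec":
        from dataclasses import replace

        return replace(self, **kw)


def hard_phantom(seed: int = 1, **overrides) -> PhantomSpec:
    """Homogeneous stiff-mixture phantom at the reference modulus."""
    return PhantomSpec(body=ElasticMaterial(HARD_MODULUS_PA, 0.495), seed=seed,
                       **overrides)


def soft_phantom(seed: int = 2, **overrides) -> PhantomSpec:
    """Homogeneous soft-mixture phantom at the reference modulus."""
    return PhantomSpec(body=ElasticMaterial(SOFT_MODULUS_PA, 0.495), seed=seed,
                       **overrides)


def inclusion_phantom(seed: int = 3, **overrides) -> PhantomSpec:
    """Soft body with a stiff 8 mm cylindrical inclusion at image centre."""
    return PhantomSpec(
        body=ElasticMaterial(SOFT_MODULUS_PA, 0.495),
        inclusion=ElasticMaterial(HARD_MODULUS_PA, 0.495),
        seed=seed, **overrides,
    )


def make_speckle(
    shape: tuple[int, int],
    density: float = 0.05,
    psf_sigma: float = 1.2,
    seed: int = 0,
) -> np.ndarray:
    """Fully developed speckle: log-normal point scatterers blurred by a PSF.

    ``density`` is the expected number of scatterers per pixel; the
    result is normalized to [0, 1] and reproducible from ``seed``.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    rng = np.random.default_rng(seed)
    n_scatter = rng.poisson(density * shape[0] * shape[1])
    img = np.zeros(shape, dtype=float)
    rows = rng.uniform(0, shape[0] - 1, n_scatter)
    cols = rng.uniform(0, shape[1] - 1, n_scatter)
    amps = rng.lognormal(0.0, 0.5, n_scatter)
    # bilinear deposition so sub-pixel scatterer positions matter
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (1, 0, fr * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 1, fr * fc),
    ):
        np.add.at(img, (np.clip(r0 + dr, 0, shape[0] - 1),
                        np.clip(c0 + dc, 0, shape[1] - 1)), amps * w)
    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma)
    peak = img.max()
    if peak > 0:
        img /= peak
    return img


def _strain_profile(spec: PhantomSpec, applied_compression: float) -> dict:
    """Compressive-strain field and surface pressure for one compression depth."""
    n = spec.image_size_px
    dz = spec.pixel_size
    E = spec.modulus_map()
    d = applied_compression

    if spec.stress_model == "uniform":
        compliance = np.sum(dz / E, axis=0)  # per column
        sigma0 = d / compliance  # Pa per column
        eps = sigma0[None, :] / E
        # force: per-column stress over the footprint; columns beyond the
        # image carry body material
        sigma_body = d / (n * dz / spec.body.young_modulus)
        geo = spec.geometry
        w_img = n * dz
        mean_sigma = (
            np.mean(sigma0) * min(w_img, geo.transducer_width)
            + sigma_body * max(geo.transducer_width - w_img, 0.0)
        ) / geo.transducer_width
        force = mean_sigma * geo.footprint_area
        pressure = mean_sigma
    else:
        geo = spec.geometry
        phi = love_stress_map(geo, (n, n), geo.footprint_area, superpose=True).sigma_zz
        # calibration column: body material, off the inclusion
        cal = n // 2 if spec.inclusion is None else n // 8
        compliance = np.sum(phi[:, cal] / E[:, cal]) * dz
        pressure = d / compliance
        eps = pressure * phi / E
        force = pressure * geo.footprint_area

    eps = gaussian_filter1d(eps, EDGE_SMOOTHING_M / 2.0 / dz, axis=1)
    return {"eps": eps, "force": float(force), "pressure": float(pressure), "E": E}


def phantom_displacement_field(
    spec: PhantomSpec, applied_compression: float
) -> tuple[DisplacementField, dict]:
    """Analytic displacement field and ground-truth bundle at one depth.

    Returns the field in pixel units on the undeformed grid plus a dict
    with the signed ground-truth axial strain ``ezz`` (negative in
    compression), the modulus map, the surface pressure and force.
    """
    prof = _strain_profile(spec, applied_compression)
    eps = prof["eps"]
    n = spec.image_size_px
    dz = spec.pixel_size

    # axial, in transducer-attached image coordinates: the transducer face
    # (row 0) is the moving origin of a B-mode frame, so the contact
    # surface stays at the top and deeper material moves *up* by up to the
    # applied compression at the (lab-fixed) bottom.  Integrate the lab
    # displacement upward from the fixed bottom, then subtract the rigid
    # transducer travel.
    uz_m = np.flip(np.cumsum(np.flip(eps, axis=0), axis=0), axis=0) * dz
    uz_m = uz_m - applied_compression
    # lateral: in-plane expansion nu' * eps away from the centre line
    nu_prime = spec.body.poisson_ratio / (1.0 + spec.body.poisson_ratio)
    centre = (n - 1) / 2.0
    cs = np.cumsum(eps, axis=1) * dz
    cs_centre = _interp_columns(cs, centre)
    ux_m = nu_prime * (cs - cs_centre[:, None])

    u = DisplacementField(
        ux=ux_m / dz, uz=uz_m / dz, reference_index=0, target_index=-1, cumulative=True
    )
    truth = {
        "ezz": -eps,
        "E_map": prof["E"],
        "force": prof["force"],
        "pressure": prof["pressure"],
        "nu": spec.body.poisson_ratio,
        "nu_prime": nu_prime,
    }
    return u, truth


def _interp_columns(arr: np.ndarray, col: float) -> np.ndarray:
    c0 = int(np.floor(col))
    f = col - c0
    if c0 + 1 >= arr.shape[1]:
        return arr[:, c0]
    return (1 - f) * arr[:, c0] + f * arr[:, c0 + 1]


@dataclass
class PhantomDataset:
    """Rendered CINE frames, force log and ground truth of one phantom."""

    spec: PhantomSpec
    frames: list[Frame]
    force_log: ForceLog
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stack = [
            Frame(image=(f.image * 65535).astype(np.uint16), pixel_size=f.pixel_size,
                  time=f.time, index=f.index)
            for f in self.frames
        ]
        write_cine(outdir / "cine.tiff", stack)
        write_force_csv(outdir / "force.csv", self.force_log)
        write_map_tiff(outdir / "truth_E.tiff", self.truth["E_map"])
        write_map_tiff(outdir / "truth_ezz_final.tiff", self.truth["ezz"])
        meta = {
            "pixel_size_m": self.spec.pixel_size,
            "frame_times_s": [f.time for f in self.frames],
            "seed": self.spec.seed,
            "stress_model": self.spec.stress_model,
            "body_E_Pa": self.spec.body.young_modulus,
            "inclusion_E_Pa": (
                None if self.spec.inclusion is None
                else self.spec.inclusion.young_modulus
            ),
            "nu": self.spec.body.poisson_ratio,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
        return outdir


def _invert_field(ux: np.ndarray, uz: np.ndarray, n_iter: int = 3):
    """Fixed-point inverse of a (smooth) forward displacement field."""
    rows, cols = np.mgrid[0 : ux.shape[0], 0 : ux.shape[1]].astype(float)
    vx = ux.copy()
    vz = uz.copy()
    for _ in range(n_iter):
        rr = rows - vz
        cc = cols - vx
        vx = map_coordinates(ux, [rr, cc], order=1, mode="nearest")
        vz = map_coordinates(uz, [rr, cc], order=1, mode="nearest")
    return vx, vz


def render_sequence(spec: PhantomSpec) -> PhantomDataset:
    """Render the full CINE sequence, force log and ground-truth bundle.

    The reference speckle is warped per frame by the analytic field
    (deformation scales linearly with the instantaneous compression
    depth); frames carry independent additive Gaussian noise.  The force
    follows the phantom's effective stiffness; a non-zero hardening
    gamma of the body material multiplies the force by
    exp(3 * gamma * eps0^2) at the nominal surface strain eps0.
    """
    n = spec.image_size_px
    rng = np.random.default_rng(spec.seed)
    speckle = make_speckle((n, n), spec.scatterer_density, spec.psf_sigma,
                           seed=int(rng.integers(2**31)))
    noise_rng = np.random.default_rng(int(rng.integers(2**31)))

    unit_u, truth = phantom_displacement_field(spec, spec.compression_depth)
    times = spec.frame_times
    depths = np.minimum(spec.compression_speed * times, spec.compression_depth)
    scales = depths / spec.compression_depth

    frames: list[Frame] = []
    for k, (t, s) in enumerate(zip(times, scales)):
        if s == 0:
            img = speckle.copy()
        else:
            vx, vz = _invert_field(unit_u.ux * s, unit_u.uz * s)
            rows, cols = np.mgrid[0:n, 0:n].astype(float)
            img = map_coordinates(speckle, [rows - vz, cols - vx], order=1,
                                  mode="nearest")
        if spec.noise_level > 0:
            img = img + noise_rng.normal(0.0, spec.noise_level, img.shape)
        img = np.clip(img, 0.0, 1.0)
        frames.append(Frame(image=img, pixel_size=spec.pixel_size, time=float(t),
                            index=k))

    # force log at 100 Hz over the compression, nonlinear hardening optional
    t_log = np.arange(0.0, times[-1] + 0.01, 0.01)
    d_log = np.minimum(spec.compression_speed * t_log, spec.compression_depth)
    f_lin = truth["force"] * d_log / spec.compression_depth
    gamma = spec.body.nonlinearity_gamma
    if gamma > 0:
        eps0 = d_log / spec.image_extent
        f_lin = f_lin * np.exp(3.0 * gamma * eps0**2)
    force_log = ForceLog(times=t_log, forces=f_lin)

    truth = dict(truth)
    truth["unit_displacement"] = unit_u
    truth["scales"] = scales
    truth["depths"] = depths
    return PhantomDataset(spec=spec, frames=frames, force_log=force_log, truth=truth)
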