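"""Reading CINE sequences, force logs and run configuration; writing results.

Supported CINE dialects: a directory of ordered single-frame PNG/TIFF
images, or one multipage TIFF.  RGB input is converted to grayscale by
luminance.  The force log is a two-column CSV ``time_s,force_n`` with a
header and '.' decimal separator.  Output maps are written as 32-bit
float TIFFs, ROI summaries as CSV, configuration as YAML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from imageio import v3 as iio

from .materials import Frame, Geometry

logger = logging.getLogger(__name__)

__all__ = [
    "ForceLog",
    "RunConfig",
    "read_cine",
    "read_force_csv",
    "resample_force_to_frames",
    "write_map_tiff",
    "read_map_tiff",
]

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class ForceLog:
    """Load-cell record: times (s, strictly increasing) and forces (N)."""

    times: np.ndarray
    forces: np.ndarray
    max_plausible_force: float = 50.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "forces", np.asarray(self.forces, dtype=float))
        if self.times.size != self.forces.size or self.times.size < 2:
            raise ValueError("force log needs >= 2 matching samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("force-log times must be strictly increasing")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("force log contains non-finite forces")
        if np.any(self.forces < -1e-9) or np.any(self.forces > self.max_plausible_force):
            raise ValueError(
                f"forces outside plausibility bound [0, {self.max_plausible_force}] N"
            )


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the raw data."""

    geometry: Geometry = field(default_factory=Geometry)
    gamma: float = 0.0
    nu_assumed: float = 0.495
    density: float = 1000.0
    rho_min: float = 0.9
    p_min: float = 0.9
    filter_half_width_M: int = 5
    blur_sigma: float = 1.0
    flow_backend: str = "hybrid"
    strain_floor: float = 1e-4
    stress_model: str = "love"  # "love" or "plane"
    # Image rows within the maximum compression travel of the base plate
    # show material that leaves the specimen during the sequence (the
    # plate interface rises through them); they are untrackable and are
    # excluded from the analysis. Default equals the 3 mm protocol travel.
    bottom_exclusion_m: float = 3e-3
    rois: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_min <= 1.0 and self.rho_min != 0.0:
            raise ValueError("rho_min must be in (0, 1] (or exactly 0 to disable)")
        if not 0.0 <= self.p_min <= 1.0:
            raise ValueError("p_min must be in [0, 1]")
        if int(self.filter_half_width_M) < 1:
            raise ValueError("filter_half_width_M must be an integer >= 1")
        self.filter_half_width_M = int(self.filter_half_width_M)
        if self.stress_model not in ("love", "plane"):
            raise ValueError("stress_model must be 'love' or 'plane'")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        d["rois"] = [
            {"name": r.name, "shape": r.shape, "params": list(r.params)}
            if hasattr(r, "params") else dict(r)
            for r in self.rois
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .modulus import ROI

        d = yaml.safe_load(Path(path).read_text())
        geo = d.pop("geometry", None)
        rois = d.pop("rois", [])
        cfg = cls(**d)
        if geo is not None:
            cfg.geometry = Geometry(**geo)
        cfg.rois = [ROI(r["name"], r["shape"], tuple(r["params"])) for r in rois]
        return cfg


def _to_grayscale(img: np.ndarray, source: str) -> np.ndarray:
    if img.ndim == 3:
        if img.shape[-1] in (3, 4):
            logger.info("converting RGB frame %s to grayscale by luminance", source)
            return img[..., :3].astype(float) @ _LUMA
        raise ValueError(f"cannot interpret frame shape {img.shape} from {source}")
    if img.ndim != 2:
        raise ValueError(f"cannot interpret frame shape {img.shape} from {source}")
    return img


def read_cine(path, pixel_size: float, frame_rate: float = 43.0) -> list[Frame]:
    """Read an ordered CINE stack into :class:`Frame` objects.

    ``path`` is either a directory of PNG/TIFF frames (sorted by name) or
    a multipage TIFF.  Timestamps are assigned as ``index / frame_rate``.
    """
    path = Path(path)
    images: list[tuple[str, np.ndarray]] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        for p in files:
            try:
                images.append((p.name, np.asarray(iio.imread(p))))
            except Exception as exc:  # pragma: no cover - depends on corrupt input
                raise IOError(f"failed to read CINE frame {p}: {exc}") from exc
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        images = [(f"{path.name}[{i}]", page) for i, page in enumerate(stack)]
    if len(images) < 2:
        raise ValueError(f"CINE sequence at {path} has {len(images)} frame(s); need >= 2")
    frames = []
    shape = None
    for i, (name, img) in enumerate(images):
        img = _to_grayscale(img, name)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"CINE frame {name} has shape {img.shape}, expected {shape}"
            )
        frames.append(
            Frame(image=np.asarray(img, dtype=float), pixel_size=pixel_size,
                  time=i / frame_rate, index=i)
        )
    return frames


def write_cine(path, frames: list[Frame]) -> None:
    """Write frames as a multipage TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), np.stack([f.image for f in frames]))


def read_force_csv(path, max_plausible_force: float = 50.0) -> ForceLog:
    df = pd.read_csv(path)
    for col in ("time_s", "force_n"):
        if col not in df.columns:
            raise ValueError(f"force CSV {path} lacks required column '{col}'")
    return ForceLog(df["time_s"].to_numpy(), df["force_n"].to_numpy(),
                    max_plausible_force=max_plausible_force)


def write_force_csv(path, log: ForceLog) -> None:
    pd.DataFrame({"time_s": log.times, "force_n": log.forces}).to_csv(path, index=False)


def resample_force_to_frames(log: ForceLog, frame_times) -> np.ndarray:
    """Linearly interpolate the force log onto the frame timestamps.

    Frames outside the logged interval get the nearest end value
    (constant extrapolation) with a warning.
    """
    t = np.asarray(frame_times, dtype=float)
    if np.any(t < log.times[0]) or np.any(t > log.times[-1]):
        warnings.warn(
            "frame times extend beyond the force log; extrapolating with end values",
            stacklevel=2,
        )
    return np.interp(t, log.times, log.forces)


def write_map_tiff(path, data: np.ndarray) -> None:
    """Write a float map (NaN = invalid) as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(data, dtype=np.float32))


def read_map_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path))
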