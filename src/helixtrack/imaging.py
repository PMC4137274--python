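"""Synthetic bright-field bead movies and defocus calibration stacks.

A 0.5 um bead imaged slightly out of focus appears as a roughly radially
symmetric spot whose central brightness changes monotonically with its axial
(z) position over a few hundred nm around the focal plane.  This module
renders that phenomenology directly: a symmetric 2D Gaussian spot whose peak
amplitude above background follows a configured cubic in z, plus camera
noise.  A Gaussian spot (rather than a physical defocused-bead PSF) is used
deliberately so that the downstream Gaussian-fitting tracker can be tested
for estimator correctness without PSF-mismatch confounds; the radial profile
is a config hook for robustness studies.

Coordinates: positions are in nm with the origin at the field center; pixel
(row i, col j) has center ((j - (W-1)/2) * pixel_size, (i - (H-1)/2) *
pixel_size) in (x, y).  x is the MT/motion axis, y the in-plane
perpendicular axis, z the optical axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .motor import Trajectory3D

__all__ = [
    "ImagingConfig",
    "Frame",
    "Movie",
    "defocus_amplitude",
    "render_frame",
    "render_movie",
    "generate_calibration_stack",
    "center_in_field",
]

#: Default cubic mapping z (nm) -> peak amplitude above background (counts).
#: Chosen strictly monotone over +/-250 nm with curvature qualitatively like
#: a bright-field defocus curve; the actual coefficients are synthetic by
#: construction and always recorded in config/sidecar metadata.
DEFAULT_DEFOCUS_COEFFS = (200.0, 0.5, 0.0, 6.0e-7)


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering parameters for synthetic bright-field frames.

    ``defocus_coeffs`` are (c0, c1, c2, c3) of the cubic
    ``amplitude(z) = c0 + c1 z + c2 z^2 + c3 z^3`` (counts above background)
    which must be strictly monotone over ``z_range``.
    """

    pixel_size: float = 160.0
    shape: tuple[int, int] = (64, 64)
    spot_sigma: float = 250.0
    defocus_coeffs: tuple[float, float, float, float] = DEFAULT_DEFOCUS_COEFFS
    background_level: float = 100.0
    read_noise_sd: float = 4.0
    poisson_noise: bool = False
    z_range: tuple[float, float] = (-250.0, 250.0)
    contrast_inversion: bool = False
    contrast_inversion_halfwidth: float = 25.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be non-negative")
        if len(self.shape) != 2 or any(s < 8 for s in self.shape):
            raise ValueError("shape must be (H, W) with both >= 8 pixels")
        zlo, zhi = self.z_range
        if zhi <= zlo:
            raise ValueError("z_range must be increasing")
        z = np.linspace(zlo, zhi, 501)
        c0, c1, c2, c3 = self.defocus_coeffs
        deriv = c1 + 2 * c2 * z + 3 * c3 * z**2
        if not (np.all(deriv > 0) or np.all(deriv < 0)):
            raise ValueError("defocus cubic must be strictly monotonic over z_range")

    @property
    def field_extent(self) -> tuple[float, float]:
        """Half-extent of the field in nm, (x_half, y_half)."""
        h, w = self.shape
        return (w - 1) / 2 * self.pixel_size, (h - 1) / 2 * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.shape
        x = (np.arange(w) - (w - 1) / 2) * self.pixel_size
        y = (np.arange(h) - (h - 1) / 2) * self.pixel_size
        return x, y

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "shape": list(self.shape),
            "spot_sigma": self.spot_sigma,
            "defocus_coeffs": list(self.defocus_coeffs),
            "background_level": self.background_level,
            "read_noise_sd": self.read_noise_sd,
            "poisson_noise": self.poisson_noise,
            "z_range": list(self.z_range),
        }


def defocus_amplitude(z: float | np.ndarray, config: ImagingConfig) -> float | np.ndarray:
    """Peak spot amplitude above background at axial position z (nm)."""
    c0, c1, c2, c3 = config.defocus_coeffs
    return c0 + c1 * z + c2 * z**2 + c3 * z**3


@dataclass
class Frame:
    """One rendered camera frame."""

    data: np.ndarray
    time_s: float = 0.0
    pixel_size: float = 160.0
    out_of_range: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2D")
        if np.any(self.data < 0):
            raise ValueError("frame intensities must be non-negative")


@dataclass
class Movie:
    """A stack of frames plus the config and seed that produced it."""

    frames: np.ndarray  # (T, H, W)
    time_s: np.ndarray
    config: ImagingConfig
    seed: Optional[int] = None
    truth: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.frames[i], float(self.time_s[i]), self.config.pixel_size)

    def to_tiff(self, path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar (config, seed, truth)."""
        path = str(path)
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")
        sidecar = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "time_s": self.time_s.tolist(),
        }
        if self.truth is not None:
            sidecar["truth"] = self.truth.to_dict(orient="list")
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_tiff(cls, path) -> "Movie":
        path = str(path)
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        cfg = sidecar["config"]
        config = ImagingConfig(
            pixel_size=cfg["pixel_size"],
            shape=tuple(cfg["shape"]),
            spot_sigma=cfg["spot_sigma"],
            defocus_coeffs=tuple(cfg["defocus_coeffs"]),
            background_level=cfg["background_level"],
            read_noise_sd=cfg["read_noise_sd"],
            poisson_noise=cfg["poisson_noise"],
            z_range=tuple(cfg["z_range"]),
        )
        truth = pd.DataFrame(sidecar["truth"]) if "truth" in sidecar else None
        return cls(frames, np.asarray(sidecar["time_s"]), config, sidecar.get("seed"), truth)


def _spot_image(position, config: ImagingConfig) -> np.ndarray:
    x0, y0, z = position
    amp = defocus_amplitude(z, config)
    if config.contrast_inversion and abs(z) < config.contrast_inversion_halfwidth:
        # near-focus artifact: the bead image loses its Gaussian character;
        # emulated as a ring (negative central lobe on a broader envelope)
        amp = -0.5 * amp
    xc, yc = config.pixel_centers()
    dx2 = (xc[None, :] - x0) ** 2
    dy2 = (yc[:, None] - y0) ** 2
    img = config.background_level + amp * np.exp(-(dx2 + dy2) / (2.0 * config.spot_sigma**2))
    return img


def render_frame(
    position: Sequence[float],
    config: ImagingConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    time_s: float = 0.0,
) -> Frame:
    """Render one frame of a bead at ``position = (x, y, z)`` nm.

    Positions outside the camera field are rejected; z outside the
    calibration range is rendered but flagged via ``Frame.out_of_range``.
    """
    x0, y0, z = (float(v) for v in position)
    x_half, y_half = config.field_extent
    if abs(x0) > x_half or abs(y0) > y_half:
        raise ValueError(f"position ({x0:.0f}, {y0:.0f}) nm is outside the camera field")
    img = _spot_image((x0, y0, z), config)
    if rng is None:
        rng = np.random.default_rng(seed)
    if config.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    out = not (config.z_range[0] <= z <= config.z_range[1])
    return Frame(img, time_s, config.pixel_size, out_of_range=out)


def render_movie(traj: Trajectory3D, config: ImagingConfig, seed: Optional[int] = None) -> Movie:
    """Render one frame per trajectory sample."""
    rng = np.random.default_rng(seed)
    frames = np.empty((len(traj),) + tuple(config.shape))
    for i in range(len(traj)):
        frames[i] = render_frame(
            (traj.x_nm[i], traj.y_nm[i], traj.z_nm[i]), config, rng=rng, time_s=traj.time_s[i]
        ).data
    truth = traj.to_frame()
    return Movie(frames, traj.time_s.copy(), config, seed, truth)


def center_in_field(traj: Trajectory3D, config: ImagingConfig) -> Trajectory3D:
    """Shift a trajectory's (x, y) so its bounding box is centered in the field.

    Returns a shifted copy (truth columns shifted identically); raises if the
    trajectory cannot fit the field at all.
    """
    dx = -(traj.x_nm.max() + traj.x_nm.min()) / 2
    dy = -(traj.y_nm.max() + traj.y_nm.min()) / 2
    x_half, y_half = config.field_extent
    if (traj.x_nm.max() - traj.x_nm.min()) / 2 > x_half or (traj.y_nm.max() - traj.y_nm.min()) / 2 > y_half:
        raise ValueError("trajectory extent exceeds the camera field")
    return Trajectory3D(
        time_s=traj.time_s.copy(),
        x_nm=traj.x_nm + dx,
        y_nm=traj.y_nm + dy,
        z_nm=traj.z_nm.copy(),
        true_x_nm=None if traj.true_x_nm is None else traj.true_x_nm + dx,
        true_y_nm=None if traj.true_y_nm is None else traj.true_y_nm + dy,
        true_z_nm=None if traj.true_z_nm is None else traj.true_z_nm.copy(),
        meta={**traj.meta, "field_shift_nm": (dx, dy)},
    )


def generate_calibration_stack(
    config: ImagingConfig,
    z_min: float = -250.0,
    z_max: float = 250.0,
    z_step: float = 25.0,
    n_repeats: int = 20,
    seed: Optional[int] = None,
    bead_xy: tuple[float, float] = (0.0, 0.0),
) -> Movie:
    """Defocus calibration stack: a stationary bead swept through z.

    The bead is rendered at every z plane from ``z_min`` to ``z_max`` in
    ``z_step`` increments (21 planes for the +/-250 nm, 25 nm default) and
    the whole sweep is repeated ``n_repeats`` times (20 by default).  The
    returned movie's ``truth`` table carries the true z per frame.
    """
    n_span = (z_max - z_min) / z_step
    if abs(n_span - round(n_span)) > 1e-9:
        raise ValueError("z_step must evenly divide the z range")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    z_planes = z_min + z_step * np.arange(int(round(n_span)) + 1)
    rng = np.random.default_rng(seed)
    z_all = np.tile(z_planes, n_repeats)
    frames = np.empty((len(z_all),) + tuple(config.shape))
    for i, z in enumerate(z_all):
        frames[i] = render_frame((bead_xy[0], bead_xy[1], z), config, rng=rng).data
    time_s = np.arange(len(z_all), dtype=float)
    truth = pd.DataFrame({"frame": np.arange(len(z_all)), "z_nm": z_all})
    return Movie(frames, time_s, config, seed, truth)
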