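"""Bead tracking: xy localization, z calibration and 3D track assembly.

The xy position of the bead in each frame comes from a nonlinear
least-squares fit of a symmetric 2D Gaussian plus constant background.  The
z position comes from the bead's central brightness: a calibration stack of
a stationary bead swept through known z planes yields a third-order
polynomial mapping z to normalized center intensity, which is then inverted
(bracketed root finding on the monotone cubic) for every movie frame.

Normalization: the calibration fit stores its background and intensity
scale; tracking a movie reuses those constants, so calibration and movie
intensities are commensurable whenever they share an imaging configuration.
A per-movie-maximum normalization is available as an option.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .imaging import Frame, Movie

__all__ = [
    "CalibrationCurve",
    "LocalizationResult",
    "Track3D",
    "localize_xy",
    "measure_center_intensity",
    "fit_z_calibration",
    "invert_z",
    "track_movie",
    "smooth_track",
    "subtract_reference",
]

#: Gaussian-fit quality threshold: frames whose normalized fit residual
#: exceeds this are flagged (no z estimate).
DEFAULT_QUALITY_THRESHOLD = 0.2

#: Radius (pixels) of the center-intensity window; the window is a Gaussian
#: apodization of this SD (truncated at 3 SD) so the measured intensity is
#: invariant to sub-pixel bead position.
DEFAULT_DISC_RADIUS_PX = 2.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Cubic z-calibration: normalized center intensity as a function of z.

    ``coeffs`` are ascending (c0, c1, c2, c3) so the model is
    ``I(z) = c0 + c1 z + c2 z^2 + c3 z^3``, strictly monotone over
    ``z_range`` by construction.  ``background`` and ``scale`` are the
    normalization constants applied to raw window intensities before the
    fit; they are reused when tracking movies against this curve.
    """

    coeffs: tuple[float, float, float, float]
    z_range: tuple[float, float]
    r_squared: float
    background: float
    scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")
        zlo, zhi = self.z_range
        if zhi <= zlo:
            raise ValueError("z_range must be increasing")
        z = np.linspace(zlo, zhi, 501)
        d = self.derivative(z)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("calibration cubic must be strictly monotonic over its valid range")

    def __call__(self, z):
        c0, c1, c2, c3 = self.coeffs
        z = np.asarray(z, dtype=float)
        out = c0 + c1 * z + c2 * z**2 + c3 * z**3
        return float(out) if out.ndim == 0 else out

    def derivative(self, z):
        _, c1, c2, c3 = self.coeffs
        return c1 + 2 * c2 * np.asarray(z, dtype=float) + 3 * c3 * np.asarray(z, dtype=float) ** 2

    @property
    def intensity_range(self) -> tuple[float, float]:
        lo, hi = self(self.z_range[0]), self(self.z_range[1])
        return (lo, hi) if lo <= hi else (hi, lo)

    def normalize(self, raw_intensity):
        """Map a raw (background-subtracted) window intensity onto the curve's scale."""
        return np.asarray(raw_intensity, dtype=float) / self.scale

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coeffs": list(self.coeffs),
                    "z_range": list(self.z_range),
                    "r_squared": self.r_squared,
                    "background": self.background,
                    "scale": self.scale,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coeffs=tuple(d["coeffs"]),
            z_range=tuple(d["z_range"]),
            r_squared=d["r_squared"],
            background=d["background"],
            scale=d["scale"],
        )


@dataclass(frozen=True)
class LocalizationResult:
    x_nm: float
    y_nm: float
    amplitude: float
    sigma_nm: float
    background: float
    quality: float  # RMS residual / |amplitude|; lower is better
    ok: bool


@dataclass
class Track3D:
    """Per-frame 3D track: time, position (nm), normalized intensity, flags.

    Flagged frames (``valid == False``) carry no z estimate (NaN).
    """

    time_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    z_nm: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        self.time_s = t
        for name in ("x_nm", "y_nm", "z_nm", "intensity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm, self.z_nm])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "x_nm": self.x_nm,
                "y_nm": self.y_nm,
                "z_nm": self.z_nm,
                "intensity_norm": self.intensity,
                "quality_flag": (~self.valid).astype(int),
            }
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.meta.items():
                fh.write(f"# {key}: {value}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Track3D":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(
            time_s=df["time_s"].to_numpy(),
            x_nm=df["x_nm"].to_numpy(),
            y_nm=df["y_nm"].to_numpy(),
            z_nm=df["z_nm"].to_numpy(),
            intensity=df.get("intensity_norm", pd.Series(np.full(len(df), np.nan))).to_numpy(),
            valid=df.get("quality_flag", pd.Series(np.zeros(len(df)))).to_numpy() == 0,
            meta=meta,
        )


def _frame_data(frame, pixel_size: Optional[float]) -> tuple[np.ndarray, float]:
    if isinstance(frame, Frame):
        return frame.data, frame.pixel_size
    if pixel_size is None:
        raise ValueError("pixel_size is required when passing a bare array")
    return np.asarray(frame, dtype=float), float(pixel_size)


def _border_background(data: np.ndarray, width: int = 2) -> float:
    border = np.concatenate(
        [data[:width].ravel(), data[-width:].ravel(), data[:, :width].ravel(), data[:, -width:].ravel()]
    )
    return float(np.median(border))


def _pixel_centers_nm(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    x = (np.arange(w) - (w - 1) / 2) * pixel_size
    y = (np.arange(h) - (h - 1) / 2) * pixel_size
    return x, y


def localize_xy(
    frame,
    pixel_size: Optional[float] = None,
    roi_halfwidth_px: int = 8,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> LocalizationResult:
    """Fit a symmetric 2D Gaussian + constant background to the dominant spot.

    Returns the center in nm (field-centered coordinates), the fitted
    amplitude, and a residual-based quality; a divergent or poor fit yields
    ``ok=False`` rather than an exception.
    """
    data, px = _frame_data(frame, pixel_size)
    h, w = data.shape
    xc, yc = _pixel_centers_nm(data.shape, px)

    # ROI around the brightest pixel (assumed near the spot even for dim spots)
    i0, j0 = np.unravel_index(np.argmax(data), data.shape)
    i_lo, i_hi = max(0, i0 - roi_halfwidth_px), min(h, i0 + roi_halfwidth_px + 1)
    j_lo, j_hi = max(0, j0 - roi_halfwidth_px), min(w, j0 + roi_halfwidth_px + 1)
    roi = data[i_lo:i_hi, j_lo:j_hi]
    X, Y = np.meshgrid(xc[j_lo:j_hi], yc[i_lo:i_hi])

    bg0 = _border_background(data)
    amp0 = float(data[i0, j0] - bg0)
    p0 = (float(xc[j0]), float(yc[i0]), amp0 if amp0 != 0 else 1.0, 1.5 * px, bg0)

    def model(_, x0, y0, amp, sigma, bg):
        return (bg + amp * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sigma**2))).ravel()

    dummy_x = np.zeros(roi.size)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model,
                dummy_x,
                roi.ravel(),
                p0=p0,
                maxfev=2000,
                bounds=(
                    [xc[0] - px, yc[0] - px, -np.inf, 0.2 * px, -np.inf],
                    [xc[-1] + px, yc[-1] + px, np.inf, 10 * px, np.inf],
                ),
            )
    except (RuntimeError, ValueError):
        return LocalizationResult(np.nan, np.nan, np.nan, np.nan, bg0, np.inf, False)

    x0, y0, amp, sigma, bg = popt
    resid = roi.ravel() - model(None, *popt)
    quality = float(np.sqrt(np.mean(resid**2)) / abs(amp)) if amp != 0 else np.inf
    # a fitted spot must actually stand out of the background: structureless
    # frames otherwise "fit" with vanishing amplitude and zero residual
    significant = amp > max(1e-3 * abs(bg), 1e-9)
    ok = bool(np.isfinite(quality) and quality <= quality_threshold and significant)
    return LocalizationResult(float(x0), float(y0), float(amp), float(sigma), float(bg), quality, ok)


def measure_center_intensity(
    frame,
    center_xy_nm: tuple[float, float],
    pixel_size: Optional[float] = None,
    radius_px: float = DEFAULT_DISC_RADIUS_PX,
    background: Optional[float] = None,
    scale: float = 1.0,
) -> float:
    """Background-subtracted center intensity of the bead, normalized by ``scale``.

    A Gaussian-apodized window (SD ``radius_px`` pixels, truncated at 3 SD)
    centered on the sub-pixel bead position weights the pixels; the weighted
    mean is invariant to sub-pixel shifts of the center, unlike a hard-edged
    disc.  ``background`` defaults to the median of a 2-pixel image border.
    Returns NaN when the window would overrun the frame edge.
    """
    data, px = _frame_data(frame, pixel_size)
    xc, yc = _pixel_centers_nm(data.shape, px)
    x0, y0 = center_xy_nm
    reach = 3.0 * radius_px * px
    if not (xc[0] + reach <= x0 <= xc[-1] - reach) or not (yc[0] + reach <= y0 <= yc[-1] - reach):
        return np.nan
    if background is None:
        background = _border_background(data)
    d2 = (xc[None, :] - x0) ** 2 + (yc[:, None] - y0) ** 2
    sd_nm = radius_px * px
    # untruncated window: a hard cutoff makes the weight sum (denominator)
    # ripple by ~0.3% with sub-pixel center shifts, which aliases into z
    w = np.exp(-d2 / (2 * sd_nm**2))
    value = float(np.sum((data - background) * w) / np.sum(w))
    return value / scale


def _fit_cubic(z: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares cubic fit; returns ascending coefficients and R^2.

    Fitted on the rescaled [-1, 1] domain (z spans hundreds of nm, so a raw
    Vandermonde solve loses ~6 digits on the cubic coefficient) and
    converted back to unscaled-z coefficients.
    """
    poly = np.polynomial.Polynomial.fit(z, intensity, deg=3).convert()
    coeffs = np.zeros(4)
    coeffs[: len(poly.coef)] = poly.coef
    fitted = poly(z)
    ss_res = float(np.sum((intensity - fitted) ** 2))
    ss_tot = float(np.sum((intensity - np.mean(intensity)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coeffs, r2


def fit_z_calibration(
    stack: Movie,
    z_table: Optional[pd.DataFrame] = None,
    radius_px: float = DEFAULT_DISC_RADIUS_PX,
) -> CalibrationCurve:
    """Fit the cubic z-calibration from a calibration stack.

    Each frame is localized, its window intensity measured, and the per-plane
    means (background-subtracted, normalized to the brightest plane) fitted
    with a third-order polynomial in z.  Fails if fewer than 4 distinct z
    planes are present or if the fitted cubic is not monotone over the
    spanned range.
    """
    if z_table is None:
        z_table = stack.truth
    if z_table is None or "z_nm" not in z_table.columns:
        raise ValueError("a truth table with a z_nm column is required")
    z_all = z_table["z_nm"].to_numpy(dtype=float)
    if len(z_all) != len(stack):
        raise ValueError("truth table and stack length differ")
    planes = np.unique(z_all)
    if len(planes) < 4:
        raise ValueError(f"need >= 4 distinct z planes to fit a cubic, got {len(planes)}")

    raw = np.full(len(stack), np.nan)
    bgs = np.full(len(stack), np.nan)
    for i in range(len(stack)):
        fr = stack.frame(i)
        loc = localize_xy(fr)
        if not loc.ok:
            continue
        bg = _border_background(fr.data)
        raw[i] = measure_center_intensity(fr, (loc.x_nm, loc.y_nm), radius_px=radius_px, background=bg)
        bgs[i] = bg
    ok = np.isfinite(raw)
    if ok.sum() < 4:
        raise ValueError("too few usable calibration frames")

    plane_means = np.array([np.mean(raw[ok & (z_all == z)]) for z in planes])
    usable = np.isfinite(plane_means)
    if usable.sum() < 4:
        raise ValueError("fewer than 4 z planes have usable frames")
    planes, plane_means = planes[usable], plane_means[usable]

    scale = float(np.max(np.abs(plane_means)))
    if scale == 0:
        raise ValueError("calibration stack has zero contrast")
    normalized = plane_means / scale
    coeffs, r2 = _fit_cubic(planes, normalized)
    curve = CalibrationCurve(  # monotonicity enforced in the constructor
        coeffs=tuple(coeffs),
        z_range=(float(planes.min()), float(planes.max())),
        r_squared=r2,
        background=float(np.nanmean(bgs)),
        scale=scale,
    )
    return curve


def invert_z(
    intensity: float,
    curve: CalibrationCurve,
    range_tolerance: float = 0.02,
) -> tuple[float, bool]:
    """Invert the calibration cubic at a normalized intensity.

    Returns ``(z_nm, ok)``.  Within the curve's attained intensity range the
    root is unique (the cubic is monotone) and found by bracketed root
    finding; intensities outside the range by more than ``range_tolerance``
    (fraction of the intensity span) are clamped to the boundary and flagged.
    Non-finite intensities yield ``(nan, False)``.
    """
    if not np.isfinite(intensity):
        return (np.nan, False)
    zlo, zhi = curve.z_range
    i_lo, i_hi = curve.intensity_range
    span = i_hi - i_lo
    ok = True
    if intensity < i_lo or intensity > i_hi:
        if intensity < i_lo - range_tolerance * span or intensity > i_hi + range_tolerance * span:
            ok = False
        increasing = curve(zhi) >= curve(zlo)
        if intensity < i_lo:
            return (zlo if increasing else zhi, ok)
        return (zhi if increasing else zlo, ok)
    z = optimize.brentq(lambda zz: curve(zz) - intensity, zlo, zhi, xtol=1e-6)
    return (float(z), True)


def track_movie(
    movie: Movie,
    curve: CalibrationCurve,
    radius_px: float = DEFAULT_DISC_RADIUS_PX,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    normalization: str = "calibration",
) -> Track3D:
    """Track a movie in 3D: per-frame xy Gaussian fit + intensity-based z.

    ``normalization='calibration'`` (default) normalizes window intensities
    with the calibration curve's stored scale; ``'movie_max'`` uses the
    movie's own background-subtracted maximum instead.
    """
    n = len(movie)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        fr = movie.frame(i)
        loc = localize_xy(fr, quality_threshold=quality_threshold)
        if not loc.ok:
            continue
        x[i], y[i] = loc.x_nm, loc.y_nm
        value = measure_center_intensity(fr, (loc.x_nm, loc.y_nm), radius_px=radius_px)
        if np.isfinite(value):
            raw[i] = value
            valid[i] = True

    if normalization == "calibration":
        scale = curve.scale
    elif normalization == "movie_max":
        scale = float(np.nanmax(np.abs(raw))) if np.any(np.isfinite(raw)) else 1.0
    else:
        raise ValueError("normalization must be 'calibration' or 'movie_max'")

    z = np.full(n, np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        z[i], ok = invert_z(raw[i] / scale, curve)
        valid[i] = ok
        if not ok:
            z[i] = np.nan
    if not valid.any():
        warnings.warn("all frames flagged; track contains no valid 3D positions")
    return Track3D(
        time_s=movie.time_s.copy(),
        x_nm=x,
        y_nm=y,
        z_nm=z,
        intensity=raw / scale,
        valid=valid,
        meta={"normalization": normalization, "n_flagged": int(n - valid.sum())},
    )


def _moving_average(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring invalid samples; shrunken edge windows."""
    v = np.where(valid, values, 0.0)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def smooth_track(track, window: int = 5):
    """Centered moving-average smoothing of the coordinates of a track.

    ``window`` must be odd (default five data points).  Edges use shrunken
    centered windows; flagged frames are excluded from the averages and stay
    flagged.  Works on :class:`Track3D` and :class:`~helixtrack.motor.Trajectory3D`.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    n = len(track)
    if window > n:
        raise ValueError(f"window {window} exceeds track length {n}")
    if window == 1:
        return track
    valid = np.asarray(track.valid, dtype=bool)
    finite = np.isfinite(np.asarray(track.x_nm)) & np.isfinite(np.asarray(track.y_nm))
    use = valid & finite

    import copy

    out = copy.deepcopy(track)
    for name in ("x_nm", "y_nm", "z_nm"):
        vals = np.asarray(getattr(track, name), dtype=float)
        ok = use & np.isfinite(vals)
        sm = _moving_average(vals, ok, window)
        setattr(out, name, np.where(ok, sm, vals))
    if hasattr(out, "meta"):
        out.meta = {**getattr(track, "meta", {}), "smoothing_window": window}
    return out


def subtract_reference(
    track,
    reference: pd.DataFrame,
    axes: tuple[str, ...] = ("perpendicular",),
):
    """Subtract a fiducial reference trace (MT-bridge fluctuation) from a track.

    ``reference`` must have ``time_s`` plus ``perp_nm`` (and optionally
    ``par_nm``) columns; it is linearly interpolated onto the track's time
    base.  By default only the perpendicular (y) axis is corrected, matching
    how quantum-dot motor traces are corrected for MT oscillation; pass
    ``axes=('perpendicular', 'parallel')`` to also correct x.  The residual
    reference SD over the overlap is recorded in the output metadata.
    """
    t = np.asarray(track.time_s, dtype=float)
    rt = reference["time_s"].to_numpy(dtype=float)
    if t[0] > rt[-1] or t[-1] < rt[0]:
        raise ValueError("track and reference time ranges do not overlap")

    import copy

    out = copy.deepcopy(track)
    applied = {}
    for axis in axes:
        if axis == "perpendicular":
            col, attr = "perp_nm", "y_nm"
        elif axis == "parallel":
            col, attr = "par_nm", "x_nm"
        else:
            raise ValueError(f"unknown axis {axis!r}")
        ref = np.interp(t, rt, reference[col].to_numpy(dtype=float))
        setattr(out, attr, np.asarray(getattr(track, attr), dtype=float) - ref)
        applied[axis] = float(np.std(ref))
    if hasattr(out, "meta"):
        out.meta = {**getattr(track, "meta", {}), "reference_sd_nm": applied}
    return out
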