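"""Helical-motility analysis of 3D probe tracks.

Given a 3D track of a probe orbiting a straight microtubule, this module
estimates the MT axis (principal direction of the point cloud, oriented
along the net displacement, i.e. toward the minus end for dynein), converts
the track to cylindrical coordinates (axial coordinate s, unwrapped azimuth
theta, radius r), and extracts:

* rotation segments — consecutive spans of exactly 2*pi of unwrapped phase,
  each with a measured pitch |delta s|, handedness (sign of delta theta under
  the right-hand rule about the motion axis) and mean helical speed;
* handedness switch events — persistent sign reversals of the windowed
  angular velocity;
* supertwist-corrected pitches — removal of the lattice's own twist rate
  from the measured rotation rate, via signed rates:
  corrected_rate = measured_rate - lattice_rate, with rate = (+/-)1/pitch
  (positive right-handed).  On an untwisted lattice corrected == measured;
  on a left-handed lattice the corrected pitch is longer than measured for
  left-handed rotations and shorter for right-handed ones.

The statsmodels-style frontend is :class:`HelixModel` (construct from a
track, call :meth:`HelixModel.fit`) returning :class:`HelixResults` with the
per-rotation table, switch events, summary statistics and a ``summary()``
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice import TWO_PI, LatticeSpec
from .tracking import Track3D, _moving_average

__all__ = [
    "Axis",
    "CylindricalTrace",
    "RotationSegment",
    "SwitchEvent",
    "CorrectedPitch",
    "estimate_axis",
    "to_cylindrical",
    "segment_rotations",
    "detect_switches",
    "helical_speed",
    "correct_supertwist",
    "HelixModel",
    "HelixResults",
]


@dataclass(frozen=True)
class Axis:
    """MT axis estimate: a point on the axis and a unit direction.

    The direction points along the net displacement of the probe, i.e.
    toward the MT minus end for a minus-end-directed motor.
    """

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis direction must be a finite nonzero vector")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Transverse orthonormal basis (e1, e2) with e1 x e2 = direction.

        Azimuth measured as atan2(q.e2, q.e1) then increases by the
        right-hand rule about the motion axis (the package convention:
        positive = right-handed).
        """
        d = self.direction
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(d, helper)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        return e1, e2


@dataclass
class CylindricalTrace:
    """A track in cylindrical coordinates about an MT axis.

    ``theta_rad`` is the unwrapped azimuth (continuous; no jumps > pi between
    valid frames), ``s_nm`` the axial coordinate increasing toward the minus
    end, ``r_nm`` the radial distance.  Frames with radius below the phase
    resolution limit are flagged invalid.
    """

    time_s: np.ndarray
    s_nm: np.ndarray
    theta_rad: np.ndarray
    r_nm: np.ndarray
    valid: np.ndarray
    axis: Axis
    phase_reliable: bool = True

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def frame_interval(self) -> float:
        dt = np.diff(self.time_s)
        return float(np.median(dt)) if len(dt) else np.nan


@dataclass
class RotationSegment:
    """One complete 2*pi turn of the probe about the MT axis."""

    start_index: float
    end_index: float
    start_time: float
    end_time: float
    ds_nm: float
    dtheta_rad: float  # exactly +/- 2*pi by construction
    pitch_nm: float
    handedness: str
    speed_nm_per_s: float
    pitch_corrected_nm: Optional[float] = None
    handedness_corrected: Optional[str] = None
    protofilament_tracking: bool = False


@dataclass(frozen=True)
class SwitchEvent:
    """A persistent reversal of the sign of the angular velocity."""

    frame_index: int
    time_s: float
    preceding: str
    following: str

    def __post_init__(self) -> None:
        if self.preceding == self.following:
            raise ValueError("a switch event must change handedness")


@dataclass(frozen=True)
class CorrectedPitch:
    """Supertwist-corrected pitch: magnitude, handedness, degenerate-case flag."""

    pitch_nm: float
    handedness: str
    protofilament_tracking: bool = False


def _transverse_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _circle_fit_residual(pts: np.ndarray, d: np.ndarray) -> tuple[float, np.ndarray]:
    """Algebraic (Kasa) circle fit of the points projected along ``d``.

    Returns the mean squared residual of |q - c|^2 about a constant and the
    fitted 3D center offset in the transverse plane.  Zero residual means
    the points lie on a perfect cylinder about an axis along ``d``.
    """
    e1, e2 = _transverse_basis(d)
    q = np.column_stack([pts @ e1, pts @ e2])
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    b = np.sum(q**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ sol
    center3d = sol[0] * e1 + sol[1] * e2
    scale = max(np.mean(b), 1e-300)
    return float(np.mean(resid**2) / scale**2), center3d


def estimate_axis(track, min_frames: int = 10, refine: bool = True) -> Axis:
    """Estimate the MT axis from the probe point cloud.

    The initial direction is the principal component of the (valid)
    positions, oriented along the net displacement.  Because a finite helix
    correlates axial position with orbit phase, the raw principal axis of a
    helical trace is slightly tilted; by default the direction is therefore
    refined by a cylinder fit — the direction is optimized until the
    transverse points are best explained by a circle (exact for a noiseless
    helix).  The origin is placed on the fitted cylinder axis.  Tracks with
    no clear net motion (net displacement not exceeding twice the RMS
    transverse spread) are rejected as degenerate.
    """
    pts = _valid_points(track)
    if len(pts) < min_frames:
        raise ValueError(f"need >= {min_frames} valid frames, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    net = pts[-1] - pts[0]
    if np.dot(direction, net) < 0:
        direction = -direction
    transverse = centered - np.outer(centered @ direction, direction)
    r_rms = float(np.sqrt(np.mean(np.sum(transverse**2, axis=1))))
    net_along = abs(float(np.dot(net, direction)))
    if net_along <= 2.0 * r_rms:
        raise ValueError(
            "degenerate track: net displacement does not dominate the transverse spread"
        )
    origin = centroid
    # cylinder refinement needs a resolvable orbit; below ~1 nm of transverse
    # spread the circle fit is degenerate and the PCA line is already exact
    if refine and r_rms > 1.0:
        from scipy import optimize as _opt

        u, w = _transverse_basis(direction)

        def objective(ab):
            d = direction + ab[0] * u + ab[1] * w
            d = d / np.linalg.norm(d)
            return _circle_fit_residual(centered, d)[0]

        res = _opt.minimize(objective, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-18, "maxiter": 400})
        d = direction + res.x[0] * u + res.x[1] * w
        direction = d / np.linalg.norm(d)
        _, center3d = _circle_fit_residual(centered, direction)
        origin = centroid + center3d
    return Axis(origin=origin, direction=direction)


def _valid_points(track) -> np.ndarray:
    xyz = np.column_stack(
        [np.asarray(track.x_nm, float), np.asarray(track.y_nm, float), np.asarray(track.z_nm, float)]
    )
    valid = np.asarray(getattr(track, "valid", np.ones(len(xyz), bool)), dtype=bool)
    valid &= np.all(np.isfinite(xyz), axis=1)
    return xyz[valid]


def to_cylindrical(track, axis: Axis, r_min: float = 1.0, r_snr_min: float = 3.0) -> CylindricalTrace:
    """Convert a 3D track to cylindrical coordinates about ``axis``.

    Invalid/non-finite frames are flagged and excluded from phase
    unwrapping; frames with radius below ``r_min`` nm are flagged (azimuth
    undefined).  The trace-level ``phase_reliable`` flag records whether the
    mean radius dominates the radial scatter (mean r > r_snr_min * SD of r):
    when a probe does not actually orbit the axis, its apparent radius is
    pure localization noise and the unwrapped phase is a meaningless random
    walk, so rotation counting and switch detection are suppressed
    downstream.
    """
    xyz = np.column_stack(
        [np.asarray(track.x_nm, float), np.asarray(track.y_nm, float), np.asarray(track.z_nm, float)]
    )
    valid = np.asarray(getattr(track, "valid", np.ones(len(xyz), bool)), dtype=bool).copy()
    finite = np.all(np.isfinite(xyz), axis=1)
    valid &= finite
    q = np.where(finite[:, None], xyz, 0.0) - axis.origin
    s = q @ axis.direction
    e1, e2 = axis.basis()
    a = q @ e1
    b = q @ e2
    r = np.hypot(a, b)
    valid &= r >= r_min
    theta = np.full(len(s), np.nan)
    if valid.any():
        theta_valid = np.unwrap(np.arctan2(b[valid], a[valid]))
        theta[valid] = theta_valid
    if valid.any():
        r_ok = r[valid]
        r_sd = float(np.std(r_ok))
        reliable = bool(np.mean(r_ok) > r_snr_min * r_sd) if r_sd > 0 else True
    else:
        reliable = False
    return CylindricalTrace(
        time_s=np.asarray(track.time_s, float),
        s_nm=s,
        theta_rad=theta,
        r_nm=r,
        valid=valid,
        axis=axis,
        phase_reliable=reliable,
    )


def _smoothed_phase(ct: CylindricalTrace, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed (theta, s) restricted to valid frames, plus their indices."""
    idx = np.flatnonzero(ct.valid)
    theta = ct.theta_rad[idx]
    s = ct.s_nm[idx]
    if window > 1 and len(idx) >= window:
        ones = np.ones(len(idx), dtype=bool)
        theta = _moving_average(theta, ones, window)
        s = _moving_average(s, ones, window)
    return theta, s, idx


def segment_rotations(
    ct: CylindricalTrace,
    smooth_window: int = 5,
    hysteresis_rad: float = math.pi / 2,
) -> list[RotationSegment]:
    """Slice the unwrapped phase into consecutive complete 2*pi turns.

    Segments are anchored where the previous one ended; a segment closes at
    the first (linearly interpolated) crossing of +/-2*pi of cumulative
    phase since its anchor, whichever sign is reached first.  Turns must be
    monotone up to noise: if the phase retraces by more than
    ``hysteresis_rad`` from its running extremum since the anchor (a
    handedness reversal), the partial turn is discarded and the anchor is
    reset to that extremum, so a turn never straddles a reversal.  Partial
    turns at the trace ends are discarded.  ``pitch = |delta s|`` over the
    segment; the handedness is the sign of the completed phase (right = +).
    """
    if not ct.phase_reliable:
        return []
    theta, s, idx = _smoothed_phase(ct, smooth_window)
    if len(theta) < 2:
        return []
    times = ct.time_s[idx]
    segments: list[RotationSegment] = []

    def state_at(j: int):
        return theta[j], s[j], times[j], float(idx[j])

    theta_anchor, s_anchor, t_anchor, idx_anchor = state_at(0)
    j_max = j_min = 0  # running extrema since the anchor
    j = 1
    while j < len(theta):
        dphi = theta[j] - theta_anchor
        if abs(dphi) >= TWO_PI:
            sign = 1.0 if dphi > 0 else -1.0
            target = theta_anchor + sign * TWO_PI
            # linear interpolation between j-1 and j to the exact crossing
            d1, d2 = theta[j - 1], theta[j]
            frac = (target - d1) / (d2 - d1) if d2 != d1 else 1.0
            frac = min(max(frac, 0.0), 1.0)
            s_cross = s[j - 1] + frac * (s[j] - s[j - 1])
            t_cross = times[j - 1] + frac * (times[j] - times[j - 1])
            i_cross = idx[j - 1] + frac * (idx[j] - idx[j - 1])
            ds = s_cross - s_anchor
            seg = RotationSegment(
                start_index=idx_anchor,
                end_index=float(i_cross),
                start_time=float(t_anchor),
                end_time=float(t_cross),
                ds_nm=float(ds),
                dtheta_rad=float(sign * TWO_PI),
                pitch_nm=float(abs(ds)),
                handedness="right" if sign > 0 else "left",
                speed_nm_per_s=np.nan,
            )
            seg.speed_nm_per_s = helical_speed(ct, seg)
            segments.append(seg)
            theta_anchor, s_anchor, t_anchor = target, s_cross, t_cross
            idx_anchor = float(i_cross)
            j_max = j_min = j
            # re-examine the same j: another full turn may complete within it
            continue
        if theta[j] > theta[j_max]:
            j_max = j
        if theta[j] < theta[j_min]:
            j_min = j
        # reversal: retracement beyond the hysteresis band discards the
        # partial turn and re-anchors at the extremum
        if theta[j_max] - theta[j] > hysteresis_rad and theta[j_max] > theta_anchor:
            theta_anchor, s_anchor, t_anchor, idx_anchor = state_at(j_max)
            j_min = j
        elif theta[j] - theta[j_min] > hysteresis_rad and theta[j_min] < theta_anchor:
            theta_anchor, s_anchor, t_anchor, idx_anchor = state_at(j_min)
            j_max = j
        j += 1
    return segments


def _interp_at(ct: CylindricalTrace, i: float) -> tuple[float, float, float]:
    """(s, theta, r) linearly interpolated at fractional frame index ``i``."""
    i0 = int(math.floor(i))
    i1 = min(i0 + 1, len(ct) - 1)
    f = i - i0
    s = ct.s_nm[i0] + f * (ct.s_nm[i1] - ct.s_nm[i0])
    th = ct.theta_rad[i0] + f * (ct.theta_rad[i1] - ct.theta_rad[i0])
    r = ct.r_nm[i0] + f * (ct.r_nm[i1] - ct.r_nm[i0])
    return float(s), float(th), float(r)


def helical_speed(ct: CylindricalTrace, segment: RotationSegment) -> float:
    """Mean speed along the helical path over a rotation segment (nm/s).

    The path length is the per-frame sum of sqrt(ds^2 + (r dtheta)^2)
    (fractional end frames included by linear interpolation), divided by the
    segment duration.
    """
    i_start, i_end = segment.start_index, segment.end_index
    duration = segment.end_time - segment.start_time
    if duration <= 0:
        return np.nan
    knots = [i_start] + [float(k) for k in range(math.ceil(i_start), math.floor(i_end) + 1)] + [i_end]
    knots = [k for n, k in enumerate(knots) if n == 0 or k > knots[n - 1]]
    path = 0.0
    s_prev, th_prev, r_prev = _interp_at(ct, knots[0])
    for k in knots[1:]:
        s_k, th_k, r_k = _interp_at(ct, k)
        if np.isfinite(th_k) and np.isfinite(th_prev):
            r_mid = 0.5 * (r_k + r_prev)
            path += math.hypot(s_k - s_prev, r_mid * (th_k - th_prev))
        s_prev, th_prev, r_prev = s_k, th_k, r_k
    return path / duration


def _windowed_angular_velocity(ct: CylindricalTrace, window_s: float) -> np.ndarray:
    """Central-difference angular velocity over a sliding window (rad/s)."""
    dt = ct.frame_interval
    w = max(1, int(round(window_s / (2 * dt))))
    n = len(ct)
    omega = np.full(n, np.nan)
    theta = ct.theta_rad
    t = ct.time_s
    for i in range(n):
        lo, hi = max(0, i - w), min(n - 1, i + w)
        if hi > lo and np.isfinite(theta[hi]) and np.isfinite(theta[lo]):
            omega[i] = (theta[hi] - theta[lo]) / (t[hi] - t[lo])
    return omega


def detect_switches(
    ct: CylindricalTrace,
    min_persist: int = 10,
    omega_min: float = 0.5,
    window_s: float = 1.0,
) -> list[SwitchEvent]:
    """Detect persistent handedness reversals of the rotation.

    The angular velocity is estimated over a sliding ``window_s`` window;
    frames are classified right (+), left (-) or indeterminate
    (|omega| <= omega_min rad/s, the hysteresis band suppressing
    noise-driven flips).  An event is recorded between two successive runs
    of opposite sign that each persist for at least ``min_persist`` frames;
    the event is placed at the zero crossing of the angular velocity
    between them.
    """
    if not ct.phase_reliable:
        return []
    omega = _windowed_angular_velocity(ct, window_s)
    state = np.zeros(len(omega), dtype=int)
    state[omega > omega_min] = 1
    state[omega < -omega_min] = -1

    runs: list[tuple[int, int, int]] = []  # (sign, start, end_exclusive)
    i = 0
    n = len(state)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        if j - i >= min_persist:
            runs.append((int(state[i]), i, j))
        i = j

    events: list[SwitchEvent] = []
    for (sign_a, _, end_a), (sign_b, start_b, _) in zip(runs, runs[1:]):
        if sign_a == sign_b:
            continue
        # zero crossing of omega between the two runs
        cross = end_a - 1
        for k in range(end_a - 1, start_b + 1):
            if k + 1 < n and np.isfinite(omega[k]) and np.isfinite(omega[k + 1]):
                if omega[k] == 0 or (omega[k] > 0) != (omega[k + 1] > 0):
                    cross = k if abs(omega[k]) <= abs(omega[k + 1]) else k + 1
                    break
        events.append(
            SwitchEvent(
                frame_index=int(cross),
                time_s=float(ct.time_s[cross]),
                preceding="right" if sign_a > 0 else "left",
                following="right" if sign_b > 0 else "left",
            )
        )
    return events


def _signed_rate(pitch_nm: float, handedness: str) -> float:
    sign = 1.0 if handedness == "right" else -1.0
    return sign / pitch_nm


def correct_supertwist(
    pitch_measured: float,
    handedness_measured: str,
    mt_supertwist: float | LatticeSpec,
    rate_tolerance: float = 1e-12,
) -> CorrectedPitch:
    """Remove the lattice supertwist from a measured rotation.

    Implemented on signed twist rates (rate = +/- 1/pitch, positive
    right-handed): ``corrected_rate = measured_rate - lattice_rate``.  An
    untwisted lattice (zero twist rate) leaves the pitch unchanged.  If the
    measured rotation equals the lattice supertwist the corrected rate is
    zero — the probe is simply tracking a protofilament (the kinesin limit)
    — and the result is flagged instead of reporting an infinite pitch.
    """
    if pitch_measured <= 0:
        raise ValueError("pitch_measured must be positive")
    if handedness_measured not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    if isinstance(mt_supertwist, LatticeSpec):
        mt_rate = mt_supertwist.twist_rate / TWO_PI  # turns per nm, signed
    else:
        mt_rate = 0.0 if mt_supertwist == 0 else 1.0 / mt_supertwist
    measured_rate = _signed_rate(pitch_measured, handedness_measured)
    corrected_rate = measured_rate - mt_rate
    if abs(corrected_rate) < rate_tolerance:
        return CorrectedPitch(math.inf, "none", protofilament_tracking=True)
    return CorrectedPitch(
        pitch_nm=abs(1.0 / corrected_rate),
        handedness="right" if corrected_rate > 0 else "left",
    )


def apply_supertwist_correction(
    segments: Sequence[RotationSegment], lattice: LatticeSpec | float
) -> list[RotationSegment]:
    """Fill the corrected-pitch fields of rotation segments in place."""
    for seg in segments:
        corr = correct_supertwist(seg.pitch_nm, seg.handedness, lattice)
        seg.pitch_corrected_nm = corr.pitch_nm
        seg.handedness_corrected = corr.handedness
        seg.protofilament_tracking = corr.protofilament_tracking
    return list(segments)


def segments_to_frame(segments: Sequence[RotationSegment]) -> pd.DataFrame:
    cols = [
        "start_index",
        "end_index",
        "start_time",
        "end_time",
        "ds_nm",
        "dtheta_rad",
        "pitch_nm",
        "handedness",
        "speed_nm_per_s",
        "pitch_corrected_nm",
        "handedness_corrected",
        "protofilament_tracking",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in segments], columns=cols)


class HelixModel:
    """Helical-motility model of a 3D probe track.

    Parameters
    ----------
    track : Track3D or Trajectory3D or DataFrame
        The 3D positions to analyse (any object with ``time_s, x_nm, y_nm,
        z_nm`` and optionally ``valid``).
    lattice : LatticeSpec or signed supertwist pitch (nm), optional
        If given, measured pitches are also reported supertwist-corrected.
    smooth_window : int
        Moving-average window (frames) applied to the unwrapped phase before
        rotation segmentation (five data points by default).
    min_persist : int
        Frames a reversed angular-velocity sign must persist to count as a
        handedness switch.
    omega_min : float
        Hysteresis band (rad/s) for switch detection.
    """

    def __init__(
        self,
        track,
        lattice: Optional[LatticeSpec | float] = None,
        smooth_window: int = 5,
        min_persist: int = 10,
        omega_min: float = 0.5,
        switch_window_s: float = 1.0,
    ) -> None:
        if isinstance(track, pd.DataFrame):
            track = Track3D(
                time_s=track["time_s"].to_numpy(),
                x_nm=track["x_nm"].to_numpy(),
                y_nm=track["y_nm"].to_numpy(),
                z_nm=track["z_nm"].to_numpy(),
                intensity=np.full(len(track), np.nan),
                valid=np.ones(len(track), dtype=bool),
            )
        self.track = track
        self.lattice = lattice
        self.smooth_window = smooth_window
        self.min_persist = min_persist
        self.omega_min = omega_min
        self.switch_window_s = switch_window_s

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HelixModel":
        return cls(Track3D.from_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HelixModel":
        return cls(df, **kwargs)

    def fit(self) -> "HelixResults":
        axis = estimate_axis(self.track)
        ct = to_cylindrical(self.track, axis)
        segments = segment_rotations(ct, smooth_window=self.smooth_window)
        if self.lattice is not None:
            apply_supertwist_correction(segments, self.lattice)
        switches = detect_switches(
            ct,
            min_persist=self.min_persist,
            omega_min=self.omega_min,
            window_s=self.switch_window_s,
        )
        return HelixResults(self, axis, ct, segments, switches)


class HelixResults:
    """Fitted helical-motility results.

    Attributes
    ----------
    axis : Axis
    cylindrical : CylindricalTrace
    segments : list of RotationSegment
    switches : list of SwitchEvent
    """

    def __init__(self, model, axis, cylindrical, segments, switches) -> None:
        self.model = model
        self.axis = axis
        self.cylindrical = cylindrical
        self.segments = segments
        self.switches = switches

    @property
    def n_rotations(self) -> int:
        return len(self.segments)

    @property
    def pitches_nm(self) -> np.ndarray:
        return np.array([s.pitch_nm for s in self.segments])

    @property
    def handedness(self) -> list[str]:
        return [s.handedness for s in self.segments]

    @property
    def fraction_right(self) -> float:
        if not self.segments:
            return np.nan
        return sum(h == "right" for h in self.handedness) / len(self.segments)

    @property
    def mean_radius_nm(self) -> float:
        ct = self.cylindrical
        return float(np.mean(ct.r_nm[ct.valid])) if ct.valid.any() else np.nan

    def rotations_frame(self) -> pd.DataFrame:
        return segments_to_frame(self.segments)

    def switches_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "frame_index": e.frame_index,
                    "time_s": e.time_s,
                    "preceding": e.preceding,
                    "following": e.following,
                }
                for e in self.switches
            ],
            columns=["frame_index", "time_s", "preceding", "following"],
        )

    def pitch_stats(self, corrected: bool = False) -> dict[str, tuple[float, float, int]]:
        """(mean, SEM, n) of pitch overall and per handedness."""
        from .report import mean_sem

        df = self.rotations_frame()
        col = "pitch_corrected_nm" if corrected else "pitch_nm"
        out = {}
        for key, sub in [("all", df)] + [(h, df[df["handedness"] == h]) for h in ("left", "right")]:
            vals = sub[col].dropna().to_numpy() if len(sub) else np.array([])
            vals = vals[np.isfinite(vals)]
            out[key] = mean_sem(vals) if len(vals) else (np.nan, np.nan, 0)
        return out

    def summary(self) -> str:
        """Human-readable summary of the fitted helical motion."""
        lines = ["Helical motility fit", "=" * 52]
        d = self.axis.direction
        lines.append(f"axis direction          [{d[0]: .3f} {d[1]: .3f} {d[2]: .3f}]")
        lines.append(f"mean orbit radius (nm)  {self.mean_radius_nm: .1f}")
        lines.append(f"complete rotations      {self.n_rotations}")
        if self.segments:
            stats = self.pitch_stats()
            for key in ("all", "left", "right"):
                m, sem, n = stats[key]
                if n:
                    lines.append(f"pitch {key:<5} (nm)        {m:8.1f} +/- {sem:5.1f} (SEM, N={n})")
            lines.append(f"fraction right-handed   {self.fraction_right: .2f}")
            if self.model.lattice is not None:
                cstats = self.pitch_stats(corrected=True)
                m, sem, n = cstats["all"]
                if n:
                    lines.append(f"corrected pitch (nm)    {m:8.1f} +/- {sem:5.1f} (SEM, N={n})")
            speeds = [s.speed_nm_per_s for s in self.segments if np.isfinite(s.speed_nm_per_s)]
            if speeds:
                lines.append(f"mean helical speed      {np.mean(speeds):8.1f} nm/s")
        lines.append(f"handedness switches     {len(self.switches)}")
        return "\n".join(lines)
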