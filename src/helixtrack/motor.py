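"""Stochastic motor stepping and synthetic probe trajectories.

Two layers of synthesis:

* a site-resolved Markov stepping model on the binding-site lattice, in which
  the relative weight of the three forward targets decays exponentially with
  their distance and an orientation factor can favour the rightward (or
  leftward) target — the mechanistic picture behind biased helical motility;
* phenomenological cargo trajectories: a probe center orbiting the MT axis at
  a fixed radius along programmed helical segments (pitch + handedness), or
  phase-locked to a simulated multi-motor binding site whose orientation
  state flips stochastically.

Also provides the protofilament-tracking control (a kinesin-like probe whose
only rotation is the lattice supertwist) and AR(1) MT-bridge fluctuation
traces used for reference subtraction of quantum-dot data.

All generators take an explicit seed and are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .lattice import TWO_PI, BindingSite, LatticeSpec, forward_sites, neighbor_distances, site_position

__all__ = [
    "StepModel",
    "PitchSegment",
    "CargoSimConfig",
    "Trajectory3D",
    "step_probabilities",
    "simulate_single_motor",
    "simulate_cargo",
    "simulate_protofilament_tracker",
    "simulate_bridge_fluctuation",
]

Handedness = Literal["left", "right"]

#: Default per-axis localization-like noise (x, y, z), nm.
DEFAULT_NOISE_SD_XYZ = (3.0, 5.0, 10.0)


@dataclass(frozen=True)
class StepModel:
    """Forward-step choice law on the lattice.

    The three forward targets (same protofilament, right neighbour, left
    neighbour) get weights ``exp(-d_i / distance_scale)`` from their
    distances ``d_i``; the target on the favoured side is additionally
    multiplied by ``orientation_bias``.  The exponential form is a modelling
    choice — the underlying biophysics fixes only the ordinal preference
    (nearest site most likely) — so ``distance_scale`` tunes how strongly
    distance penalizes a target.

    Parameters
    ----------
    step_rate : float
        Stepping attempts per second (12.5 /s = 100 nm/s of 8 nm steps).
    distance_scale : float
        Length constant (nm) of the exponential distance penalty.
    backward_fraction : float
        Probability that an attempt is a backward (plus-end) step.
    orientation_bias : float
        Multiplicative weight (>1 favours) applied to the favoured side.
    """

    step_rate: float = 12.5
    distance_scale: float = 2.0
    backward_fraction: float = 0.0
    orientation_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.step_rate <= 0:
            raise ValueError("step_rate must be positive")
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be positive")
        if not 0.0 <= self.backward_fraction <= 1.0:
            raise ValueError("backward_fraction must be in [0, 1]")
        if self.orientation_bias <= 0:
            raise ValueError("orientation_bias must be positive")


@dataclass(frozen=True)
class PitchSegment:
    """One programmed helical segment: duration (s), pitch (nm) and handedness."""

    duration_s: float
    pitch_nm: float
    handedness: Handedness

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.pitch_nm <= 0:
            raise ValueError("segment pitch must be positive")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def angular_rate_sign(self) -> float:
        return 1.0 if self.handedness == "right" else -1.0


def _as_segments(program: Sequence) -> tuple[PitchSegment, ...]:
    out = []
    for seg in program:
        out.append(seg if isinstance(seg, PitchSegment) else PitchSegment(*seg))
    return tuple(out)


@dataclass(frozen=True)
class CargoSimConfig:
    """Cargo/probe trajectory synthesis parameters.

    ``orbit_radius`` is the probe-center distance from the MT axis (~250 nm
    for a 0.5 um bead around a 25 nm MT; ~50 nm for a quantum dot).  Frames
    are sampled every ``frame_interval`` seconds (100 ms default).
    ``pitch_program`` drives the programmed mode and sets the total duration
    in the mechanistic mode; ``switch_rate`` is the Markov flip rate of the
    motor-team orientation state in the mechanistic mode.
    """

    pitch_program: tuple[PitchSegment, ...]
    orbit_radius: float = 250.0
    axial_speed: float = 100.0
    frame_interval: float = 0.1
    noise_sd_xyz: tuple[float, float, float] = DEFAULT_NOISE_SD_XYZ
    switch_rate: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pitch_program", _as_segments(self.pitch_program))
        if len(self.pitch_program) == 0:
            raise ValueError("pitch_program must contain at least one segment")
        if self.orbit_radius <= 0:
            raise ValueError("orbit_radius must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.axial_speed <= 0:
            raise ValueError("axial_speed must be positive")
        if any(s < 0 for s in self.noise_sd_xyz):
            raise ValueError("noise SDs must be non-negative")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be non-negative")

    @property
    def total_duration(self) -> float:
        return float(sum(seg.duration_s for seg in self.pitch_program))


@dataclass
class Trajectory3D:
    """Time-stamped 3D probe positions (nm), optionally with noise-free truth."""

    time_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    z_nm: np.ndarray
    true_x_nm: Optional[np.ndarray] = None
    true_y_nm: Optional[np.ndarray] = None
    true_z_nm: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("time_s must be a non-empty 1D array")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        for name in ("x_nm", "y_nm", "z_nm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != t.shape:
                raise ValueError(f"{name} must match time_s in length")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)
        self.time_s = t
        if self.valid is None:
            self.valid = np.ones(len(t), dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm, self.z_nm])

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s, "x_nm": self.x_nm, "y_nm": self.y_nm, "z_nm": self.z_nm}
        if self.true_x_nm is not None:
            data["true_x_nm"] = self.true_x_nm
            data["true_y_nm"] = self.true_y_nm
            data["true_z_nm"] = self.true_z_nm
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.meta.items():
                fh.write(f"# {key}: {value}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory3D":
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
        kwargs = {}
        if "true_x_nm" in df.columns:
            kwargs = {
                "true_x_nm": df["true_x_nm"].to_numpy(),
                "true_y_nm": df["true_y_nm"].to_numpy(),
                "true_z_nm": df["true_z_nm"].to_numpy(),
            }
        return cls(
            time_s=df["time_s"].to_numpy(),
            x_nm=df["x_nm"].to_numpy(),
            y_nm=df["y_nm"].to_numpy(),
            z_nm=df["z_nm"].to_numpy(),
            meta=meta,
            **kwargs,
        )


def step_probabilities(
    distances, model: StepModel, favored_side: Literal["right", "left", "none"] = "right"
) -> np.ndarray:
    """Normalized probabilities of the three forward targets.

    ``distances`` is the (same_pf, right, left) triple in nm — a dict from
    :func:`helixtrack.lattice.neighbor_distances` or a length-3 sequence.
    """
    if isinstance(distances, dict):
        d = np.array(
            [distances["same_pf_forward"], distances["forward_right"], distances["forward_left"]]
        )
    else:
        d = np.asarray(distances, dtype=float)
    if d.shape != (3,) or np.any(d <= 0):
        raise ValueError("distances must be three positive values (same_pf, right, left)")
    # shift by the minimum distance: identical probabilities, but stable in
    # the small-distance-scale limit (softmax trick)
    w = np.exp(-(d - d.min()) / model.distance_scale)
    if favored_side == "right":
        w[1] *= model.orientation_bias
    elif favored_side == "left":
        w[2] *= model.orientation_bias
    elif favored_side != "none":
        raise ValueError("favored_side must be 'right', 'left' or 'none'")
    return w / w.sum()


def simulate_single_motor(
    spec: LatticeSpec,
    model: StepModel,
    n_steps: int,
    seed: Optional[int] = None,
    initial_site: BindingSite = BindingSite(0, 0),
    favored_side: Literal["right", "left", "none"] = "none",
) -> tuple[list[BindingSite], np.ndarray]:
    """Markov chain of binding sites with exponential waiting times.

    Returns the visited sites (length ``n_steps + 1`` including the start)
    and their occupation times.  Single motors carry no orientation bias by
    default (``favored_side='none'``) — biased stepping is the dimer /
    multi-motor regime.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    probs = step_probabilities(neighbor_distances(spec), model, favored_side)
    site = initial_site
    sites = [site]
    times = [0.0]
    t = 0.0
    for _ in range(n_steps):
        t += rng.exponential(1.0 / model.step_rate)
        if model.backward_fraction > 0 and rng.random() < model.backward_fraction:
            site = BindingSite(site.pf_index, site.axial_index - 1)
        else:
            target = rng.choice(3, p=probs)
            key = ("same_pf_forward", "forward_right", "forward_left")[target]
            site = forward_sites(site)[key]
        sites.append(site)
        times.append(t)
    return sites, np.asarray(times)


def _programmed_phase(config: CargoSimConfig, t: np.ndarray, twist_rate: float) -> np.ndarray:
    """Unwrapped azimuth of the programmed helix at times ``t``."""
    theta = np.zeros_like(t)
    t0 = 0.0
    theta0 = 0.0
    v = config.axial_speed
    for seg in config.pitch_program:
        omega = seg.angular_rate_sign * TWO_PI * v / seg.pitch_nm + twist_rate * v
        in_seg = t >= t0
        theta[in_seg] = theta0 + omega * (t[in_seg] - t0)
        theta0 += omega * seg.duration_s
        t0 += seg.duration_s
    return theta


def _sample_piecewise_constant(event_times: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(event_times, t, side="right") - 1
    return values[np.clip(idx, 0, len(values) - 1)]


def simulate_cargo(
    config: CargoSimConfig,
    spec: Optional[LatticeSpec] = None,
    mode: Literal["programmed", "mechanistic"] = "programmed",
    seed: Optional[int] = None,
    model: Optional[StepModel] = None,
    initial_orientation: Literal["right", "left"] = "right",
) -> Trajectory3D:
    """Synthesize a cargo-bead (or quantum-dot) trajectory.

    programmed
        Deterministic helix of radius ``orbit_radius``: axial advance at
        ``axial_speed``, azimuthal rate ±2π·speed/pitch per program segment
        plus the lattice supertwist rotation (if a lattice is given), plus
        per-axis Gaussian noise.
    mechanistic
        The probe is phase-locked to the azimuth of a multi-motor binding
        site simulated on the lattice; the motor-team orientation state
        (which lateral side the bias favours) flips as a 2-state Markov
        process at ``switch_rate``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_frames = int(round(config.total_duration / config.frame_interval)) + 1
    t = np.arange(n_frames) * config.frame_interval
    twist_rate = spec.twist_rate if spec is not None else 0.0

    if mode == "programmed":
        s = config.axial_speed * t
        theta = _programmed_phase(config, t, twist_rate)
    elif mode == "mechanistic":
        if spec is None:
            raise ValueError("mechanistic mode requires a lattice spec")
        if model is None:
            model = StepModel()
        s, theta = _mechanistic_site_path(config, spec, model, rng, initial_orientation, t)
    else:
        raise ValueError("mode must be 'programmed' or 'mechanistic'")

    R = config.orbit_radius
    true_x = s
    true_y = R * np.cos(theta)
    true_z = R * np.sin(theta)
    noise = np.column_stack(
        [rng.normal(0.0, sd, n_frames) if sd > 0 else np.zeros(n_frames) for sd in config.noise_sd_xyz]
    )
    return Trajectory3D(
        time_s=t,
        x_nm=true_x + noise[:, 0],
        y_nm=true_y + noise[:, 1],
        z_nm=true_z + noise[:, 2],
        true_x_nm=true_x,
        true_y_nm=true_y,
        true_z_nm=true_z,
        meta={"mode": mode, "seed": seed, "orbit_radius_nm": R},
    )


def _mechanistic_site_path(
    config: CargoSimConfig,
    spec: LatticeSpec,
    model: StepModel,
    rng: np.random.Generator,
    initial_orientation: str,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial position and unwrapped azimuth of the leading-motor site over time."""
    distances = neighbor_distances(spec)
    duration = float(t[-1])
    orientation = initial_orientation
    site = BindingSite(0, 0)
    times = [0.0]
    s_vals = [0.0]
    theta_vals = [0.0]
    # track azimuth continuously (site azimuth is only defined mod 2pi)
    dphi = TWO_PI / spec.n_protofilaments
    theta = 0.0
    s = 0.0
    next_flip = rng.exponential(1.0 / config.switch_rate) if config.switch_rate > 0 else np.inf
    clock = 0.0
    while clock < duration:
        dt = rng.exponential(1.0 / model.step_rate)
        clock += dt
        if clock > next_flip:
            orientation = "left" if orientation == "right" else "right"
            next_flip += rng.exponential(1.0 / config.switch_rate)
        probs = step_probabilities(distances, model, favored_side=orientation)
        target = rng.choice(3, p=probs)
        if target == 0:
            ds = spec.axial_repeat
            dth = 0.0
        elif target == 1:  # right neighbour: +azimuth, stagger shortens the rise
            ds = spec.axial_repeat - spec.stagger
            dth = dphi
        else:  # left neighbour
            ds = spec.axial_repeat + spec.stagger
            dth = -dphi
        s += ds
        theta += dth + spec.twist_rate * ds
        times.append(clock)
        s_vals.append(s)
        theta_vals.append(theta)
    times = np.asarray(times)
    s_arr = _sample_piecewise_constant(times, np.asarray(s_vals), t)
    theta_arr = _sample_piecewise_constant(times, np.asarray(theta_vals), t)
    return s_arr, theta_arr


def simulate_protofilament_tracker(
    spec: LatticeSpec,
    axial_speed: float = 100.0,
    duration: float = 60.0,
    noise_sd_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: Optional[int] = None,
    orbit_radius: float = 250.0,
    frame_interval: float = 0.1,
) -> Trajectory3D:
    """Probe rigidly following a single protofilament (kinesin-like control).

    The probe's only rotation about the MT axis is the lattice supertwist,
    so the measured helical pitch of this trajectory is the supertwist pitch
    itself (no rotation on an untwisted 13-protofilament lattice).
    """
    if axial_speed <= 0 or duration <= 0 or frame_interval <= 0:
        raise ValueError("axial_speed, duration and frame_interval must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval)) + 1
    t = np.arange(n_frames) * frame_interval
    s = axial_speed * t
    theta = spec.twist_rate * s
    true_x = s
    true_y = orbit_radius * np.cos(theta)
    true_z = orbit_radius * np.sin(theta)
    noise = np.column_stack(
        [rng.normal(0.0, sd, n_frames) if sd > 0 else np.zeros(n_frames) for sd in noise_sd_xyz]
    )
    return Trajectory3D(
        time_s=t,
        x_nm=true_x + noise[:, 0],
        y_nm=true_y + noise[:, 1],
        z_nm=true_z + noise[:, 2],
        true_x_nm=true_x,
        true_y_nm=true_y,
        true_z_nm=true_z,
        meta={"mode": "protofilament_tracker", "seed": seed, "supertwist_pitch_nm": spec.supertwist_pitch},
    )


def simulate_bridge_fluctuation(
    sd_perp: float = 35.0,
    sd_par: float = 17.0,
    n_frames: int = 1000,
    seed: Optional[int] = None,
    frame_interval: float = 0.1,
    correlation_time: float = 0.5,
) -> pd.DataFrame:
    """Thermal fluctuation of a suspended MT bridge as seen by a fiducial probe.

    Zero-mean AR(1) series with the requested stationary SDs (nm) in the
    directions perpendicular and parallel to the MT long axis.  Returns a
    DataFrame with columns ``time_s, perp_nm, par_nm``.
    """
    if sd_perp < 0 or sd_par < 0:
        raise ValueError("SDs must be non-negative")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    rho = math.exp(-frame_interval / correlation_time) if correlation_time > 0 else 0.0

    def ar1(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n_frames)
        x = np.empty(n_frames)
        x[0] = rng.normal(0.0, sd)
        innov = rng.normal(0.0, sd * math.sqrt(1.0 - rho**2), n_frames - 1)
        for i in range(1, n_frames):
            x[i] = rho * x[i - 1] + innov[i - 1]
        return x

    t = np.arange(n_frames) * frame_interval
    return pd.DataFrame({"time_s": t, "perp_nm": ar1(sd_perp), "par_nm": ar1(sd_par)})
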