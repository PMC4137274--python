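"""Microtubule binding-site lattice geometry.

A microtubule (MT) is modelled as a uniform helical lattice of tubulin-dimer
binding sites on a cylinder.  Sites repeat every 8 nm along each protofilament;
laterally adjacent protofilaments are staggered axially (B-lattice), which
breaks the left/right symmetry of sideways steps taken by a motor walking
toward the minus end.  Lattices with 12 or 14 protofilaments additionally
carry a slow supertwist: the protofilaments themselves wind around the MT
axis, right-handed with a 4000 nm pitch for 12 protofilaments and left-handed
with a 6400 nm pitch for 14; 13-protofilament lattices are untwisted.

Shared sign convention (used by every module in this package): the motion
axis points toward the MT minus end (the travel direction of dynein); a
right-handed helix has azimuth increasing by the right-hand rule about that
axis.  Signed pitches and twist rates are positive for right-handed twist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeSpec",
    "BindingSite",
    "build_lattice",
    "site_position",
    "neighbor_distances",
    "forward_sites",
    "SUPERTWIST_PITCH_NM",
]

TWO_PI = 2.0 * math.pi

#: Signed supertwist pitch (nm per full turn) by protofilament count.
#: Positive = right-handed; an untwisted lattice is encoded as 0 (zero twist
#: rate), not an infinite pitch.
SUPERTWIST_PITCH_NM: dict[int, float] = {12: 4000.0, 13: 0.0, 14: -6400.0}

#: Lattice constants not fixed by the geometry facts above.  The lateral
#: spacing and B-lattice stagger are reverse-engineered so that the forward
#: right/left neighbour distances come out at 9.3 / 10.8 nm (to 0.1 nm);
#: they are overridable per spec.
DEFAULT_LATERAL_SPACING_NM = 6.0
DEFAULT_AXIAL_REPEAT_NM = 8.0
DEFAULT_STAGGER_NM = 0.92
DEFAULT_MT_RADIUS_NM = 12.5

_POLYMER_TYPES = ("GMP-CPP", "taxol")


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of one microtubule lattice.

    Parameters
    ----------
    n_protofilaments : int
        Number of protofilament tracks (12, 13 or 14).
    supertwist_pitch : float
        Signed supertwist pitch in nm per full turn.  Positive means a
        right-handed supertwist, negative left-handed; ``0`` encodes an
        untwisted lattice (zero twist rate).
    lateral_spacing : float
        Surface distance in nm between adjacent protofilament axes.
    axial_repeat : float
        nm per tubulin dimer along a protofilament (8 nm).
    stagger : float
        Axial rise in nm between laterally adjacent binding sites
        (B-lattice, ~0.92 nm).
    mt_radius : float
        nm from the MT axis to the binding-site surface.
    polymer_type : str
        Polymerization condition the lattice was built for (bookkeeping).
    """

    n_protofilaments: int
    supertwist_pitch: float
    lateral_spacing: float = DEFAULT_LATERAL_SPACING_NM
    axial_repeat: float = DEFAULT_AXIAL_REPEAT_NM
    stagger: float = DEFAULT_STAGGER_NM
    mt_radius: float = DEFAULT_MT_RADIUS_NM
    polymer_type: str = "taxol"

    def __post_init__(self) -> None:
        if self.n_protofilaments not in (12, 13, 14):
            raise ValueError(
                f"unsupported protofilament count {self.n_protofilaments}; "
                "supported counts are 12, 13 and 14"
            )
        if not math.isfinite(self.supertwist_pitch):
            raise ValueError("supertwist_pitch must be finite; use 0 for an untwisted lattice")
        if self.axial_repeat <= 0:
            raise ValueError("axial_repeat must be positive")
        if self.lateral_spacing <= 0:
            raise ValueError("lateral_spacing must be positive")
        if not 0 <= self.stagger < self.axial_repeat:
            raise ValueError("stagger must satisfy 0 <= stagger < axial_repeat")
        if self.mt_radius <= 0:
            raise ValueError("mt_radius must be positive")

    @property
    def twist_rate(self) -> float:
        """Signed supertwist rate in rad per nm of axial advance (0 if untwisted)."""
        if self.supertwist_pitch == 0.0:
            return 0.0
        return TWO_PI / self.supertwist_pitch

    @property
    def handedness(self) -> str:
        """Supertwist handedness: 'right', 'left' or 'none'."""
        if self.supertwist_pitch == 0.0:
            return "none"
        return "right" if self.supertwist_pitch > 0 else "left"

    def to_dict(self) -> dict:
        return {
            "polymer_type": self.polymer_type,
            "n_protofilaments": self.n_protofilaments,
            "supertwist_pitch": self.supertwist_pitch,
            "lateral_spacing": self.lateral_spacing,
            "axial_repeat": self.axial_repeat,
            "stagger": self.stagger,
            "mt_radius": self.mt_radius,
        }


@dataclass(frozen=True)
class BindingSite:
    """One tubulin-dimer binding site, addressed on the helical lattice.

    ``pf_index`` wraps modulo the protofilament count but is stored unwrapped
    so that walking around the lattice accumulates azimuth and stagger
    continuously (the seam is ignored; the lattice is treated as a uniform
    helical family).
    """

    pf_index: int
    axial_index: int


def build_lattice(polymer_type: str, n_protofilaments: int, **overrides) -> LatticeSpec:
    """Construct a :class:`LatticeSpec` for a polymerization condition.

    The supertwist follows the protofilament count: 12 -> right-handed
    4000 nm pitch, 13 -> untwisted, 14 -> left-handed 6400 nm pitch.
    ``overrides`` may replace any other lattice constant.
    """
    if polymer_type not in _POLYMER_TYPES:
        raise ValueError(f"unknown polymer_type {polymer_type!r}; expected one of {_POLYMER_TYPES}")
    if n_protofilaments not in SUPERTWIST_PITCH_NM:
        raise ValueError(
            f"unsupported protofilament count {n_protofilaments}; "
            f"supported counts are {sorted(SUPERTWIST_PITCH_NM)}"
        )
    return LatticeSpec(
        n_protofilaments=n_protofilaments,
        supertwist_pitch=SUPERTWIST_PITCH_NM[n_protofilaments],
        polymer_type=polymer_type,
        **overrides,
    )


def _axial_coordinate(spec: LatticeSpec, site: BindingSite) -> float:
    # Axial coordinate increases toward the minus end (travel direction).
    return site.axial_index * spec.axial_repeat + site.pf_index * spec.stagger


def _azimuth(spec: LatticeSpec, site: BindingSite) -> float:
    # pf_index decreases azimuth: with stagger accumulating at +pf, the
    # forward site on the RIGHT neighbour (azimuth +2pi/n, i.e. pf-1) then
    # sits 'stagger' nm closer, reproducing the rightward-bias geometry.
    s = _axial_coordinate(spec, site)
    return -site.pf_index * TWO_PI / spec.n_protofilaments + spec.twist_rate * s


def site_position(spec: LatticeSpec, site: BindingSite) -> np.ndarray:
    """3D position of a binding site, in nm.

    The x axis is the motion axis (toward the minus end); (y, z) span the
    transverse plane so that increasing azimuth follows the right-hand rule
    about +x.  The azimuth of a site is its protofilament angle plus the
    supertwist rotation accumulated over its axial position.
    """
    s = _axial_coordinate(spec, site)
    theta = _azimuth(spec, site)
    return np.array(
        [s, spec.mt_radius * math.cos(theta), spec.mt_radius * math.sin(theta)]
    )


def forward_sites(site: BindingSite) -> dict[str, BindingSite]:
    """The three forward step targets from ``site``.

    'same_pf_forward' is the next dimer on the same protofilament;
    'forward_right' / 'forward_left' are the nearest forward sites on the
    right / left neighbouring protofilaments (right = +azimuth = pf_index-1
    under this package's sign convention).
    """
    return {
        "same_pf_forward": BindingSite(site.pf_index, site.axial_index + 1),
        "forward_right": BindingSite(site.pf_index - 1, site.axial_index + 1),
        "forward_left": BindingSite(site.pf_index + 1, site.axial_index + 1),
    }


def neighbor_distances(spec: LatticeSpec) -> dict[str, float]:
    """Distances (nm) from a bound site to its three forward neighbours.

    Computed on the unrolled (flat) lattice: the next site along the same
    protofilament is one axial repeat ahead; the nearest forward site on the
    right neighbouring protofilament is one lateral spacing across and
    (repeat - stagger) ahead, on the left (repeat + stagger) ahead.  With the
    default constants these are 8.0 / 9.3 / 10.8 nm after 0.1 nm rounding,
    the asymmetry underlying a net rightward stepping preference.  No
    rounding is applied here.
    """
    a, w, g = spec.axial_repeat, spec.lateral_spacing, spec.stagger
    return {
        "same_pf_forward": a,
        "forward_right": math.hypot(w, a - g),
        "forward_left": math.hypot(w, a + g),
    }
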