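# Methods

This note documents the models implemented in `helixtrack`, their
assumptions, the parameter defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Microtubule lattice (`helixtrack.lattice`)

A microtubule is modelled as a uniform helical lattice of tubulin-dimer
binding sites on a cylinder.  Fixed geometric facts:

| quantity | value | notes |
|---|---|---|
| axial repeat | 8 nm / dimer | along one protofilament |
| supertwist, 12 pf | +4000 nm / turn | right-handed |
| supertwist, 13 pf | 0 (untwisted) | encoded as zero twist rate |
| supertwist, 14 pf | −6400 nm / turn | left-handed |

Constants that are *not* fixed by those facts — lateral spacing 6.0 nm,
B-lattice stagger 0.92 nm (≈ the 12 nm three-start rise divided by 13), MT
radius 12.5 nm — were reverse-engineered so that the unrolled-lattice
distances from a bound site to the nearest forward sites on the right and
left neighbouring protofilaments come out at 9.3 and 10.8 nm after 0.1 nm
rounding (√(6.0² + (8 − 0.92)²) = 9.28, √(6.0² + (8 + 0.92)²) = 10.75).
They are overridable per lattice.  Distances are computed on the unrolled
(flat) lattice rather than as chords on the cylinder; the difference is
< 0.1 nm at these scales.  The seam and lattice defects are ignored: the
stepping model below is seam-agnostic.

**Sign convention (package-wide).**  The motion axis points toward the MT
minus end (dynein's travel direction); azimuth increases by the right-hand
rule about that axis, so right-handed helices have positive twist rates and
signed pitches.  With the stagger accumulating at +1 per protofilament
index, consistency with "the forward-right site is the nearer one" forces
the protofilament index to *decrease* azimuth — the opposite sign would put
the 9.3 nm site on the left.

## Stepping model (`helixtrack.motor`)

The step-choice law is a modelling choice, not an established result: the
underlying geometry fixes only the ordinal preference (nearest forward site
most likely).  We use exponential distance weighting

    w_i = exp(−d_i / λ) × (orientation bias on the favoured side),

normalized over {same-protofilament, forward-right, forward-left}, with
λ = `distance_scale` (default 2 nm) controlling how strongly distance
penalizes a target.  At the default geometry this gives step fractions of
roughly 0.56 / 0.30 / 0.14, i.e. a net rightward drift of ~0.16 sideways
steps per step and an emergent right-handed pitch of a few hundred nm on a
13-protofilament lattice — the observed order of magnitude.  Waiting times
are exponential at `step_rate` (default 12.5 s⁻¹ ≈ 100 nm/s of 8 nm steps).

Handedness switching of a motor *team* is modelled phenomenologically as a
two-state Markov process over the team orientation (which lateral side the
bias favours), flipping at `switch_rate` (default 0.1 s⁻¹).  No mechanistic
rate law is asserted; the observed per-rotation switch ratios in the two
documented conditions (4/67 and 8/33) bracket plausible values but do not
determine a mechanism.

Cargo trajectories assume the bead center is rigidly phase-locked to the
leading motor azimuth at a fixed orbit radius (default 250 nm for beads,
50 nm for quantum dots) — no tether compliance, no bead rotation about its
own center.  The MT bridge is perfectly straight and stationary for bead
simulations; thermal bridge fluctuation is only added in quantum-dot
scenarios, as a zero-mean AR(1) series with stationary SDs 35 nm
(perpendicular) and 17 nm (parallel) and a 0.5 s correlation time (the
correlation time is a free choice; only the stationary SDs are
constrained).  Localization noise is isotropic per-axis Gaussian, default
(3, 5, 10) nm for (x, y, z), echoing the stated tracking precisions.

## Image synthesis (`helixtrack.imaging`)

Frames are rendered as a symmetric 2D Gaussian spot (SD 250 nm) on a
constant background, sampled at pixel centers (160 nm pixels), with the
peak amplitude above background following a cubic in z:

    A(z) = c0 + c1 z + c2 z² + c3 z³,   default (200, 0.5, 0, 6·10⁻⁷) counts,

strictly monotone over ±250 nm.  The coefficients are synthetic by
construction (no published values exist to copy) and are recorded in every
config/sidecar.  A Gaussian spot rather than a physical defocused-bead PSF
is deliberate: the tracker fits a Gaussian, so a Gaussian phantom isolates
estimator correctness from PSF mismatch.  A config hook
(`contrast_inversion`) can emulate the near-focus regime where a real
defocused bead image stops being Gaussian-fittable; it is off by default.
Noise is Gaussian read noise (SD 4 counts) with optional Poisson.

The calibration protocol is a stationary bead swept over ±250 nm in 25 nm
steps (21 planes), the sweep repeated 20 times.

## Tracking (`helixtrack.tracking`)

* **xy localization**: nonlinear least squares of a symmetric 2D Gaussian +
  constant background on a 17×17-pixel ROI around the brightest pixel.
  Quality = RMS residual / amplitude; frames above the 0.2 cutoff (or with
  insignificant amplitude) are flagged, never raised.  At the default
  noise, the RMS error is ≈ 2.5 nm per axis (the analytic bound for
  Gaussian read noise is σ·a·√(2/π)/A ≈ 2.6 nm).
* **Center intensity**: a Gaussian-apodized window (SD 2 pixels) centered
  on the *sub-pixel* fitted position, background-subtracted (border
  median).  A hard-edged disc was rejected: its weight sum jumps by ~0.3%
  as the center crosses pixel boundaries, which aliases into ~10 nm z
  errors; the untruncated apodized window is sub-pixel invariant to ~10⁻⁶.
* **z calibration**: per-plane mean window intensities, normalized to the
  brightest plane, fitted with a cubic *on the rescaled [−1, 1] domain*
  (a raw Vandermonde solve at z ~ 250 loses ~6 digits on the cubic
  coefficient) and converted back.  Construction fails for < 4 planes or a
  non-monotone fit.  The curve stores its normalization constants
  (background, scale); movies tracked against it reuse them, which makes
  calibration and movie intensities commensurable whenever they share an
  imaging configuration.  A per-movie-maximum normalization is available
  (`normalization="movie_max"`) and agrees for movies that span the full z
  range; the stored-constants default is also correct when they do not.
* **z inversion**: bracketed root finding (Brent) on the monotone cubic,
  tolerance 10⁻⁶ nm; intensities outside the attained range by more than
  2% of the span are clamped to the boundary and flagged.
* **Smoothing**: centered moving average, default window 5 frames,
  shrunken windows at the edges, flagged frames excluded.
* **Reference subtraction**: the fiducial trace is interpolated onto the
  track's time base and subtracted on the perpendicular axis only by
  default (matching how quantum-dot traces are corrected for bridge
  oscillation); the parallel axis is optional.

## Helix analysis (`helixtrack.helix`)

* **Axis estimation**: principal component of the point cloud, oriented
  along net displacement (valid because motors on a single bridge move
  unidirectionally along the axis), then refined by a cylinder fit: the
  direction is optimized (Nelder–Mead over two tilt parameters) until the
  transverse points are best explained by a circle (algebraic Kåsa fit,
  which also supplies the axis origin).  The refinement matters: the raw
  principal axis of a *finite* helix is genuinely tilted (~2° for typical
  traces) because axial position correlates with orbit phase, and that
  tilt alone biases pitch estimates by ~1%.  With refinement, noiseless
  recovery is exact.  Degenerate tracks — net displacement not exceeding
  twice the RMS transverse spread — are rejected.
* **Phase reliability**: when the mean orbit radius does not exceed 3× the
  SD of the radius, the apparent azimuth is dominated by localization
  noise (the probe is not actually orbiting) and its unwrapped phase is a
  random walk; rotation counting and switch detection are suppressed for
  such traces.  This is what keeps the false-positive rate of switch
  detection at zero on non-rotating noisy traces.
* **Rotation segmentation**: the unwrapped phase (5-point smoothed) is
  sliced into consecutive complete 2π turns anchored where the previous
  turn ended, with linear interpolation to the exact crossing.  Turns must
  be monotone up to noise: a retracement of more than π/2 from the running
  extremum discards the partial turn and re-anchors at the extremum, so no
  turn straddles a handedness reversal.  Partial turns at the ends are
  discarded.
* **Switch detection**: angular velocity over a 1 s sliding window; frames
  classified right/left/indeterminate with a ±0.5 rad/s hysteresis band
  (a genuine rotation at ~600 nm pitch and 100 nm/s runs at ~1 rad/s,
  while phase noise at a 250 nm orbit contributes < 0.1 rad/s); events are
  recorded between opposite-sign runs that each persist ≥ 1 s, at the zero
  crossing of the angular velocity.  Half-turn reversals are detected even
  though only full turns are counted as rotations.
* **Supertwist correction** is exact algebra on signed rates and is the
  exact inverse of how the simulator composes motor rotation with lattice
  twist.  Corrected pitches are always reported alongside raw ones, and
  outputs state which is which.

## Statistics (`helixtrack.report`)

Mean ± SEM uses the n−1 sample SD; SEM for a single value is reported as
undefined.  The two-sample t test defaults to Welch's unequal-variance form
(a plain "t test" is ambiguous; the pooled Student form is available by
flag).  The N−1 two-proportion test is the pooled two-proportion z
statistic times √((N−1)/N) with a normal reference.  Tests are two-sided by
default with a one-sided option; no multiple-testing correction is applied.
Pitch histograms use 100 nm bins over 0–1500 nm.  Report regeneration from
the same inputs is byte-identical, with any timestamp isolated to a single
header line.

## What the generators do not emulate

Passing the pipeline on synthetic data shows estimator correctness under
the stated models, not robustness to everything real data contains.  Not
modelled: physical optics of defocused beads (Mie rings, aberrations),
camera gain structure, bead tether compliance and rotational diffusion,
curved or oscillating bridges in bead assays, force-dependent stepping
kinetics, detachment/run-length statistics, and multi-bead fields.  The
step-choice law and team-orientation switching are phenomenological
stand-ins for unknown mechanisms, with their parameters exposed.

## Problem sizes

Default validation runs use 15–40 s trajectories at 10 Hz (150–400
frames), 50–200 random seeds for stochastic claims, 21 × 20-frame
calibration stacks, and 145 s / 90 s noise-free tracker runs for the
supertwist references (≥ 2 full turns at 100 nm/s).  These sizes put the
statistical error of each check well below its tolerance while keeping the
full suite under a minute of compute.
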