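# Methods

## Scope and model overview

`speckleflow` models the post-beamformed image domain of blood speckle
imaging: multichannel cine loops of a tissue brightness channel, an
in-plane velocity field, and a [0, 1] confidence channel, acquired at a
pixel pitch of 0.0825 mm/pixel and a pulse repetition frequency (PRF) of
6 kHz, with a tracking velocity limit of 2 m/s. Acoustics (beamforming, RF
data, attenuation), 3D motion and proprietary scanner file formats are out
of scope.

Coordinates: x is the long (flow) axis, y the short axis, y increasing
toward the posterior wall; pixel (0, 0) is the top-left (anterior) corner
and physical positions are pixel index × pitch in mm, 0-based.

## Synthetic phantom

**What it emulates.** Fully developed blood speckle texture (point
scatterers at 4 per PSF area, Rayleigh-distributed reflectivities, Gaussian
point-spread function with σ = 1.2 px), pulsatile flow with a raised-cosine
systolic envelope peaking at t/T = 0.2 and vanishing for t/T ∈ [0.5, 1),
and two clinically motivated scenarios: a symmetric top-hat outflow jet
(post-repair) and an anteriorly deflecting stenotic jet with posterior flow
reversal (pre-repair). Additive Gaussian brightness noise (σ = 0.02
relative to a unit speckle peak) models electronic noise; an optional
depth-proportional noise ramp (off by default) emulates depth-dependent
confidence loss.

**What it does not emulate.** Out-of-plane scatterer motion, tissue/valve
motion, depth-dependent resolution loss, reverberation and clutter, and
speckle decorrelation mechanisms other than in-plane deformation. Passing
tests therefore demonstrate correctness of the quantification chain under
ideal 2D speckle transport, not robustness to every clinical artifact.

**Timing.** Frames are spaced at 1/PRF — the interval the tracker converts
displacements with — and one cardiac cycle spans `frames_per_cycle` frames,
so the phantom period is `frames_per_cycle / prf` (≈ 8.3 ms at the
defaults). The cycle is deliberately compressed relative to physiology:
what tracking and the phase axis t/T see — displacement per frame pair and
fraction of cycle — is kept in the clinically reported regime, while a
physiological 0.8 s cycle at 6 kHz would cost 4800 frames per cycle for no
additional validation power.

**Stenotic flow construction.** The pre-repair field superposes (i) a
forward jet core with squared-parabola (C¹) edges that narrows and drifts
anteriorly as systole develops, and (ii) a posterior lobe of fixed
parabolic geometry whose amplitude crossfades from a forward "wash" early
in systole to retrograde recirculation once the jet detaches. Two
numerical consequences drove this construction: a parabolic lobe has a
linear velocity gradient across the near-wall band, which finite matching
kernels average without bias; and producing the wall-WSS sign change by an
amplitude crossfade rather than by sweeping steep spatial structure past
the wall keeps the transition trackable. The resulting analytic
posterior-wall OSI is ≈ 0.24 — the order of magnitude reported clinically
for pre-operative outflow obstruction — while the top-hat scenario gives
OSI ≈ 0.

**Advection** uses a midpoint (RK2) step of the analytic flow at 1/PRF.
Scatterers leaving the margined domain re-enter periodically at the
opposite edge of the axis they left with fresh reflectivities, conserving
count and density without seeding holes in recirculating regions.

## Block-matching tracker

For kernels (default 15 × 15 px on a 4 px grid) the tracker scans integer
lags in a square search window (radius `ceil(v_max/(prf·pitch)) + 1` = 6 px
at the defaults) and scores normalized cross-correlation (NCC; sum of
absolute differences available as a speed option, with NCC still evaluated
at the chosen lag for confidence). Only lags inside the disc
|d| ≤ v_max/(prf·pitch) ≈ 4.04 px are admissible — the implementation of
the 2 m/s tracking limit; the extra ring of scores exists so sub-pixel
refinement always has neighbors. Ties are broken deterministically by
smallest displacement magnitude, then dy, then dx.

**Sub-pixel refinement** defaults to the three-point Gaussian fit (a
parabola on log-scores), which is exact for the Gaussian-shaped NCC peak
produced by a Gaussian PSF and suppresses the integer-pixel peak-locking
bias a plain parabolic fit exhibits; the parabolic fit is retained as an
option. A perfect score skips refinement (an exact match is already at
zero offset). Refined displacements are clamped radially to the admissible
disc, so reported speeds never exceed `v_max`; true motion beyond the disc
is matched at the nearest admissible lag — an underestimated speed with
depressed confidence, the saturation signature of the modality.

**Confidence** is the NCC value at the best integer lag clamped to [0, 1];
kernels whose search window touches the frame border carry confidence 0.
The on-device confidence definition of commercial scanners is not public;
clamped NCC is the simplest quantity honoring the "block-matching
fidelity" semantics and the [0, 1] range.

**Vector-field regularization.** Kernel-grid velocities are smoothed with
a small Gaussian (σ = 0.75 grid cells, configurable, 0 disables) before
being rasterized to the pixel grid. The grid is padded by odd reflection
first so linear shear ramps pass through unchanged at the grid edge. This
is standard PIV practice: speckle-pattern estimation noise (≈ 0.02–0.03 px
per kernel, largely independent of additive image noise) otherwise
dominates differentiated quantities. Rasterization to pixel density is
bilinear from the valid-kernel subgrid, with nearest-edge extension and
zero confidence outside the valid hull; bilinear interpolation is exact
for linear fields and keeps confidence within [0, 1].

Displacements convert to velocity as v = d · pitch · PRF. Frame pair
(k, k+1) fills frame k; the final frame repeats the previous estimate.

## Hemodynamic indicators

Shear profiles differentiate the long-axis velocity along a sampling line
with central differences in the interior and one-sided differences at the
ends of each contiguous run of confidence-passing samples (threshold 0.5 by
default); masked gaps are never bridged. Uniform sample spacing is
required; velocities are m/s, distances mm, stresses Pa with blood modeled
as Newtonian at μ = 0.0035 Pa·s (configurable; the underlying acquisitions
do not report viscosity).

Wall WSS series sample the shear value at the confidence-passing sample
nearest the chosen endpoint of the probe line ("anterior" = start,
"posterior" = end), with the posterior sign flipped so forward near-wall
flow is positive at both walls — a flow reversal is then a sign change of
the series at either wall. Frames lacking a valid near-wall sample are
dropped; more than 20 % of them is a quality error. The series is closed
periodically at t₀ + T and integrated with the composite trapezoid rule on
the actual frame times: TAWSS = (1/T)∫|WSS|dt and
OSI = ½(1 − |∫WSS dt| / ∫|WSS| dt), clipped to [0, 0.5]; an identically
zero series leaves OSI undefined and raises. Only the axial (long-axis)
WSS component enters OSI; the in-plane vector form would be a
straightforward extension.

`ensemble_wall_series` averages wall series over parallel probe lines at
several long-axis positions. For axially homogeneous flow these are
replicate measurements of the same waveform with largely independent
speckle noise; averaging the series before summarizing reduces both the
variance and the noise-rectification bias of TAWSS/OSI. The default probe
lines (`default_line`, `wall_probe_lines`) are aligned with kernel-grid
nodes — endpoints on the first/last valid kernel rows, one sample per grid
stride — so profile samples coincide with kernel estimates and a tracked
series and a ground-truth series share the identical finite-difference
recipe.

Peak-velocity traces take the per-frame maximum of |V_long| along the line
together with the mean confidence there; the simplified Bernoulli gradient
is ΔP = 4 v² mmHg with the standard clinical constant.

## Validation experiments and problem sizes

The test suite validates each operation against independent oracles
(exhaustive-search block matching, rendered sub-pixel shifts, analytic
derivatives and quadratures) and runs two phantom experiments sized for a
single CPU:

* **Saturation**: a 3 m/s stenotic jet at 25 frames/cycle, 128² px,
  tracked at v_max = 2 m/s — maximum reported speed equals the limit and
  jet-core confidence drops relative to an unsaturated 1.5 m/s run.
* **End-to-end recovery**: four replicate 50-frame stenotic phantoms plus
  one top-hat phantom at 128² px. Posterior-wall indicators from tracked
  data, ensemble-averaged over ~13 probe lines and the replicates, match
  the analytic-field indicators within 15 % (TAWSS) and 0.05 (OSI), and
  OSI(stenotic) > OSI(top-hat) reproduces the qualitative pre/post
  contrast. Single-probe, single-realization wall WSS carries irreducible
  ±15–30 % speckle-noise swings; the replicate averaging is the
  experimental remedy, not a change to the per-line recipe.

## Numerical choices and degenerate inputs

* Tie-breaks in the lag search are deterministic (see above); all
  randomness flows from a single seed via `numpy.random.SeedSequence`
  spawning, so containers and summaries are bit-reproducible.
* Zero-variance kernels (flat image regions) score 0 and never win over a
  genuine correlation.
* Sub-pixel offsets are clipped to ±0.5 px; non-concave three-point
  configurations fall back to zero offset.
* `shear_profile` requires ≥ 3 valid samples; runs shorter than 3 are NaN.
* `cycle_phase` and all container constructors validate positivity and
  monotonicity of their metadata and raise typed errors (`ValidationError`,
  `ParameterError`, `DomainError`, `QualityError`) that the CLI maps to
  exit codes 2/2/2/3.

## Known limitations

* The confidence model (clamped NCC) is a proxy; absolute confidence
  values are not comparable to any specific scanner's channel, only the
  qualitative behavior (1 for exact matches, depressed under noise,
  decorrelation and saturation) is.
* Wall shear stress at the anterior wall of the stenotic phantom sits in a
  low-gradient, near-edge region of the jet and is recovered less
  accurately than the posterior wall; the validation experiment therefore
  targets the posterior wall, where the clinically interesting reversal
  lives.
* Tracked velocities lag the frame timestamp by half a frame (displacement
  over [t, t+1/PRF] is reported at t); at 50 frames per cycle this shifts
  wall-series phase by 1 % of the cycle and is ignored.
* The phantom's diastole is flow-free; diastolic inflow patterns are not
  modeled.
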