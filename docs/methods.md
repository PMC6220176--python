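# Methods

This note records the model, the numerical and design choices behind the
package, what the synthetic data do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Excitable network on the perimeter

The protrusion-generating network is a two-species activator–inhibitor
system on a periodic ring representing the cell boundary:

    ∂X/∂t = D_X ∇²X − a₁X − a₂(Y − R)X + a₃X²/(a₄² + X²) + a₅ + U_N
    ∂Y/∂t = D_Y ∇²Y + ε(−Y + b₁X)

Assumptions: the boundary is one-dimensional and does not deform (no
mechanochemistry); concentrations are dimensionless activity levels; the
stochastic input U_N is spatially independent white noise acting on the
activator only; the stimulus R is spatially uniform unless a localized
patch is requested explicitly.

Discretization: 300 grid points, dx = 1 model length unit (no physical
µm calibration is claimed), central-difference Laplacian with periodic
wraparound, explicit Euler–Maruyama with dt = 0.01 model seconds and the
√dt·σ_N noise scaling. The stability bound dt·max(D_X, D_Y)/dx² ≤ 0.5 is
enforced at construction. Negative excursions are not clamped; a
non-finite state raises a numerical-instability error naming the step.
Step-halving convergence of deterministic runs is part of the test suite.

### Parameter values and the preset-tuning procedure

The shared constants are

| constant | value | role |
|---|---|---|
| D_X / D_Y | 1 / 5 | activator vs faster inhibitor diffusion (lateral inhibition) |
| a₁ | 1.0 | activator decay (sets the fast time scale, ~1 s) |
| a₂ | 2.0 | inhibition coupling |
| a₃ / a₄ | 10 / 1.0 | autocatalysis rate and half-saturation |
| a₅ | 0.02 | basal production (rest state X* ≈ 0.022) |
| ε | 0.08 | inhibitor time scale (~12 s), sets firing duration/refractoriness |

These were chosen, before any acceptance measurement, by nullcline
analysis: the activator nullcline is cubic-like with a knee near X ≈ 1,
and b₁ ≥ ~2.5 makes the inhibitor nullcline Y = b₁X cross only on the
left branch, giving a unique stable rest state with a firing threshold
(kick amplitude ≈ 0.075 on a 20-point arc) and a large excursion
(X ≈ 4). The two presets then modulate exactly the two knobs the regimes
require:

* `high_threshold`: b₁ = 3.0, σ_N = 0.035 — noise reaches the threshold
  rarely; firings are localized (< 50% of the perimeter) and drive
  discrete ERK pulses;
* `low_threshold`: b₁ = 2.2, σ_N = 0.16 — lower threshold and stronger
  noise give near-continuous firing and sustained ERK activation.

σ_N was selected by scanning the spontaneous firing rate at fixed b₁ and
keeping the value that yields a handful of well-separated firings per
two-hour-equivalent run (high) or near-continuous activity (low); the
regime dichotomy is then verified independently by the acceptance tests.
The count of discrete pulses in any single 2-h run is seed-dependent
(typically 3–6 for the high preset).

### Time scale

The integrator step is 0.01 model seconds while imaging-cadence data are
in minutes. A single constant, `MODEL_SECONDS_PER_MINUTE = 10`, maps
model time to displayed minutes (600 model s ≙ 1 h). With this mapping a
firing lasts ~1–2 displayed minutes per perimeter location and the
refractory period is ~5 displayed minutes.

### Excitability measurements

`threshold_probe` kicks the activator on a contiguous arc at rest
(deterministic mode) and records the peak excursion of the spatial mean
of X. An excitable parameter set shows an all-or-none jump: responses
above threshold cluster within ~25% and dwarf subthreshold responses.

`refractory_period` applies two identical kicks separated by a gap and
reports the smallest tested gap at which the second response reaches 80%
of the first. Two methodological details matter. First, the second
response is isolated by subtracting a single-kick control run — at short
gaps the tail of the first response would otherwise be mistaken for
recovery. Second, the packaged characterization probes with a
just-suprathreshold kick (1.5× the measured threshold): strong probes
force firing during the relative refractory phase and produce a
non-monotone recovery curve with a supernormal window, whereas the
near-threshold probe gives a clean all-or-none recovery gap (~50 model s
for the high preset).

## Zero-order ultrasensitive ERK switch

Whole-cell active ERK Z follows a Goldbeter–Koshland push–pull cycle
with an extra linear loss c₅Z that speeds the off-transition; diffusion
is ignored because the readout is global. The drive is the instantaneous
spatial mean of the inhibitor, U_E = ⟨Y⟩(t), floored at 0 (with a logged
count) against transient undershoots.

Defaults: c₁ = 0.1, c₂ = 1, c₃ = 0.05, c₄ = 0.3, c₅ = 0.1. Rationale:
c₃/c₂ = 0.05 puts the cycle in the zero-order regime (EC90/EC10 far
below the Michaelian 81); the switch threshold sits near c₄, chosen
between the resting drive (⟨Y⟩ ≈ 0.07 = b₁X*) and the drive during a
localized firing (⟨Y⟩ ≈ 1), so a protrusion occupying a small arc still
flips the switch fully; c₁ sets rise/fall times of a few displayed
minutes. Integration is fixed-step RK4 with the drive held
piecewise-constant between network samples (default step = the network
sampling interval, 1 model s); the state is clipped to [0, c₂] to absorb
solver overshoot at the saturated rails. Steady states are found by
bracketed root finding on [0, c₂], where monotonicity of the terms makes
the root unique.

## Stimulus-protocol experiments

The growth-factor protocols use the high-threshold preset with the noise
reduced to σ_N = 0.01 — enough to keep the setting stochastic without
seeding spontaneous firings that would confound stimulus-evoked peaks —
and a uniform stimulus of amplitude 0.3 switched on at t = 100 model s.
The amplitude is comfortably suprathreshold while leaving the driven
oscillation slow enough (period ≈ 50 model s) for the ERK switch to
track each cycle; much stronger drives oscillate faster than the switch
can follow. "Sustained" keeps R on for the rest of the run; "transient"
switches off after 30 model s (3 displayed minutes), before the first
refractory period has elapsed, which is what makes the response a single
peak. The packaged measurements are: perimeter coverage of the first
excursion, ERK peak spacing relative to the measured refractory period,
and the transient/sustained first-peak ratio.

## Frame Difference Method

Percent change per pixel between two `avg_window`-frame temporal
averages separated by `interval_minutes` (default 6 min), with the
*earlier* average as the denominator, so +100 is exactly a twofold
increase. Averaging (default window 3, the midpoint of the supported
2–4) precedes differencing. Pixels whose earlier average falls below an
intensity floor (default 1% of the stack maximum) are NaN-masked, never
silently zero. The percent-change movie is scale-invariant by
construction.

Detection thresholds and filters keep the published defaults: 100% over
6 min within a ±3 px band around the segmented outline for protrusions,
with ≥ 5 min duration and ≥ 25 px peak area; 10% after eroding the mask
(default 5 px) for interior flashes, with no duration filter. Tracking
links 8-connected per-frame components across frames by ≥ 1 px overlap
with no gap closing; merging tracks count as one event. Segmentation is
Otsu threshold → largest component → hole fill → longest iso-contour as
the ordered boundary polyline.

Conventions: pixel coordinates are 0-based, row-major, origin top-left;
perimeter angles measure counter-clockwise from the +x (column) axis
with y up; kymograph bin 0 starts at angle 0. Kymographs sample the
percent-change image (masked pixels as 0), max-pooled over a 2-px disc,
along the boundary polyline, resampled by arclength. Event angular
positions are area-weighted centroids about the cell centroid.

For movies rendered from model trajectories the analysis uses
avg_window = 1: the renderer has no boundary-undulation noise for the
averaging to suppress, and the simulated excitation travels as a wave
that visits each perimeter bin for roughly one frame, so averaging would
dilute the differenced signal threefold.

## Trace metrics

Pulse calling smooths with a 3-frame moving average (configurable),
takes each local maximum against its preceding local minimum as
baseline, and emits an event when the fractional rise exceeds the
threshold (default 20%). The baseline definition (preceding local
minimum) is a documented choice; overlapping rises sharing a baseline
are fused into one flagged event; equal-height peak ties resolve to the
earlier peak. The detector is invariant to positive rescaling.

Cross-correlation computes the Pearson coefficient of overlapping
segments at every integer-frame lag in ±max_lag; r(L) = corr(a(t),
b(t+L)), so a positive best lag means the second trace follows the
first (protrusion leads → positive ERK lag). Ties break toward the
smallest |lag|, then negative. Zero-variance overlaps are flagged NaN
and excluded from the argmax.

Half-maximum lags pair each reporter pulse with the nearest preceding
protrusion peak within a pairing window (default 15 min; the
nearest-preceding rule is a documented stand-in for the narrative event
pairing) and difference the first crossings of baseline + ½(peak −
baseline) on the rising edges, linearly interpolated between samples.
Summary statistics are mean ± s.e.m. (sample s.d./√n).

## Synthetic data

Trace-level: protrusion activity is a baseline plus Gaussian bumps
(FWHM = pulse width) at seeded random onsets kept ≥ 2.5 widths apart;
the reporter echoes each bump delayed by the planted lag and scaled by
the coupling gain, with optional white noise on both.

Movie-level: a static disc cell (radius 30 px in a 96×96 field) with a
disc nucleus; four channels. Protrusion-marker: baseline 100 inside the
cell; each planted protrusion is a disc bump straddling the boundary
whose intensity ramps linearly (2 min) to `amplitude_fold`× and holds
for its duration; interior flashes are boxcar patches at 0.45× the cell
radius. Reporter: rests nuclear-enriched (N:C = 2:1) and redistributes
nucleus→cytoplasm conserving total intensity, with fractional C/N
increase = erk_gain × (fold − 1) per event, delayed by `erk_delay`
(default 5 min) with a triangular 3-min-rise/4-min-fall profile. Volume
and membrane channels are uniform over the cell; an optional
multiplicative "shape artifact" modulates the cytoplasm identically in
the reporter and volume channels so volume normalization is testable.
Read noise is additive Gaussian, clipped at zero; all generators are
bitwise-reproducible under a fixed seed. Default cadence: 1 min/frame
for 360 min.

The default planted schedule uses folds 2.6–3.2 held 9–11 min: after
3-frame averaging and 6-min differencing, the contrast stays above the
100% threshold for the full 5-min minimum duration. A marginal event
(e.g. fold 2.4 with a 2-min ramp) drops below threshold partway through
the interval and is — correctly — rejected by the duration filter.

What the generator does not emulate: boundary deformation (bumps change
intensity, not geometry), photobleaching, drift, multi-cell fields,
PSF/optics, Poisson-dominated shot noise at low counts, and reporter
saturation. Passing tests therefore demonstrate correctness of the
measurement chain under controlled ground truth, not robustness to
every artifact of real microscopy.

The model-to-movie bridge (`render_from_model`) maps the activator field
to boundary-band intensity folds (1 + 0.5·X at the matching perimeter
angle, frames resampled to 1 min) and the normalized switch state to the
same conserved reporter redistribution (gain 0.5).

## Problem sizes

Defaults were sized for interactive use: spontaneous-regime runs are
1200 model s (120 000 steps × 300 points, a few seconds each), protocol
runs 1000 model s, planted-recovery analyses use ten 360-frame 96×96
movies, and lag recovery twenty 360-sample trace pairs. The full test
suite runs in about two minutes on one CPU; the acceptance script in
about one.

## Known limitations

* The refractory-period contract assumes a monotone recovery curve; it
  holds for near-threshold probes but strong probes reveal a supernormal
  phase, which `refractory_period` does not model beyond returning the
  smallest qualifying gap.
* The discrete-pulse count of a single stochastic run has wide seed
  variability; regime claims should be read distributionally.
* Event tracking has no gap closing: an event whose percent-change dips
  below threshold for one frame splits in two.
* `segment_cell` assumes one dominant bright cell; it is a deterministic
  stand-in for interactive segmentation, not a general cell segmenter.
* The C/N measurement in the packaged pipeline uses the generator's
  nucleus mask; nucleus segmentation from the reporter channel alone is
  out of scope.
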