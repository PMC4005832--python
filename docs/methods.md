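# Methods

## Model of a recorded session

A simulated LHR session is a fixed camera's grayscale video (default
30 Hz, 8-bit) of a rectangular target (reference: 140 mm × 90 mm) that is
dark except when a laser pulse fires (repetition ≤ 2 Hz). The scene model
behind the pipeline is: background ≈ 0 with small sensor noise; a fired
pulse adds a compact bright blob (the laser window blurred by the
diffusing silicone sheet and the camera PSF); an air fire (pulse fired
with the applicator lifted) adds a weak, spatially diffuse brightness lift
with no blob. Secondary reflections may add smaller bright clusters.

## Calibration

One known physical dimension and its pixel extent define the conversion
ratio `C` [mm/px] (reference: 140 mm = 397 px, C = 0.3526). The template
side is `round(laser_window / C)` with **half-up** rounding — the only
convention that maps the 12 mm window at this calibration to the reference
34 px template. `C` is stored at full precision; 0.35 is a display
rounding. A corner-based estimator (mean centroid of repeated shots at
each target corner, pixel extent = mean of top and bottom edge lengths) is
provided for when no ruler measurement exists; the mapping of calibration
shots to corners is this package's convention.

## Frame extraction

Candidate exposures are contiguous runs of the mean-intensity trace above
`q + ε·(max − q)`, where `q` is the 0.5 trace quantile and `ε = 0.05`; the
event sits at the run maximum, taking the **first frame of a plateau** (a
2 Hz pulse can span frames at 30 Hz, but each pulse is one exposure). The
relative ε makes detection invariant to uniform intensity rescaling and
keeps half-above-median background fluctuation from generating events.
Events closer than `floor(frame_rate / (2·max_pulse_rate))` frames (7 at
30 Hz / 2 Hz) are merged keeping the taller peak.

The air-fire rule rejects events below 30% of the "normal" peak height.
Normal is not observable directly, so it is fixed as the **median** of all
candidate peak heights — robust against the air fires themselves. Heights
are measured above the candidacy baseline, which keeps the ratio test
meaningful when background noise lifts the whole trace. The filter flags
events rather than dropping them (idempotent, and the flags are useful
diagnostics); downstream steps use only valid events.

## Spot detection

Binarization at 30% of the frame maximum (inclusive ≥), component
labelling with **8-connectivity** (a blurred spot is compact; 8-neighbours
resist single-pixel threshold cuts), largest component wins, ties broken
by the component containing the lexicographically smallest (row, col)
pixel. The centroid is the unweighted mean of the binary component's
pixel coordinates (the binarized image, not intensity, carries the
position). Coordinates are 0-based (row, col), row increasing downward;
distances are convention-free.

## LDM synthesis

Continuous centroids are rounded half-up to a grid cell; the template
spans `ceil((t−1)/2)` cells before and `floor((t−1)/2)` after the center
in each axis (t = 34: 17 before, 16 after — an even side cannot be
centered symmetrically, so the convention is fixed and documented).
Templates overhanging the target edge are **clipped**, not rejected:
firing at the target boundary is legal technique. Exposure conservation
(`ΣL = β·t²` for unclipped spots) holds as an exact integer identity and
is tested as such.

## Indices: numerical choices

* `υ` uses the **sample** (n−1) standard deviation; the reference worked
  example (ratio 0.1453 → 0.15) is reproduced only by the sample form
  (population std gives 0.119).
* The defining formula carries a ×100, but the reference worked example
  prints the raw ratio; both forms are exposed (`upsilon_pct`,
  `upsilon_ratio`) and no intent is guessed.
* `μ` is computed at full precision. The reference worked example's
  printed 3.87 arises from averaging the distances *at their printed 2-dp
  precision* (3.61, 4.12 → 3.865 → 3.87); full precision gives 3.8643.
  Where the printed value is asserted, the printed-precision chain is
  reproduced explicitly (decimal quantization, half-up).
* `d_c` is defined over the temporal detection order; `d_n` is
  order-free. No raster turn-around exclusion is applied to `μ` (the
  source procedure defines none).
* Degenerate inputs: β < 2 raises (distance indices undefined); all-spots
  coincident raises for `υ`; an all-zero LDM yields δ₀ = 100, δ_z = 0.

## Synthetic-session generator

The generator emulates the study conditions rather than any measured
operator model (none exists): intended positions on a serpentine raster of
pitch 12 mm (the laser-window side — the uniform-coverage ideal) inset by
pitch/2 from the target edges; isotropic Gaussian jitter per fired pulse;
omission, double-exposure and (SBS only, at row turn-arounds) air-fire
events as Bernoulli draws. Presets encode the qualitative technique
contrast: sliding jitter 2.0 mm vs. SBS 1.2 mm (sliding showed higher
delivery randomness), air fires only in SBS, omission 0.08/0.05, a
technique-neutral double rate of 0.03 (an asymmetric double rate would
confound the jitter-driven υ contrast, since near-coincident spots
dominate the nearest-neighbour CV). Feedback multiplies jitter by 0.7 and
omissions by 0.6. One seeded generator drives each session; identical
seed and config give bit-identical ground truth.

Rendering: pulses are placed with sub-pixel accuracy by fractional pixel
coverage of the continuous window square (side `laser_window/C` px, peak
200), blurred with a Gaussian of σ = 2 px; zero-mean Gaussian sensor noise
(σ = 0.5 gray levels) is added per frame before quantization to 8 bits.
Frames include a margin of one template side around the target, mirroring
the camera's wider view, so edge-adjacent spots are not clipped in image
space (they are clipped later, in the LDM). Air-fire frames add a uniform
level equal to 25% of a pulse frame's mean signal above background, which
puts them below the 30% rejection cutoff with deterministic margin at any
noise level. Pulse/air events occupy one frame each at the
`frame_rate/pulse_rate` spacing (15 frames).

What the generator does **not** emulate: gel marks and their behavioural
illusions, curved anatomy, non-uniform within-window fluence, thermal
relaxation, camera distortion, or realistic operator learning. Passing
pipeline tests therefore demonstrate correctness of the image-processing
and scoring chain under the stated scene model, not performance on
arbitrary clinical video.

## Session analysis

Paired (post − pre; sliding − SBS relative to the SBS reference) and
one-sample (μ against the 12 mm window) two-sided t-tests, computed from
the textbook statistic with Student-t tails. Zero-variance differences are
reported with an explicit `degenerate` flag (t = 0, p = 1 when the mean
difference is also zero; p = 0 otherwise) instead of NaN. No
multiple-testing correction is applied across the four indices, matching
the tabular convention being emulated. ANOVA/Tukey and normality checks
are left to standard statistical libraries.

## Problem sizes and verification scale

The deterministic worked example runs in milliseconds. Stochastic suites
use sizes chosen to keep the full test run at desk scale while preserving
statistical power: rendered-video recovery uses 50 seeded SBS sessions on
a 60 × 48 mm target (20 intended spots, ~330 frames of 204 × 238 px each);
the jitter sweep uses 10 σ levels × 20 seeds on generated spot sequences.
Observed behaviour at these sizes: every session's detected pulse count
matches ground truth, all rendered air fires are rejected, and detected
centroids land within 0.5 px of truth per coordinate in ≥ 95% of spots
(empirically ~0.3 px maximum at default blur/noise).

## Known limitations

* Peak-trace extraction assumes at most one pulse per frame and pulses
  separated by several frames; lasers pulsing faster than the camera frame
  rate are out of scope.
* The air-fire rule needs a majority of valid pulses for the median
  reference to be "normal"; a session that is mostly air fires would
  mis-reference.
* The centroid is unweighted over the binarized blob, so heavily
  asymmetric blur or saturation could bias it; the simulator's symmetric
  PSF does not probe this.
* Operator-behaviour distributions are stand-ins for testing, not claims
  about human operators.
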