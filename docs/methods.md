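# Methods

This note documents the models implemented in `flexbeam`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic data do and do not establish about real acquisitions.

## Coordinate and unit conventions

Lateral position `x` (mm) increases with element index; axial depth `z`
(mm) is positive into the medium; the origin is the aperture's lateral
center on the skin line. Sound speed is in m/s (default 1540), times in
seconds, sampling rate `fs` in Hz (default 40 MHz). Delays are integer
samples throughout: `d = Δt · fs`. Positive delay shifts a trace later
in time. Depth↔sample conversion uses the pulse-echo convention
`n = round((2z/c − t0)·fs)`.

## Array geometries

`make_geometry` builds flat, circular-arc and polyline apertures,
centered so the mean lateral position is zero. Arc elements are spaced
equally **in arc length** (a bent physical array preserves the
inter-element distance along its face), convex toward the medium: the
apex element stays on the skin line, the edges move to `z > 0`. The
available descriptions of the bent-probe experiments are consistent
with convex curvature, and convex is what a probe strapped over a
curved abdomen assumes; concave shapes can still be expressed as
polylines. The sag is computed as `2R·sin²(θ/2)` rather than
`R(1 − cos θ)` to avoid catastrophic cancellation at large radii (at
R = 10⁹ mm the exact edge sag of a 127 mm aperture is 2·10⁻⁶ mm and the
naive form is all rounding error).

Probe defaults are 128 elements at 1 mm pitch (a ≈128 mm footprint);
center frequency 5 MHz with 60% fractional (−6 dB) bandwidth. The
element-level hardware parameters of the physical flexible probe are
not public, so these are package defaults chosen to be representative
of an abdominal-imaging linear array, and everything is configurable.

## RF channel-data simulator

`simulate_rf` is a desk-scale time-of-flight simulator, not a
spatial-impulse-response solver. For each scanline (one transmit
element, all elements receiving) and each scatterer it adds a
Gaussian-modulated cosine replica centered at the **exact** two-way
ToF, with amplitude `a / (r_tx · r_rx)` (spherical spreading; distances
clamped below 0.25 mm so an element-coincident scatterer cannot produce
an infinite amplitude — the ToF itself needs no guard). Optional
cosine element directivity is available but off by default. White
Gaussian noise of standard deviation `noise_level × max|clean data|`
is added when requested and always requires an explicit seed.

What this reproduces faithfully: arrival times (the quantity APR
estimates), relative channel amplitudes, the weak-edge-response
behavior that limits APR at the aperture edges, linearity, and
tx/rx reciprocity. What it omits: diffraction from finite element
faces, elevation aperture, frequency-dependent attenuation, nonlinear
propagation, and calibrated speckle statistics. Consequently the tests
demonstrate the *delay-estimation logic* under controlled conditions;
they do not certify image quality on a physical system, where echo
consistency — the method's known weak point — is worse.

Phantoms: single center target (0, 30) mm, two targets (±30, 30) mm, a
single right-side target (30, 30) mm, and a seeded scatter cloud
(default 10,000 scatterers, Gaussian reflectivity) with an embedded
circular region whose amplitude is scaled by a contrast factor (0 =
anechoic). The cloud's box, disc position/radius and contrast are
package defaults exposed as parameters, since no reference values are
published for them.

## Artificial curvature (`curve_rf`)

To obtain bent-probe data with known ground truth, flat-acquisition RF
data are re-delayed: for every scanline, focal points are placed one
per depth sample along the scanline's recorded beam axis, and each
channel trace is resampled through the time warp defined by the pairs
(two-way ToF with the source shape, two-way ToF with the target shape).

Two numerical decisions matter here:

* **The warp is inverted on its monotone branch.** For a curved target
  the two-way ToF along the axis is not monotone in depth above the
  raised edge elements (the focal point first approaches, then recedes
  from, an element standing at `z_e > 0`). Interpolating over the full
  table silently corrupts the mapping; the inversion therefore starts
  at each element's ToF minimum. Focal points on the shallow branch
  (above the element height) are not representable — they are also not
  imaged by the beamformer.
* **Band-limited resampling.** Fractional delays are applied by 8×
  FFT oversampling followed by linear interpolation on the fine grid
  (`mode="bandlimited"`, the default; plain `linear` and `nearest`
  remain available). At 8 samples per carrier cycle, plain linear
  interpolation leaves ~8% per-channel errors; these are invisible at
  the image peak but dominate pixels 40 dB down, where beamforming sums
  cancel almost completely. With band-limited resampling the
  flat→arc→DAS round trip agrees with the flat DAS image to <0.5 dB
  everywhere in the top 40 dB of the display range.

The RF container carries `scanline_x`, the lateral position of each
scanline's beam axis. This is an acquisition property — curving the
data does not move the lines along which the scanlines were recorded —
and both `curve_rf` and the DAS beamformer use it, which is what makes
the round trip an identity up to interpolation.

## Preprocessing

Normalization is global first (divide by the maximum magnitude of the
tensor), then optionally gated: divide by the maximum inside a depth
band around the marker, 9–24 mm by default, matching a marker structure
≈17 mm tall sitting on the skin. The gated step exists for
experimental-style data with echoes from below the standoff; in
simulation mode, where the marker is the only reflector, the default
gate is the whole record. Note that with a *single* marker and the full
128 mm aperture, the marker echo of an edge element arrives at an
apparent pulse-echo depth of ~66 mm — far outside a literal 9–24 mm
window — so a hard gate is only appropriate when markers are
distributed across the aperture (the four-needle experimental layout)
or the aperture is small.

RF-trace smoothing for peak detection is a window-9 moving average of
the analytic-signal magnitude (reflective boundaries, so a constant
trace is unchanged). The round-1 delay curve can be re-smoothed with a
Savitzky–Golay filter, window 21 (the nearest odd value to the nominal
20; a symmetric filter needs odd support), polynomial order 2. SG of
order 2 passes quadratics exactly but attenuates the quartic component
of the true delay hyperbola; with the window spanning 21 of 128
scanlines this bias stays ≈1 sample, and the smoothed curve is rounded
back to integers and re-anchored so the reference scanline stays at 0.
The window should be scaled down for much smaller apertures — on a
32-element aperture a 21-scanline window is disproportionate and the
raw estimate is more accurate.

## Two-round APR

`peak_sample` returns the argmax of the smoothed envelope magnitude
inside the gate, ties broken toward the earliest sample; an identically
zero gated segment raises a no-peak error. Round 1 aligns each
scanline's own-transmit-element trace to the reference scanline's;
round 2, after round 1 is applied, aligns the per-element traces within
each scanline to the transmit element's trace, walking outward and
clamping element-to-element increments to ±threshold (default 5
samples). A no-peak column inherits its inner neighbor's delay; a
no-peak scanline inherits the nearest valid scanline's delay; only a
no-peak on the reference is fatal. Substitution counts are logged and
reported (`DelayCurve.n_substituted`) because weak edge responses are
the method's primary failure mode.

**Reference scanline.** The default is `"strongest"` — the scanline
with the largest gated peak amplitude, i.e. the one nearest a marker.
The reference fixes the image's depth datum: every aligned peak lands
at the reference's peak sample. Anchoring on an edge scanline (e.g.
"first") with a single center marker would place the marker at the edge
element's apparent depth (~70 mm for the 30 mm target) and destroy
depth recovery; the strongest response is also the most reliable
estimate. `"first"`, `"middle"` and explicit indices are supported.

**Threshold.** The clamp is an outlier guard for noisy data, not a
physical bound: for strongly curved geometries the *true*
neighbor-to-neighbor receive-delay increment reaches ~25 samples per
element at the aperture edges (fs = 40 MHz), so on clean wide-aperture
data the clamp distorts the outer columns of round 2. Fixed-focus
summation is forgiving of this — the misaligned outer columns add
incoherently and the image maximum is unaffected — but delay-accuracy
studies against the geometric oracle disable the clamp
(`threshold=None`).

**Oracle delays.** `oracle_delays` computes, from known element
positions and a known marker, exactly the delays a perfect APR would
estimate (`total[s, e] = t_ref − t[s, e]` in samples). It provides the
ground-truth curves for the delay-error metric and the fixed-focus DAS
reference, and doubles as an independent check of the estimator: on
noise-free simulated data the estimated scanline-level curve agrees
with the oracle to ≤1.4 samples MAE for the flat and 500/700 mm convex
shapes, and unclamped round 2 agrees to ≈0.3 samples MAE on every
column whose echo remains inside the record after the round-1 shift
(with a single marker and a wide aperture, scanline-constant alignment
pushes the far-element echoes of off-center scanlines out of the
record; those columns are unrecoverable by construction and are
excluded from the comparison).

## Beamforming

Both beamformers share the image grid (one column per scanline, one row
per RF depth sample, `z = c·(t0 + n/fs)/2`), envelope detection
(analytic-signal magnitude) and log compression (`20·log10(x/max)`
clipped at −60 dB by default). No apodization and no aperture growth:
all 128 receive elements contribute at every depth. No scan conversion
is applied; columns follow scanline axes.

* `beamform_apr`: integer-delay application, summation over elements —
  fixed-focus by construction.
* `beamform_das`: the geometry-aware reference. Dynamic receive
  focusing (exact two-way ToF per focal point, band-limited channel
  resampling) is the default ground truth; a fixed-focus mode applies
  integer oracle delays for a stated focal depth and is bit-identical
  to `beamform_apr` fed with oracle delays.

## Metrics

* FWHM: linear interpolation between the half-maximum crossings of the
  envelope profile through the target's peak pixel, in mm. Undefined
  (error) if the profile never falls below half maximum — which
  genuinely happens for the lateral profile of an APR image on a small
  aperture; the pipeline reports NaN in that case.
* CNR = `20·log10(|μ_out − μ_in| / sqrt(σ_out² + σ_in²))` on
  linear-scale pixels. The absolute difference keeps the metric real
  when the target is brighter than the background; equal means return
  a −∞ sentinel.
* PSNR = `10·log10(peak²/MSE)` over dB-domain images with peak = the
  60 dB display span (a standard definition, adopted as such; identical
  images return +∞).
* Location error = ground-truth depth − estimated depth (mm, signed).
* Delay error: total = Σ per-scanline |estimated − truth| in samples,
  mean = total / n_scanlines. A squared-difference mode is provided;
  absolute differences are the default reading of "quantity variance".

## Acceptance-scale study conditions

The acceptance suite runs the full 128-element, 1 mm-pitch, 40 MHz,
noise-free configuration for the point-recovery and delay-oracle
checks and the 500 mm round trip. The noise-degradation study uses a
64-element aperture (the mechanism under test — peak misdetection on
weak traces — does not depend on the aperture being full-width) with
noise levels 0, 0.05, 0.1 and 0.2 of the clean maximum, 10 seeds each,
and the raw (un-resmoothed) scanline-level estimate. Below ≈0.05 the
added noise acts as *dither* on the integer-sample rounding of the
peak positions and can nudge the MAE in either direction by fractions
of a sample; monotone degradation is a property of the regime where
misdetection, not quantization, dominates. This is a known limitation
of integer-sample delay estimation, not of the test.

## Known limitations

* Fixed-focus delays: resolution and accuracy hold near the marker
  depth only; integrating dynamic focusing would require inverting the
  delays into element positions, which is out of scope.
* Integer-sample delays only; no sub-sample refinement and no
  cross-correlation estimator.
* The simulator's idealizations (above) mean quantitative image-quality
  numbers (FWHM/CNR/PSNR) from simulation are not comparable to values
  measured on physical phantoms; they are reported for relative
  comparisons within a run.
* With a single marker, delay estimates far from the marker's lateral
  position degrade (weak echoes, record truncation after alignment);
  multiple distributed markers trade this against inter-marker
  interference.
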