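# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind phantomqa's measurements and its simulator.

## Coordinate conventions

Phantom frame: right-handed, origin at the phantom center, units mm,
`+y` anterior ("up" in a displayed axial slice). The phantom pose in an
image is a rigid in-plane transform (rotation + translation, mm); all
conversions between array indices and physical positions pass through this
transform — analyzers never interpret raw indices as positions. Pixel
centers sit on a half-integer grid when rasterized.

## Phantom layouts

Layouts are declarative YAML documents (`acr.yaml`, `insight.yaml`), the
single source of truth shared by the simulator and the analyzers, so
recovery tests are self-consistent; users can substitute their own file.
The large-FOV layout places its 25 mm grid lattice, the four test zones
(center, anterior edge, left/right edges), five ramp pairs, eight periodic
patterns, four uniform wells, and ten alignment channels (four sets mixing
the 1.5 and 3.0 mm channel gauges) on separate slices of a 5-slice series,
mirroring how multi-insert phantoms dedicate slices to tests. The exact
internal coordinates of the commercial phantom are not published; the
bundled defaults are chosen to be geometrically plausible and internally
consistent (every structure inside the signal region, every measurement
path terminating on grid landmarks). The zone-2 pattern pair is stacked
vertically so the whole pattern slice keeps the layout's left-right mirror
symmetry — a property the simulator tests exploit.

The diagonal nominal length is kept at the conventional printed value of
282.9 mm although the corner-to-corner distance on the 200 mm lattice is
200·√2 = 282.84 mm; ideal renders therefore carry a built-in −0.06 mm
diagonal "error", far below the measurement tolerances.

The ACR resolution insert is modeled as three hole arrays of pitch
1.1/1.0/0.9 mm (hole diameter = pitch/2) — the true pitches are not
published and these are configurable; each block carries a large reference
hole whose contrast normalizes the per-pitch scores.

## Simulator

Rendering per slice: the scene is evaluated analytically on a 4×
supersampled pixel grid (factor fixed); each supersample center is mapped
image → phantom frame by inverting the rigid pose and then the distortion
field (fixed-point iteration, 4 steps), i.e. distortion is applied by
exact inverse mapping. Edges are antialiased with a signed-distance
coverage ramp one supersample wide — binary inside/outside tests would
quantize edge coverage and bias half-maximum edge positions by up to half
a supersample (~0.12 mm at 1 mm pixels), which is visible at the 0.05 mm
level the geometry tests work at. After rasterization: Gaussian PSF of the
configured FWHM, multiplicative bias field (evaluated in the image frame,
`1 + gx·u + gy·v + g2·r²` — the linear terms approximate an array coil's
gradient across a large FOV), block-average downsampling, scaling to a
nominal signal level of 1000, additive Gaussian noise (σ as a fraction of
that level; Rician optional for magnitude images at low SNR — Gaussian is
the default because the analyzer tests need an analytically tractable
model), and rounding to the integer grid used by the DICOM writer so
in-memory and on-disk pixels are identical. All randomness derives from
the config seed; renders are bit-reproducible.

Through-plane structures are rendered by their in-plane projection rather
than volumetric integration: a rectangular slice profile intersecting a
plate of slope ratio R yields exactly a linear transition of length R·t,
and a phantom tilt θ splits an opposed pair into lengths
`R·t/(1 ± R·tanθ)`. This choice makes the 10:1 ramp-length relation and
the harmonic tilt correction exact identities, so deviations measured in
tests are attributable to the estimators, not the phantom model. Wedge
bars encode a through-plane slice displacement d as bar lengths base ± d
(the 45° geometry), and alignment channels are simply present or absent
according to the configured marker states.

Distortion is a smooth global field: an affine 2×2 term (scale/shear) plus
a radial term `k·r²·r̂`, matching the peripheral-distortion phenomenology;
per-structure jitter is not modeled. Ground truth records the displacement
at every grid landmark, the per-ramp transition lengths, pattern
modulations, marker states, noise, blur and bias, and can evaluate the
analytic apparent length of any measurement path.

## Estimators

**Registration.** Otsu threshold → largest connected component; centroid
gives translation; for the rectangular phantom, rotation comes from the
four corner directions of the boundary, then the pose is refined by a
least-squares rigid (Kabsch) fit of detected rod centroids to nominal
positions. Residual = RMS landmark misfit (boundary misfit for the
circular phantom); registration fails above 5 mm. Recovery on synthetic
poses is ~0.001° / 0.001 mm; the corner estimate alone is good to ~0.1°.

**Grid landmarks.** Intensity-weighted centroid of the dark-rod depth
(plateau minus intensity, floored at 25% of the local maximum depth) in a
±3 mm window sampled at 0.25 mm; a window without ≥30% contrast is flagged
missing, never silently dropped; >20% missing raises a quality error.
Two rods in one window bias toward the stronger; re-centering resolves the
tie toward the nominal position.

**Phantom-outline endpoints (ACR diameters).** Edge located by the
area-under-profile (integral) estimator on the normalized edge profile,
which is exactly unbiased for any symmetric edge-spread function — the
interpolated half-maximum crossing carries a sub-pixel phase bias of up to
~0.1 mm. A far-outside baseline is subtracted first (magnitude images have
a rectified-noise floor), and the crossing radius is averaged over a fan
of 7 parallel rays (±3 mm), each converted back to a radius, cancelling
pixel-phase effects without biasing the diameter. Isotropic pixel spacing
is assumed for diagonal paths (true of the protocols modeled).

**MTF.** The image is flattened by dividing out a Gaussian low-pass
(FWHM = 5× pattern period) before σ/μ — otherwise a coil gradient inflates
σ. The noise floor, estimated as σ/μ in a structure-free background ROI on
the same slice, is subtracted in variance (floored at zero). The
conversion `MTF = √2·σ/μ` is chosen because σ/μ of a sinusoid of
modulation M is M/√2, and it reproduces the calibrated correspondence
√2·0.56 = 0.792 ≈ 0.8. A validity flag is cleared when the pattern's
fundamental (zero-padded FFT peak of a profile through the ROI) deviates
more than 10% from nominal — the signature of local distortion warping the
plate stack, which invalidates the resolution number. The default pattern
period is 6 mm; at 1 mm pixels the box-sampling MTF is ~0.95, so even
ideal renders report ≈0.94, not 1.0 — the metric measures the whole
imaging chain, display sampling included.

**Hole arrays.** Per pitch and direction, mean peak-to-valley contrast
along the hole rows/columns (bilinear sampling at hole centers and
midpoints), normalized by the reference-hole contrast; "resolved" at ≥25%.
The 25% surrogate for the manual visual call is a documented convention,
validated only against the simulator. Sub-millimeter pitches are at or
beyond Nyquist at ~1 mm display pixels under the simulator's box-sampling
model (real scanners behave better near Nyquist because k-space truncation
is closer to an ideal low-pass, and display interpolation helps the
reader); hole-array tests therefore render at 0.25 mm pixels, where the
bundled pitch set orders meaningfully and the resolved pitch degrades
monotonically with blur.

**Ramp profiles.** Sampled at 0.1 mm by bilinear interpolation, averaged
over 5 lanes across 60% of the strip width. Inflection points from a
3-segment piecewise-linear least-squares fit: levels are closed-form given
the breakpoints; breakpoints from a 41×41 coarse grid refined by
Nelder-Mead (xatol 1e-4). The fit must show a real transition (contrast
≥10% of profile range, breakpoints interior) or a measurement error is
raised. On rendered (pixel-sampled) trapezoids the corner rounding biases
the transition length low by ~0.7%, i.e. ≈0.02 mm in thickness at the 3 mm
protocol — inside the 0.05 mm recovery tolerance and far inside clinical
action levels. A 25–75%-span (FWHM-style) estimator is provided as a
cross-check; each result records which estimator produced it.

**Markers.** A channel counts visible when its contrast-to-noise ratio
(depth of the channel core below the flanking plateau, over the flank
std floored at 1% of plateau so noiseless renders are well-defined) is
≥3. The percentage is reported over all channels expected in the session's
acquisitions; 0% is a valid result. The metric is a ratio and invariant
under global intensity rescaling.

**Uniformity.** PIU automates the manual window/level hunt as an
exhaustive circular-mean search (FFT convolution; every pixel whose 1 cm²
ROI fits inside the eroded mask), verified exactly against a brute-force
per-pixel oracle. ROI radii are converted from cm² through the pixel
spacing, rounded to 0.1 mm. The ACR helper erodes the region 10 mm inside
the outline to keep partial-volume boundary pixels out of the search. The
multi-ROI metric reports per-ROI stats and flags ROIs whose pixel
distribution shows structure (>2% of pixels more than 15% off the ROI
median — plain noise at a few percent essentially never does).

## Report and trending

Pass flags are pure functions of (value, threshold); shipped defaults
(MTF ≥ 0.8; |geometric error| ≤ 2 mm; |thickness error| ≤ 0.7 mm;
PIU ≥ 82) follow common accreditation practice and are configuration, not
policy baked into measurement code — the multi-ROI uniformity and marker
metrics default to report-only. Reports serialize to versioned JSON and
round-trip losslessly. Trending uses mean ± 3σ control limits from a
baseline window (default 10 sessions; below 3 the limits are undefined and
flagging is suppressed with a notice).

## What the simulator does and does not emulate

It emulates: the geometric structure of both phantoms, smooth geometric
distortion, PSF blur, Gaussian/Rician noise, coil-like multiplicative
bias, phantom setup rotation/offset/tilt, slice displacement, and missing
alignment markers. It does not emulate: k-space sampling and its
truncation artifacts (ringing, the near-Nyquist behavior noted above),
ghosting, B0-inhomogeneity or susceptibility distortion, through-slice
profile shapes other than rectangular, or sequence-dependent contrast.
Passing recovery tests therefore demonstrates that the estimators are
accurate and unbiased on images whose degradations match these models —
not that every scanner artifact is handled; on real data the validity
flags and quality warnings are the guard rails.

## Problem sizes

Default renders are 300×300 px at 1 mm (large-FOV) and 256×256 px at
0.98 mm (ACR), 3–5 slices, 4× supersampled; hole-array analyses use
0.25 mm pixels. The full test suite renders every fixture from code at
run time; no image data is stored.
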