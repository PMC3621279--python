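# Methods

This note documents the models behind `mbdose`: what is simulated, what is
estimated, every tunable that matters, and the numerical choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The measurement problem

A microbeam array deposits very high dose (tens to hundreds of Gy) in
micrometre-wide peaks and a small dose in the valleys between them. The
peak-to-valley dose ratio PVDR(x) = x / D_valley(x) must be measured with a
detector whose calibrated range ends far below the peak dose. The method
implemented here takes the peak dose as the *delivered* (nominal) dose x —
never as a measured response — and obtains the valley dose by inverting a
calibration curve fitted on low-dose irradiations at the measured valley
response. This works because the valley dose at clinically relevant peak
doses falls inside the calibrated range (roughly x / PVDR ≈ 1–3 Gy for the
fluorescence branch at 50–150 Gy, 10–35 Gy for film at 300–800 Gy).

A subtle and deliberate consequence: any multiplicative factor in the
delivery chain (dose-rate uncertainty, scatter redistribution) appears in
both the calibration scans and the measurement scans and cancels in the
ratio. The PVDR estimate is therefore insensitive to the absolute dose
scale; the test suite exercises this by fitting calibrations on scans that
include scatter and verifying the recovered PVDR still matches truth.

## Synthetic dose field

The ground-truth cross-beam dose profile is

```
D(u) = x·(1−f)·[comb ⊛ G(σ_p)](u) + x·f·[comb ⊛ G(σ_s)](u)
```

where `comb` is the top-hat indicator of the beam array (sub-pixel
fractional coverage per pixel), `G(σ)` a unit-sum Gaussian kernel applied
with periodic boundaries, `σ_p` the penumbra width, and the second term
redistributes a fraction `f` of the dose through a long-range scatter
kernel of width `σ_s ≫ pitch`. Unit-sum periodic kernels make total dose
independent of both widths (asserted to 1e-6 relative in the tests).
Scatter from several beams overlaps mid-array, so central valleys are
systematically hotter than outer ones — the mechanism behind the large
between-valley spread of pooled PVDRs and their minimum at the central
valley. The scatter form is a modelling choice with two interpretable
parameters, not a transport calculation; no spectra, kerma or half-value
layers are modelled.

Depth broadening is modelled on the beam *width*: at depth z (mm) the
top-hat width is `w0 + z·depth_width_slope`. The default slope of zero
represents a non-diffusing beam — identical true width at every depth —
which is the case the depth comparison is designed to confirm. (For a
top-hat much wider than the penumbra, FWHM equals the top-hat width, so a
slope s changes the FWHM by s·Δz between depths.)

Geometry defaults: 8 beams, 25 µm wide, 200 µm centre-to-centre (8 peaks,
7 valleys per irradiation); fields are auto-sized to the beam pattern plus
a 3·σ_s margin so the scatter kernel is fully contained. The array centre
is snapped to a pixel centre so that beam/valley landmarks do not sit on
sampling-window rounding boundaries, where an infinitesimal error in a
detected centre would flip the discrete 16-pixel window by a whole pixel.

`DoseModel` dataclass defaults describe the ideal delivered beam
(σ_p = 0, f = 0). The realistic study conditions live in the default
`PipelineConfig` and were chosen once as plausible for a synchrotron
microbeam imaged by the fluorescence route: σ_p = 2 µm, f = 0.15,
σ_s = 500 µm (2.5 pitches). With these values the generator's ground-truth
PVDR comes out in the several-tens range typical of microbeam arrays; the
per-valley values and their mean are computed, not asserted. The film
configuration uses σ_p = 8 µm and f = 0.22 (film diffuses dose visibly
more than gel dosimeters and reads lower PVDRs).

## Detector models

**Fluorescence** (`kind="fluorescence"`, 12-bit, stored 16-bit):
`counts = c0 + c1·d + c2·d²` with defaults c0 = 240.96, c1 = 144.33,
c2 = −3.3971 (counts, counts/Gy, counts/Gy²). The parabola peaks at
d* = −c1/(2c2) ≈ 21.24 Gy. Above d* the model holds the response constant
at the vertex value rather than following the decreasing parabola: a
physical detector response is non-decreasing in dose. This matters for
high-dose scans (peaks at 50–250 Gy render as a saturated plateau) and is
prominent because the behaviour above ~21 Gy is otherwise undefined. A
visible consequence reproduced by the simulator: the *response* FWHM of a
saturated peak exceeds the true dose FWHM, and grows with peak dose,
because the half-maximum level is reached further out on the penumbra.

**Optical density / film** (`kind="optical_density"`, 8-bit RGB):
`counts = α·ln(d) + β`, defaults α = 45, β = 30 counts, chosen so the
2.5–75 Gy calibration range and the 10–35 Gy valley responses stay inside
8 bits. ln(0) is undefined; for d ≤ 0.01 Gy the response is the unexposed
baseline β. The microbeam signal is written to the red channel; green and
blue carry attenuated copies (0.6× and 0.35×), mirroring the convention of
analysing only the red scanner channel. Film additionally carries
fixed-pattern inhomogeneity noise (uneven chromophore distribution) that
frame averaging cannot reduce.

**Noise and quantization.** Read noise is Gaussian with per-pixel sd
`noise_sigma / sqrt(n_frames_averaged)` — frame averaging is simulated
analytically rather than by rendering n frames, for speed; the empirical
sd of rendered minus noiseless images is verified against this to 5%.
Defaults: 20 counts/frame, 8 frames (fluorescence); 2 counts, 1 frame plus
1 count fixed-pattern (film). Values are rounded half-to-even and clipped
to [0, 2^bits − 1]. A single integer seed drives one generator stream per
image; identical seeds give bit-identical images.

## Readout and analysis

* **Profiles** are means over a strip of rows along the beam direction;
  the strip height enters the reported pixel counts (a 16-pixel window on
  a 48-row strip samples 768 image pixels per valley; the four-scan
  default study samples > 4000 valley pixels per scan).
* **Smoothing** is a centred moving average with the odd pixel span
  nearest the requested window (default 6.25 µm ≈ 5 pixels), chosen as the
  least-structured smoother; edges shrink symmetrically. Every output is a
  unit-weight symmetric average, so linear profiles pass through exactly.
* **Peak detection** takes local maxima separated by ≥ half a pitch above
  a prominence threshold (10% of the profile range), then refines each to
  the response-weighted centroid of the contiguous above-half-maximum
  region, which is sub-pixel stable under noise and handles saturated
  plateaus. **Valleys** are defined as midpoints between adjacent accepted
  peaks (the instrument procedure does not say where in the gap it
  sampled; the midpoint mirrors the peak rule), so n_valleys = n_peaks − 1
  always.
* **Region sampling** takes the `round(width / pixel_size)` pixels centred
  on a position — 16 pixels for the default 20 µm at 1.25 µm pixels — and
  reports their mean and (n−1) sd.
* **Calibration** is unweighted least squares (quadratic in dose, or
  linear in ln dose); response sds are retained as diagnostics only. At
  least 3 (quadratic) / 2 (logarithmic) distinct doses are required;
  a fitted a ≥ 0 or a calibration range reaching the vertex is recorded as
  a warning, not an error. An advisory check flags calibration responses
  above 50% of detector saturation (the acquisition rule for PMT gain).
* **Inversion** solves the quadratic by the closed-form formula and keeps
  the smaller root — the rising branch below the vertex, where the whole
  calibration range lives; agreement with a bisection root-finder is part
  of the acceptance surface. Responses above the vertex value (negative
  discriminant) or below the calibration floor raise errors; doses beyond
  the calibration dose domain are returned but flagged, and valleys whose
  inversion fails are excluded and counted, never imputed.
* **PVDR pooling** is over individual per-valley values across dose points
  (not over per-point means), keeping the dominant between-valley spread
  visible in the reported sd; the per-dose-point breakdown is retained.
* **FWHM** is measured above a baseline, default the median response over
  the two flanking valley windows (microbeam profiles sit on a nonzero
  valley floor), with `global_min` as the alternative. The width is the
  distance between the outermost linearly interpolated half-level
  crossings within half a pitch of the peak on each side: outermost to
  avoid noise-spike underestimates, half a pitch to stay clear of
  neighbouring beams. The definition is invariant under affine response
  transforms, so widths compare across dosimeters without normalization
  (profile overlays min-max normalize for display only).
* **Depth comparison** uses Welch's two-sample t-test (equal variances not
  assumed) with Welch–Satterthwaite degrees of freedom, two-sided p, and a
  0.05 threshold, implemented from the explicit formulas; the degenerate
  both-variances-zero case returns t = 0, p = 1 for equal means.

## What the simulations do and do not show

Passing tests demonstrate that the analysis recovers known ground truth
under the generator's assumptions: straight parallel beams, spatially
uniform detector response, Gaussian read noise, exact knowledge of the
delivered peak dose, and a scatter model with the stated two-parameter
form. Real scans add effects the generator does not emulate: geometric
distortion from curved dosimeter surfaces, scanner colour management,
dosimeter fading between irradiation and readout (only a global scale
factor could stand in for it, which the ratio cancels anyway),
magnification-dependent apparent widths, and dose-rate or energy
dependence of the response. Agreement on synthetic data therefore
validates the *estimators*, not any particular physical beamline; the
published headline values for real scans are not reproduction targets.

Problem sizes were chosen to keep the default study informative but quick:
scans of ~3700 × 48 pixels (1.25 µm), four measurement dose points, eight
calibration doses, 20-replicate recovery studies, 1000-replicate null
calibration of the depth test with a 60-replicate pilot for the
noise-induced FWHM sd and 200-replicate power checks.

## Known limitations

* The scatter kernel is phenomenological; its parameters are plausible,
  not fitted to any measured valley profile.
* Peak-region responses of high-dose scans are saturated by construction;
  the pipeline never uses them quantitatively (by design), so nothing
  checks detector behaviour far above the vertex beyond monotonicity.
* The Welch comparison treats per-peak FWHMs within a scan as independent;
  adjacent peaks share flanking-valley baseline windows, a small positive
  correlation measured in development to be ~0.04 between neighbours. The
  realised null rejection rate is computed (not assumed) by the acceptance
  script and sits near the nominal 5%.
* Valley location is defined as the peak-to-peak midpoint; if a real
  instrument sampled elsewhere in the gap, valley doses shift by the local
  scatter gradient.
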