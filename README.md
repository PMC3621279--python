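# mbdose — microbeam dosimetry analysis

Microbeam radiation therapy (MRT) delivers arrays of micrometre-wide,
highly collimated synchrotron X-ray beams: lethal dose in the "peak"
strips, sub-lethal dose in the shielded "valleys" between them. The key
safety/efficacy figure is the **peak-to-valley dose ratio**

```
PVDR(x) = x / D_valley(x)
```

where `x` is the dose delivered to the peak (Gy) and `D_valley(x)` the dose
measured midway between beams. Measuring it is awkward: at clinically
relevant peak doses (50–800 Gy) every practical dosimeter saturates in the
peak, while the valley dose sits comfortably inside the calibrated range.
`mbdose` implements the resulting measurement trick for two dosimeter
families read out as images:

* **Fluorescence (gel/solid radiochromic) readout** — response modelled as
  a saturating quadratic, `counts = c0 + b·d + a·d²` with `a < 0`
  (defaults `c0 = 240.96`, `b = 144.33`, `a = −3.3971`), digitized to
  12 bits. A calibration fitted on low peak doses (0–15 Gy) is inverted at
  the valley response by the quadratic formula, taking the rising-branch
  root below the vertex `−b/(2a) ≈ 21.2 Gy`.
* **Radiochromic film readout** — red-channel response modelled as
  `counts = α·ln(d) + β`, digitized to 8 bits, calibrated over 2.5–75 Gy
  and inverted in closed form.

Around the inversion sits a full pipeline: beam-perpendicular profile
extraction with strip averaging, moving-average smoothing, sub-pixel
peak/valley detection, the instrument's 20 µm (16-pixel at 1.25 µm)
sampling rule, per-valley PVDRs pooled as mean ± sd, FWHM beam-width
measurement above a valley-floor baseline, and Welch's unequal-variance
t-test for comparing beam widths between scan depths.

Because no real scans ship with the package, a first-class **synthetic
scan generator** provides ground truth for every stage: an 8-beam top-hat
comb (25 µm beams, 200 µm pitch) with Gaussian penumbra, a wide-Gaussian
long-range scatter term that raises central valleys more than outer ones,
the two detector response models, frame-averaged Gaussian noise and
12-bit/8-bit quantization. Who this is for: medical physicists prototyping
microbeam readout analysis, and anyone needing a tested reference
implementation of calibration-inversion PVDR estimation.

## Worked example

```python
from mbdose import default_config, run_end_to_end

report = run_end_to_end(default_config(seed=1), "out/")
cal = report["calibration"]; pvdr = report["pvdr"]
print(f"pooled PVDR: {pvdr['mean_pvdr']:.1f} +/- {pvdr['sd_pvdr']:.1f}")
```

prints (exactly reproducible from config + seed):

```
calibration: response = 241.00 + 123.16*d -2.4751*d^2   (R^2 = 1.000000)
pooled PVDR: 58.9 +/- 7.4 over 28 valley readings
ground-truth PVDR: 58.9
  peak    50 Gy: PVDR 58.9 +/- 8.0 (5376 valley pixels)
  peak    75 Gy: PVDR 58.9 +/- 7.8 (5376 valley pixels)
  peak   100 Gy: PVDR 58.8 +/- 7.8 (5376 valley pixels)
  peak   150 Gy: PVDR 58.8 +/- 7.8 (5376 valley pixels)
depth comparison 20 vs 100 mm: t = 0.00, df = 14.0, p = 0.997 -> no significant difference
```

Reading the numbers: the quadratic refitted from the simulated calibration
scans differs from the detector's own coefficients because 15% of the
delivered dose is redistributed as scatter — the fit absorbs the delivery
factor, which is exactly why the inversion recovers the true PVDR (the
same factor appears in calibration and measurement and cancels). The
pooled estimate (58.9) matches the generator's ground truth; the ±7.4
spread is dominated by real between-valley structure (central valleys
collect scatter from more beams, so their PVDR is lowest), not noise. The
depth comparison finds no width change between 20 mm and 100 mm because
the simulated beam does not diffuse — the sanity check the depth
experiment is designed to pass.

The same stages are scriptable from the shell:

```sh
mbdose config --defaults          # every constant, overridable via YAML
mbdose simulate --out scans/ --seed 5
mbdose profile --image scans/scan_peak_100Gy.tif --smooth-um 6.25 --out p.csv
mbdose calibrate --points points.csv --model quadratic --out curve.json
mbdose pvdr --profile p.csv --calibration curve.json --peak-dose 100 --out pvdr.json
mbdose run --out results/ --seed 1
```

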