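"""Synthetic microbeam dosimeter scans with known ground truth.

The original fluorescence and film scans of microbeam-irradiated dosimeters
are not deposited anywhere, so every analysis stage here is validated
against simulated scans whose peak/valley doses, positions and beam widths
are known by construction.

Physical picture
----------------
A collimator produces an array of parallel microbeams: nominally 25 µm-wide
strips on a 200 µm centre-to-centre pitch (eight peaks, seven valleys per
irradiation). The delivered dose field is modelled as

* an ideal top-hat comb of height ``peak_dose * (1 - scatter_fraction)``,
  convolved with a narrow Gaussian penumbra kernel, plus
* the remaining ``peak_dose * scatter_fraction`` redistributed by a wide
  Gaussian scatter kernel (sigma much larger than the pitch), which raises
  the valley floor and — because scatter from many beams accumulates —
  raises the *central* valleys more than the outermost ones.

Detectors are modelled as a saturating quadratic fluorescence response
(counts = c0 + c1·dose + c2·dose², c2 < 0, held at the vertex above it)
digitized to 12 bits, or a logarithmic optical-density film response
(counts = alpha·ln(dose) + beta) digitized to 8 bits with the microbeam
signal in the red channel. Frame averaging is simulated analytically: noise
sd per pixel is ``noise_sigma / sqrt(n_frames_averaged)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import DomainError, GeometryError
from .imaging import ScanImage, write_scan

__all__ = [
    "BeamGeometry",
    "DoseModel",
    "DetectorModel",
    "DoseMapTruth",
    "DoseMap",
    "generate_dose_map",
    "render_scan",
    "generate_calibration_set",
    "generate_depth_series",
    "write_truth_csv",
    "write_scan",
]

SAMPLE_WIDTH_UM = 20.0  # readout sampling window used for the truth bookkeeping


@dataclass(frozen=True)
class BeamGeometry:
    """Microbeam array geometry: n beams of a given width on a regular pitch."""

    n_beams: int = 8
    beam_width_um: float = 25.0
    pitch_um: float = 200.0

    def __post_init__(self) -> None:
        if self.n_beams < 2:
            raise GeometryError("need at least 2 beams")
        if self.beam_width_um <= 0 or self.pitch_um <= 0:
            raise GeometryError("beam width and pitch must be positive")
        if self.beam_width_um >= self.pitch_um:
            raise GeometryError("beam width must be smaller than the pitch")

    @property
    def pattern_extent_um(self) -> float:
        """Nominal span of the beam pattern (n_beams pitches)."""
        return self.n_beams * self.pitch_um


@dataclass(frozen=True)
class DoseModel:
    """Parameters of the delivered dose field.

    Defaults describe the ideal collimated beam (no penumbra, no scatter);
    realistic study conditions are set in the pipeline configuration.

    peak_dose_gy
        Delivered (nominal) dose to the peak region — the ``x`` of the
        PVDR formula PVDR(x) = x / D_valley(x).
    penumbra_sigma_um
        Gaussian blur of the ideal top-hat profile at each beam edge.
    scatter_fraction
        Fraction of the peak dose redistributed as long-range scatter; this
        is what puts dose into the valleys, so it fixes the ground-truth
        PVDR.
    scatter_sigma_um
        Width of the scatter kernel; must exceed the pitch so scatter from
        several beams overlaps in each valley.
    depth_width_slope_um_per_mm
        Beam-width increase per mm of depth into the dosimeter. Zero (the
        default) models a non-diffusing beam: width identical at all depths.
    """

    peak_dose_gy: float = 100.0
    penumbra_sigma_um: float = 0.0
    scatter_fraction: float = 0.0
    scatter_sigma_um: float = 500.0
    depth_width_slope_um_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_dose_gy < 0:
            raise DomainError("peak dose must be non-negative")
        if self.penumbra_sigma_um < 0:
            raise DomainError("penumbra sigma must be non-negative")
        if not (0 <= self.scatter_fraction < 1):
            raise DomainError("scatter fraction must lie in [0, 1)")
        if self.scatter_sigma_um <= 0:
            raise DomainError("scatter sigma must be positive")
        if self.depth_width_slope_um_per_mm < 0:
            raise DomainError("depth width slope must be non-negative")


@dataclass(frozen=True)
class DetectorModel:
    """Dose → counts response model plus digitization and noise parameters.

    ``kind`` is ``"fluorescence"`` (saturating quadratic, 12-bit) or
    ``"optical_density"`` (logarithmic, 8-bit RGB with the signal in the
    red channel). ``coefficients`` is (c0, c1, c2) or (alpha, beta)
    respectively. ``inhomogeneity_sigma`` is film-only fixed-pattern noise
    (uneven chromophore distribution) that frame averaging cannot reduce.
    """

    kind: str = "fluorescence"
    coefficients: tuple = (240.96, 144.33, -3.3971)
    bit_depth: int = 12
    noise_sigma: float = 0.0
    n_frames_averaged: int = 8
    inhomogeneity_sigma: float = 0.0

    OD_EPSILON_GY = 0.01  # below this dose the film response is the offset beta

    def __post_init__(self) -> None:
        if self.kind not in ("fluorescence", "optical_density"):
            raise DomainError(f"unknown detector kind {self.kind!r}")
        if self.bit_depth not in (8, 12):
            raise DomainError("bit depth must be 8 or 12")
        if self.kind == "fluorescence":
            if len(self.coefficients) != 3:
                raise DomainError("fluorescence model needs (c0, c1, c2)")
            c0, c1, c2 = self.coefficients
            if not (c2 < 0 < c1):
                raise DomainError(
                    "fluorescence response must saturate: c2 < 0 and c1 > 0"
                )
        else:
            if len(self.coefficients) != 2:
                raise DomainError("optical-density model needs (alpha, beta)")
        if self.noise_sigma < 0 or self.inhomogeneity_sigma < 0:
            raise DomainError("noise parameters must be non-negative")
        if self.n_frames_averaged < 1:
            raise DomainError("n_frames_averaged must be >= 1")

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def vertex_dose_gy(self) -> float:
        """Dose at which the quadratic fluorescence response peaks."""
        if self.kind != "fluorescence":
            raise DomainError("vertex is defined only for the fluorescence model")
        _, c1, c2 = self.coefficients
        return -c1 / (2 * c2)

    @property
    def vertex_response(self) -> float:
        c0, c1, c2 = self.coefficients
        d = self.vertex_dose_gy
        return c0 + c1 * d + c2 * d * d

    def response(self, dose_gy: np.ndarray | float) -> np.ndarray:
        """Noiseless, unquantized response (counts), clipped to the ADC range.

        Fluorescence doses beyond the parabola vertex are held at the vertex
        value: a physical detector response does not decrease with dose.
        Film response at dose ≤ 0.01 Gy is the unexposed baseline ``beta``.
        """
        d = np.asarray(dose_gy, dtype=float)
        if self.kind == "fluorescence":
            c0, c1, c2 = self.coefficients
            d_eff = np.minimum(d, self.vertex_dose_gy)
            r = c0 + c1 * d_eff + c2 * d_eff * d_eff
        else:
            alpha, beta = self.coefficients
            safe = np.maximum(d, self.OD_EPSILON_GY)
            r = np.where(d <= self.OD_EPSILON_GY, beta, alpha * np.log(safe) + beta)
        return np.clip(r, 0.0, float(self.saturation_level))

    @staticmethod
    def fluorescence(**kwargs) -> "DetectorModel":
        defaults = dict(
            kind="fluorescence",
            coefficients=(240.96, 144.33, -3.3971),
            bit_depth=12,
            noise_sigma=20.0,
            n_frames_averaged=8,
        )
        defaults.update(kwargs)
        return DetectorModel(**defaults)

    @staticmethod
    def optical_density(**kwargs) -> "DetectorModel":
        defaults = dict(
            kind="optical_density",
            coefficients=(45.0, 30.0),
            bit_depth=8,
            noise_sigma=2.0,
            n_frames_averaged=1,
            inhomogeneity_sigma=1.0,
        )
        defaults.update(kwargs)
        return DetectorModel(**defaults)


@dataclass(frozen=True)
class DoseMapTruth:
    """Ground-truth bookkeeping computed from the noiseless dose map."""

    peak_positions_um: tuple
    valley_positions_um: tuple
    peak_doses_gy: tuple
    valley_doses_gy: tuple
    per_peak_fwhm_um: tuple
    fwhm_um: float

    @property
    def per_valley_pvdr(self) -> tuple:
        """Nominal-peak / valley-dose ratios are reported by the pipeline;
        the truth ratio here uses the *actual* window-mean peak dose, which
        is what the calibration-inversion route recovers (both numerator
        and denominator pick up the same delivery factors)."""
        mean_peak = float(np.mean(self.peak_doses_gy))
        return tuple(mean_peak / v for v in self.valley_doses_gy)

    @property
    def mean_pvdr(self) -> float:
        return float(np.mean(self.per_valley_pvdr))


@dataclass(frozen=True)
class DoseMap:
    """Ground-truth 2-D absorbed-dose field (Gy) on a pixel grid.

    Beams run along axis 0; dose varies across columns. Positions are in µm
    from the first pixel centre.
    """

    values: np.ndarray
    pixel_size_um: float
    truth: DoseMapTruth
    nominal_peak_dose_gy: float
    depth_mm: float = 0.0
    beam_axis: int = 0

    @property
    def profile(self) -> np.ndarray:
        """The (constant-along-beam) cross-beam dose profile."""
        return self.values[0]

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.pixel_size_um


# ---------------------------------------------------------------------------
# Dose-map construction


def _comb_coverage(
    positions: np.ndarray, centres: np.ndarray, width: float, px: float
) -> np.ndarray:
    """Fractional pixel coverage of the top-hat comb (sub-pixel accurate)."""
    comb = np.zeros_like(positions)
    for c in centres:
        lo, hi = c - width / 2, c + width / 2
        overlap = np.minimum(positions + px / 2, hi) - np.maximum(
            positions - px / 2, lo
        )
        comb += np.clip(overlap, 0.0, None) / px
    return comb


def _window_mean(values: np.ndarray, px: float, centre_um: float, width_um: float) -> float:
    """Mean over the round(width/px)-pixel window centred at a position.

    Same window convention as the analysis-side region sampling, because the
    truth is defined as what an ideal noiseless readout would record.
    """
    n = max(1, int(round(width_um / px)))
    start = int(np.floor(centre_um / px - n / 2 + 0.5))
    start = max(0, min(start, values.size - n))
    return float(values[start : start + n].mean())


def _half_max_width(
    positions: np.ndarray, values: np.ndarray, centre_um: float,
    pitch_um: float, baseline: float,
) -> float:
    """Linear-interpolated full width at half maximum above a baseline.

    Independent, minimal crossing scan used only for the generator's truth
    bookkeeping (the analysis-side FWHM lives in :mod:`mbdose.beamwidth`).
    """
    px = positions[1] - positions[0]
    mask = np.abs(positions - centre_um) <= pitch_um / 2
    idx = np.nonzero(mask)[0]
    seg_v = values[idx]
    peak_val = seg_v.max()
    half = baseline + 0.5 * (peak_val - baseline)
    i_pk = idx[int(np.argmax(seg_v))]
    # walk outwards from the maximum to the first sub-half samples
    left = i_pk
    while left - 1 >= idx[0] and values[left - 1] >= half:
        left -= 1
    right = i_pk
    while right + 1 <= idx[-1] and values[right + 1] >= half:
        right += 1
    if left == idx[0] and values[left] >= half:
        raise GeometryError("no left half-maximum crossing for truth FWHM")
    if right == idx[-1] and values[right] >= half:
        raise GeometryError("no right half-maximum crossing for truth FWHM")
    xl = positions[left] - px * (values[left] - half) / (values[left] - values[left - 1])
    xr = positions[right] + px * (values[right] - half) / (values[right] - values[right + 1])
    return float(xr - xl)


def generate_dose_map(
    geometry: BeamGeometry = BeamGeometry(),
    dose_model: DoseModel = DoseModel(),
    pixel_size_um: float = 1.25,
    field_size_um: tuple[float, float] | None = None,
    depth_mm: float = 0.0,
) -> DoseMap:
    """Build the ground-truth dose field for one irradiation.

    ``field_size_um`` is (width across the beams, height along the beams);
    ``None`` auto-sizes the field to the beam pattern plus a 3·scatter_sigma
    margin (so the wide scatter kernel is fully contained) and a 60 µm
    strip height. Convolutions use periodic boundaries with unit-sum
    kernels, so total dose is conserved regardless of the blur widths.
    """
    if depth_mm < 0:
        raise DomainError("depth must be non-negative")
    dm = dose_model
    if dm.scatter_fraction > 0 and dm.scatter_sigma_um <= geometry.pitch_um:
        raise DomainError("scatter sigma must exceed the pitch when scatter is on")

    width_eff = geometry.beam_width_um + depth_mm * dm.depth_width_slope_um_per_mm
    margin = 3 * dm.scatter_sigma_um if dm.scatter_fraction > 0 else 0.0
    margin = max(margin, 6 * dm.penumbra_sigma_um + 2 * geometry.beam_width_um)
    pattern_span = (geometry.n_beams - 1) * geometry.pitch_um + width_eff

    if field_size_um is None:
        field_size_um = (pattern_span + 2 * margin, 60.0)
    field_w, field_h = field_size_um
    if field_w < pattern_span + 2 * (3 * dm.scatter_sigma_um if dm.scatter_fraction > 0 else 0):
        raise GeometryError(
            "field too small: must span the beam pattern plus a 3*scatter_sigma margin"
        )

    px = pixel_size_um
    n_cols = int(round(field_w / px))
    n_rows = max(1, int(round(field_h / px)))
    positions = np.arange(n_cols) * px
    # snap the array centre to a pixel centre: beam/valley landmarks then sit
    # away from sampling-window rounding boundaries, so a sub-pixel error in
    # a detected centre cannot flip the 16-pixel window by a whole pixel
    field_centre = round(positions[-1] / 2 / px) * px
    offsets = (np.arange(geometry.n_beams) - (geometry.n_beams - 1) / 2) * geometry.pitch_um
    centres = field_centre + offsets

    comb = _comb_coverage(positions, centres, width_eff, px)

    def blur(arr: np.ndarray, sigma_um: float) -> np.ndarray:
        if sigma_um <= 0:
            return arr
        return gaussian_filter1d(arr, sigma_um / px, mode="wrap")

    d = dm.peak_dose_gy
    f = dm.scatter_fraction
    profile = d * (1 - f) * blur(comb, dm.penumbra_sigma_um) + d * f * blur(
        comb, dm.scatter_sigma_um
    )
    profile = np.clip(profile, 0.0, None)

    valley_centres = 0.5 * (centres[:-1] + centres[1:])
    peak_doses = tuple(_window_mean(profile, px, c, SAMPLE_WIDTH_UM) for c in centres)
    valley_doses = tuple(
        _window_mean(profile, px, c, SAMPLE_WIDTH_UM) for c in valley_centres
    )
    if max(valley_doses, default=0.0) >= min(peak_doses) and d > 0:
        raise GeometryError("degenerate dose map: a valley dose reaches a peak dose")

    if d > 0:
        fwhms = []
        for i, c in enumerate(centres):
            flank = [valley_doses[j] for j in (i - 1, i) if 0 <= j < len(valley_doses)]
            baseline = float(np.mean(flank)) if flank else 0.0
            fwhms.append(
                _half_max_width(positions, profile, c, geometry.pitch_um, baseline)
            )
    else:
        # zero delivered dose: the profile is flat and the width undefined
        fwhms = [float("nan")] * len(centres)

    truth = DoseMapTruth(
        peak_positions_um=tuple(float(c) for c in centres),
        valley_positions_um=tuple(float(c) for c in valley_centres),
        peak_doses_gy=peak_doses,
        valley_doses_gy=valley_doses,
        per_peak_fwhm_um=tuple(fwhms),
        fwhm_um=float(np.mean(fwhms)),
    )
    values = np.tile(profile, (n_rows, 1))
    return DoseMap(
        values=values,
        pixel_size_um=px,
        truth=truth,
        nominal_peak_dose_gy=d,
        depth_mm=depth_mm,
    )


# ---------------------------------------------------------------------------
# Rendering


def render_scan(dose_map: DoseMap, detector: DetectorModel, seed: int) -> ScanImage:
    """Render a dose map into a quantized detector image.

    Per pixel: detector response → additive Gaussian read noise of sd
    ``noise_sigma / sqrt(n_frames_averaged)`` → fixed-pattern inhomogeneity
    (added once; not reduced by frame averaging) → round-half-to-even →
    clip to the ADC range. The same seed always yields the identical image.
    """
    rng = np.random.default_rng(seed)
    r = detector.response(dose_map.values)
    if detector.noise_sigma > 0:
        r = r + rng.normal(
            0.0,
            detector.noise_sigma / math.sqrt(detector.n_frames_averaged),
            size=r.shape,
        )
    if detector.inhomogeneity_sigma > 0:
        r = r + rng.normal(0.0, detector.inhomogeneity_sigma, size=r.shape)
    sat = detector.saturation_level
    q = np.clip(np.rint(r), 0, sat)
    meta = {
        "pixel_size_um": dose_map.pixel_size_um,
        "peak_dose_gy": dose_map.nominal_peak_dose_gy,
        "depth_mm": dose_map.depth_mm,
        "detector_kind": detector.kind,
        "seed": int(seed),
        "truth": dose_map.truth,
    }
    if detector.kind == "optical_density":
        red = q.astype(np.uint8)
        green = np.clip(np.rint(0.6 * r), 0, sat).astype(np.uint8)
        blue = np.clip(np.rint(0.35 * r), 0, sat).astype(np.uint8)
        pixels = np.stack([red, green, blue], axis=-1)
        bit_depth = 8
    else:
        pixels = q.astype(np.uint16)
        bit_depth = 12
    return ScanImage(
        pixels=pixels,
        pixel_size_um=dose_map.pixel_size_um,
        bit_depth=bit_depth,
        metadata=meta,
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def generate_calibration_set(
    doses_gy,
    geometry: BeamGeometry = BeamGeometry(),
    dose_model: DoseModel = DoseModel(),
    detector: DetectorModel = DetectorModel(),
    seed: int = 0,
    pixel_size_um: float = 1.25,
    field_size_um: tuple[float, float] | None = None,
) -> list[tuple[float, ScanImage]]:
    """One rendered scan per calibration dose (peak_dose set to each dose).

    Fluorescence calibration must stay on the rising branch of the quadratic
    response: a dose at or beyond the vertex is a domain error, because such
    points could not be inverted unambiguously.
    """
    doses = [float(d) for d in doses_gy]
    if detector.kind == "fluorescence":
        vertex = detector.vertex_dose_gy
        bad = [d for d in doses if d >= vertex]
        if bad:
            raise DomainError(
                f"calibration doses {bad} at/beyond the fluorescence vertex "
                f"({vertex:.2f} Gy); calibration must stay below saturation"
            )
    out = []
    for d, s in zip(doses, _child_seeds(seed, len(doses))):
        dm = replace(dose_model, peak_dose_gy=d)
        dmap = generate_dose_map(
            geometry, dm, pixel_size_um=pixel_size_um, field_size_um=field_size_um
        )
        out.append((d, render_scan(dmap, detector, int(s))))
    return out


def generate_depth_series(
    geometry: BeamGeometry = BeamGeometry(),
    dose_model: DoseModel = DoseModel(),
    depths_mm=(20.0, 100.0),
    detector: DetectorModel = DetectorModel(),
    seed: int = 0,
    pixel_size_um: float = 1.25,
    field_size_um: tuple[float, float] | None = None,
) -> list[tuple[float, ScanImage]]:
    """One scan per depth, beam width broadened by depth * depth_width_slope.

    With the default slope of zero the true width is identical at every
    depth — the non-diffusing-beam case the depth comparison is meant to
    confirm.
    """
    depths = [float(z) for z in depths_mm]
    if any(z < 0 for z in depths):
        raise DomainError("depths must be non-negative")
    out = []
    for z, s in zip(depths, _child_seeds(seed, len(depths))):
        dmap = generate_dose_map(
            geometry,
            dose_model,
            pixel_size_um=pixel_size_um,
            field_size_um=field_size_um,
            depth_mm=z,
        )
        out.append((z, render_scan(dmap, detector, int(s))))
    return out


def write_truth_csv(dose_map: DoseMap, path: str | Path) -> None:
    """Ground-truth sidecar: position_um, role {peak|valley}, true_dose_gy."""
    t = dose_map.truth
    rows = [
        {"position_um": p, "role": "peak", "true_dose_gy": d}
        for p, d in zip(t.peak_positions_um, t.peak_doses_gy)
    ] + [
        {"position_um": p, "role": "valley", "true_dose_gy": d}
        for p, d in zip(t.valley_positions_um, t.valley_doses_gy)
    ]
    pd.DataFrame(rows).sort_values("position_um").to_csv(path, index=False)
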