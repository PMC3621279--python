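"""End-to-end seeded pipeline: simulate → calibrate → invert → PVDR → FWHM.

The run mirrors the measurement campaign: render a calibration set, fit the
dose-response curve on peak readings, render high-dose scans whose valley
responses are inverted through the curve into PVDRs, render a depth series
and compare beam widths between depths with Welch's test. All outputs are
reproducible from (config, seed) alone; the manifest records a SHA-256 per
written file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from .beamwidth import compare_depths
from .calibration import (
    CalibrationPoint,
    check_calibration_range,
    fit_logarithmic,
    fit_quadratic,
)
from .config import PipelineConfig
from .errors import MbdoseError
from .imaging import (
    detect_peaks,
    extract_profile,
    sample_region,
    smooth_profile,
    split_red_channel,
    write_profile,
)
from .pvdr import aggregate_pvdr, compute_pvdr, compute_valley_doses
from .synthetic import (
    generate_calibration_set,
    generate_depth_series,
    generate_dose_map,
    render_scan,
    write_scan,
)

__all__ = ["run_end_to_end", "StageFailure"]


class StageFailure(MbdoseError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _as_single_channel(image):
    return split_red_channel(image) if image.pixels.ndim == 3 else image


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(
    config: PipelineConfig,
    out_dir: str | Path,
    write_images: bool = False,
) -> dict:
    """Run the full pipeline and write result JSONs plus a manifest.

    Returns the report dict (also written to ``report.json``). Identical
    config + seed produce byte-identical result files. Set
    ``write_images=True`` to also keep the rendered TIFF scans.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cal_seed, pvdr_seed_base, depth_seed = rng.integers(0, 2**31 - 1, size=3)
    pvdr_seeds = np.random.default_rng(pvdr_seed_base).integers(
        0, 2**31 - 1, size=len(config.pvdr_peak_doses_gy)
    )
    written: list[Path] = []

    # -- stage 1: calibration set + fit -----------------------------------
    stage = "calibration"
    try:
        cal_set = generate_calibration_set(
            config.calibration.doses_gy,
            geometry=config.geometry,
            dose_model=config.dose_model,
            detector=config.detector,
            seed=int(cal_seed),
            pixel_size_um=config.pixel_size_um,
        )
        points = []
        for dose, scan in cal_set:
            profile = extract_profile(_as_single_channel(scan))
            truth = scan.metadata["truth"]
            samples = [
                sample_region(profile, c, config.sampling.sample_width_um)
                for c in truth.peak_positions_um
            ]
            means = np.array([s.mean_response for s in samples])
            points.append(
                CalibrationPoint(
                    dose_gy=dose,
                    response=float(means.mean()),
                    response_sd=float(means.std(ddof=1)) if means.size > 1 else 0.0,
                )
            )
        fit = fit_quadratic if config.calibration.kind == "quadratic" else fit_logarithmic
        curve = fit(points)
        range_report = check_calibration_range(curve, config.detector.saturation_level)
        curve.save(out / "calibration.json")
        written.append(out / "calibration.json")
    except MbdoseError as err:
        raise StageFailure(stage, err) from err

    # -- stage 2: high-dose scans → PVDR ----------------------------------
    stage = "pvdr"
    try:
        results = []
        for dose, seed_i in zip(config.pvdr_peak_doses_gy, pvdr_seeds):
            dm = replace(config.dose_model, peak_dose_gy=float(dose))
            dmap = generate_dose_map(
                config.geometry,
                dm,
                pixel_size_um=config.pixel_size_um,
                field_size_um=None,
            )
            scan = render_scan(dmap, config.detector, int(seed_i))
            if write_images:
                write_scan(scan, out / f"scan_peak_{dose:g}Gy.tif")
            profile = extract_profile(_as_single_channel(scan))
            profile = smooth_profile(profile, config.sampling.smooth_window_um)
            write_profile(profile, out / f"profile_peak_{dose:g}Gy.csv")
            written.append(out / f"profile_peak_{dose:g}Gy.csv")
            _, valleys = detect_peaks(
                profile, config.geometry.pitch_um, config.sampling.prominence_frac
            )
            vd = compute_valley_doses(
                profile, valleys, curve, config.sampling.sample_width_um
            )
            results.append(
                compute_pvdr(dose, vd.doses_gy, vd.n_pixels_sampled, vd.excluded)
            )
        summary = aggregate_pvdr(results)
        (out / "pvdr.json").write_text(
            json.dumps(summary.to_dict(), indent=1, sort_keys=True)
        )
        written.append(out / "pvdr.json")
    except MbdoseError as err:
        raise StageFailure(stage, err) from err

    # -- stage 3: depth series → FWHM comparison --------------------------
    stage = "depth_comparison"
    try:
        dm = replace(config.dose_model, peak_dose_gy=config.depth_peak_dose_gy)
        depth_scans = generate_depth_series(
            config.geometry,
            dm,
            config.depths_mm,
            config.detector,
            seed=int(depth_seed),
            pixel_size_um=config.pixel_size_um,
        )
        if write_images:
            for z, scan in depth_scans:
                write_scan(scan, out / f"scan_depth_{z:g}mm.tif")
        depth_scans = [(z, _as_single_channel(s)) for z, s in depth_scans]
        comparison = compare_depths(
            depth_scans,
            smooth_window_um=config.sampling.smooth_window_um,
            pitch_um=config.geometry.pitch_um,
        )
        (out / "depth_comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=1, sort_keys=True)
        )
        written.append(out / "depth_comparison.json")
    except MbdoseError as err:
        raise StageFailure(stage, err) from err

    # ground truth of the measurement scans, for validation reporting
    truth_map = generate_dose_map(
        config.geometry,
        replace(config.dose_model, peak_dose_gy=100.0),
        pixel_size_um=config.pixel_size_um,
    )
    report = {
        "calibration": {
            **curve.to_dict(),
            "range_check": {
                "threshold": range_report.threshold,
                "passed": range_report.passed,
                "n_flagged": len(range_report.flagged),
            },
        },
        "pvdr": summary.to_dict(),
        "depth_comparison": comparison.to_dict(),
        "ground_truth": {
            "mean_pvdr": truth_map.truth.mean_pvdr,
            "per_valley_pvdr": list(truth_map.truth.per_valley_pvdr),
            "fwhm_um": truth_map.truth.fwhm_um,
        },
        "config": config.to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    written.append(out / "report.json")

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report
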