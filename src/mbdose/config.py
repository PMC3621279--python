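"""Pipeline configuration: every knob of the end-to-end run in one place.

The default configuration encodes the fluorescence study conditions:
an 8-beam array (25 µm beams, 200 µm pitch) imaged at 1.25 µm pixels,
quadratic fluorescence response (240.96 + 144.33·d − 3.3971·d² counts,
12-bit), calibration peak doses spanning 0–15 Gy, measurement peak doses
{50, 75, 100, 150} Gy, read noise of 20 counts per frame averaged over 8
frames, a 2 µm penumbra and 15% of the peak dose scattered over a 500 µm
kernel (ground-truth PVDR ≈ 55). ``film_config()`` gives the analogous
radiochromic-film setup (logarithmic response, 8-bit red channel,
calibration 2.5–75 Gy, measurement 300–800 Gy).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError, MbdoseError
from .synthetic import BeamGeometry, DetectorModel, DoseModel

__all__ = ["SamplingConfig", "CalibrationConfig", "PipelineConfig",
           "default_config", "film_config"]


@dataclass(frozen=True)
class SamplingConfig:
    """Profile readout parameters."""

    smooth_window_um: float = 6.25   # ~5 pixels at 1.25 µm
    sample_width_um: float = 20.0    # 16 pixels at 1.25 µm
    prominence_frac: float = 0.1


@dataclass(frozen=True)
class CalibrationConfig:
    """Which doses to calibrate on and with which model."""

    kind: str = "quadratic"
    doses_gy: tuple = (0.0, 1.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0)


@dataclass(frozen=True)
class PipelineConfig:
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    dose_model: DoseModel = field(
        default_factory=lambda: DoseModel(
            penumbra_sigma_um=2.0, scatter_fraction=0.15, scatter_sigma_um=500.0
        )
    )
    detector: DetectorModel = field(default_factory=DetectorModel.fluorescence)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    pvdr_peak_doses_gy: tuple = (50.0, 75.0, 100.0, 150.0)
    depths_mm: tuple = (20.0, 100.0)
    depth_peak_dose_gy: float = 250.0
    pixel_size_um: float = 1.25
    field_height_um: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        """Cross-field checks beyond the per-dataclass invariants."""
        if self.calibration.kind not in ("quadratic", "logarithmic"):
            raise ConfigError(f"unknown calibration kind {self.calibration.kind!r}")
        if self.detector.kind == "fluorescence":
            vertex = self.detector.vertex_dose_gy
            bad = [d for d in self.calibration.doses_gy if d >= vertex]
            if bad:
                raise ConfigError(
                    f"calibration doses {bad} at/beyond the fluorescence "
                    f"vertex ({vertex:.2f} Gy)"
                )
        if self.calibration.kind == "logarithmic" and any(
            d <= 0 for d in self.calibration.doses_gy
        ):
            raise ConfigError("logarithmic calibration requires positive doses")
        if (
            self.dose_model.scatter_fraction > 0
            and self.dose_model.scatter_sigma_um <= self.geometry.pitch_um
        ):
            raise ConfigError("scatter sigma must exceed the pitch when scatter is on")
        if not self.pvdr_peak_doses_gy:
            raise ConfigError("at least one measurement peak dose is required")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel size must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("pvdr_peak_doses_gy", "depths_mm"):
            d[key] = list(d[key])
        d["calibration"]["doses_gy"] = list(d["calibration"]["doses_gy"])
        d["detector"]["coefficients"] = list(d["detector"]["coefficients"])
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        try:
            det = d["detector"]
        except KeyError as err:
            raise ConfigError("config is missing the detector section") from err
        try:
            return PipelineConfig(
                geometry=BeamGeometry(**d.get("geometry", {})),
                dose_model=DoseModel(**d.get("dose_model", {})),
                detector=DetectorModel(
                    **{**det, "coefficients": tuple(det["coefficients"])}
                ),
                sampling=SamplingConfig(**d.get("sampling", {})),
                calibration=CalibrationConfig(
                    kind=d.get("calibration", {}).get("kind", "quadratic"),
                    doses_gy=tuple(d.get("calibration", {}).get("doses_gy", ())),
                ),
                pvdr_peak_doses_gy=tuple(d.get("pvdr_peak_doses_gy", ())),
                depths_mm=tuple(d.get("depths_mm", (20.0, 100.0))),
                depth_peak_dose_gy=float(d.get("depth_peak_dose_gy", 250.0)),
                pixel_size_um=float(d.get("pixel_size_um", 1.25)),
                field_height_um=float(d.get("field_height_um", 60.0)),
                seed=int(d.get("seed", 0)),
            )
        except (TypeError, KeyError, MbdoseError) as err:
            raise ConfigError(f"invalid pipeline config: {err}") from err

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))


def default_config(seed: int = 0) -> PipelineConfig:
    """Fluorescence (gel-dosimeter) study configuration."""
    return PipelineConfig(seed=seed)


def film_config(seed: int = 0) -> PipelineConfig:
    """Radiochromic-film study configuration (red-channel, logarithmic)."""
    return PipelineConfig(
        dose_model=DoseModel(
            penumbra_sigma_um=8.0, scatter_fraction=0.22, scatter_sigma_um=500.0
        ),
        detector=DetectorModel.optical_density(),
        calibration=CalibrationConfig(
            kind="logarithmic", doses_gy=(2.5, 5.0, 10.0, 20.0, 40.0, 75.0)
        ),
        pvdr_peak_doses_gy=(300.0, 400.0, 600.0, 800.0),
        seed=seed,
    )
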