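"""Dose-response calibration curves and their inversion.

The measurement trick at the heart of the PVDR method: the *peak* response
of a heavily irradiated dosimeter is far beyond the detector's sensitive
range, but the *valley* response is not. A calibration curve fitted on
low peak doses (fluorescence: quadratic over 0–15 Gy; film: logarithmic
over 2.5–75 Gy) is therefore inverted at the valley response to obtain the
valley dose, while the peak dose is taken as the delivered nominal dose.

The fluorescence curve is ``response(d) = c0 + b·d + a·d²`` with ``a < 0``
(saturating). Inversion solves ``a·x² + b·x + (c0 − response) = 0`` by the
quadratic formula and takes the root on the rising branch — the smaller
root, which lies below the vertex ``−b/(2a)``; the whole calibration range
sits below that vertex, so the response is strictly increasing there. The
film curve is ``response(d) = α·ln(d) + β`` with the closed-form inverse
``exp((response − β)/α)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError, FitError, InversionError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "RangeReport",
    "fit_quadratic",
    "fit_logarithmic",
    "invert_to_dose",
    "check_calibration_range",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: delivered peak dose and mean response."""

    dose_gy: float
    response: float
    response_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise DomainError("calibration dose must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted dose→response model with its valid dose domain.

    ``kind`` is ``"quadratic"`` (coefficients (a, b, c0), response =
    c0 + b·d + a·d²) or ``"logarithmic"`` (coefficients (alpha, beta),
    response = alpha·ln(d) + beta). Inversion is defined only for responses
    in the image of ``dose_domain``; doses outside the domain are still
    returned but flagged by :meth:`contains`.
    """

    kind: str
    coefficients: tuple
    dose_domain: tuple
    rmse: float = 0.0
    r2: float = 1.0
    n_points: int = 0
    warnings: tuple = ()
    fit_doses: tuple = ()
    fit_responses: tuple = ()

    def response(self, dose_gy) -> np.ndarray:
        """Forward-evaluate the fitted model (no saturation handling)."""
        d = np.asarray(dose_gy, dtype=float)
        if self.kind == "quadratic":
            a, b, c0 = self.coefficients
            return c0 + b * d + a * d * d
        alpha, beta = self.coefficients
        return alpha * np.log(d) + beta

    @property
    def vertex_dose_gy(self) -> float:
        if self.kind != "quadratic":
            raise DomainError("vertex defined only for quadratic curves")
        a, b, _ = self.coefficients
        return -b / (2 * a)

    def contains(self, dose_gy: float) -> bool:
        lo, hi = self.dose_domain
        return lo <= dose_gy <= hi

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": list(self.coefficients),
            "dose_domain": list(self.dose_domain),
            "rmse": self.rmse,
            "r2": self.r2,
            "n_points": self.n_points,
            "warnings": list(self.warnings),
        }

    @staticmethod
    def from_dict(d: dict) -> "CalibrationCurve":
        return CalibrationCurve(
            kind=d["kind"],
            coefficients=tuple(d["coefficients"]),
            dose_domain=tuple(d["dose_domain"]),
            rmse=float(d.get("rmse", 0.0)),
            r2=float(d.get("r2", 1.0)),
            n_points=int(d.get("n_points", 0)),
            warnings=tuple(d.get("warnings", ())),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "CalibrationCurve":
        return CalibrationCurve.from_dict(json.loads(Path(path).read_text()))


def _diagnostics(pred: np.ndarray, resp: np.ndarray) -> tuple[float, float]:
    resid = resp - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return rmse, r2


def fit_quadratic(points) -> CalibrationCurve:
    """Ordinary least-squares second-order polynomial of response on dose.

    Requires at least 3 distinct doses; a fitted leading coefficient
    ``a >= 0`` (no saturation curvature) is recorded as a warning in the
    diagnostics rather than rejected, as is a calibration range that
    reaches the parabola vertex.
    """
    points = list(points)
    dose = np.array([p.dose_gy for p in points], dtype=float)
    resp = np.array([p.response for p in points], dtype=float)
    if np.unique(dose).size < 3:
        raise FitError("quadratic fit needs >= 3 distinct doses")
    a, b, c0 = np.polyfit(dose, resp, 2)
    warnings = []
    if a >= 0:
        warnings.append("saturation-shape warning: fitted a >= 0 (no curvature down)")
    else:
        vertex = -b / (2 * a)
        if dose.max() >= vertex:
            warnings.append(
                f"dose domain reaches the response vertex ({vertex:.3f} Gy); "
                "inversion is ambiguous at the top of the range"
            )
    rmse, r2 = _diagnostics(c0 + b * dose + a * dose**2, resp)
    return CalibrationCurve(
        kind="quadratic",
        coefficients=(float(a), float(b), float(c0)),
        dose_domain=(float(dose.min()), float(dose.max())),
        rmse=rmse,
        r2=r2,
        n_points=len(points),
        warnings=tuple(warnings),
        fit_doses=tuple(dose),
        fit_responses=tuple(resp),
    )


def fit_logarithmic(points) -> CalibrationCurve:
    """Least-squares fit of response on ln(dose): response = α·ln(d) + β."""
    points = list(points)
    dose = np.array([p.dose_gy for p in points], dtype=float)
    resp = np.array([p.response for p in points], dtype=float)
    if (dose <= 0).any():
        raise DomainError("logarithmic calibration requires strictly positive doses")
    if np.unique(dose).size < 2:
        raise FitError("logarithmic fit needs >= 2 distinct doses")
    alpha, beta = np.polyfit(np.log(dose), resp, 1)
    rmse, r2 = _diagnostics(alpha * np.log(dose) + beta, resp)
    return CalibrationCurve(
        kind="logarithmic",
        coefficients=(float(alpha), float(beta)),
        dose_domain=(float(dose.min()), float(dose.max())),
        rmse=rmse,
        r2=r2,
        n_points=len(points),
        warnings=(),
        fit_doses=tuple(dose),
        fit_responses=tuple(resp),
    )


def invert_to_dose(curve: CalibrationCurve, response: float) -> float:
    """Map a measured response back to dose through the calibration curve.

    Quadratic curves: solve ``a·x² + b·x + (c0 − response) = 0`` and return
    the rising-branch (smaller) root. A response above the vertex value has
    no real root (negative discriminant) and a response below the response
    at the domain minimum lies under the calibration floor; both raise
    :class:`InversionError`. Logarithmic curves invert in closed form.

    The returned dose may lie outside ``curve.dose_domain`` (extrapolation);
    use :meth:`CalibrationCurve.contains` to flag such values.
    """
    r = float(response)
    if curve.kind == "quadratic":
        a, b, c0 = curve.coefficients
        if a == 0:
            raise InversionError("degenerate quadratic (a == 0)")
        floor = float(curve.response(curve.dose_domain[0]))
        if r < floor - 1e-9:
            raise InversionError(
                f"response {r:.4g} below the calibration floor {floor:.4g}"
            )
        disc = b * b - 4 * a * (c0 - r)
        if disc < 0:
            raise InversionError(
                f"response {r:.4g} exceeds the saturation vertex of the curve"
            )
        # a < 0, so adding sqrt(disc) selects the smaller (rising-branch) root
        return (-b + math.sqrt(disc)) / (2 * a)
    alpha, beta = curve.coefficients
    if alpha == 0:
        raise InversionError("degenerate logarithmic curve (alpha == 0)")
    return math.exp((r - beta) / alpha)


@dataclass(frozen=True)
class RangeReport:
    """Advisory check that calibration responses stay well below saturation."""

    threshold: float
    flagged: tuple = ()

    @property
    def passed(self) -> bool:
        return len(self.flagged) == 0


def check_calibration_range(
    curve: CalibrationCurve, saturation_level: float
) -> RangeReport:
    """Flag calibration responses above 50% of the detector saturation.

    Mirrors the acquisition rule of keeping the whole calibration curve
    under half the PMT saturation so the response stays comfortably linear
    in gain. Advisory only: nothing is rejected.
    """
    threshold = 0.5 * float(saturation_level)
    flagged = tuple(
        (d, r)
        for d, r in zip(curve.fit_doses, curve.fit_responses)
        if r > threshold
    )
    return RangeReport(threshold=threshold, flagged=flagged)
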