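"""Beam-width (FWHM) analysis and the unequal-variance depth comparison.

FWHM is measured above a baseline because microbeam profiles sit on a
nonzero valley floor: the half-maximum level is
``baseline + (peak - baseline) / 2`` with the baseline taken (by default)
as the median response over the two flanking valley windows. The width is
the distance between the outermost linearly interpolated crossings of that
level within half a pitch of the peak centre on each side — taking the
outermost crossing avoids noise-spike underestimates, and staying within
half a pitch keeps the search away from neighbouring beams.

Because the half level is defined relative to baseline and peak, the FWHM
is invariant under affine response transforms (gain * response + offset),
so it can be compared across dosimeters without normalization.

Depth series (same beam imaged at several depths through the dosimeter)
are compared with Welch's two-sample t-test — equal variances are not
assumed — with Welch–Satterthwaite degrees of freedom and a two-sided p,
at a 0.05 significance threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import InputError, WidthError
from .imaging import Profile, detect_peaks, extract_profile, smooth_profile

__all__ = [
    "FwhmResult",
    "TTestResult",
    "DepthComparison",
    "compute_fwhm",
    "fwhm_for_profile",
    "welch_t_test",
    "compare_depths",
    "plot_profile_overlay",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class FwhmResult:
    """Per-peak FWHMs for one profile with mean ± sample sd (n−1)."""

    per_peak_fwhm_um: tuple
    mean_fwhm_um: float
    sd_fwhm_um: float
    baseline: float
    half_max_level: float

    def to_dict(self) -> dict:
        return {
            "per_peak_fwhm_um": list(self.per_peak_fwhm_um),
            "fwhm_mean_um": self.mean_fwhm_um,
            "fwhm_sd_um": self.sd_fwhm_um,
            "n_peaks": len(self.per_peak_fwhm_um),
        }


@dataclass(frozen=True)
class TTestResult:
    """Welch's t-test result (Satterthwaite df, two-sided p)."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float

    def to_dict(self) -> dict:
        return {
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_value,
            "group_means_um": [self.mean_a, self.mean_b],
            "group_sds_um": [self.sd_a, self.sd_b],
        }


def _fwhm_detail(
    profile: Profile,
    peak_centre_um: float,
    baseline_mode: str = "valley_median",
    pitch_um: float = 200.0,
    valley_window_um: float = 20.0,
) -> tuple[float, float, float]:
    """Return (width, baseline, half_level) for one peak."""
    pos = profile.positions_um
    v = profile.values
    px = profile.pixel_size_um

    in_win = np.abs(pos - peak_centre_um) <= pitch_um / 2
    if not in_win.any():
        raise WidthError("peak centre outside the profile")
    idx = np.nonzero(in_win)[0]

    if baseline_mode == "valley_median":
        flank_vals = []
        for vc in (peak_centre_um - pitch_um / 2, peak_centre_um + pitch_um / 2):
            m = np.abs(pos - vc) <= valley_window_um / 2
            if m.any():
                flank_vals.append(v[m])
        if not flank_vals:
            raise WidthError("no flanking valley windows inside the profile")
        baseline = float(np.median(np.concatenate(flank_vals)))
    elif baseline_mode == "global_min":
        baseline = float(v.min())
    else:
        raise WidthError(f"unknown baseline mode {baseline_mode!r}")

    near = np.abs(pos - peak_centre_um) <= pitch_um / 4
    peak_val = float(v[near].max()) if near.any() else float(v[idx].max())
    if peak_val <= baseline:
        raise WidthError("peak response does not rise above the baseline")
    half = baseline + 0.5 * (peak_val - baseline)

    above = v >= half
    lo, hi = idx[0], idx[-1]
    # outermost upward crossing on the left, downward on the right
    x_left = x_right = None
    for i in range(lo, hi):
        if not above[i] and above[i + 1]:
            x_left = pos[i] + px * (half - v[i]) / (v[i + 1] - v[i])
            break
    for i in range(hi, lo, -1):
        if not above[i] and above[i - 1]:
            x_right = pos[i] - px * (half - v[i]) / (v[i - 1] - v[i])
            break
    if x_left is None or x_right is None or x_right <= x_left:
        raise WidthError("no half-maximum crossing on one or both sides within a pitch")
    return float(x_right - x_left), baseline, half


def compute_fwhm(
    profile: Profile,
    peak_centre_um: float,
    baseline_mode: str = "valley_median",
    pitch_um: float = 200.0,
    valley_window_um: float = 20.0,
) -> float:
    """Full width at half maximum (µm) of one peak above its local baseline."""
    width, _, _ = _fwhm_detail(
        profile, peak_centre_um, baseline_mode, pitch_um, valley_window_um
    )
    return width


def fwhm_for_profile(
    profile: Profile,
    peak_centres_um,
    baseline_mode: str = "valley_median",
    pitch_um: float = 200.0,
    valley_window_um: float = 20.0,
) -> FwhmResult:
    """FWHM of every detected peak, summarised as mean ± sample sd."""
    widths, baselines, halves = [], [], []
    for c in peak_centres_um:
        w, b, h = _fwhm_detail(profile, float(c), baseline_mode, pitch_um, valley_window_um)
        widths.append(w)
        baselines.append(b)
        halves.append(h)
    if not widths:
        raise WidthError("no peaks to measure")
    arr = np.asarray(widths)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return FwhmResult(
        per_peak_fwhm_um=tuple(widths),
        mean_fwhm_um=float(arr.mean()),
        sd_fwhm_um=sd,
        baseline=float(np.mean(baselines)),
        half_max_level=float(np.mean(halves)),
    )


def welch_t_test(group_a, group_b) -> TTestResult:
    """Welch's two-sample t-test (equal variances not assumed).

    t = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b), with Welch–Satterthwaite
    degrees of freedom and a two-sided p from the t distribution. When both
    sample variances are zero the statistic degenerates: equal means give
    t = 0, p = 1; unequal means give p = 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        df = float(na + nb - 2)
        if ma == mb:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, ma - mb)
            p = 0.0
    else:
        se2 = va / na + vb / nb
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        mean_a=ma,
        mean_b=mb,
        sd_a=math.sqrt(va),
        sd_b=math.sqrt(vb),
    )


@dataclass(frozen=True)
class DepthComparison:
    """Per-depth FWHM summaries plus pairwise Welch tests."""

    per_depth: tuple  # (depth_mm, FwhmResult) pairs
    tests: tuple  # (depth_a, depth_b, TTestResult, significant) tuples

    @property
    def any_significant(self) -> bool:
        return any(sig for _, _, _, sig in self.tests)

    def to_dict(self) -> dict:
        return {
            "per_depth": [
                dict(depth_mm=z, **res.to_dict()) for z, res in self.per_depth
            ],
            "tests": [
                dict(
                    depth_a_mm=za,
                    depth_b_mm=zb,
                    significant=sig,
                    **tt.to_dict(),
                )
                for za, zb, tt, sig in self.tests
            ],
        }


def compare_depths(
    scans,
    smooth_window_um: float = 6.25,
    pitch_um: float = 200.0,
    baseline_mode: str = "valley_median",
    strip: tuple[int, int] | None = None,
) -> DepthComparison:
    """FWHM per depth and pairwise Welch tests between depths.

    ``scans`` is a sequence of (depth_mm, ScanImage). Each scan is profiled,
    smoothed, peak-detected and measured; depths are then compared pairwise
    at the 0.05 level. A non-diffusing beam should show no significant
    difference in width between depths.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise InputError("depth comparison needs at least two depths")
    per_depth = []
    for depth, scan in scans:
        profile = extract_profile(scan, strip)
        profile = smooth_profile(profile, smooth_window_um)
        peaks, _ = detect_peaks(profile, pitch_um)
        if peaks.size < 2:
            raise InputError(f"need >= 2 peaks per depth, found {peaks.size}")
        per_depth.append(
            (float(depth), fwhm_for_profile(profile, peaks, baseline_mode, pitch_um))
        )
    tests = []
    for (za, ra), (zb, rb) in combinations(per_depth, 2):
        tt = welch_t_test(ra.per_peak_fwhm_um, rb.per_peak_fwhm_um)
        tests.append((za, zb, tt, tt.p_value < SIGNIFICANCE_LEVEL))
    return DepthComparison(per_depth=tuple(per_depth), tests=tuple(tests))


def plot_profile_overlay(profiles, labels, path) -> None:
    """Overlay min-max-normalized profiles and write a PNG.

    Normalization is for display only; FWHM itself is affine invariant and
    is always computed on the unnormalized profiles.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for profile, label in zip(profiles, labels):
        v = profile.values
        rng = v.max() - v.min()
        norm = (v - v.min()) / rng if rng > 0 else v * 0
        ax.plot(profile.positions_um, norm, label=label)
    ax.set_xlabel("position (µm)")
    ax.set_ylabel("normalized response")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
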