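"""Generator tests: dose-map construction, detector rendering, series."""

import numpy as np
import pytest

from mbdose import (
    BeamGeometry,
    DetectorModel,
    DoseModel,
    generate_calibration_set,
    generate_depth_series,
    generate_dose_map,
    render_scan,
)
from mbdose.errors import DomainError, GeometryError

from conftest import PRINTED_COEFFS


class TestGenerateDoseMap:
    def test_ideal_beam_has_clean_peaks_and_empty_valleys(self):
        dm = generate_dose_map(BeamGeometry(), DoseModel(peak_dose_gy=100.0))
        assert dm.truth.peak_doses_gy == pytest.approx([100.0] * 8)
        assert dm.truth.valley_doses_gy == pytest.approx([0.0] * 7)

    def test_default_geometry_yields_eight_peaks_seven_valleys(self):
        dm = generate_dose_map()
        assert len(dm.truth.peak_positions_um) == 8
        assert len(dm.truth.valley_positions_um) == 7

    def test_delta_comb_with_gaussian_penumbra_has_gaussian_fwhm(self):
        # a near-delta comb blurred with sigma=10 µm is a Gaussian of
        # FWHM 2*sqrt(2 ln 2)*sigma = 23.55 µm
        geom = BeamGeometry(n_beams=2, beam_width_um=1e-3, pitch_um=200.0)
        dm = generate_dose_map(geom, DoseModel(peak_dose_gy=100.0, penumbra_sigma_um=10.0))
        expected = 2 * np.sqrt(2 * np.log(2)) * 10.0
        assert dm.truth.fwhm_um == pytest.approx(expected, abs=0.2)

    def test_scatter_elevates_central_valley_and_matches_direct_convolution(self):
        geom = BeamGeometry(n_beams=4, beam_width_um=25.0, pitch_um=200.0)
        model = DoseModel(
            peak_dose_gy=50.0, scatter_fraction=0.05, scatter_sigma_um=500.0
        )
        px = 5.0  # low resolution for the O(N^2) oracle
        dm = generate_dose_map(geom, model, pixel_size_um=px)
        vd = dm.truth.valley_doses_gy
        assert vd[1] > vd[0] and vd[1] > vd[2]

        # brute-force periodic convolution of the comb with the two kernels
        n = dm.values.shape[1]
        positions = np.arange(n) * px
        centre = positions[-1] / 2
        offsets = (np.arange(4) - 1.5) * 200.0
        comb = np.zeros(n)
        for c in centre + offsets:
            lo, hi = c - 12.5, c + 12.5
            overlap = np.minimum(positions + px / 2, hi) - np.maximum(positions - px / 2, lo)
            comb += np.clip(overlap, 0, None) / px

        def direct_periodic_gauss(arr, sigma_px):
            n = arr.size
            # same truncated kernel radius as scipy's default (4 sigma)
            radius = int(4 * sigma_px + 0.5)
            k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_px) ** 2)
            k /= k.sum()
            out = np.zeros(n)
            for i in range(n):
                for j, w in zip(range(i - radius, i + radius + 1), k):
                    out[i] += arr[j % n] * w
            return out

        expected = 50.0 * (0.95 * comb + 0.05 * direct_periodic_gauss(comb, 500.0 / px))
        assert np.allclose(dm.profile, expected, rtol=1e-9, atol=1e-9)

    def test_field_too_small_raises_geometry_error(self):
        with pytest.raises(GeometryError):
            generate_dose_map(
                BeamGeometry(),
                DoseModel(peak_dose_gy=10.0, scatter_fraction=0.1, scatter_sigma_um=500.0),
                field_size_um=(1800.0, 60.0),
            )

    def test_dose_conservation_under_blur(self):
        """Unit-sum periodic kernels conserve total dose for any widths."""
        geom = BeamGeometry()
        base = generate_dose_map(geom, DoseModel(peak_dose_gy=80.0))
        total0 = base.profile.sum()
        for model in [
            DoseModel(peak_dose_gy=80.0, penumbra_sigma_um=15.0),
            DoseModel(peak_dose_gy=80.0, scatter_fraction=0.3, scatter_sigma_um=450.0),
            DoseModel(peak_dose_gy=80.0, penumbra_sigma_um=5.0,
                      scatter_fraction=0.1, scatter_sigma_um=600.0),
        ]:
            dm = generate_dose_map(geom, model, field_size_um=(5200.0, 60.0))
            ref = generate_dose_map(geom, DoseModel(peak_dose_gy=80.0),
                                    field_size_um=(5200.0, 60.0))
            assert dm.profile.sum() == pytest.approx(ref.profile.sum(), rel=1e-6)
        assert total0 > 0

    def test_valley_doses_unimodal_with_wide_scatter(self):
        dm = generate_dose_map(
            BeamGeometry(),
            DoseModel(peak_dose_gy=100.0, scatter_fraction=0.2, scatter_sigma_um=400.0),
        )
        vd = np.array(dm.truth.valley_doses_gy)
        mid = len(vd) // 2
        assert np.argmax(vd) == mid
        assert np.all(np.diff(vd[: mid + 1]) > 0)
        assert np.all(np.diff(vd[mid:]) < 0)

    def test_geometry_invariants_rejected(self):
        with pytest.raises(GeometryError):
            BeamGeometry(n_beams=1)
        with pytest.raises(GeometryError):
            BeamGeometry(beam_width_um=250.0, pitch_um=200.0)
        with pytest.raises(DomainError):
            DoseModel(scatter_fraction=1.5)


class TestRenderScan:
    def test_zero_dose_uniform_at_intercept(self, noiseless_fluorescence):
        dm = generate_dose_map(BeamGeometry(), DoseModel(peak_dose_gy=0.0))
        img = render_scan(dm, noiseless_fluorescence, seed=0)
        assert np.unique(img.pixels).tolist() == [round(PRINTED_COEFFS[0])]

    def test_one_gray_plateau_at_forward_polynomial(self, noiseless_fluorescence):
        # ideal (unblurred) 1 Gy beams: every in-beam pixel reads the
        # forward-evaluated polynomial at 1 Gy, every valley pixel the intercept
        dm = generate_dose_map(BeamGeometry(), DoseModel(peak_dose_gy=1.0))
        img = render_scan(dm, noiseless_fluorescence, seed=0)
        c0, c1, c2 = PRINTED_COEFFS
        expected = round(c0 + c1 * 1.0 + c2 * 1.0)  # 382 counts
        px = dm.pixel_size_um
        for c in dm.truth.peak_positions_um:
            col = int(round(c / px))
            assert np.unique(img.pixels[:, col]).tolist() == [expected]
        for v in dm.truth.valley_positions_um:
            col = int(round(v / px))
            assert np.unique(img.pixels[:, col]).tolist() == [round(c0)]

    def test_same_seed_bit_identical(self, study_dose_model):
        dm = generate_dose_map(BeamGeometry(), study_dose_model)
        det = DetectorModel.fluorescence()
        a = render_scan(dm, det, seed=42)
        b = render_scan(dm, det, seed=42)
        assert np.array_equal(a.pixels, b.pixels)
        c = render_scan(dm, det, seed=43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_noise_scaling_matches_frame_averaging(self):
        """Empirical sd of rendered-minus-noiseless ≈ noise_sigma/sqrt(n)."""
        geom = BeamGeometry(n_beams=2, beam_width_um=150.0, pitch_um=200.0)
        model = DoseModel(peak_dose_gy=5.0)
        dm = generate_dose_map(geom, model, field_size_um=(600.0, 400.0))
        assert dm.values.size >= 1e5
        det = DetectorModel.fluorescence(noise_sigma=20.0, n_frames_averaged=8)
        det0 = DetectorModel.fluorescence(noise_sigma=0.0)
        noisy = render_scan(dm, det, seed=7).pixels.astype(float)
        clean = render_scan(dm, det0, seed=7).pixels.astype(float)
        sd = np.std(noisy - clean)
        assert sd == pytest.approx(20.0 / np.sqrt(8), rel=0.05)

    def test_film_render_is_rgb_with_strongest_red_contrast(self, study_dose_model):
        dm = generate_dose_map(BeamGeometry(), study_dose_model)
        img = render_scan(dm, DetectorModel.optical_density(), seed=3)
        assert img.pixels.ndim == 3 and img.pixels.shape[2] == 3
        assert img.bit_depth == 8
        contrasts = [img.pixels[:, :, k].astype(float).std() for k in range(3)]
        assert contrasts[0] == max(contrasts)

    def test_saturating_doses_held_at_vertex(self, noiseless_fluorescence):
        det = noiseless_fluorescence
        r_vertex = det.response(det.vertex_dose_gy)
        assert det.response(300.0) == pytest.approx(r_vertex)
        assert det.response(det.vertex_dose_gy + 5) == pytest.approx(r_vertex)


class TestCalibrationSet:
    def test_peak_means_match_printed_polynomial(self, noiseless_fluorescence):
        from mbdose.imaging import extract_profile, sample_region

        doses = [0.0, 5.0, 10.0, 15.0]
        cal = generate_calibration_set(doses, detector=noiseless_fluorescence, seed=0)
        assert len(cal) == 4
        c0, c1, c2 = PRINTED_COEFFS
        for dose, scan in cal:
            profile = extract_profile(scan)
            means = [
                sample_region(profile, c, 20.0).mean_response
                for c in scan.metadata["truth"].peak_positions_um
            ]
            expected = c0 + c1 * dose + c2 * dose**2
            # quantization to integer counts is the only deviation
            assert np.mean(means) == pytest.approx(expected, abs=0.5)

    def test_empty_dose_list_gives_empty_set(self):
        assert generate_calibration_set([], seed=0) == []

    def test_film_calibration_stays_in_8bit_range(self):
        doses = [2.5, 5, 10, 20, 40, 75]
        cal = generate_calibration_set(
            doses, detector=DetectorModel.optical_density(), seed=1
        )
        for _, scan in cal:
            assert scan.pixels.dtype == np.uint8
            assert scan.pixels.max() <= 255

    def test_dose_beyond_vertex_rejected(self, noiseless_fluorescence):
        vertex = noiseless_fluorescence.vertex_dose_gy
        with pytest.raises(DomainError):
            generate_calibration_set([0, 5, vertex + 1], detector=noiseless_fluorescence)


class TestDepthSeries:
    def test_zero_slope_gives_identical_true_widths(self):
        series_truth = []
        scans = generate_depth_series(
            BeamGeometry(), DoseModel(peak_dose_gy=50.0, penumbra_sigma_um=2.0),
            depths_mm=[20.0, 100.0], detector=DetectorModel.fluorescence(), seed=0,
        )
        for _, scan in scans:
            series_truth.append(scan.metadata["truth"].fwhm_um)
        assert series_truth[0] == pytest.approx(series_truth[1], abs=1e-9)

    def test_width_slope_broadens_fwhm_by_slope_times_depth(self):
        # slope 0.1 µm/mm over depths 20 and 100 mm → widths differ by 8 µm
        scans = generate_depth_series(
            BeamGeometry(),
            DoseModel(peak_dose_gy=50.0, penumbra_sigma_um=1.0,
                      depth_width_slope_um_per_mm=0.1),
            depths_mm=[20.0, 100.0], detector=DetectorModel.fluorescence(), seed=0,
        )
        w20 = scans[0][1].metadata["truth"].fwhm_um
        w100 = scans[1][1].metadata["truth"].fwhm_um
        assert w100 - w20 == pytest.approx(8.0, abs=0.2)

    def test_single_depth_gives_series_of_length_one(self):
        scans = generate_depth_series(depths_mm=[20.0], seed=0,
                                      dose_model=DoseModel(peak_dose_gy=10.0))
        assert len(scans) == 1

    def test_negative_depth_rejected(self):
        with pytest.raises(DomainError):
            generate_depth_series(depths_mm=[-1.0], seed=0)
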