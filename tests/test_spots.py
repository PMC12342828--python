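"""Spot detection, intensity-mixture calibration and per-cell counting."""

import math

import numpy as np
import pandas as pd
import pytest

from burstlab import (
    DetectionConfig,
    assign_spots_to_cells,
    detect_spots,
    fit_intensity_mixture,
    intensities_to_counts,
    render_spot_field,
    sample_spot_intensities,
)


def _match_to_truth(spots, truth, radius=2.0):
    """Greedy nearest matching of detections to ground-truth positions."""
    used = set()
    matches = []
    for _, s in spots.iterrows():
        best, best_d = None, radius
        for j, t in truth.iterrows():
            if j in used:
                continue
            d = math.hypot(s["x"] - t["x"], s["y"] - t["y"])
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            used.add(best)
            matches.append((best, best_d))
    return matches


class TestDetectSpots:
    def test_blank_image_yields_no_spots(self):
        rng = np.random.default_rng(1)
        image = 100.0 + rng.normal(0, 5.0, size=(96, 96))
        spots = detect_spots(image, DetectionConfig(maxima_threshold=150.0, height_threshold=25.0))
        assert len(spots) == 0

    @pytest.mark.parametrize("prefilter", ["none", "log"])
    def test_five_isolated_spots_recovered_subpixel(self, prefilter):
        truth_xy = [(20.3, 25.7), (60.1, 20.4), (40.6, 48.2), (70.8, 70.3), (25.2, 72.9)]
        noise_sd = 10.0
        intensity = 10.0 * noise_sd * 2 * math.pi * 1.3**2  # SNR 10
        image, truth, _ = render_spot_field(
            cells=[], spots=[(x, y, intensity) for x, y in truth_xy],
            shape=(96, 96), psf_sigma_px=1.3, background=100.0,
            noise_sd=noise_sd, seed=5,
        )
        threshold = 100.0 + 5 * noise_sd if prefilter == "none" else 8.0
        config = DetectionConfig(
            prefilter=prefilter, maxima_threshold=threshold, height_threshold=5 * noise_sd
        )
        spots = detect_spots(image, config)
        assert len(spots) == 5
        matches = _match_to_truth(spots, truth, radius=1.5)
        assert len(matches) == 5
        assert all(d < 0.5 for _, d in matches)

    def test_adjacent_maxima_deduplicated_to_one_spot(self):
        """Two noise-split maxima of one physical spot collapse to a single
        detection (brute-force nearest-truth matching oracle)."""
        image, truth, _ = render_spot_field(
            cells=[], spots=[(32.0, 32.0, 4000.0)], shape=(64, 64),
            background=100.0, noise_sd=0.0,
        )
        # split the peak by hand so two local maxima sit in one fit window
        image[32, 31] = image[32, 32]
        spots = detect_spots(
            image, DetectionConfig(maxima_threshold=120.0, height_threshold=20.0)
        )
        assert len(spots) == 1
        assert len(_match_to_truth(spots, truth, radius=1.5)) == 1

    def test_rejects_non_2d_input(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((4, 4, 4)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(fit_window_px=4)
        with pytest.raises(ValueError):
            DetectionConfig(maxima_threshold=-1.0)


class TestIntensityMixture:
    def test_recovers_singlet_mean_within_two_percent(self):
        sample = sample_spot_intensities(100.0, 20.0, frac_doublets=0.2, n=5000, seed=7)
        fit = fit_intensity_mixture(sample.intensities)
        assert fit.b_i == pytest.approx(100.0, rel=0.02)
        assert fit.c == pytest.approx(20.0, rel=0.25)
        assert fit.a > 0 and fit.d > 0

    def test_pure_singlets_suppress_doublet_mode(self):
        sample = sample_spot_intensities(100.0, 20.0, frac_doublets=0.0, n=5000, seed=8)
        fit = fit_intensity_mixture(sample.intensities)
        assert fit.b_i == pytest.approx(sample.intensities.mean(), rel=0.03)
        assert fit.d < 0.1 * fit.a

    def test_scale_equivariance(self):
        sample = sample_spot_intensities(100.0, 20.0, frac_doublets=0.2, n=5000, seed=9)
        fit1 = fit_intensity_mixture(sample.intensities)
        fit2 = fit_intensity_mixture(sample.intensities * 3.0)
        assert fit2.b_i == pytest.approx(3.0 * fit1.b_i, rel=0.01)
        assert fit2.c == pytest.approx(3.0 * fit1.c, rel=0.05)

    def test_estimates_tighten_with_sample_size(self):
        """Consistency: average |bias| of (b_i, c) shrinks from n=500 to
        n=5000 across seeded repetitions."""
        def mean_abs_err(n):
            errs = []
            for seed in range(6):
                s = sample_spot_intensities(100.0, 20.0, 0.2, n=n, seed=100 + seed)
                f = fit_intensity_mixture(s.intensities)
                errs.append(abs(f.b_i - 100.0) / 100.0 + abs(f.c - 20.0) / 20.0)
            return np.mean(errs)

        assert mean_abs_err(5000) < mean_abs_err(500)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_intensity_mixture(np.full(10, 100.0))


class TestIntensitiesToCounts:
    @pytest.fixture
    def fit(self):
        sample = sample_spot_intensities(100.0, 20.0, 0.2, n=5000, seed=11)
        return fit_intensity_mixture(sample.intensities)

    def test_nearest_integer_rule(self, fit):
        b = fit.b_i
        spots = pd.DataFrame(
            {"x": [1.0] * 3, "y": [1.0] * 3,
             "integrated_intensity": [b, 2 * b, 1.4 * b],
             "peak_height": [1.0] * 3, "fit_sigma": [1.3] * 3}
        )
        out = intensities_to_counts(spots, fit)
        assert out["multiplicity"].tolist() == [1, 2, 1]

    def test_floor_at_one_and_monotonicity(self, fit):
        intensities = np.linspace(1.0, 6 * fit.b_i, 50)
        spots = pd.DataFrame(
            {"x": np.ones(50), "y": np.ones(50),
             "integrated_intensity": intensities,
             "peak_height": np.ones(50), "fit_sigma": np.ones(50)}
        )
        mult = intensities_to_counts(spots, fit)["multiplicity"].to_numpy()
        assert mult.min() == 1
        assert np.all(np.diff(mult) >= 0)

    def test_halo_mode_counts_each_spot_once(self):
        spots = pd.DataFrame(
            {"x": [1.0, 2.0], "y": [1.0, 2.0],
             "integrated_intensity": [500.0, 900.0],
             "peak_height": [1.0, 1.0], "fit_sigma": [1.3, 1.3]}
        )
        out = intensities_to_counts(spots, mode="halo")
        assert out["multiplicity"].tolist() == [1, 1]


class TestAssignSpotsToCells:
    def _mask(self):
        mask = np.zeros((40, 40), dtype=np.uint16)
        mask[5:15, 5:15] = 1
        mask[25:35, 25:35] = 2
        return mask

    def test_all_spots_in_one_cell(self):
        spots = pd.DataFrame(
            {"x": [6.0, 8.0, 10.0], "y": [6.0, 8.0, 10.0], "multiplicity": [1, 2, 1]}
        )
        table, report = assign_spots_to_cells(spots, self._mask())
        by_cell = table.set_index("cell_id")["count"]
        assert by_cell[1] == 4
        assert by_cell[2] == 0
        assert report["discarded_multiplicity"] == 0

    def test_background_spot_discarded_and_reported(self):
        spots = pd.DataFrame({"x": [6.0, 20.0], "y": [6.0, 20.0], "multiplicity": [1, 3]})
        table, report = assign_spots_to_cells(spots, self._mask())
        assert report["discarded_multiplicity"] == 3
        assert report["assigned_multiplicity"] == 1
        assert table["count"].sum() == 1

    def test_multiplicity_conservation(self):
        rng = np.random.default_rng(13)
        spots = pd.DataFrame(
            {"x": rng.uniform(0, 39, 50), "y": rng.uniform(0, 39, 50),
             "multiplicity": rng.integers(1, 4, 50)}
        )
        table, report = assign_spots_to_cells(spots, self._mask())
        assert (
            report["assigned_multiplicity"] + report["discarded_multiplicity"]
            == report["total_multiplicity"]
        )
        assert table["count"].sum() == report["assigned_multiplicity"]

    def test_out_of_frame_spot_rejected(self):
        spots = pd.DataFrame({"x": [100.0], "y": [5.0], "multiplicity": [1]})
        with pytest.raises(ValueError):
            assign_spots_to_cells(spots, self._mask())

    def test_concentration_uses_label_area(self):
        spots = pd.DataFrame({"x": [6.0], "y": [6.0], "multiplicity": [4]})
        table, _ = assign_spots_to_cells(spots, self._mask(), pixel_area_um2=0.01)
        row = table.set_index("cell_id").loc[1]
        assert row["area_um2"] == pytest.approx(1.0)
        assert row["concentration"] == pytest.approx(4.0)


class TestEndToEndPipeline:
    def test_detection_f1_and_exact_count_recovery(self, spot_field):
        """On the standard SNR-10 fixture the full pipeline (detect -> halo
        counts -> assign) reaches F1 >= 0.95 and recovers per-cell counts."""
        image, truth, mask = spot_field
        config = DetectionConfig(maxima_threshold=150.0, height_threshold=50.0)
        spots = detect_spots(image, config)
        matches = _match_to_truth(spots, truth, radius=2.0)
        tp = len(matches)
        precision = tp / len(spots)
        recall = tp / len(truth)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95
        counted = intensities_to_counts(spots, mode="halo")
        table, report = assign_spots_to_cells(counted, mask)
        expected = truth[truth["cell_id"] > 0].groupby("cell_id").size()
        got = table.set_index("cell_id")["count"]
        assert all(got.get(c, 0) == n for c, n in expected.items())
        assert got.drop(expected.index, errors="ignore").sum() == 0
        assert (
            report["assigned_multiplicity"] + report["discarded_multiplicity"]
            == report["total_multiplicity"]
        )
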