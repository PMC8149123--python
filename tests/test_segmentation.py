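"""Plane selection, background subtraction, segmentation accuracy, tracking."""
import collections

import numpy as np
import pandas as pd
import pytest

from capdyn.errors import DetectionError, ParameterError
from capdyn.segmentation import (link_tracks, measure_caps, measure_movie,
                                 segment_caps, select_measurement_plane,
                                 subtract_background)
from capdyn.stack_io import ImageStack4D
from capdyn.synthetic import SceneConfig, simulate_cap_movie


def _disk_image(shape, center, radius, amplitude, edge=2.0):
    """Flat-top disk with a Gaussian edge whose half-max sits at ``radius``."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    w = edge * np.sqrt(2 * np.log(2))
    e = d - radius
    return amplitude * np.where(e <= -w, 1.0, np.exp(-(e + w) ** 2 / (2 * edge ** 2)))


class TestPlaneSelection:
    def _stack(self, apical_z, n_z=8, z_step=0.3):
        # cap signal appears at apical_z and decays below; nothing above
        data = np.full((1, n_z, 64, 64), 100.0)
        mask = np.hypot(*np.mgrid[-32:32, -32:32]) < 16  # ~20% of the field
        for z in range(apical_z, n_z):
            data[0, z][mask] += 500.0 * np.exp(-0.3 * (z - apical_z))
        return ImageStack4D(data, pixel_size_um=0.25, z_step_um=z_step)

    def test_offset_three_planes_below_apical(self):
        stack = self._stack(apical_z=2)
        assert select_measurement_plane(stack, offset_um=0.9)[0] == 5

    def test_zero_offset_returns_apical(self):
        stack = self._stack(apical_z=2)
        assert select_measurement_plane(stack, offset_um=0.0)[0] == 2

    def test_uniform_noise_stack_raises(self, rng):
        data = rng.normal(100, 5, size=(1, 6, 32, 32)).clip(0)
        with pytest.raises(DetectionError):
            select_measurement_plane(ImageStack4D(data, z_step_um=0.3))

    def test_too_few_planes_raises(self):
        stack = self._stack(apical_z=0, n_z=2)
        with pytest.raises(ParameterError):
            select_measurement_plane(stack, offset_um=0.9)


class TestBackground:
    def test_constant_image_goes_to_zero(self):
        img = np.full((32, 32), 7.5)
        corrected, bg = subtract_background(img)
        assert bg == 7.5
        assert np.all(corrected == 0.0)

    def test_recovers_generator_background(self):
        cfg = SceneConfig(n_frames=2, noise_sd=0.0, seed=0)
        stack, _ = simulate_cap_movie(cfg)
        _, bg = subtract_background(stack.data[0, 5].astype(float))
        assert bg == pytest.approx(cfg.background, abs=1.0)
        # with noise the low-percentile estimate sits within ~2 noise SD
        cfg_n = SceneConfig(n_frames=2, noise_sd=20.0, seed=0)
        stack_n, _ = simulate_cap_movie(cfg_n)
        _, bg_n = subtract_background(stack_n.data[0, 5].astype(float))
        assert abs(bg_n - cfg_n.background) <= 2.5 * cfg_n.noise_sd

    def test_zero_background_image_unchanged(self):
        img = np.zeros((16, 16))
        img[4:8, 4:8] = 50.0
        corrected, bg = subtract_background(img)
        assert bg == 0.0
        assert np.array_equal(corrected, img)


class TestSegmentation:
    @pytest.mark.parametrize("radius_px", [10, 15, 20, 30])
    def test_disk_area_within_5_percent(self, radius_px):
        ps = 0.1
        img = _disk_image((160, 160), (80, 80), radius_px, 1000.0)
        labels = segment_caps(img, ps)
        assert labels.max() == 1
        true_area = np.pi * radius_px ** 2 * ps ** 2
        meas = measure_caps(labels, img, ps)
        assert abs(meas["area_um2"][0] - true_area) / true_area <= 0.05

    def test_two_disks_two_labels(self):
        img = _disk_image((160, 160), (40, 40), 12, 800.0) \
            + _disk_image((160, 160), (110, 110), 15, 800.0)
        labels = segment_caps(img, 0.1)
        assert labels.max() == 2
        meas = measure_caps(labels, img, 0.1)
        # labels sorted by descending area
        assert meas["area_um2"].is_monotonic_decreasing
        for r, area in zip([15, 12], meas["area_um2"]):
            true = np.pi * r ** 2 * 0.01
            assert abs(area - true) / true <= 0.05

    def test_all_zero_image_yields_no_objects(self):
        assert segment_caps(np.zeros((32, 32)), 0.1).max() == 0

    def test_label_map_deterministic(self, rng):
        img = _disk_image((96, 96), (48, 48), 14, 600.0) + rng.normal(0, 5, (96, 96))
        img = img.clip(0)
        assert np.array_equal(segment_caps(img, 0.1), segment_caps(img, 0.1))


class TestMeasurement:
    def test_uniform_object_zero_sd(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[4:10, 4:10] = 1
        img = np.where(labels == 1, 40.0, 0.0)
        meas = measure_caps(labels, img, 1.0)
        assert meas["sd_int"][0] == 0.0
        assert meas["mean_int"][0] == 40.0

    def test_mean_and_sd_closed_form(self):
        # one row of N pixels with intensities 1..N
        n = 20
        labels = np.zeros((3, n + 2), dtype=int)
        labels[1, 1:n + 1] = 1
        img = np.zeros_like(labels, dtype=float)
        img[1, 1:n + 1] = np.arange(1, n + 1)
        meas = measure_caps(labels, img, 1.0)
        assert meas["mean_int"][0] == pytest.approx((n + 1) / 2, abs=1e-12)
        assert meas["sd_int"][0] == pytest.approx(np.sqrt((n ** 2 - 1) / 12), rel=1e-12)

    def test_brute_force_mean_sd_agreement(self, rng):
        img = rng.random((64, 64)) * 100
        labels = segment_caps(_disk_image((64, 64), (32, 32), 12, 500.0), 1.0)
        meas = measure_caps(labels, img, 1.0)
        vals = img[labels == 1]
        assert meas["mean_int"][0] == pytest.approx(vals.mean(), abs=1e-12)
        assert meas["sd_int"][0] == pytest.approx(vals.std(), abs=1e-12)

    def test_eccentricity_increases_with_stretch(self):
        yy, xx = np.mgrid[:80, :80]
        circle = ((yy - 40) ** 2 + (xx - 40) ** 2 <= 15 ** 2)
        ellipse = (((yy - 40) / 0.5) ** 2 + (xx - 40) ** 2 <= 15 ** 2)
        m_c = measure_caps(circle.astype(int), circle * 10.0, 1.0)
        m_e = measure_caps(ellipse.astype(int), ellipse * 10.0, 1.0)
        assert m_c["ecc"][0] < 0.2
        assert m_e["ecc"][0] > m_c["ecc"][0]

    def test_absent_label_raises(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:4, 2:4] = 1
        with pytest.raises(LookupError):
            measure_caps(labels, labels.astype(float), 1.0, ids=[3])


def _measurement_row(frame, cap_id, cy, cx):
    return {"frame": frame, "cap_id": cap_id, "area_um2": 10.0, "mean_int": 5.0,
            "sd_int": 1.0, "cy_um": cy, "cx_um": cx, "major_um": 4.0,
            "minor_um": 3.0, "ecc": 0.1, "touching": False}


class TestTracking:
    def test_single_drifting_cap_one_track(self):
        rows = [_measurement_row(f, 1, 10.0 + 0.1 * f, 10.0) for f in range(20)]
        tracks = link_tracks(pd.DataFrame(rows), max_displacement_um=1.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_gap_of_one_frame_bridged(self):
        rows = [_measurement_row(f, 1, 5.0, 5.0) for f in range(10) if f != 4]
        tracks = link_tracks(pd.DataFrame(rows), max_gap_frames=1)
        assert len(tracks) == 1
        assert tracks[0].n_gaps == 1

    def test_jump_beyond_limit_starts_new_track(self):
        rows = [_measurement_row(0, 1, 5.0, 5.0), _measurement_row(1, 1, 25.0, 25.0)]
        tracks = link_tracks(pd.DataFrame(rows), max_displacement_um=2.0)
        assert len(tracks) == 2

    def test_identities_preserved_on_default_movie(self, default_movie):
        cfg, stack, truth = default_movie
        meas = measure_movie(stack)
        tracks = link_tracks(meas)
        tt = truth.table
        correct = total = 0
        for tr in tracks:
            assigned = []
            for _, row in tr.data.iterrows():
                sub = tt[tt["frame"] == row["frame"]]
                d = np.hypot(sub["cy_um"] - row["cy_um"], sub["cx_um"] - row["cx_um"])
                assigned.append(int(sub["cap_id"].iloc[int(np.argmin(d.to_numpy()))]))
            modal = collections.Counter(assigned).most_common(1)[0][0]
            correct += sum(a == modal for a in assigned)
            total += len(assigned)
        assert total >= cfg.n_frames * cfg.n_caps * 0.95
        assert correct / total >= 0.99


class TestMovieAccuracy:
    def test_measured_areas_match_truth(self, default_movie):
        cfg, stack, truth = default_movie
        meas = measure_movie(stack)
        tt = truth.table
        errs = []
        for f in range(0, cfg.n_frames, 5):
            sub = meas[(meas["frame"] == f) & (~meas["touching"])]
            true_area = tt[tt["frame"] == f]["area_um2"].iloc[0]
            if true_area / cfg.pixel_size_um ** 2 < np.pi * 100:
                continue  # radius below 10 px
            for a in sub["area_um2"]:
                errs.append(abs(a - true_area) / true_area)
        assert errs and max(errs) <= 0.05
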