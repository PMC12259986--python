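"""ROI statistics, shape phases, MTSD, stationarisation, modulus."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from furrowmech import morphometrics as mm
from furrowmech import synthetic as syn


def disc_mask(radius, pad=3):
    n = 2 * (radius + pad) + 1
    yy, xx = np.ogrid[-radius - pad:radius + pad + 1,
                      -radius - pad:radius + pad + 1]
    return (xx ** 2 + yy ** 2) <= radius ** 2


def ellipse_mask(a, b, pad=3):
    yy, xx = np.ogrid[-b - pad:b + pad + 1, -a - pad:a + pad + 1]
    return (xx ** 2 / a ** 2 + yy ** 2 / b ** 2) <= 1.0


class TestRoiStats:
    def test_constant_map(self):
        s = mm.roi_stats(np.full((8, 8), 5.1), np.ones((8, 8), bool))
        assert s.mean == pytest.approx(5.1)
        assert s.median == pytest.approx(5.1)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_four_pixel_example(self):
        m = np.zeros((2, 2))
        m.flat = [1, 2, 3, 4]
        s = mm.roi_stats(m, np.ones((2, 2), bool))
        assert (s.mean, s.median, s.min, s.max) == (2.5, 2.5, 1.0, 4.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_sorted_computation(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(5.1, 0.05, (20, 20))
        mask = rng.random((20, 20)) < 0.4
        s = mm.roi_stats(vals, mask)
        picked = sorted(vals[r, c] for r, c in np.argwhere(mask))
        n = len(picked)
        med = (picked[n // 2] if n % 2 else
               0.5 * (picked[n // 2 - 1] + picked[n // 2]))
        assert s.median == pytest.approx(med)
        assert s.mean == pytest.approx(sum(picked) / n)
        assert s.min == pytest.approx(picked[0])
        assert s.max == pytest.approx(picked[-1])
        assert s.min <= s.median <= s.max

    def test_empty_roi_raises(self):
        with pytest.raises(mm.EmptyRoiError):
            mm.roi_stats(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestNormalizeToOnset:
    def test_onset_becomes_zero_and_arithmetic(self):
        out = mm.normalize_to_onset([5.10, 5.12, 5.09], 0)
        assert out[0] == 0.0
        assert out * 1000 == pytest.approx([0.0, 20.0, -10.0])  # MHz

    def test_constant_series_all_zero(self):
        assert np.all(mm.normalize_to_onset(np.full(7, 5.1), 3) == 0.0)


class TestTopFractionMask:
    def test_distinct_values_select_exact_count(self):
        frame = np.arange(100, dtype=float).reshape(10, 10)
        sel = mm.top_fraction_mask(frame, fraction=0.04)
        assert sel.sum() == 4
        assert set(frame[sel]) == {96.0, 97.0, 98.0, 99.0}

    def test_constant_map_keeps_all_ties(self):
        sel = mm.top_fraction_mask(np.full((6, 6), 2.0), fraction=0.04)
        assert sel.all()

    def test_threshold_frozen_at_reference_frame(self):
        stack = np.stack([np.arange(16.0).reshape(4, 4),
                          np.arange(16.0).reshape(4, 4) + 100.0])
        sel = mm.top_fraction_mask(stack, fraction=0.25, reference_frame=0)
        assert sel[0].sum() == 4
        assert sel[1].all()  # later frame entirely above the frozen threshold

    def test_hotspot_recovery_jaccard(self):
        stack, truth = syn.gen_shift_series(seed=3, contrast_ghz=0.025,
                                            noise_sd_ghz=0.00625)  # SNR 4
        sel = mm.top_fraction_mask(stack, fraction=truth.params["hotspot_area_fraction"],
                                   reference_frame=-1)
        got, want = sel[-1], truth.params["hotspot_mask"]
        jac = (got & want).sum() / (got | want).sum()
        assert jac >= 0.8


class TestShapeDescriptors:
    def test_disc_is_nearly_circular(self):
        d = mm.shape_descriptors(disc_mask(50))
        assert 0.95 <= d["circularity"] <= 1.04  # Crofton can overshoot
        assert d["major_axis"] / d["minor_axis"] <= 1.05

    def test_two_to_one_ellipse_matches_ramanujan(self):
        d = mm.shape_descriptors(ellipse_mask(100, 50))
        a, b = 2.0, 1.0  # Ramanujan perimeter of the continuous 2:1 ellipse
        p = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        expected = 4 * np.pi * (np.pi * a * b) / p ** 2
        assert d["circularity"] == pytest.approx(expected, abs=0.02)
        assert d["major_axis"] / d["minor_axis"] == pytest.approx(2.0, rel=0.02)

    def test_scaling_doubles_axes_keeps_circularity(self):
        small = mm.shape_descriptors(ellipse_mask(40, 20))
        big = mm.shape_descriptors(ellipse_mask(80, 40))
        assert big["major_axis"] == pytest.approx(2 * small["major_axis"], rel=0.02)
        assert big["minor_axis"] == pytest.approx(2 * small["minor_axis"], rel=0.02)
        assert big["circularity"] == pytest.approx(small["circularity"], rel=0.02)

    def test_pixel_size_converts_units(self):
        d1 = mm.shape_descriptors(disc_mask(30), pixel_size=1.0)
        d2 = mm.shape_descriptors(disc_mask(30), pixel_size=0.5)
        assert d2["major_axis"] == pytest.approx(0.5 * d1["major_axis"])
        assert d2["area"] == pytest.approx(0.25 * d1["area"])

    def test_tiny_mask_rejected(self):
        m = np.zeros((6, 6), bool)
        m[2, 2:5] = True
        with pytest.raises(mm.DegenerateShapeError):
            mm.shape_descriptors(m)


class TestTrackAxes:
    def test_recovers_planted_isotropy_without_noise(self):
        masks, truth = syn.gen_shape_track(seed=0, noise=0.0)
        track = mm.track_axes(mm.ShapeTrack.from_masks(masks))
        assert track.transition_index == truth.params["iso_frame"]

    def test_recovers_isotropy_with_noise_within_one_frame(self):
        masks, truth = syn.gen_shape_track(seed=1, noise=0.8)
        track = mm.track_axes(mm.ShapeTrack.from_masks(masks))
        assert abs(track.transition_index - truth.params["iso_frame"]) <= 1

    def test_axis_series_continuous_at_transition(self):
        masks, _ = syn.gen_shape_track(seed=0, noise=0.0, n_frames=30)
        track = mm.track_axes(mm.ShapeTrack.from_masks(masks))
        f = track.frame
        i = track.transition_index
        jump = abs(f["apical_basal_axis"].iloc[i] - f["apical_basal_axis"].iloc[i - 1])
        step = abs(f["major_axis"].iloc[i] - f["major_axis"].iloc[i - 1]) + \
            abs(f["minor_axis"].iloc[i] - f["minor_axis"].iloc[i - 1]) + 1.0
        assert jump <= step

    def test_phases_partition_the_track(self):
        masks, _ = syn.gen_shape_track(seed=0)
        track = mm.track_axes(mm.ShapeTrack.from_masks(masks))
        phases = track.frame["phase"].to_numpy()
        assert np.all(np.diff(phases) >= 0)  # exactly one 1 -> 2 switch
        assert set(phases) == {1, 2}

    def test_constant_circular_series_transitions_at_first_frame(self):
        masks = np.stack([disc_mask(20)] * 5)
        track = mm.track_axes(mm.ShapeTrack.from_masks(masks))
        assert track.transition_index == 0
        assert np.all(track.frame["phase"] == 2)


class TestSelectCellsByTransitionTime:
    def _tracks_with_times(self, times):
        out = []
        for i, t in enumerate(times):
            frame = pd.DataFrame({"t": np.arange(10), "circularity": 0.5,
                                  "major_axis": 10.0, "minor_axis": 5.0})
            frame.loc[t, "circularity"] = 0.9
            tr = mm.track_axes(mm.ShapeTrack(frame=frame, cell_id=i))
            out.append(tr)
        return out

    def test_nine_tracks_keep_seven(self):
        tracks = self._tracks_with_times(list(range(1, 10)))
        kept = mm.select_cells_by_transition_time(tracks)
        assert len(kept) == 7
        assert {t.cell_id for t in kept} == set(range(1, 8))

    def test_identical_times_keep_all(self):
        tracks = self._tracks_with_times([4] * 6)
        assert len(mm.select_cells_by_transition_time(tracks)) == 6

    def test_two_tracks_filter_inapplicable(self):
        tracks = self._tracks_with_times([1, 9])
        with pytest.warns(UserWarning):
            kept = mm.select_cells_by_transition_time(tracks)
        assert len(kept) == 2


class TestMtsd:
    def test_parallel_fibres(self):
        img, _ = syn.gen_orientation_image(seed=2, sd_deg=0.0, mean_deg=30.0)
        r = mm.mtsd(img)
        assert r.mtsd_deg <= 3.0
        assert abs(r.mean_direction_deg - 30.0) <= 2.0

    def test_two_line_families_give_45(self):
        img1, _ = syn.gen_orientation_image(seed=1, sd_deg=0.0, mean_deg=45.0,
                                            n_fibers=75)
        img2, _ = syn.gen_orientation_image(seed=2, sd_deg=0.0, mean_deg=135.0,
                                            n_fibers=75)
        r = mm.mtsd(img1 + img2)
        assert r.mtsd_deg == pytest.approx(45.0, abs=3.0)

    def test_uniform_orientations_near_52(self):
        vals = []
        for seed in range(3):
            img, _ = syn.gen_orientation_image(seed=seed, sd_deg=1e6,
                                               mean_deg=0.0, n_fibers=600,
                                               shape=(384, 384))
            vals.append(mm.mtsd(img).mtsd_deg)
        assert np.mean(vals) == pytest.approx(180.0 / np.sqrt(12.0), abs=3.0)

    def test_rotation_equivariance(self):
        img, _ = syn.gen_orientation_image(seed=4, sd_deg=8.0, mean_deg=20.0)
        r0 = mm.mtsd(img)
        rot = ndimage.rotate(img, 30.0, reshape=False, order=1)
        r1 = mm.mtsd(rot[48:-48, 48:-48])
        # rotating the image by +30 deg (counter-clockwise in standard
        # orientation) shifts the axial mean by +30
        shift = (r1.mean_direction_deg - r0.mean_direction_deg) % 180.0
        shift = min(shift, 180.0 - shift)
        assert shift == pytest.approx(30.0, abs=2.0)
        assert r1.mtsd_deg == pytest.approx(r0.mtsd_deg, abs=2.0)

    def test_blank_roi_raises(self):
        with pytest.raises(mm.UndefinedOrientationError):
            mm.mtsd(np.zeros((32, 32)))


class TestMakeStationary:
    def test_linear_trend_differences_to_constant(self):
        x = 2.0 + 0.3 * np.arange(50)
        dx, stat, flag = mm.make_stationary(x)
        assert np.allclose(dx, 0.3)
        assert stat == 0.0 and not flag

    def test_white_noise_rarely_flagged(self):
        flags = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=201)
            flags.append(mm.make_stationary(x)[2])
        assert np.mean(flags) <= 0.05

    def test_random_walk_flagged_without_differencing(self):
        flags = []
        for seed in range(100):
            w = np.cumsum(np.random.default_rng(seed).normal(size=200))
            flags.append(mm.make_stationary(w, difference=False)[2])
        assert np.mean(flags) >= 0.90

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            mm.make_stationary(np.arange(5))


class TestResidualCorrelation:
    def test_identical_series_give_rho_one(self):
        a, b, _ = syn.gen_paired_series(n=120, innovation_rho=1.0,
                                        trend_coeffs=((0.0,), (0.0,)), seed=0)
        r = mm.residual_correlation(np.diff(a), np.diff(b))
        assert r.spearman_rho == pytest.approx(1.0)

    def test_independent_white_noise_is_uncorrelated(self):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            r = mm.residual_correlation(rng.normal(size=200),
                                        rng.normal(size=200), max_order=1)
            hits += abs(r.spearman_rho) < 0.15
        assert hits >= n_seeds - 1

    def test_planted_correlation_recovered(self):
        rhos = []
        for seed in range(5):
            a, b, truth = syn.gen_paired_series(n=200, innovation_rho=0.43,
                                                seed=seed)
            da, _, _ = mm.make_stationary(a)
            db, _, _ = mm.make_stationary(b)
            rhos.append(mm.residual_correlation(da, db).spearman_rho)
        assert np.mean(rhos) == pytest.approx(
            truth.params["expected_spearman"], abs=0.1)

    def test_full_detrending_chain_reports_kpss(self):
        a, b, _ = syn.gen_paired_series(n=150, innovation_rho=0.5, seed=1)
        r = mm.detrended_association(a, b)
        assert r.kpss_stat_a is not None and r.kpss_stat_b is not None
        assert -1.0 <= r.spearman_rho <= 1.0


class TestShiftToModulus:
    def test_water_like_reference_point(self):
        # 5 GHz, 532 nm, n=1.33, rho=1000, backscattering -> v=1 km/s, M=1 GPa
        M = mm.shift_to_modulus(5e9, mm.ModulusParams())
        assert M == pytest.approx(1e9, rel=1e-6)

    def test_quadratic_in_shift(self):
        p = mm.ModulusParams()
        assert mm.shift_to_modulus(10e9, p) == pytest.approx(
            4 * mm.shift_to_modulus(5e9, p))

    def test_inverse_square_in_refractive_index(self):
        p1 = mm.ModulusParams(refractive_index=1.33)
        p2 = mm.ModulusParams(refractive_index=2.66)
        assert mm.shift_to_modulus(5e9, p2) == pytest.approx(
            mm.shift_to_modulus(5e9, p1) / 4)

    def test_monotone_in_density(self):
        p1 = mm.ModulusParams(density=1000.0)
        p2 = mm.ModulusParams(density=1100.0)
        assert mm.shift_to_modulus(5e9, p2) > mm.shift_to_modulus(5e9, p1)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            mm.ModulusParams(scattering_angle_deg=0.0)
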