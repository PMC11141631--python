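import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from nemaflow import synthgen as sg
from nemaflow import tracks as tk


def spot_frame(shape, positions_px, sigma_px=3.0):
    img = np.zeros(shape)
    rows, cols = np.indices(shape, dtype=float)
    for x, y in positions_px:
        img += np.exp(-((rows - y) ** 2 + (cols - x) ** 2) / (2 * sigma_px ** 2))
    return img


class TestDetectNuclei:
    def test_counts_and_centroids_on_ground_truth(self):
        rng = np.random.default_rng(0)
        spec = sg.SyntheticSpec(image_shape=(640, 640), pixel_size=1.3, seed=1,
                                n_frames=1, initial_cells=200,
                                carrying_capacity=5000.0, min_separation_um=20.0,
                                seed_margin_um=25.0)
        tr, stack = sg.gen_growth_tracks(spec)
        truth = tr[tr.frame == 0][["x_um", "y_um"]].to_numpy()
        det = tk.detect_nuclei(stack[0], pixel_size=1.3)
        assert abs(len(det) - 200) <= 2
        d, _ = cKDTree(det).query(truth)
        assert np.median(d) < 1.3   # sub-pixel centroids

    def test_blank_frame_no_detections(self):
        det = tk.detect_nuclei(np.zeros((128, 128)), pixel_size=1.0)
        assert len(det) == 0

    def test_size_gate_excludes_oversized_spot(self):
        big = spot_frame((256, 256), [(128, 128)], sigma_px=15.0)  # ~42 um at 1 um/px
        det = tk.detect_nuclei(big, pixel_size=1.0)
        assert len(det) == 0
        ok = spot_frame((256, 256), [(128, 128)], sigma_px=4.0)
        assert len(tk.detect_nuclei(ok, pixel_size=1.0)) == 1


class TestLinkTracks:
    def test_single_frame_singleton_tracks(self):
        pts = [np.array([[0.0, 0.0], [10.0, 10.0]])]
        out = tk.link_tracks(pts, max_disp=5.0)
        assert sorted(out.track_id) == [0, 1]

    def test_noncrossing_walkers_fully_linked(self):
        rng = np.random.default_rng(1)
        start = rng.uniform(50, 450, size=(40, 2))
        frames = [start + f * rng.uniform(-2, 2, size=(40, 2)) * 0 + f * 3.0
                  for f in range(6)]
        out = tk.link_tracks(frames, max_disp=10.0)
        assert out.track_id.nunique() == 40
        steps, _ = tk.migration_stats(out)
        assert len(steps) == 40 * 5

    def test_jump_beyond_gate_starts_new_track(self):
        pts = [np.array([[0.0, 0.0]]), np.array([[100.0, 0.0]])]
        out = tk.link_tracks(pts, max_disp=10.0)
        assert out.track_id.nunique() == 2

    def test_generator_positions_linked_above_98_percent(self):
        spec = sg.SyntheticSpec(image_shape=(512, 512), pixel_size=1.3, seed=2,
                                n_frames=10, initial_cells=120,
                                carrying_capacity=120 / ((512 * 1.3) ** 2 / 1e6),
                                growth_rate=0.001, speed=6.0, persistence=0.3,
                                seed_margin_um=30.0)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        frames = [tr[tr.frame == f][["x_um", "y_um"]].to_numpy()
                  for f in sorted(tr.frame.unique())]
        out = tk.link_tracks(frames, max_disp=20.0)
        steps, _ = tk.migration_stats(out)
        assert len(steps) >= 0.98 * 120 * 9


class TestCellDensity:
    def test_counts_over_area(self):
        pts = [np.zeros((400, 2)), np.zeros((410, 2))]
        ds = tk.cell_density(pts, field_area_mm2=0.1, frame_interval=2.0)
        assert ds.density[0] == pytest.approx(4000.0)
        assert ds.t_raw[1] == 2.0

    def test_empty_frame_zero_density(self):
        ds = tk.cell_density([np.empty((0, 2))], field_area_mm2=0.5)
        assert ds.density[0] == 0.0

    def test_matches_generator_curve(self):
        spec = sg.SyntheticSpec(image_shape=(256, 256), pixel_size=2.0, seed=5,
                                n_frames=40, initial_cells=50,
                                carrying_capacity=3000.0, growth_rate=0.25)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        area = tr.attrs["field_area_mm2"]
        counts = tr.groupby("frame").size()
        ds = tk.cell_density(
            [tr[tr.frame == f][["x_um", "y_um"]].to_numpy() for f in counts.index],
            field_area_mm2=area)
        assert np.allclose(ds.density, counts.to_numpy() / area)


class TestAlignTimeSeries:
    def test_offset_places_peak_at_36(self):
        t = np.arange(0, 100.0, 2.0)
        dens = 4000 * np.exp(-((t - 60.0) / 15.0) ** 2)
        out = tk.align_time_series(tk.DensitySeries(t, dens))
        assert out.offset == pytest.approx(-24.0)
        assert out.t_a[np.argmax(out.density)] == pytest.approx(36.0)

    def test_lagged_replicates_align(self):
        t = np.arange(0, 120.0, 3.0)
        base = 4000 / (1 + 50 * np.exp(-0.15 * t)) * np.exp(-((t - 70) / 40.0) ** 2)
        a = tk.align_time_series(tk.DensitySeries(t, base))
        b = tk.align_time_series(tk.DensitySeries(t, np.interp(t - 9.0, t, base)))
        pa = a.t_a[np.argmax(a.density)]
        pb = b.t_a[np.argmax(b.density)]
        assert abs(pa - pb) <= 3.0

    def test_flat_series_flagged_zero_offset(self):
        out = tk.align_time_series(tk.DensitySeries(np.arange(5.0), np.ones(5)))
        assert out.flagged and out.offset == 0.0

    def test_monotone_series_flagged(self):
        out = tk.align_time_series(tk.DensitySeries(np.arange(6.0), np.arange(6.0)))
        assert out.flagged


class TestMigrationStats:
    def test_straight_track_constant_speed_and_angle(self):
        df = pd.DataFrame({
            "track_id": 0, "frame": np.arange(5), "t_h": np.arange(5.0),
            "x_um": 10.0 * np.arange(5.0), "y_um": np.zeros(5),
        })
        steps, cells = tk.migration_stats(df)
        assert np.allclose(steps.speed_um_h, 10.0)
        assert np.allclose(steps.angle_deg, 0.0)
        assert cells.mean_speed_um_h.iloc[0] == pytest.approx(10.0)

    def test_zero_length_step_speed_zero_no_angle(self):
        df = pd.DataFrame({
            "track_id": 0, "frame": [0, 1], "t_h": [0.0, 1.0],
            "x_um": [5.0, 5.0], "y_um": [5.0, 5.0],
        })
        steps, _ = tk.migration_stats(df)
        assert steps.speed_um_h.iloc[0] == 0.0
        assert np.isnan(steps.angle_deg.iloc[0])

    def test_unbiased_walk_mean_speed_near_parameter(self):
        spec = sg.SyntheticSpec(image_shape=(512, 512), pixel_size=1.3, seed=6,
                                n_frames=15, initial_cells=100,
                                carrying_capacity=100 / ((512 * 1.3) ** 2 / 1e6) * 50,
                                growth_rate=0.001, speed=12.0, bias=0.0)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        steps, _ = tk.migration_stats(tr)
        # density far below capacity: slowdown negligible
        assert steps.speed_um_h.mean() == pytest.approx(12.0, rel=0.1)


class TestNormalizedDirectionalMigration:
    def test_uniform_directions_ratio_one(self):
        rng = np.random.default_rng(3)
        ratio = tk.normalized_directional_migration(rng.uniform(-180, 180, 200000))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_all_steps_at_5_degrees_saturates(self):
        assert tk.normalized_directional_migration(np.full(100, 5.0)) == 9.0

    def test_antiparallel_steps_count_toward_director_axis(self):
        # 175 deg folds to -5 deg: migration along the director axis in the
        # reverse direction still counts (axial fold, as in the 2/18 = 11.111%
        # normalization over 18 bins spanning 180 deg)
        assert tk.normalized_directional_migration(np.full(100, 175.0)) == 9.0

    def test_perpendicular_steps_ratio_zero(self):
        assert tk.normalized_directional_migration(np.full(100, 90.0)) == 0.0

    def test_equivariant_under_director_rotation(self):
        rng = np.random.default_rng(4)
        ang = rng.normal(30.0, 8.0, 5000)
        r30 = tk.normalized_directional_migration(ang, director=30.0)
        r0 = tk.normalized_directional_migration(ang - 30.0, director=0.0)
        assert r30 == pytest.approx(r0)

    def test_bias_strength_monotone_in_ratio(self):
        """Stronger directional bias gives larger normalized migration."""
        from scipy.stats import spearmanr
        biases = [0.0, 0.7, 1.5, 3.0, 6.0]
        ratios = []
        for b in biases:
            spec = sg.SyntheticSpec(image_shape=(256, 256), seed=8, n_frames=15,
                                    initial_cells=150, growth_rate=0.01,
                                    persistence=0.0, bias=b)
            tr, _ = sg.gen_growth_tracks(spec, render_images=False)
            steps, _ = tk.migration_stats(tr)
            ratios.append(tk.normalized_directional_migration(
                steps.angle_deg.to_numpy()))
        rho, _ = spearmanr(biases, ratios)
        assert rho > 0.9

    def test_series_per_time_point(self):
        steps = pd.DataFrame({"t_h": [0.0, 0.0, 1.0],
                              "angle_deg": [5.0, -5.0, 90.0]})
        out = tk.directional_migration_series(steps)
        assert out.normalized_migration.iloc[0] == 9.0
        assert out.normalized_migration.iloc[1] == 0.0


class TestDivisionAxis:
    def test_horizontal_pair_in_zero_bin(self):
        dist = tk.division_axis([[0.0, 0.0, 10.0, 0.0]])
        idx = np.argmax(dist.frequency)
        assert dist.bin_edges[idx] == -10.0  # the (-10, 10] bin

    def test_vertical_pair_folds_to_plus_90(self):
        dist = tk.division_axis([[0.0, 0.0, 0.0, 10.0]])
        idx = np.argmax(dist.frequency)
        assert dist.bin_edges[idx + 1] == 90.0  # the (70, 90] bin

    def test_uniform_axes_near_flat(self):
        rng = np.random.default_rng(5)
        ang = rng.uniform(0, np.pi, 100000)
        pairs = np.column_stack([np.zeros_like(ang), np.zeros_like(ang),
                                 np.cos(ang), np.sin(ang)])
        dist = tk.division_axis(pairs)
        assert np.all(np.abs(dist.frequency - 1.0 / 9.0) < 0.01)

    def test_coincident_pair_rejected(self):
        with pytest.raises(ValueError):
            tk.division_axis([[1.0, 1.0, 1.0, 1.0]])


class TestProfileVsDensity:
    def test_two_replicates_average_at_lattice_points(self):
        d1, v1 = np.array([100.0, 200.0]), np.array([10.0, 20.0])
        d2, v2 = np.array([100.0, 200.0]), np.array([30.0, 10.0])
        out = tk.profile_vs_density([(d1, v1), (d2, v2)], increment=50.0)
        at150 = out[out.density_per_mm2 == 150.0].value.iloc[0]
        assert at150 == pytest.approx((15.0 + 20.0) / 2.0)

    def test_replicate_only_contributes_inside_its_range(self):
        d1, v1 = np.array([0.0, 100.0]), np.array([1.0, 1.0])
        d2, v2 = np.array([50.0, 200.0]), np.array([3.0, 3.0])
        out = tk.profile_vs_density([(d1, v1), (d2, v2)], increment=50.0)
        assert out[out.density_per_mm2 == 0.0].n_replicates.iloc[0] == 1
        assert out[out.density_per_mm2 == 100.0].n_replicates.iloc[0] == 2


class TestTrackIO:
    def test_native_schema_roundtrip(self, tmp_path):
        df = pd.DataFrame({"track_id": [0, 0], "frame": [0, 1],
                           "t_h": [0.0, 0.5], "x_um": [1.0, 2.0],
                           "y_um": [3.0, 4.0]})
        p = tmp_path / "tracks.csv"
        df.to_csv(p, index=False)
        assert tk.read_track_csv(p).equals(df)

    def test_trackmate_style_schema(self, tmp_path):
        df = pd.DataFrame({"TRACK_ID": [1, 1], "FRAME": [0, 1],
                           "POSITION_X": [1.0, 2.0], "POSITION_Y": [3.0, 4.0]})
        p = tmp_path / "spots.csv"
        df.to_csv(p, index=False)
        out = tk.read_track_csv(p, frame_interval=0.5)
        assert list(out.columns) == tk.TRACK_COLUMNS
        assert out.t_h.iloc[1] == 0.5
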