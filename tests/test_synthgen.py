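import numpy as np
import pytest

from nemaflow import defects as dfx
from nemaflow import nemorder as no
from nemaflow import synthgen as sg
from nemaflow import tracks as tk


class TestUniformField:
    def test_all_angles_equal_and_perfect_order(self):
        f = sg.gen_uniform_field((16, 16), 30.0)
        assert np.all(f.theta == 30.0)
        assert np.all(f.coherency == 1.0)
        assert no.global_order(f) == pytest.approx(1.0)

    def test_zero_angle(self):
        f = sg.gen_uniform_field((16, 16), 0.0)
        assert np.all(f.theta == 0.0)

    def test_out_of_nematic_range_rejected(self):
        with pytest.raises(ValueError):
            sg.gen_uniform_field((16, 16), 90.0001)


class TestCorrelatedField:
    def test_deterministic_given_seed(self):
        a = sg.gen_correlated_field((32, 32), 4.0, seed=5)
        b = sg.gen_correlated_field((32, 32), 4.0, seed=5)
        assert np.array_equal(a.theta, b.theta)

    def test_angles_in_nematic_range(self):
        f = sg.gen_correlated_field((32, 32), 2.0, seed=1)
        assert np.all(f.theta > -90.0) and np.all(f.theta <= 90.0)

    def test_large_smoothing_approaches_uniform(self):
        f = sg.gen_correlated_field((32, 32), 40.0, seed=2)
        assert no.global_order(f) > 0.95

    def test_xi_increases_with_smoothing_scale(self):
        """Correlation length ordering across smoothing scales, paired seeds."""
        wins = 0
        for seed in range(12):
            xis = []
            for scale in (4.0, 8.0):
                f = sg.gen_correlated_field((40, 40), scale, seed=1000 + seed)
                curve = no.nematic_autocorrelation(f)
                xis.append(no.correlation_length(curve))
            wins += xis[1] > xis[0]
        assert wins >= 10

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            sg.gen_correlated_field((32, 32), -1.0, seed=0)


class TestDefectField:
    def test_single_plus_half_winding(self):
        f = sg.gen_defect_field((64, 64), [(31.5, 31.5, 0.5)])
        loop = dfx.square_loop((32, 32), 8)
        q, res = dfx.winding_number(f, loop)
        assert q == 0.5
        assert res < 1e-6

    def test_pair_charges_add_to_zero(self):
        f = sg.gen_defect_field((80, 80), [(25.5, 39.5, 0.5), (55.5, 39.5, -0.5)])
        assert dfx.boundary_winding(f) == 0.0

    def test_boundary_winding_equals_contained_charge(self):
        """Charge conservation on random defect configurations."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = rng.integers(1, 4)
            defs = []
            total = 0.0
            for _ in range(n):
                k = float(rng.choice([0.5, -0.5]))
                defs.append((float(rng.uniform(15, 65)) + 0.5,
                             float(rng.uniform(15, 65)) + 0.5, k))
                total += k
            f = sg.gen_defect_field((80, 80), defs)
            assert dfx.boundary_winding(f) == pytest.approx(total, abs=1e-6)

    def test_empty_list_gives_uniform(self):
        f = sg.gen_defect_field((32, 32), [], theta0=10.0)
        assert np.all(f.theta == 10.0)

    def test_coincident_cores_rejected(self):
        with pytest.raises(ValueError):
            sg.gen_defect_field((64, 64), [(10.5, 10.5, 0.5), (10.5, 10.5, -0.5)])

    def test_bad_charge_rejected(self):
        with pytest.raises(ValueError):
            sg.gen_defect_field((64, 64), [(10.5, 10.5, 1.0)])


class TestFilamentImage:
    def test_zero_density_blank(self):
        f = sg.gen_uniform_field((64, 64), 0.0)
        img = sg.gen_filament_image(f, filament_density=0.0, seed=0)
        assert np.all(img == 0.0)

    def test_deterministic(self):
        f = sg.gen_uniform_field((64, 64), 20.0)
        a = sg.gen_filament_image(f, seed=3)
        b = sg.gen_filament_image(f, seed=3)
        assert np.array_equal(a, b)

    def test_orientation_recovered_by_structure_tensor(self):
        from nemaflow import orientfield as of
        f = sg.gen_uniform_field((200, 200), 30.0)
        img = sg.gen_filament_image(f, filament_length=15, filament_density=0.03,
                                    seed=1)
        pm = of.structure_tensor(img, 1.5, 10.0)
        hist = of.orientation_histogram(pm, bin_width=2.0, min_coherency=0.25)
        assert abs(hist.mode_angle() - 30.0) <= 2.0


class TestDisplacedPair:
    def test_zero_flow_identical(self, speckle_image):
        a, b = sg.gen_displaced_pair(speckle_image, (0.0, 0.0))
        assert np.allclose(a, b, atol=1e-10)

    def test_constant_shift_moves_content(self, speckle_image):
        a, b = sg.gen_displaced_pair(speckle_image, (5.0, 0.0))
        # content moved +5 columns: b shifted back should match a
        assert np.allclose(np.roll(b, -5, axis=1), a, atol=1e-8)

    def test_flow_shape_mismatch_rejected(self, speckle_image):
        with pytest.raises(ValueError):
            sg.gen_displaced_pair(speckle_image, (np.zeros((4, 4)), np.zeros((4, 4))))


class TestGrowthTracks:
    def test_deterministic(self):
        spec = sg.SyntheticSpec(seed=9, n_frames=6, initial_cells=30)
        t1, s1 = sg.gen_growth_tracks(spec)
        t2, s2 = sg.gen_growth_tracks(spec)
        assert t1.equals(t2)
        assert np.array_equal(s1, s2)

    def test_logistic_plateau_at_capacity(self):
        spec = sg.SyntheticSpec(image_shape=(256, 256), pixel_size=2.0, seed=5,
                                n_frames=80, initial_cells=50,
                                carrying_capacity=4000.0, growth_rate=0.2,
                                speed=10.0)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        area = tr.attrs["field_area_mm2"]
        final = tr[tr.frame >= spec.n_frames - 5].groupby("frame").size().mean() / area
        assert final == pytest.approx(4000.0, rel=0.05)

    def test_saturating_bias_steps_exactly_along_director(self):
        spec = sg.SyntheticSpec(seed=4, n_frames=10, initial_cells=50,
                                growth_rate=0.01, bias=np.inf)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        steps, _ = tk.migration_stats(tr)
        ratio = tk.normalized_directional_migration(steps["angle_deg"].to_numpy())
        assert ratio == 9.0

    def test_positions_inside_field(self):
        spec = sg.SyntheticSpec(seed=2, n_frames=15, initial_cells=40, speed=30.0)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        w_um = spec.image_shape[1] * spec.pixel_size
        h_um = spec.image_shape[0] * spec.pixel_size
        assert tr.x_um.between(0, w_um).all()
        assert tr.y_um.between(0, h_um).all()

    def test_blue_noise_seeding_respects_separation(self):
        from scipy.spatial import cKDTree
        spec = sg.SyntheticSpec(image_shape=(512, 512), seed=3, n_frames=1,
                                initial_cells=100, min_separation_um=20.0)
        tr, _ = sg.gen_growth_tracks(spec, render_images=False)
        pts = tr[tr.frame == 0][["x_um", "y_um"]].to_numpy()
        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() >= 20.0

    def test_spec_json_roundtrip(self, tmp_path):
        spec = sg.SyntheticSpec(seed=7, bias=np.inf)
        p = tmp_path / "spec.json"
        spec.to_json(p)
        back = sg.SyntheticSpec.from_json(p)
        assert back == spec

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sg.SyntheticSpec(pixel_size=0.0)
        with pytest.raises(ValueError):
            sg.SyntheticSpec(image_shape=(32, 128))
        with pytest.raises(ValueError):
            sg.SyntheticSpec(persistence=1.0)
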