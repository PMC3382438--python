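"""blob-ELLR folding, expansion, application — all against the dense oracle."""

import numpy as np
import pytest

import blobtomo as bt


class TestRayOffsets:
    @pytest.mark.parametrize("rf,expected", [
        (3.25, (3, 0.75)),
        (-1.75, (-2, 0.75)),   # floor convention keeps w1 well-defined below zero
        (5.0, (5, 1.0)),       # integer hit
    ])
    def test_split_ray_offset(self, rf, expected):
        base, w1 = bt.split_ray_offset(rf)
        assert (base, w1) == pytest.approx(expected)

    def test_integer_hit_window(self):
        base, _ = bt.split_ray_offset(5.0)
        assert list(range(base - 1, base + 3)) == [4, 5, 6, 7]

    def test_projected_offset_at_zero_angle(self, paired_geom):
        # pixel x=1.25 at theta=0 lands at index origin+1.25 = 16.75
        base, w1 = bt.projected_offset(1.25, 0.7, 0.0, paired_geom)
        assert base == 16
        assert w1 == pytest.approx(0.25)

    @pytest.mark.parametrize("w1,expected", [
        (0.75, (1.75, 0.25, 1.25)),
        (1.0, (2.0, 0.0, 1.0)),    # distance 2 sits at the blob edge: F(2) = 0
        (0.5, (1.5, 0.5, 1.5)),
    ])
    def test_neighbor_distances(self, w1, expected):
        assert bt.neighbor_distances(w1) == pytest.approx(expected)

    @pytest.mark.parametrize("w1", [0.0, -0.2, 1.2])
    def test_neighbor_distances_rejects_out_of_range(self, w1):
        with pytest.raises(ValueError):
            bt.neighbor_distances(w1)


class TestBuildShapes:
    def test_level0_is_4B_by_N(self, params):
        geom = bt.make_geometry([-30.0, 30.0], 16)
        grid = bt.PixelGrid(4, 4)
        ellr = bt.build(geom, grid, params, symmetry_level=0)
        assert ellr.A.shape == (8, 16)
        assert ellr.I.shape == (8, 16)

    def test_stored_offsets_in_unit_interval(self, ellr16):
        assert np.all(ellr16.A > 0.0)
        assert np.all(ellr16.A <= 1.0)

    def test_level3_requires_paired_angles(self, params):
        geom = bt.make_geometry([-30.0, 0.0, 20.0], 16)
        grid = bt.PixelGrid(4, 4)
        with pytest.warns(UserWarning, match="degrading"):
            ellr = bt.build(geom, grid, params, symmetry_level=3)
        assert ellr.symmetry_level == 2
        with pytest.raises(ValueError, match="symmetric"):
            bt.build(geom, grid, params, symmetry_level=3, on_downgrade="error")

    def test_invalid_level(self, paired_geom, grid16, params):
        with pytest.raises(ValueError):
            bt.build(paired_geom, grid16, params, symmetry_level=4)


class TestStorageFolding:
    def test_successive_level_ratios_exact(self, paired_geom, grid32, params):
        entries = [bt.build(paired_geom, grid32, params, symmetry_level=lvl).A.size
                   for lvl in range(4)]
        assert entries[1] / entries[0] == 0.25         # fold the 4-ray window
        assert entries[2] / entries[1] == 0.5          # fold pixel pairs (even N)
        assert entries[3] / entries[2] == 0.5          # fold view pairs (no 0 view)
        assert entries[3] / entries[0] == 1.0 / 16.0

    def test_storage_stats_accounting(self, ellr16):
        stats = ellr16.storage_stats()
        assert stats.stored_entries == ellr16.A.size
        assert stats.nbytes == 8 * stats.stored_entries
        assert stats.ratio_vs_unsym == stats.stored_entries / (4 * 8 * 256)

    def test_forecast_matches_built_instance(self, paired_geom, grid16, params):
        for lvl in range(4):
            built = bt.build(paired_geom, grid16, params, symmetry_level=lvl)
            forecast = bt.storage_forecast(paired_geom.n_views, grid16.n_pixels, lvl)
            assert forecast.stored_entries == built.A.size

    def test_odd_counts_store_selfpaired_center_explicitly(self, params):
        # 0-degree view and odd grid pair with themselves: ceil shapes, ratios
        # land near (not exactly at) 1/16 -- the "nearly"
        geom = bt.make_geometry(np.arange(-60.0, 61.0, 15.0), 32)  # 9 views, has 0
        grid = bt.PixelGrid(5, 5)
        ellr = bt.build(geom, grid, params, symmetry_level=3)
        assert ellr.A.shape == (5, 13)
        ratio = ellr.storage_stats().ratio_vs_unsym
        assert ratio > 1.0 / 16.0
        assert ratio == pytest.approx(1.0 / 16.0, rel=0.3)
        np.testing.assert_allclose(ellr.materialize(),
                                   bt.dense_oracle(geom, grid, params),
                                   rtol=0, atol=1e-10)

    def test_production_plane_baseline_under_3p5_gb(self):
        # unfolded weights of a 2048x430 slice plane, 119 views
        stats = bt.storage_forecast(119, 2048 * 430, symmetry_level=0)
        assert stats.nbytes <= 3.5e9


@pytest.mark.parametrize("level", [0, 1, 2, 3])
class TestOracleEquality:
    def test_expansion_equals_dense_oracle_16(self, paired_geom, grid16, params,
                                              dense_w, level):
        ellr = bt.build(paired_geom, grid16, params, symmetry_level=level)
        np.testing.assert_allclose(ellr.materialize(), dense_w, rtol=0, atol=1e-10)

    def test_expansion_equals_dense_oracle_32(self, paired_geom, grid32, params, level):
        dense = bt.dense_oracle(paired_geom, grid32, params)
        ellr = bt.build(paired_geom, grid32, params, symmetry_level=level)
        np.testing.assert_allclose(ellr.materialize(), dense, rtol=0, atol=1e-10)

    def test_forward_matches_dense_product(self, paired_geom, grid16, params,
                                           dense_w, level):
        ellr = bt.build(paired_geom, grid16, params, symmetry_level=level)
        rng = np.random.default_rng(3)
        x = rng.normal(size=grid16.n_pixels)
        ref = dense_w @ x
        np.testing.assert_allclose(ellr.apply_forward(x), ref,
                                   atol=1e-10 * np.abs(ref).max())

    def test_transpose_matches_dense_product(self, paired_geom, grid16, params,
                                             dense_w, level):
        ellr = bt.build(paired_geom, grid16, params, symmetry_level=level)
        rng = np.random.default_rng(4)
        r = rng.normal(size=paired_geom.n_values)
        ref = dense_w.T @ r
        np.testing.assert_allclose(ellr.apply_transpose(r), ref,
                                   atol=1e-10 * np.abs(ref).max())


class TestOperatorProperties:
    def test_zero_maps_to_zero(self, ellr16):
        assert not ellr16.apply_forward(np.zeros(256)).any()
        assert not ellr16.apply_transpose(np.zeros(8 * 32)).any()

    def test_center_pixel_projects_around_detector_center(self, params, table):
        # unit pixel at the grid center: per view, 4 footprint values at the
        # rays around detector coordinate 0
        geom = bt.make_geometry([-30.0, 30.0], 16)
        grid = bt.PixelGrid(5, 5)   # odd: true center pixel exists
        ellr = bt.build(geom, grid, params, symmetry_level=1)
        x = np.zeros(25)
        x[12] = 1.0
        p = ellr.apply_forward(x).reshape(2, 16)
        origin = geom.detector_origin  # 7.5
        for v in range(2):
            expected = np.zeros(16)
            for ray in (6, 7, 8, 9):
                expected[ray] = table(abs(origin - ray))
            np.testing.assert_allclose(p[v], expected, atol=1e-12)

    def test_adjoint_identity(self, ellr16):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(size=256)
            r = rng.normal(size=8 * 32)
            lhs = ellr16.apply_forward(x) @ r
            rhs = x @ ellr16.apply_transpose(r)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_weight_sums_are_operator_sums(self, ellr16, dense_w):
        col, row = ellr16.weight_sums()
        np.testing.assert_allclose(col, dense_w.sum(axis=0), atol=1e-10)
        np.testing.assert_allclose(row, dense_w.sum(axis=1), atol=1e-10)
        np.testing.assert_allclose(col, ellr16.apply_transpose(np.ones(8 * 32)))
        np.testing.assert_allclose(row, ellr16.apply_forward(np.ones(256)))

    def test_size_mismatch_raises(self, ellr16):
        with pytest.raises(ValueError):
            ellr16.apply_forward(np.zeros(10))
        with pytest.raises(ValueError):
            ellr16.apply_transpose(np.zeros(10))

    def test_expand_pixel_view_symmetries(self, ellr16, dense_w):
        geom, grid = ellr16.geom, ellr16.grid
        S, N = geom.n_rays, grid.n_pixels
        rng = np.random.default_rng(5)
        for j in rng.integers(0, N, 12):
            for v in rng.integers(0, geom.n_views, 3):
                pairs = ellr16.expand_pixel_view(int(j), int(v))
                assert len(pairs) <= 4
                col = dense_w[v * S:(v + 1) * S, j]
                for ray, w in pairs:
                    assert w == pytest.approx(col[ray], abs=1e-10)
                # point reflection: mirrored pixel, same view -> rays mirror
                # about the detector center, identical weights
                mirrored = ellr16.expand_pixel_view(N - 1 - int(j), int(v))
                assert len(mirrored) == len(pairs)
                for (ray, w), (mray, mw) in zip(pairs, reversed(mirrored)):
                    assert mray == (S - 1) - ray
                    assert mw == pytest.approx(w, abs=1e-10)

    def test_tilt_mirror_shares_coefficients(self, ellr16):
        # pixel (-x, z) at angle -theta vs pixel (x, z) at theta
        geom, grid = ellr16.geom, ellr16.grid
        S, B = geom.n_rays, geom.n_views
        perm = grid.mirror_x_perm
        for j in (0, 37, 100, 255):
            for v in (0, 2):
                pairs = ellr16.expand_pixel_view(j, v)
                flipped = ellr16.expand_pixel_view(int(perm[j]), B - 1 - v)
                assert len(flipped) == len(pairs)
                for (ray, w), (fray, fw) in zip(pairs, reversed(flipped)):
                    assert fray == (S - 1) - ray
                    assert fw == pytest.approx(w, abs=1e-10)

    def test_index_out_of_range(self, ellr16):
        with pytest.raises(IndexError):
            ellr16.expand_pixel_view(256, 0)
        with pytest.raises(IndexError):
            ellr16.expand_pixel_view(0, 8)


class TestDenseOracle:
    def test_at_most_four_rays_per_pixel_per_view(self, paired_geom, grid16, dense_w):
        S = paired_geom.n_rays
        for v in range(paired_geom.n_views):
            block = dense_w[v * S:(v + 1) * S]
            assert int((block > 0).sum(axis=0).max()) <= 4

    def test_entries_nonnegative(self, dense_w):
        assert np.all(dense_w >= 0.0)

    def test_size_guard(self, params):
        geom = bt.make_geometry(np.arange(-60.0, 61.0, 1.0), 2048)
        with pytest.raises(ValueError, match="capped"):
            bt.dense_oracle(geom, bt.PixelGrid(2048, 2048), params)


class TestOffDetectorHandling:
    def test_adjoint_exact_with_dropped_rays(self, params):
        # grid diagonal far exceeds the detector: many windows fall off the
        # edge; forward/transpose must stay an exact adjoint pair regardless
        geom = bt.make_geometry([-60.0, -20.0, 20.0, 60.0], 8)
        grid = bt.PixelGrid(16, 16)
        ellr = bt.build(geom, grid, params, symmetry_level=3)
        dense = bt.dense_oracle(geom, grid, params)
        np.testing.assert_allclose(ellr.materialize(), dense, rtol=0, atol=1e-10)
        rng = np.random.default_rng(2)
        x, r = rng.normal(size=256), rng.normal(size=32)
        assert ellr.apply_forward(x) @ r == pytest.approx(
            x @ ellr.apply_transpose(r), rel=1e-10)


class TestSerialization:
    def test_hdf5_round_trip(self, ellr16, tmp_path):
        path = tmp_path / "weights.h5"
        bt.save_blob_ellr(path, ellr16)
        loaded = bt.load_blob_ellr(path)
        assert loaded.symmetry_level == ellr16.symmetry_level
        np.testing.assert_array_equal(loaded.A, ellr16.A)
        np.testing.assert_array_equal(loaded.I, ellr16.I)
        np.testing.assert_array_equal(loaded.materialize(), ellr16.materialize())
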