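"""Slab decomposition, axial blob coupling, and the parallel exchange scheme."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blobtomo as bt

# mpmath, dps=30: normalized axial coupling weights at the default blob
G0_REF = 0.55604940029378519772
G1_REF = 0.22197529985310740114


def small_volume_world(n_slices=8, n=32):
    geom = bt.make_geometry([-60.0, -45.0, -30.0, -15.0, 15.0, 30.0, 45.0, 60.0], n)
    grid = bt.PixelGrid(n, n)
    spec = bt.PhantomSpec(dims=(n_slices, n, n),
                          objects=[bt.Shell((0.0, 0.0, 0.0), 3.2, 1.5, 1.0),
                                   bt.Sphere((0.0, 6.0, -6.0), 2.0, 1.0)])
    vol = bt.make_phantom(spec)
    series = bt.simulate_tilt_series(vol, geom)
    return geom, grid, vol, series


class TestDecompose:
    def test_halved_volume_one_redundant_slice_each(self):
        slabs = bt.decompose_slabs(190, 2, blob_a=2.0)
        assert [len(s.own) for s in slabs] == [95, 95]
        assert slabs[0].halos == (95,)
        assert slabs[1].halos == (94,)

    def test_single_worker_no_halos(self):
        (slab,) = bt.decompose_slabs(12, 1, blob_a=2.0)
        assert slab.own == range(0, 12)
        assert slab.halos == ()

    def test_balance_and_middle_halos(self):
        slabs = bt.decompose_slabs(10, 3, blob_a=2.0)
        assert [len(s.own) for s in slabs] == [4, 3, 3]
        assert len(slabs[1].halos) == 2

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(n=st.integers(1, 200), w=st.integers(1, 16))
    def test_own_ranges_partition_all_slices(self, n, w):
        if w > n:
            with pytest.raises(ValueError):
                bt.decompose_slabs(n, w)
            return
        slabs = bt.decompose_slabs(n, w)
        owned = [y for s in slabs for y in s.own]
        assert owned == list(range(n))
        sizes = [len(s.own) for s in slabs]
        assert max(sizes) - min(sizes) <= 1

    @pytest.mark.parametrize("a,width", [(2.0, 1), (1.5, 1), (1.0, 0), (0.5, 0)])
    def test_halo_width_from_blob_radius(self, a, width):
        assert bt.halo_width(a) == width

    def test_zero_width_halo_means_no_halos(self):
        slabs = bt.decompose_slabs(10, 2, blob_a=1.0)
        assert all(s.halos == () for s in slabs)


class TestAxialWeights:
    def test_normalization_and_symmetry(self, params, table):
        g = bt.axial_weights(params, table)
        assert g[0] + 2 * g[1] == pytest.approx(1.0, abs=1e-14)
        assert g[-1] == g[1]
        assert set(g) == {-1, 0, 1}

    def test_matches_independent_quadrature(self, params):
        g = bt.axial_weights(params)
        assert g[0] == pytest.approx(G0_REF, abs=1e-9)
        assert g[1] == pytest.approx(G1_REF, abs=1e-9)

    def test_wide_blob_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            bt.axial_weights(bt.BlobParams(a=3.0))

    def test_coupling_vanishes_at_blob_edge(self, table):
        assert table(2.0) == 0.0


class TestExchangeContract:
    def test_payload_shapes(self, paired_geom, grid16):
        rep = bt.exchange_contract("reprojection", paired_geom, grid16)
        assert rep.per_slice_shape == (8, 32)
        back = bt.exchange_contract("backprojection", paired_geom, grid16)
        assert back.per_slice_shape == (256,)
        assert rep.exchanges_per_iteration + back.exchanges_per_iteration == 2

    def test_unknown_phase(self):
        with pytest.raises(ValueError):
            bt.exchange_contract("initialization")


@pytest.fixture(scope="module")
def world():
    return small_volume_world()


class TestReconstructVolume:
    def run(self, world, n_workers, mode, n_iters=4, trace=False):
        geom, grid, _, series = world
        job = bt.VolumeJob(series, geom, grid, sirt=bt.SirtConfig(n_iters=n_iters),
                           n_workers=n_workers, exchange_mode=mode)
        return bt.reconstruct_volume(job, collect_trace=trace)

    def test_worker_count_invariance(self, world):
        ref = self.run(world, 1, "sync").volume
        for nw in (2, 4):
            vol = self.run(world, nw, "sync").volume
            scale = np.abs(ref).max()
            assert np.abs(vol - ref).max() <= 1e-5 * scale

    def test_sync_equals_async_exactly(self, world):
        for nw in (1, 2, 4):
            sync = self.run(world, nw, "sync").volume
            asyn = self.run(world, nw, "async").volume
            np.testing.assert_array_equal(sync, asyn)

    def test_two_exchanges_per_iteration_per_boundary(self, world):
        n_iters = 4
        for nw in (2, 4):
            res = self.run(world, nw, "sync", n_iters=n_iters)
            boundaries = nw - 1
            # each phase ships one payload to each side of each boundary
            assert res.exchange_events["reprojection"] == n_iters * 2 * boundaries
            assert res.exchange_events["backprojection"] == n_iters * 2 * boundaries
            assert set(res.exchange_events) == {"reprojection", "backprojection"}

    def test_halo_copies_match_owner_exactly(self, world):
        res = self.run(world, 2, "async", n_iters=3, trace=True)
        assert res.trace
        for rec in res.trace:
            np.testing.assert_array_equal(rec.payload, rec.owner_value)

    def test_async_schedules_boundary_slices_first(self, world):
        res = self.run(world, 2, "async", n_iters=1)
        first_slab, second_slab = res.slabs
        assert res.stage_order[0][0] == first_slab.stop - 1
        assert res.stage_order[1][0] == second_slab.start

    def test_single_slice_volume_reduces_to_2d_sirt(self, params):
        geom, grid, _, series = small_volume_world(n_slices=1, n=16)
        cfg = bt.SirtConfig(n_iters=5)
        job = bt.VolumeJob(series, geom, grid, sirt=cfg, n_workers=1)
        vol = bt.reconstruct_volume(job).volume
        ellr = bt.build(geom, grid, params, symmetry_level=3)
        state = bt.run_sirt(ellr, series[:, 0, :].ravel(), cfg)
        np.testing.assert_array_equal(vol[0].ravel(), state.x)

    def test_job_validation(self, world):
        geom, grid, _, series = world
        with pytest.raises(ValueError, match="n_workers"):
            bt.VolumeJob(series, geom, grid, n_workers=9)
        with pytest.raises(ValueError, match="exchange"):
            bt.VolumeJob(series, geom, grid, exchange_mode="mpi")
        with pytest.raises(ValueError, match="shape"):
            bt.VolumeJob(series[:, :, :-1], geom, grid)
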