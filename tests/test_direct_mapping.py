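"""Direct (patient-tractogram) disconnection mapping tests."""

import numpy as np
import pytest

import disconn as dc
from disconn.core_geometry import ROLE_T, ROLE_T_PLUS_O, Tractogram
from disconn.direct_mapping import (
    compute_direct_sd,
    density_map,
    population_average_density,
    select_intersecting,
    symmetrize,
    threshold_dsd,
)

from conftest import vmap


def straight_bundle(grid, x_mm, n=50, spread=0.0, rng=None):
    """Bundle running along +y at lateral position x_mm."""
    spec = dc.BundleSpec(start=(x_mm, -40.0, 0.0), end=(x_mm, 40.0, 0.0),
                         n_streamlines=n, spread_mm=spread, n_points=40)
    return dc.make_bundle(spec, grid, rng or np.random.default_rng(0))


def ball_lesion(grid, center_mm, radius_mm, role=ROLE_T_PLUS_O, side="left"):
    idx = np.indices(grid.dims, dtype=float).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    vox = (np.linalg.norm(world - np.asarray(center_mm), axis=1)
           <= radius_mm).reshape(grid.dims)
    return dc.LesionMask(vox, grid, role, side)


class TestSelection:
    def test_empty_lesion_selects_nothing(self, grid_default):
        t = straight_bundle(grid_default, -20.0)
        empty = dc.LesionMask(np.zeros(grid_default.dims, bool), grid_default,
                              ROLE_T, "left")
        assert len(select_intersecting(t, empty)) == 0

    def test_full_grid_lesion_selects_all(self, grid_default):
        t = straight_bundle(grid_default, -20.0, n=17)
        full = dc.LesionMask(np.ones(grid_default.dims, bool), grid_default,
                             ROLE_T, "left")
        assert len(select_intersecting(t, full)) == 17

    def test_only_the_crossing_bundle_is_selected(self, grid_default):
        rng = np.random.default_rng(5)
        a = straight_bundle(grid_default, -20.0, n=30, spread=1.0, rng=rng)
        b = straight_bundle(grid_default, 30.0, n=25, spread=1.0, rng=rng)
        merged = Tractogram(a.streamlines + b.streamlines, grid_default)
        lesion = ball_lesion(grid_default, (-20.0, 0.0, 0.0), 8.0)
        sel = select_intersecting(merged, lesion)
        assert len(sel) == 30
        for s, orig in zip(sel, a):
            assert np.array_equal(s, orig)   # order preserved

    def test_grid_mismatch_rejected(self, grid_default, grid16):
        t = straight_bundle(grid_default, -20.0)
        lesion = dc.LesionMask(np.zeros(grid16.dims, bool), grid16, ROLE_T, "left")
        with pytest.raises(dc.GridMismatchError):
            select_intersecting(t, lesion)


class TestDensityMap:
    def test_empty_tractogram_gives_zero_map(self, grid16):
        d = density_map(Tractogram([], grid16))
        assert np.all(d.values == 0)

    def test_single_streamline_gives_indicator(self, grid16):
        rng = np.random.default_rng(7)
        s = rng.uniform(-14, 14, size=(6, 3))
        d = density_map(Tractogram([s], grid16))
        visited = dc.voxels_visited(s, grid16)
        assert d.values.sum() == len(visited)
        for v in visited:
            assert d.values[v] == 1

    def test_mass_conservation_against_per_streamline_counts(self, grid16):
        rng = np.random.default_rng(8)
        sls = [rng.uniform(-18, 18, size=(rng.integers(2, 7), 3))
               for _ in range(40)]
        t = Tractogram(sls, grid16)
        d = density_map(t)
        brute = sum(len(dc.voxels_visited(s, grid16)) for s in sls)
        assert d.values.sum() == brute


class TestPopulationAverage:
    def test_single_subject_no_lesion_is_identity(self, grid16):
        rng = np.random.default_rng(9)
        d = vmap(rng.integers(0, 9, size=grid16.dims), grid16)
        empty = dc.LesionMask(np.zeros(grid16.dims, bool), grid16, ROLE_T, "left")
        avg = population_average_density([d], [empty])
        assert np.array_equal(avg.values, d.values)

    def test_per_voxel_mean_and_lesion_exclusion(self, grid16):
        d1 = vmap(np.full(grid16.dims, 2.0), grid16)
        d2 = vmap(np.full(grid16.dims, 4.0), grid16)
        les1 = np.zeros(grid16.dims, bool)
        les1[3, 3, 3] = True     # subject 1 lesioned at v
        m1 = dc.LesionMask(les1, grid16, ROLE_T, "left")
        m0 = dc.LesionMask(np.zeros(grid16.dims, bool), grid16, ROLE_T, "left")
        avg = population_average_density([d1, d2], [m1, m0])
        assert avg.values[0, 0, 0] == 3.0             # mean of contributors
        assert avg.values[3, 3, 3] == 4.0             # subject 2 only

    def test_voxel_lesioned_everywhere_is_zero_flagged(self, grid16):
        d = vmap(np.full(grid16.dims, 5.0), grid16)
        les = np.zeros(grid16.dims, bool)
        les[1, 1, 1] = True
        m = dc.LesionMask(les, grid16, ROLE_T, "left")
        avg, coverage = population_average_density([d], [m], return_coverage=True)
        assert avg.values[1, 1, 1] == 0.0
        assert coverage[1, 1, 1] == 0

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            population_average_density([], [])


class TestSymmetrize:
    def test_symmetric_input_unchanged(self, grid16):
        rng = np.random.default_rng(10)
        half = rng.uniform(size=(8, 16, 16))
        full = np.concatenate([half, half[::-1]], axis=0)
        m = vmap(full, grid16)
        assert np.allclose(symmetrize(m).values, full)

    def test_single_voxel_splits_with_its_mirror(self, grid16):
        v = np.zeros(grid16.dims)
        v[2, 5, 5] = 8.0
        out = symmetrize(vmap(v, grid16))
        assert out.values[2, 5, 5] == 4.0
        assert out.values[13, 5, 5] == 4.0

    def test_idempotent_mass_preserving_and_mirror_symmetric(self, grid16):
        rng = np.random.default_rng(11)
        m = vmap(rng.uniform(size=grid16.dims), grid16)
        once = symmetrize(m)
        assert np.allclose(symmetrize(once).values, once.values, atol=1e-12)
        assert once.values.sum() == pytest.approx(m.values.sum())
        assert np.allclose(once.values, once.values[::-1], atol=1e-12)

    def test_asymmetric_midplane_rejected(self):
        g = dc.VoxelGrid((16, 16, 16), np.diag([2.0, 2.0, 2.0, 1.0]),
                         midplane=5.0)
        with pytest.raises(ValueError):
            symmetrize(vmap(np.ones(g.dims), g))


class TestThreshold:
    def test_forced_arithmetic(self, grid16):
        dsd = np.zeros(grid16.dims)
        avg = np.full(grid16.dims, 100.0)
        dsd[0, 0, 0] = 5.0    # 5% of 100: not significant at 10%
        dsd[1, 0, 0] = 11.0   # 11%: significant
        sig = threshold_dsd(vmap(dsd, grid16, "sd_direct"), vmap(avg, grid16), 0.10)
        assert sig.values[0, 0, 0] == 0
        assert sig.values[1, 0, 0] == 1

    def test_zero_denominator_rule(self, grid16):
        dsd = np.zeros(grid16.dims)
        dsd[2, 2, 2] = 3.0
        avg = np.zeros(grid16.dims)
        sig = threshold_dsd(vmap(dsd, grid16, "sd_direct"), vmap(avg, grid16), 0.10)
        assert sig.values[2, 2, 2] == 1     # evidence where norm is null
        assert sig.values[0, 0, 0] == 0     # 0/0 is not significant

    def test_all_zero_dsd_gives_empty_mask(self, grid16):
        sig = threshold_dsd(vmap(np.zeros(grid16.dims), grid16, "sd_direct"),
                            vmap(np.ones(grid16.dims), grid16), 0.10)
        assert np.all(sig.values == 0)

    @pytest.mark.parametrize("t", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_threshold_rejected(self, grid16, t):
        m = vmap(np.zeros(grid16.dims), grid16, "sd_direct")
        with pytest.raises(ValueError):
            threshold_dsd(m, vmap(np.ones(grid16.dims), grid16), t)


class TestComputeDirectSD:
    def test_empty_lesion_gives_empty_result(self, grid_default):
        t = straight_bundle(grid_default, -20.0, n=20, spread=1.0)
        empty = dc.LesionMask(np.zeros(grid_default.dims, bool), grid_default,
                              ROLE_T, "left")
        avg = vmap(np.ones(grid_default.dims), grid_default)
        res = compute_direct_sd(t, empty, avg)
        assert res.selected_count == 0
        assert np.all(res.dsd.values == 0)
        assert np.all(res.significant.values == 0)

    def test_nested_lesions_give_voxelwise_dominated_maps(self, grid_default):
        rng = np.random.default_rng(12)
        t = straight_bundle(grid_default, -20.0, n=80, spread=3.0, rng=rng)
        lt = ball_lesion(grid_default, (-20.0, 0.0, 0.0), 6.0, ROLE_T)
        lto = ball_lesion(grid_default, (-20.0, 0.0, 0.0), 12.0, ROLE_T_PLUS_O)
        avg = density_map(t)
        rt = compute_direct_sd(t, lt, avg)
        rto = compute_direct_sd(t, lto, avg)
        assert np.all(rt.dsd.values <= rto.dsd.values)
        assert rt.selected_count <= rto.selected_count
        assert rt.significant.values.sum() <= rto.significant.values.sum()
        # dominance by the whole-tractogram density
        assert np.all(rto.dsd.values <= avg.values)
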