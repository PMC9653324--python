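"""Synthetic phantom generator tests: bundles, lesions, displacement, cohorts."""

import numpy as np
import pytest

import disconn as dc
from disconn.phantom import (
    BundleSpec,
    PhantomSpec,
    apply_displacement,
    build_patient,
    displace_oedema,
    make_bundle,
    make_cohort,
    make_grid,
    make_lesions,
)


def simple_spec(center=(-20.0, 0.0, 0.0), t_radii=(8.0, 8.0, 8.0),
                to_radii=(14.0, 14.0, 14.0), **kw):
    bundles = (BundleSpec(start=(-20.0, -40.0, 0.0), end=(-20.0, 40.0, 0.0),
                          n_streamlines=60, spread_mm=2.0),)
    return PhantomSpec(bundles=bundles, tumour_center=center,
                       t_radii=t_radii, to_radii=to_radii, **kw)


class TestMakeBundle:
    def test_zero_spread_collapses_to_centerline(self, grid_default):
        spec = BundleSpec(start=(0.0, -40.0, 0.0), end=(0.0, 40.0, 0.0),
                          n_streamlines=5, spread_mm=0.0)
        b = make_bundle(spec, grid_default, np.random.default_rng(0))
        for s in b:
            assert np.array_equal(s, b.streamlines[0])

    def test_deterministic_given_seed(self, grid_default):
        spec = BundleSpec(start=(5.0, -40.0, 3.0), end=(5.0, 40.0, 3.0),
                          n_streamlines=8, spread_mm=3.0)
        a = make_bundle(spec, grid_default, np.random.default_rng(11))
        b = make_bundle(spec, grid_default, np.random.default_rng(11))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa, sb)

    def test_narrow_bundle_contains_centerline_column(self, grid_default):
        # centerline through voxel centres (x=-19, z=1), not along a face
        spec = BundleSpec(start=(-19.0, -40.0, 1.0), end=(-19.0, 40.0, 1.0),
                          n_streamlines=10, spread_mm=0.1)
        b = make_bundle(spec, grid_default, np.random.default_rng(1))
        column = dc.voxels_visited(
            np.array([[-19.0, -40.0, 1.0], [-19.0, 40.0, 1.0]]), grid_default)
        for s in b:
            assert column <= dc.voxels_visited(s, grid_default)

    def test_endpoint_outside_grid_rejected(self, grid_default):
        spec = BundleSpec(start=(0.0, -400.0, 0.0), end=(0.0, 40.0, 0.0))
        with pytest.raises(ValueError):
            make_bundle(spec, grid_default, np.random.default_rng(0))


class TestMakeLesions:
    def test_equal_radii_make_identical_masks(self, grid_default):
        spec = simple_spec(to_radii=(8.0, 8.0, 8.0))
        t, to = make_lesions(spec, grid_default)
        assert np.array_equal(t.voxels, to.voxels)

    def test_nesting_always_holds(self, grid_default):
        rng = np.random.default_rng(2)
        for _ in range(10):
            tr = rng.uniform(4, 10, 3)
            spec = simple_spec(t_radii=tuple(tr),
                               to_radii=tuple(tr + rng.uniform(0, 8, 3)))
            t, to = make_lesions(spec, grid_default)
            assert not np.any(t.voxels & ~to.voxels)

    def test_voxel_count_approximates_ellipsoid_volume(self):
        grid = make_grid((64, 64, 64), 2.0)
        radii = (12.0, 14.0, 16.0)      # >= 5 voxels along each axis
        spec = simple_spec(center=(0.0, 0.0, 0.0), t_radii=radii,
                           to_radii=radii)
        t, _ = make_lesions(spec, grid)
        analytic = 4.0 / 3.0 * np.pi * np.prod(radii)
        counted = t.voxels.sum() * np.prod(grid.voxel_size)
        assert abs(counted - analytic) / analytic < 0.10

    def test_side_label_follows_centre_hemisphere(self, grid_default):
        left, _ = make_lesions(simple_spec(center=(-20.0, 0.0, 0.0)),
                               grid_default)
        right, _ = make_lesions(simple_spec(center=(20.0, 0.0, 0.0)),
                                grid_default)
        mid, _ = make_lesions(simple_spec(center=(0.0, 0.0, 0.0)),
                              grid_default)
        assert left.side == "left"
        assert right.side == "right"
        assert mid.side == "bilateral"

    def test_centre_outside_grid_rejected(self, grid_default):
        with pytest.raises(ValueError):
            make_lesions(simple_spec(center=(500.0, 0.0, 0.0)), grid_default)


class TestDisplacement:
    def test_zero_magnitude_is_identity(self, grid_default):
        b = make_bundle(BundleSpec(start=(0.0, -40.0, 0.0),
                                   end=(0.0, 40.0, 0.0), n_streamlines=4,
                                   spread_mm=2.0),
                        grid_default, np.random.default_rng(3))
        out = apply_displacement(b, (0.0, 0.0, 0.0), 0.0, 20.0)
        for sa, sb in zip(b, out):
            assert np.array_equal(sa, sb)

    def test_points_beyond_radius_untouched(self, grid_default):
        b = make_bundle(BundleSpec(start=(0.0, -40.0, 0.0),
                                   end=(0.0, 40.0, 0.0), n_streamlines=3,
                                   spread_mm=1.0),
                        grid_default, np.random.default_rng(4))
        out = apply_displacement(b, (0.0, 0.0, 0.0), 5.0, 10.0)
        for sa, sb in zip(b, out):
            far = np.linalg.norm(sa, axis=1) >= 10.0
            assert np.allclose(sa[far], sb[far])

    def test_straight_bundle_bows_away_from_centre(self, grid_default):
        b = make_bundle(BundleSpec(start=(0.0, -40.0, 0.0),
                                   end=(0.0, 40.0, 0.0), n_streamlines=10,
                                   spread_mm=2.0),
                        grid_default, np.random.default_rng(5))
        center = np.array([0.0, 0.0, 0.0])
        out = apply_displacement(b, center, 6.0, 20.0)
        for sa, sb in zip(b, out):
            pre = np.linalg.norm(sa - center, axis=1).min()
            post = np.linalg.norm(sb - center, axis=1).min()
            assert post >= pre - 1e-9

    def test_oedema_displaced_with_the_tissue_keeps_nesting(self, grid_default):
        spec = simple_spec(center=(-20.0, 0.0, 0.0))
        t, to = make_lesions(spec, grid_default)
        moved = displace_oedema(to, t, spec.tumour_center, 6.0, 20.0)
        assert not np.any(t.voxels & ~moved.voxels)      # core still inside
        assert moved.voxels.sum() >= to.voxels.sum()     # tissue pushed outward


class TestCohort:
    def test_same_seed_reproduces_everything(self):
        a = make_cohort(n_patients=2, n_controls=2, seed=5)
        b = make_cohort(n_patients=2, n_controls=2, seed=5)
        for pa, pb in zip(a.patients, b.patients):
            assert pa.side == pb.side
            for sa, sb in zip(pa.tractogram, pb.tractogram):
                assert np.array_equal(sa, sb)
            for role in ("T", "T+O"):
                assert np.array_equal(pa.lesions[role].voxels,
                                      pb.lesions[role].voxels)
                assert np.array_equal(pa.ground_truth[role],
                                      pb.ground_truth[role])
        for ca, cb in zip(a.controls, b.controls):
            for sa, sb in zip(ca, cb):
                assert np.array_equal(sa, sb)

    def test_ground_truth_excludes_non_crossing_bundles(self, grid_default):
        bundles = (
            BundleSpec(start=(-20.0, -40.0, 0.0), end=(-20.0, 40.0, 0.0),
                       n_streamlines=40, spread_mm=1.0),
            BundleSpec(start=(30.0, -40.0, 0.0), end=(30.0, 40.0, 0.0),
                       n_streamlines=40, spread_mm=1.0),
        )
        spec = PhantomSpec(bundles=bundles, tumour_center=(-20.0, 0.0, 0.0),
                           t_radii=(6.0, 6.0, 6.0), to_radii=(10.0, 10.0, 10.0),
                           jitter_mm=0.0)
        patient = build_patient(spec, grid_default, np.random.default_rng(6))
        far_bundle_voxels = set()
        for s in patient.bundles[1]:
            far_bundle_voxels |= dc.voxels_visited(s, grid_default)
        gt = patient.ground_truth["T+O"]
        assert not any(gt[v] for v in far_bundle_voxels)
        assert gt.sum() > 0

    def test_ground_truth_respects_lesion_nesting(self):
        cohort = make_cohort(n_patients=3, n_controls=2, seed=7)
        for p in cohort.patients:
            assert not np.any(p.ground_truth["T"] & ~p.ground_truth["T+O"]
                              & ~p.lesions["T+O"].voxels)
            assert not np.any(p.lesions["T"].voxels
                              & ~p.lesions["T+O"].voxels)

    def test_displaced_cohort_keeps_mask_nesting(self):
        cohort = make_cohort(n_patients=2, n_controls=2, seed=8,
                             displacement=True)
        for p in cohort.patients:
            assert not np.any(p.lesions["T"].voxels & ~p.lesions["T+O"].voxels)
            assert p.spec.displacement_magnitude > 0
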