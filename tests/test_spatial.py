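import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from conftest import make_table, square_mask
from replihist import synthetic
from replihist.clustering import (
    conglomerate_metrics,
    detect_replication_sites,
)
from replihist.locio import ellipse_mask, segment_nucleus
from replihist.spatial import (
    classify_periphery,
    compare_distributions,
    m_function,
    pool_radial_profiles,
    radial_profile,
    recycling_scores,
    shell_volume,
    sphere_slab_volume,
    star_code,
    voronoi_density,
)


def _site_from_points(pts):
    pts = np.asarray(pts, dtype=float)
    c = conglomerate_metrics(np.zeros(len(pts), int), make_table(pts), len(pts))[0]
    from replihist.clustering import ReplicationSite

    return ReplicationSite(**vars(c))


class TestRecyclingScores:
    def _cube_site(self, side=1000.0, n=400):
        rng = np.random.default_rng(0)
        corners = np.array(
            [[0, 0, 0], [side, 0, 0], [0, side, 0], [0, 0, side],
             [side, side, 0], [side, 0, side], [0, side, side], [side, side, side]]
        )
        fill = rng.uniform(0, side, (n - 8, 3))
        return _site_from_points(np.vstack([corners, fill]))

    def test_formula(self):
        site = self._cube_site(n=400)
        rng = np.random.default_rng(1)
        inside = rng.uniform(100, 900, (20, 3))
        outside = rng.uniform(5000, 9000, (9980, 3))
        parental = make_table(np.vstack([inside, outside]))
        scores = recycling_scores(parental, [site])
        assert scores[0].h == 20
        assert scores[0].e == 400
        assert scores[0].h_total == 10_000
        assert scores[0].score == pytest.approx(5e-6)

    def test_zero_when_no_parental_inside(self):
        site = self._cube_site()
        parental = make_table(np.random.default_rng(2).uniform(5000, 9000, (100, 3)))
        assert recycling_scores(parental, [site])[0].score == 0.0

    def test_uniform_doubling_invariance(self):
        site = self._cube_site()
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.uniform(100, 900, (30, 3)), rng.uniform(4000, 9000, (70, 3))])
        s1 = recycling_scores(make_table(pts), [site])[0].score
        s2 = recycling_scores(make_table(np.vstack([pts, pts])), [site])[0].score
        assert s2 == pytest.approx(s1)

    def test_empty_parental_rejected(self):
        with pytest.raises(ValueError):
            recycling_scores(make_table(np.empty((0, 3))), [self._cube_site()])


class TestRadialProfile:
    def test_all_detections_in_first_shell(self, rng):
        pts = rng.normal(0, 8, (100, 3))  # all well under 25 nm
        prof = radial_profile(make_table(pts), [0, 0, 0], 500.0)
        assert prof.counts[0] == 100
        assert prof.counts[1:].sum() == 0

    def test_full_shell_volume_closed_form(self):
        vol = shell_volume(50.0, 100.0)
        assert vol == pytest.approx(4 / 3 * np.pi * (100**3 - 50**3))
        assert vol == pytest.approx(3.665e6, rel=1e-3)

    def test_slab_clipped_volume_matches_cap_formula(self):
        # sphere of radius 100 clipped at z in [-50, 50]: full sphere minus 2 caps
        full = 4 / 3 * np.pi * 100**3
        cap = np.pi * 50**2 * (3 * 100 - 50) / 3  # height-50 spherical cap
        assert sphere_slab_volume(100, -50, 50) == pytest.approx(full - 2 * cap)

    def test_counts_conserved_every_clip_mode(self, rng):
        pts = rng.uniform(-400, 400, (5000, 3))
        table = make_table(pts)
        for mode in ("none", "slab"):
            prof = radial_profile(
                table, [0, 0, 0], 800.0, clip_mode=mode, z_bounds=(-300, 300)
            )
            d = np.linalg.norm(pts, axis=1)
            assert prof.counts.sum() == (d < prof.edges[-1]).sum()

    def test_uniform_scene_flat_density(self, rng):
        """Poisson points in a slab: slab-clipped density flat across shells."""
        lam = 1e-5  # points per nm^3
        half = 300.0
        extent = 1500.0
        n = rng.poisson(lam * (2 * extent) ** 2 * (2 * half))
        pts = np.column_stack(
            [rng.uniform(-extent, extent, n), rng.uniform(-extent, extent, n),
             rng.uniform(-half, half, n)]
        )
        prof = radial_profile(
            make_table(pts), [0, 0, 0], 1000.0, clip_mode="slab",
            z_bounds=(-half, half),
        )
        for cnt, vol in zip(prof.counts, prof.volumes):
            expect = lam * vol
            assert abs(cnt - expect) < 5 * np.sqrt(expect)

    def test_pooling_sums_counts_and_volumes(self, rng):
        t = make_table(rng.uniform(-200, 200, (500, 3)))
        p1 = radial_profile(t, [0, 0, 0], 400.0)
        p2 = radial_profile(t, [50, 0, 0], 400.0)
        pooled = pool_radial_profiles([p1, p2])
        assert np.array_equal(pooled.counts, p1.counts + p2.counts)
        assert np.allclose(pooled.volumes, p1.volumes + p2.volumes)

    def test_center_outside_mask_warns(self, rng):
        mask = square_mask(1000.0)
        t = make_table(rng.uniform(-400, 400, (50, 3)))
        with pytest.warns(UserWarning, match="outside"):
            radial_profile(t, [10_000, 0, 0], 200.0, mask=mask)


class TestMFunction:
    def test_independent_uniform_near_one(self, nucleus_mask, rng):
        a = nucleus_mask.sample_points(3000, rng)
        b = nucleus_mask.sample_points(3000, rng)
        radii = np.arange(50.0, 501.0, 25.0)
        curve = m_function(a, b, nucleus_mask, radii, n_baseline=20, seed=0)
        assert abs(curve.m.mean() - 1.0) < 0.1

    def test_colocalized_attraction(self, nucleus_mask, rng):
        a = nucleus_mask.sample_points(2000, rng)
        b = a + rng.normal(0, 10, a.shape)
        radii = np.arange(50.0, 501.0, 50.0)
        curve = m_function(a, b, nucleus_mask, radii, n_baseline=10, seed=0)
        assert curve.m[0] > 1.5

    def test_disjoint_halves_repulsion(self, box_mask, rng):
        a = box_mask.sample_points(2000, rng)
        b = box_mask.sample_points(2000, rng)
        a[:, 0] = -np.abs(a[:, 0]) - 500  # left half only
        b[:, 0] = np.abs(b[:, 0]) + 500   # right half only
        radii = np.arange(50.0, 501.0, 50.0)
        curve = m_function(a, b, box_mask, radii, n_baseline=10, seed=0)
        assert (curve.m[:4] < 0.5).all()

    def test_rigid_motion_invariance(self, rng):
        mask = square_mask(4000.0)
        a = mask.sample_points(1500, rng)
        b = mask.sample_points(1500, rng)
        radii = np.arange(50.0, 401.0, 50.0)
        c0 = m_function(a, b, mask, radii, n_baseline=20, seed=4)
        shift = np.array([1e5, -3e4, 100.0])
        from shapely import affinity

        mask2 = square_mask(4000.0)
        mask2.polygon = affinity.translate(mask2.polygon, shift[0], shift[1])
        mask2.z_min += shift[2]
        mask2.z_max += shift[2]
        c1 = m_function(a + shift, b + shift, mask2, radii, n_baseline=20, seed=4)
        assert np.allclose(c0.m, c1.m, rtol=0.1)

    def test_parameter_validation(self, box_mask, rng):
        pts = box_mask.sample_points(10, rng)
        with pytest.raises(ValueError):
            m_function(pts, pts, box_mask, n_baseline=0)
        with pytest.raises(ValueError):
            m_function(np.empty((0, 3)), pts, box_mask)


class TestVoronoi:
    def test_one_polygon_per_detection(self, rng):
        mask = square_mask(1000.0)
        pts = mask.sample_points(50, rng)
        vmap = voronoi_density(make_table(pts), mask)
        assert len(vmap.areas_nm2) == 50

    def test_regular_grid_equal_interior_areas(self):
        xs = np.arange(10) * 100.0
        grid = np.array([[x, y, 0.0] for x in xs for y in xs])
        mask = square_mask(2000.0)
        mask.polygon = mask.polygon.buffer(0)  # square centered at 0
        grid[:, :2] -= 450.0  # center the grid
        vmap = voronoi_density(make_table(grid), mask)
        interior = vmap.areas_nm2.reshape(10, 10)[2:-2, 2:-2]
        assert np.allclose(interior, 100.0 * 100.0)

    def test_areas_sum_to_mask_area(self, rng):
        mask = square_mask(3000.0)
        pts = mask.sample_points(300, rng)
        vmap = voronoi_density(make_table(pts), mask)
        assert vmap.areas_nm2.sum() == pytest.approx(mask.area_nm2, rel=1e-3)

    def test_two_density_mosaic(self, rng):
        mask = square_mask(4000.0)
        dense = np.column_stack(
            [rng.uniform(-2000, 0, 600), rng.uniform(-2000, 2000, 600),
             np.zeros(600)]
        )
        sparse = np.column_stack(
            [rng.uniform(0, 2000, 60), rng.uniform(-2000, 2000, 60), np.zeros(60)]
        )
        vmap = voronoi_density(make_table(np.vstack([dense, sparse])), mask)
        assert np.median(vmap.areas_nm2[:600]) < np.median(vmap.areas_nm2[600:])

    def test_duplicates_jittered_with_warning(self, rng):
        mask = square_mask(1000.0)
        pts = np.vstack([mask.sample_points(10, rng)] * 2)
        with pytest.warns(UserWarning, match="duplicate"):
            vmap = voronoi_density(make_table(pts), mask)
        assert len(vmap.areas_nm2) == 20

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            voronoi_density(make_table(np.zeros((3, 3))), square_mask())


class TestCompareDistributions:
    def test_identical_samples(self, rng):
        a = rng.normal(0, 1, 100)
        cmp = compare_distributions(a, a)
        assert cmp.peak_shift_percent == 0.0
        assert cmp.p_value > 0.9
        assert cmp.stars == "ns"

    def test_minus_33_percent_convention(self, rng):
        a = 1.0 + 0.01 * rng.normal(size=500)
        b = 0.67 + 0.01 * rng.normal(size=500)
        cmp = compare_distributions(a, b)
        assert cmp.peak_shift_percent == pytest.approx(-33.0, abs=2.0)

    def test_exact_mann_whitney_disjoint(self):
        a = np.arange(1.0, 11.0)
        b = np.arange(101.0, 111.0)
        cmp = compare_distributions(a, b)
        expected_p = 2.0 / comb(20, 10, exact=True)
        assert cmp.p_value == pytest.approx(expected_p, rel=1e-9)
        assert cmp.stars == "***"

    def test_swap_negates_shift_on_swapped_reference(self, rng):
        a = 2.0 + 0.05 * rng.normal(size=300)
        b = 3.0 + 0.05 * rng.normal(size=300)
        ab = compare_distributions(a, b)
        ba = compare_distributions(b, a)
        # shift_B->A = 100 * (peak_A - peak_B) / peak_B
        assert ba.peak_shift_percent == pytest.approx(
            100 * (ab.peak_a - ab.peak_b) / ab.peak_b, rel=1e-6
        )

    def test_constant_sample_point_mass(self, rng):
        a = np.full(10, 5.0)
        b = rng.normal(7, 0.1, 50)
        cmp = compare_distributions(a, b)
        assert cmp.point_mass_a
        assert cmp.peak_a == 5.0

    def test_star_thresholds(self):
        assert star_code(0.2) == "ns"
        assert star_code(0.04) == "*"
        assert star_code(0.005) == "**"
        assert star_code(0.0005) == "***"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1, 2, 3], [4, 5, 6, 7, 8])


class TestPeriphery:
    def _site_at(self, xy):
        pts = np.array(xy + [0.0]) + np.random.default_rng(0).normal(0, 5, (10, 3))
        pts -= pts.mean(axis=0) - np.array(xy + [0.0])  # exact centroid
        return _site_from_points(pts)

    def test_centroid_on_boundary_is_peripheral(self):
        mask = square_mask(10_000.0)
        site = self._site_at([5000.0, 0.0])
        classify_periphery([site], mask, 500.0)
        assert site.peripheral is True

    def test_center_of_large_nucleus_is_interior(self):
        mask = square_mask(10_000.0)
        site = self._site_at([0.0, 0.0])
        classify_periphery([site], mask, 500.0)
        assert site.peripheral is False

    def test_infinite_band_all_peripheral(self):
        mask = square_mask(10_000.0)
        sites = [self._site_at([0.0, 0.0]), self._site_at([4000.0, 0.0])]
        classify_periphery(sites, mask, np.inf)
        assert all(s.peripheral for s in sites)


class TestEndToEndStressSignature:
    """Scenes emulating impaired recycling (weaker coupling, depleted in-site
    parental signal) must shift recycling scores down and radial profiles out."""

    def _analyse(self, coupling, seed):
        spec = synthetic.SceneSpec(
            n_conglomerates=12, detections_per_conglomerate=150,
            background_fraction=0.7, channel_coupling=coupling,
            coupling_range_nm=300.0, seed=seed,
        )
        table, _ = synthetic.generate_scene(spec)
        hist = table[table.channel == "A"].reset_index(drop=True)
        edu = table[table.channel == "B"].reset_index(drop=True)
        sites = detect_replication_sites(edu)
        scores = [s.score for s in recycling_scores(hist, sites)]
        profs = [
            radial_profile(hist, s.centroid, 1000.0) for s in sites
        ]
        pooled = pool_radial_profiles(profs)
        return np.mean(scores), pooled.mean_distance()

    def test_depleted_scene_signatures(self):
        mean_ctrl, dist_ctrl = self._analyse(coupling=4.0, seed=21)
        mean_hu, dist_hu = self._analyse(coupling=0.3, seed=21)
        assert mean_hu < mean_ctrl
        assert dist_hu > dist_ctrl
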