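import numpy as np
import pytest
from shapely.geometry import Point

from nodule4d import morpho, spatial
from nodule4d.segment import SurfaceModel
from nodule4d.stackio import Calibration

ISO = Calibration(voxel_size=(1.0, 1.0, 1.0))


def make_record(x, y, z, psi=0.8, cid=0):
    return morpho.CellRecord(
        cell_id=cid, timepoint=0, centroid=(x, y, z), volume=10, area=30,
        sphericity=psi, oblateness=0, prolateness=0, semi_axes=(3, 2, 1),
        high_sphericity=psi >= 0.7,
    )


def surface_from_mask(mask, cal=ISO):
    from nodule4d.segment import _mask_to_surface

    return _mask_to_surface(np.asarray(mask, dtype=bool), cal)


def slab_surface(z0=0, z1=6, y0=10, y1=50, x0=10, x1=50, shape=(12, 64, 64)):
    mask = np.zeros(shape, dtype=bool)
    mask[z0:z1, y0:y1, x0:x1] = True
    return surface_from_mask(mask)


def ray_cast_inside(poly_xy, px, py):
    """Independent even-odd ray-casting oracle; boundary points are inside."""
    n = len(poly_xy)
    inside = False
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        # boundary: point on segment
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
        if (y1 > py) != (y2 > py):
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xi:
                inside = not inside
    return inside


class TestClassifyCompartment:
    def test_inside_polygon_above_zmin_is_in_on(self):
        surf = slab_surface()
        recs = spatial.classify_compartment([make_record(30, 30, 3)], surf)
        assert recs[0].compartment == "IN/ON"

    def test_inside_footprint_below_zmin_is_out(self):
        surf = slab_surface(z0=5, z1=10)  # floating slab, z_min = 5
        recs = spatial.classify_compartment([make_record(30, 30, 1)], surf)
        assert surf.z_min == 5.0
        assert recs[0].compartment == "OUT"

    def test_outside_polygon_is_out(self):
        recs = spatial.classify_compartment([make_record(60, 60, 3)], slab_surface())
        assert recs[0].compartment == "OUT"

    def test_empty_surface_all_out(self):
        surf = surface_from_mask(np.zeros((4, 8, 8)))
        recs = spatial.classify_compartment([make_record(1, 1, 1)], surf)
        assert recs[0].compartment == "OUT"

    def test_shrink_zero_equals_convex_hull(self, nodule_surfaces):
        surf = nodule_surfaces[0]
        poly0 = spatial.footprint_polygon(surf, shrink=0.0)
        hull = spatial.footprint_polygon(surf, shrink=0.0).convex_hull
        assert poly0.equals(hull)

    def test_in_on_count_non_increasing_in_shrink(self, nodule_records0, nodule_surfaces):
        import copy

        counts = []
        for shrink in (0.0, 0.25, 0.5, 0.75):
            recs = spatial.classify_compartment(
                copy.deepcopy(nodule_records0), nodule_surfaces[0], shrink=shrink
            )
            counts.append(sum(r.compartment == "IN/ON" for r in recs))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_point_in_polygon_matches_ray_casting_oracle(self, nodule_surfaces):
        poly = spatial.footprint_polygon(nodule_surfaces[0], shrink=0.5)
        coords = np.asarray(poly.exterior.coords)[:-1]
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 140, size=(1000, 2))
        for px, py in pts:
            assert poly.covers(Point(px, py)) == ray_cast_inside(coords, px, py)

    def test_invalid_shrink_rejected(self, nodule_surfaces):
        with pytest.raises(ValueError, match="shrink"):
            spatial.footprint_polygon(nodule_surfaces[0], shrink=1.5)


class TestDelaunay:
    def test_unit_square_two_triangles_mean_half(self):
        mean, areas, simplices = spatial.delaunay_mean_area(
            [(0, 0), (1, 0), (0, 1), (1, 1)]
        )
        assert len(areas) == 2
        assert mean == pytest.approx(0.5)

    def test_triangles_partition_convex_hull(self):
        from shapely.geometry import MultiPoint

        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, size=(100, 2))
        _, areas, _ = spatial.delaunay_mean_area(pts)
        hull_area = MultiPoint(pts.tolist()).convex_hull.area
        assert areas.sum() == pytest.approx(hull_area, rel=1e-9)

    def test_doubling_density_halves_mean_area(self):
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(10):
            p1 = rng.uniform(0, 100, size=(150, 2))
            p2 = rng.uniform(0, 100, size=(300, 2))
            m1, _, _ = spatial.delaunay_mean_area(p1)
            m2, _, _ = spatial.delaunay_mean_area(p2)
            ratios.append(m2 / m1)
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spatial.delaunay_mean_area([(0, 0), (1, 1)])

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            spatial.delaunay_mean_area([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_lacuna_constellation_stable_over_time(self, lacuna_spot_series):
        """Fixed lacuna positions: mean triangle area varies < 10% between
        timepoints (the osteocyte-control contract)."""
        means = []
        for spots in lacuna_spot_series:
            pts = [(s.centroid[0], s.centroid[1]) for s in spots]
            mean, _, _ = spatial.delaunay_mean_area(pts)
            means.append(mean)
        assert max(means) <= 1.1 * min(means)


class TestSubRoi:
    def _surfaces(self, growth_tiles=None, shape=(8, 64, 64)):
        m0 = np.zeros(shape, dtype=bool)
        m0[0:4, 8:56, 8:56] = True
        m1 = m0.copy()
        if growth_tiles:
            for (r, c) in growth_tiles:
                m1[4:7, r * 16 : (r + 1) * 16, c * 16 : (c + 1) * 16] = True
        return surface_from_mask(m0), surface_from_mask(m1)

    def test_default_grid_has_16_subrois(self):
        s0, s1 = self._surfaces()
        recs = [make_record(20, 20, 2, psi=0.9), make_record(40, 40, 2, psi=0.3)]
        for r in recs:
            r.compartment = "IN/ON"
        tab = spatial.subroi_correlation(recs, s0, s1)
        assert len(tab.table) == 16
        assert tab.grid == (4, 4)

    def test_grid_must_tile_field(self):
        s0, s1 = self._surfaces()
        with pytest.raises(ValueError, match="tile"):
            spatial.subroi_correlation([], s0, s1, grid=(5, 4))

    def test_constructed_coupling_gives_moderate_rho(self):
        """Growth placed exactly where high-sphericity cells sit."""
        rng = np.random.default_rng(5)
        tiles = [(0, 0), (1, 2), (2, 1), (3, 3), (0, 3), (2, 2)]
        s0, s1 = self._surfaces(growth_tiles=tiles)
        recs = []
        cid = 0
        for (r, c) in tiles:  # 2 high-psi cells in each growing tile
            for k in range(2):
                rec = make_record(c * 16 + 4 + 4 * k, r * 16 + 6, 2, psi=0.9, cid=cid)
                rec.compartment = "IN/ON"
                recs.append(rec)
                cid += 1
        for _ in range(4):  # low-psi cells elsewhere
            rec = make_record(rng.uniform(8, 56), rng.uniform(8, 56), 2, psi=0.3, cid=cid)
            rec.compartment = "IN/ON"
            recs.append(rec)
            cid += 1
        tab = spatial.subroi_correlation(recs, s0, s1)
        assert tab.rho >= 0.4
        assert tab.category in ("moderate", "strong", "very strong")

    def test_independent_growth_gives_little_rho_in_expectation(self):
        rng = np.random.default_rng(6)
        rhos = []
        for _ in range(30):
            # uniform growth everywhere; random high-psi cell placement
            s0, s1 = self._surfaces(growth_tiles=[(r, c) for r in range(4) for c in range(4)])
            recs = []
            for i in range(12):
                rec = make_record(rng.uniform(0, 64), rng.uniform(0, 64), 2, psi=0.9, cid=i)
                rec.compartment = "IN/ON"
                recs.append(rec)
            # add voxel-level jitter to the growth so delta is not constant
            m1 = s1.mask.copy()
            drop = rng.integers(0, 2, size=m1.shape).astype(bool)
            m1[4:7] &= ~drop[4:7]
            tab = spatial.subroi_correlation(recs, s0, surface_from_mask(m1))
            rhos.append(tab.rho)
        assert abs(np.mean(rhos)) < 0.2

    def test_counts_only_high_sphericity_in_on(self):
        s0, s1 = self._surfaces()
        high = make_record(20, 20, 2, psi=0.9, cid=0)
        high.compartment = "IN/ON"
        low = make_record(20, 20, 2, psi=0.3, cid=1)
        low.compartment = "IN/ON"
        out = make_record(20, 20, 2, psi=0.9, cid=2)
        out.compartment = "OUT"
        tab = spatial.subroi_correlation([high, low, out], s0, s1)
        assert tab.table.n_high_sphericity.sum() == 1


class TestMipRatio:
    def _stack(self, shg_img, egfp_img):
        from nodule4d.stackio import ImageStack

        data = np.zeros((1, 4, 2, *shg_img.shape))
        data[0, :, 0] = egfp_img
        data[0, :, 1] = shg_img
        return ImageStack(data=data, calibration=ISO, channel_names=("EGFP", "SHG"))

    def test_identical_masks_ratio_one(self):
        img = np.zeros((32, 32))
        img[8:24, 8:24] = 1.0
        assert spatial.mip_ratio(self._stack(img, img), 0) == pytest.approx(1.0)

    def test_half_mask_ratio_half(self):
        egfp = np.zeros((32, 32))
        egfp[8:24, 8:24] = 1.0
        shg = np.zeros((32, 32))
        shg[8:16, 8:24] = 1.0
        assert spatial.mip_ratio(self._stack(shg, egfp), 0) == pytest.approx(0.5)

    def test_empty_egfp_mask_raises(self):
        shg = np.zeros((16, 16))
        shg[4:10, 4:10] = 1.0
        with pytest.raises(ValueError, match="EGFP"):
            spatial.mip_ratio(self._stack(shg, np.zeros((16, 16))), 0)

    def test_treated_exceeds_vehicle_then_returns(self, bio_pair):
        (stack_t, _), (stack_v, _) = bio_pair
        rt = spatial.mip_ratio_series(stack_t)
        rv = spatial.mip_ratio_series(stack_v)
        # boosted matrix: treated ratio change above vehicle at t = 1, 2
        for t in (1, 2):
            assert rt.ratio_change[t] > rv.ratio_change[t]
        # final timepoint: treated curve turns back toward baseline
        assert rt.ratio_change[3] < rt.ratio_change[2]
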