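import numpy as np
import pytest
from shapely.geometry import Polygon

import octmosaic as om
from octmosaic.phantom import _hex_lattice, _spot_image
from conftest import greedy_f1


def halfplane_voronoi_cell(points, i, bounds):
    """Independent Voronoi-cell oracle by iterative half-plane clipping.

    Starts from the bounds rectangle and clips by the perpendicular bisector
    against other sites in order of distance; once the next site is farther
    than twice the farthest current cell vertex, no later site can cut the
    cell, so iteration stops (standard security-radius argument).
    """
    p = points[i]
    x0, y0, x1, y1 = bounds
    cell = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    big = 10 * max(x1 - x0, y1 - y0) + 10
    order = np.argsort(np.hypot(points[:, 0] - p[0], points[:, 1] - p[1]))
    for j in order[1:]:
        q = points[j]
        d = float(np.hypot(*(q - p)))
        verts = np.asarray(cell.exterior.coords)
        max_v = np.hypot(verts[:, 0] - p[0], verts[:, 1] - p[1]).max()
        if d > 2 * max_v:
            break
        mid = (p + q) / 2
        n = (q - p) / d
        t = np.array([-n[1], n[0]])
        half = Polygon(
            [
                mid + t * big,
                mid - t * big,
                mid - t * big - n * big,
                mid + t * big - n * big,
            ]
        )
        cell = cell.intersection(half)
        if cell.is_empty:
            break
    return cell


class TestDetection:
    def test_blank_image_gives_no_cones(self):
        with pytest.warns(UserWarning, match="constant"):
            mosaic = om.detect_cones(np.zeros((32, 32)))
        assert len(mosaic) == 0

    def test_noiseless_lattice_of_gaussian_spots_detected_perfectly(self):
        lat = _hex_lattice(120, 120, 10.0)
        keep = (lat[:, 0] >= 0) & (lat[:, 0] <= 127) & (lat[:, 1] >= 0) & (lat[:, 1] <= 127)
        lat = lat[keep]
        img = _spot_image((128, 128), lat, 2.0, 100.0)
        mosaic = om.detect_cones(
            img,
            om.DetectionParams(min_separation_px=6, flatfield_size=0, background_sigma_px=4.0),
        )
        assert len(mosaic) == len(lat)  # zero false positives
        assert greedy_f1(mosaic.points, lat, tol_px=1.0) == 1.0

    def test_close_pair_suppressed_to_single_brighter_detection(self):
        img = np.zeros((32, 32))
        img += _spot_image((32, 32), np.array([[10.0, 16.0]]), 1.2, 100.0)
        img += _spot_image((32, 32), np.array([[13.0, 16.0]]), 1.2, 60.0)
        mosaic = om.detect_cones(
            img, om.DetectionParams(min_separation_px=6, flatfield_size=0, background_sigma_px=4.0)
        )
        assert len(mosaic) == 1
        assert mosaic.points[0, 0] == pytest.approx(10.0, abs=1.0)  # brighter kept

    def test_equal_intensity_tie_keeps_smaller_row_then_column(self):
        # two identical impulses mirror-symmetric about the image centre:
        # an exact tie for the suppressor, resolved to the smaller column
        img = np.zeros((25, 25))
        img[12, 8] = 50.0
        img[12, 16] = 50.0
        mosaic = om.detect_cones(
            img, om.DetectionParams(min_separation_px=10, flatfield_size=0,
                                    background_sigma_px=6.0, blur_sigma_px=0.0,
                                    centroid_power=1.0)
        )
        assert len(mosaic) == 1
        assert mosaic.points[0, 0] == pytest.approx(8.0, abs=0.3)
        assert mosaic.points[0, 1] == pytest.approx(12.0, abs=0.3)

    def test_sub_pixel_centres_on_offset_spots(self):
        truth = np.array([[10.4, 12.7], [20.6, 8.3]])
        img = _spot_image((32, 32), truth, 1.5, 100.0)
        mosaic = om.detect_cones(
            img, om.DetectionParams(min_separation_px=5, flatfield_size=0, background_sigma_px=4.0)
        )
        assert greedy_f1(mosaic.points, truth, tol_px=0.35) == 1.0


class TestCorrections:
    def test_add_to_empty_mosaic(self):
        m = om.ConeMosaic(points=np.zeros((0, 2)), um_per_px=1.0, bounds=(0, 0, 10, 10))
        out = om.apply_corrections(m, add=[(3.0, 4.0)])
        assert len(out) == 1

    def test_remove_only_cone(self):
        m = om.ConeMosaic(points=[(3.0, 4.0)], um_per_px=1.0, bounds=(0, 0, 10, 10))
        out = om.apply_corrections(m, remove=[(3.2, 4.1)], snap_radius_px=1.0)
        assert len(out) == 0

    def test_add_then_remove_is_identity(self, rng):
        pts = rng.uniform(5, 20, size=(10, 2))
        m = om.ConeMosaic(points=pts, um_per_px=1.0, bounds=(0, 0, 25, 25))
        out = om.apply_corrections(m, add=[(2.0, 2.0)])
        out = om.apply_corrections(out, remove=[(2.0, 2.0)], snap_radius_px=0.5)
        np.testing.assert_allclose(np.sort(out.points, axis=0), np.sort(pts, axis=0))

    def test_removal_without_match_lists_offenders(self):
        m = om.ConeMosaic(points=[(3.0, 4.0)], um_per_px=1.0, bounds=(0, 0, 10, 10))
        with pytest.raises(ValueError, match=r"9\.0"):
            om.apply_corrections(m, remove=[(9.0, 9.0)], snap_radius_px=1.0)


class TestVoronoiMetrics:
    def test_perfect_hex_lattice_is_all_six_sided(self):
        lat = _hex_lattice(80, 80, 5.0)
        mm = om.voronoi_metrics(om.ConeMosaic(points=lat, um_per_px=1.0))
        assert mm.percent_six_sided == 100.0
        assert set(mm.nsided_histogram) == {6}

    def test_square_lattice_is_all_four_sided(self):
        xs, ys = np.meshgrid(np.arange(12) * 5.0, np.arange(12) * 5.0)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        mm = om.voronoi_metrics(om.ConeMosaic(points=pts, um_per_px=1.0))
        assert mm.percent_six_sided == 0.0
        assert set(mm.nsided_histogram) == {4}

    @pytest.mark.parametrize("spacing_um", [4.0, 7.684, 12.0, 20.0])
    def test_hex_density_matches_closed_form(self, spacing_um):
        lat = _hex_lattice(30 * spacing_um, 30 * spacing_um, spacing_um)
        mm = om.voronoi_metrics(om.ConeMosaic(points=lat, um_per_px=1.0))
        ideal = 2.0 / (np.sqrt(3.0) * spacing_um**2) * 1e6  # per mm^2
        assert mm.density_per_mm2 == pytest.approx(ideal, rel=0.005)

    def test_mean_nn_distance_on_lattice_is_spacing(self):
        lat = _hex_lattice(60, 60, 6.0)
        mm = om.voronoi_metrics(om.ConeMosaic(points=lat, um_per_px=2.0))
        assert mm.mean_nn_um == pytest.approx(12.0, rel=1e-6)

    def test_histogram_sums_to_bound_cells_and_pct_consistent(self, rng):
        pts = rng.uniform(0, 100, size=(300, 2))
        mm = om.voronoi_metrics(om.ConeMosaic(points=pts, um_per_px=1.0))
        assert sum(mm.nsided_histogram.values()) == mm.n_bound_cells
        assert mm.percent_six_sided == pytest.approx(
            100.0 * mm.nsided_histogram.get(6, 0) / mm.n_bound_cells
        )

    def test_fewer_than_four_cones_is_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            om.voronoi_metrics(om.ConeMosaic(points=[(0, 0), (1, 1), (2, 0)], um_per_px=1.0))

    def test_collinear_points_are_a_tessellation_error(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        with pytest.raises(ValueError, match="collinear"):
            om.voronoi_metrics(om.ConeMosaic(points=pts, um_per_px=1.0))

    def test_translation_and_rescaling_invariance(self, rng):
        base = _hex_lattice(80, 80, 6.0) + rng.normal(0, 0.5, (len(_hex_lattice(80, 80, 6.0)), 2))
        m0 = om.voronoi_metrics(om.ConeMosaic(points=base, um_per_px=1.0))
        shifted = om.voronoi_metrics(
            om.ConeMosaic(points=base + [37.5, -12.25], um_per_px=1.0)
        )
        assert shifted.percent_six_sided == m0.percent_six_sided
        assert shifted.density_per_mm2 == pytest.approx(m0.density_per_mm2, rel=1e-9)
        # uniform rescaling of coordinates with the px size co-scaled
        scaled = om.voronoi_metrics(om.ConeMosaic(points=base * 2.0, um_per_px=0.5))
        assert scaled.percent_six_sided == m0.percent_six_sided
        assert scaled.density_per_mm2 == pytest.approx(m0.density_per_mm2, rel=1e-9)

    def test_rotation_invariance_in_disc_region(self, rng):
        """Percent six-sided is rotation invariant when the analysis region
        (a disc) is itself rotation symmetric."""
        pts = _hex_lattice(100, 100, 6.0)
        pts = pts + rng.normal(0, 0.6, pts.shape)
        centre = np.array([50.0, 50.0])

        def metrics(p):
            m = om.ConeMosaic(points=p, um_per_px=1.0, bounds=(-80, -80, 180, 180))
            return om.voronoi_metrics(om.regional_mask(m, centre, 0.0, 35.0))

        m0 = metrics(pts)
        th = 0.31
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = (pts - centre) @ R.T + centre
        m1 = metrics(rotated)
        assert m1.percent_six_sided == pytest.approx(m0.percent_six_sided, abs=1e-9)
        assert m1.n_bound_cells == m0.n_bound_cells

    def test_agrees_with_halfplane_oracle_cell_by_cell(self, rng):
        """scipy tessellation matches an independent half-plane-clipping
        oracle: same bound cells, same vertices, same areas."""
        pts = rng.uniform(0, 100, size=(500, 2))
        mosaic = om.ConeMosaic(points=pts, um_per_px=1.0, bounds=(0, 0, 100, 100))
        from octmosaic.mosaic_quant import _tessellate

        _, bound, areas, sides = _tessellate(mosaic)
        n_checked = 0
        for i in np.flatnonzero(bound):
            cell = halfplane_voronoi_cell(pts, i, mosaic.bounds)
            # oracle cell that touches the bounds rectangle is unbound
            verts = np.asarray(cell.exterior.coords)[:-1]
            assert len(verts) == sides[i], f"cell {i}: {len(verts)} vs {sides[i]}"
            assert cell.area == pytest.approx(areas[i], rel=1e-9)
            n_checked += 1
        assert n_checked > 300

    def test_bound_classification_matches_oracle(self, rng):
        """A cell is bound iff its half-plane-oracle polygon keeps clear of
        the bounds rectangle's border."""
        pts = rng.uniform(0, 60, size=(150, 2))
        mosaic = om.ConeMosaic(points=pts, um_per_px=1.0, bounds=(0, 0, 60, 60))
        from octmosaic.mosaic_quant import _tessellate

        _, bound, _, _ = _tessellate(mosaic)
        for i in range(len(pts)):
            cell = halfplane_voronoi_cell(pts, i, (-1000, -1000, 1060, 1060))
            verts = np.asarray(cell.exterior.coords)[:-1]
            inside = (
                (verts[:, 0] > 0) & (verts[:, 0] < 60) & (verts[:, 1] > 0) & (verts[:, 1] < 60)
            ).all()
            assert bool(bound[i]) == bool(inside), f"cell {i}"


class TestCrystallinePatches:
    def test_perfect_lattice_is_one_full_patch(self):
        lat = _hex_lattice(80, 80, 5.0)
        mosaic = om.ConeMosaic(points=lat, um_per_px=1.0)
        patches = om.crystalline_patches(mosaic, min_fraction_six=1.0)
        mm = om.voronoi_metrics(mosaic)
        assert len(patches) == 1
        assert patches[0].percent_six_sided == 100.0
        assert len(patches[0].members) == mm.n_bound_cells

    def test_poisson_points_have_smaller_patches_than_lattice(self, rng):
        lat = _hex_lattice(100, 100, 5.0)
        lat_area = max(p.area_mm2 for p in om.crystalline_patches(
            om.ConeMosaic(points=lat, um_per_px=1.0)))
        pois = rng.uniform(0, 100, size=(len(lat), 2))
        patches = om.crystalline_patches(om.ConeMosaic(points=pois, um_per_px=1.0))
        pois_area = max((p.area_mm2 for p in patches), default=0.0)
        assert pois_area < lat_area / 3

    def test_disordered_disc_is_excluded_from_large_patch(self):
        spec = om.PhantomSpec(cone_jitter_um=0.4, disorder_disc=(64.0, 64.0, 20.0))
        mosaic, _ = om.generate_mosaic(spec, seed=11)
        patches = om.crystalline_patches(mosaic, min_fraction_six=0.9)
        big = patches[0]
        pts = mosaic.points[big.members]
        dist = np.hypot(pts[:, 0] - 64.0, pts[:, 1] - 64.0)
        # the big crystalline patch stays out of the disordered core
        assert (dist < 10.0).sum() <= 0.02 * len(big.members)
        assert big.percent_six_sided >= 90.0

    def test_min_fraction_bounds_checked(self):
        lat = _hex_lattice(40, 40, 5.0)
        with pytest.raises(ValueError):
            om.crystalline_patches(om.ConeMosaic(points=lat, um_per_px=1.0), min_fraction_six=1.5)


class TestExports:
    def test_cell_csv_has_one_row_per_cone(self, tmp_path, rng):
        import pandas as pd

        pts = rng.uniform(0, 60, size=(80, 2))
        mosaic = om.ConeMosaic(points=pts, um_per_px=1.5, bounds=(0, 0, 60, 60))
        p = tmp_path / "cells.csv"
        om.write_cell_csv(mosaic, p)
        df = pd.read_csv(p)
        assert len(df) == 80
        assert set(df.columns) == {"x", "y", "n_sides", "area_um2", "bound"}
        mm = om.voronoi_metrics(mosaic)
        assert int(df["bound"].sum()) == mm.n_bound_cells

    def test_overlay_png_written(self, tmp_path):
        from octmosaic.phantom import _hex_lattice

        lat = _hex_lattice(50, 50, 6.0)
        p = tmp_path / "overlay.png"
        om.plot_voronoi_overlay(om.ConeMosaic(points=lat, um_per_px=1.0), p)
        assert p.stat().st_size > 1000


class TestRegionalMask:
    def test_infinite_annulus_is_identity_on_points(self, rng):
        pts = rng.uniform(0, 50, size=(40, 2))
        m = om.ConeMosaic(points=pts, um_per_px=1.0, bounds=(0, 0, 50, 50))
        out = om.regional_mask(m, (25, 25), 0.0, np.inf)
        np.testing.assert_allclose(out.points, pts)

    def test_single_cone_in_window_retained(self):
        m = om.ConeMosaic(points=[(40.0, 10.0), (80.0, 10.0)], um_per_px=1.0,
                          bounds=(0, 0, 100, 100))
        out = om.regional_mask(m, (10.0, 10.0), 20.0, 50.0)
        np.testing.assert_allclose(out.points, [[40.0, 10.0]])

    def test_annulus_count_matches_brute_force(self):
        spec = om.PhantomSpec(n_bscans=128, n_ascans=128)
        mosaic, truth = om.generate_mosaic(spec, seed=4)
        centre, r_in, r_out = (64.0, 64.0), 30.0, 90.0
        out = om.regional_mask(mosaic, centre, r_in, r_out)
        d_um = np.hypot(*(truth.cones_px - centre).T) * mosaic.um_per_px
        assert len(out) == int(((d_um >= r_in) & (d_um <= r_out)).sum())

    def test_invalid_radii_rejected(self):
        m = om.ConeMosaic(points=[(1.0, 1.0)], um_per_px=1.0, bounds=(0, 0, 10, 10))
        with pytest.raises(ValueError):
            om.regional_mask(m, (0, 0), 50.0, 20.0)
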