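"""Geometry construction: masks, wall chain, coil fill, invariants."""

import dataclasses

import numpy as np
import pytest
import shapely.geometry as sg
import shapely.ops

from coilflow import GeometryParams, build_geometry, coil_mask


def _shapely_lumen(params: GeometryParams):
    """Independent oracle: the lumen as a shapely union of the channel
    rectangle and the two dome discs."""
    lx = params.grid_nx * params.dx
    rect = sg.box(0.0, 0.0, lx, params.channel_width)
    c1, c2 = params.dome_centers()
    discs = []
    if params.dome1_radius > 0:
        discs.append(sg.Point(c1).buffer(params.dome1_radius, quad_segs=512))
    if params.dome2_radius > 0:
        discs.append(sg.Point(c2).buffer(params.dome2_radius, quad_segs=512))
    return shapely.ops.unary_union([rect, *discs])


class TestBuildGeometry:
    def test_sdf_at_channel_centerline(self, coarse_geometry):
        # far from the sac the nearest wall is half a channel width away
        p = coarse_geometry.params
        val = coarse_geometry.level(np.array([2.0e-3]), np.array([p.channel_width / 2]))
        assert val[0] == pytest.approx(-p.channel_width / 2, abs=1e-15)

    def test_lumen_mask_is_negative_sdf(self, coarse_geometry):
        assert np.array_equal(coarse_geometry.lumen_mask, coarse_geometry.sdf < 0)

    def test_lumen_area_matches_analytic_union(self, default_params):
        geo = build_geometry(default_params)
        oracle = _shapely_lumen(default_params)
        pixel_area = geo.lumen_area()
        tol = 2.0 * oracle.boundary.length * default_params.dx
        assert abs(pixel_area - oracle.area) < tol

    def test_area_error_shrinks_with_dx(self, default_params):
        errs = []
        for ny in (52, 104):
            p = dataclasses.replace(default_params, grid_ny=ny, grid_nx=2 * ny,
                                    dx=13.0e-3 / ny)
            geo = build_geometry(p)
            errs.append(abs(geo.lumen_area() - _shapely_lumen(p).area))
        assert errs[1] < errs[0]

    def test_wall_chain_closed_and_simple(self, coarse_geometry):
        poly = sg.Polygon(coarse_geometry.wall_xy)
        assert poly.is_valid  # closed, non-self-intersecting

    def test_wall_chain_length_matches_perimeter(self, default_params):
        geo = build_geometry(default_params)  # dx = neck_width/12
        seg = np.diff(geo.wall_xy, axis=0, append=geo.wall_xy[:1])
        length = np.sum(np.linalg.norm(seg, axis=1))
        perimeter = _shapely_lumen(default_params).boundary.length
        assert abs(length - perimeter) / perimeter < 0.05

    def test_wall_points_on_zero_level_set(self, coarse_geometry):
        # the open inlet/outlet closure segments are not wall
        wall = coarse_geometry.wall_is_wall
        lev = coarse_geometry.level(coarse_geometry.wall_xy[wall, 0],
                                    coarse_geometry.wall_xy[wall, 1])
        assert np.max(np.abs(lev)) < coarse_geometry.dx

    def test_wall_normals_unit(self, coarse_geometry):
        norms = np.linalg.norm(coarse_geometry.wall_normals, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-12

    def test_wall_normals_point_into_lumen(self, coarse_geometry):
        probe = coarse_geometry.wall_xy + 1.5 * coarse_geometry.dx * coarse_geometry.wall_normals
        lev = coarse_geometry.level(probe[:, 0], probe[:, 1])
        wall = coarse_geometry.wall_is_wall
        assert np.mean(lev[wall] < 0) > 0.99

    def test_neck_endpoints_on_level_set(self, coarse_geometry):
        ends = coarse_geometry.neck_segment
        lev = coarse_geometry.level(ends[:, 0], ends[:, 1])
        assert np.max(np.abs(lev)) < coarse_geometry.dx

    def test_degenerate_domes_give_plain_channel(self, straight_geometry):
        p = straight_geometry.params
        yc = straight_geometry.y_centers
        expected = np.broadcast_to((yc < p.channel_width)[None, :],
                                   straight_geometry.lumen_mask.shape)
        assert np.array_equal(straight_geometry.lumen_mask, expected)
        assert straight_geometry.coil_mask.sum() == 0
        assert straight_geometry.sac_mask.sum() == 0

    def test_rejects_disconnected_domes(self, default_params):
        p = dataclasses.replace(default_params, dome_offset=8.0e-3)
        with pytest.raises(ValueError, match="overlap"):
            build_geometry(p)

    def test_rejects_underresolved_neck(self, default_params):
        p = dataclasses.replace(default_params, grid_ny=12, grid_nx=24, dx=13.0e-3 / 12)
        with pytest.raises(ValueError, match="coarse"):
            build_geometry(p)


class TestCoilMask:
    def test_empty_at_zero_fill(self, coarse_geometry):
        assert coil_mask(coarse_geometry, 0.0).coil_mask.sum() == 0

    def test_full_fill_covers_sac(self, coarse_geometry):
        gc = coil_mask(coarse_geometry, 1.0)
        assert np.array_equal(gc.coil_mask, gc.sac_mask)

    @pytest.mark.parametrize("frac", [0.25, 0.5, 0.75])
    def test_partial_fill_area(self, coarse_geometry, frac):
        gc = coil_mask(coarse_geometry, frac)
        n_sac = coarse_geometry.sac_mask.sum()
        assert gc.coil_mask.sum() == round(frac * n_sac)

    def test_fill_grows_from_dome_tip(self, coarse_geometry):
        # the half-filled coil occupies the distal part of the sac: every
        # coil cell is farther from the neck than every uncoiled sac cell
        gc = coil_mask(coarse_geometry, 0.5)
        w = coarse_geometry.params.channel_width
        ii, jj = np.nonzero(gc.coil_mask)
        y_coil_min = coarse_geometry.y_centers[jj].min()
        rest = gc.sac_mask & ~gc.coil_mask
        _, jj2 = np.nonzero(rest)
        y_rest_mean = coarse_geometry.y_centers[jj2].mean()
        assert y_coil_min > w  # coil confined to the sac
        assert coarse_geometry.y_centers[jj].mean() > y_rest_mean

    def test_coil_subset_of_lumen(self, coarse_geometry):
        gc = coil_mask(coarse_geometry, 1.0)
        assert not np.any(gc.coil_mask & ~gc.lumen_mask)

    def test_rejects_bad_fraction(self, coarse_geometry):
        with pytest.raises(ValueError):
            coil_mask(coarse_geometry, 1.2)
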