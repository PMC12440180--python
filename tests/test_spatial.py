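"""Polygon centroid, polar normalization and fraction-map contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomlearn.errors import GeometryError
from glomlearn.spatial import (
    bulb_centroid,
    bulb_geometry,
    fraction_responsive_map,
    polar_activation_map,
)


class TestBulbCentroid:
    def test_unit_square(self):
        c = bulb_centroid([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert c == pytest.approx((0.5, 0.5))

    def test_right_triangle_closed_form(self):
        c = bulb_centroid([(0, 0), (3, 0), (0, 3)])
        assert c == pytest.approx((1.0, 1.0))

    def test_area_centroid_not_vertex_mean(self):
        # densely sampled edge should not drag the centroid
        verts = [(0, 0), (0.25, 0), (0.5, 0), (0.75, 0), (1, 0), (1, 1), (0, 1)]
        c = bulb_centroid(verts)
        assert c == pytest.approx((0.5, 0.5))

    def test_irregular_hexagon_matches_monte_carlo(self):
        verts = np.array([(0, 0), (4, -1), (6, 2), (5, 5), (2, 6), (-1, 3)], float)
        cx, cy = bulb_centroid(verts)
        # rejection-sampling oracle
        import shapely
        from shapely.geometry import Polygon

        poly = Polygon(verts)
        rng = np.random.default_rng(0)
        xs = rng.uniform(-1, 6, 400_000)
        ys = rng.uniform(-1, 6, 400_000)
        inside = shapely.contains_xy(poly, xs, ys)
        assert cx == pytest.approx(xs[inside].mean(), abs=5e-3)
        assert cy == pytest.approx(ys[inside].mean(), abs=5e-3)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeometryError):
            bulb_centroid([(0, 0), (1, 1), (2, 2)])


def _geom():
    ang = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    boundary = np.column_stack([5 + 3 * np.cos(ang), 7 + 2 * np.sin(ang)])
    return bulb_geometry(boundary)


class TestPolarActivationMap:
    def test_point_at_centroid_has_zero_radius(self):
        geom = _geom()
        pts = pd.DataFrame({"roi_id": ["a", "b"],
                            "x": [geom.centroid[0], geom.centroid[0] + 2.0],
                            "y": [geom.centroid[1], geom.centroid[1]]})
        out = polar_activation_map(pts, geom)
        assert out.loc[out.roi_id == "a", "r_norm"].iloc[0] == 0.0

    def test_farthest_point_normalized_to_exactly_one(self):
        geom = _geom()
        rng = np.random.default_rng(1)
        pts = pd.DataFrame({"roi_id": [f"r{i}" for i in range(20)],
                            "x": rng.uniform(3, 7, 20),
                            "y": rng.uniform(5, 9, 20)})
        out = polar_activation_map(pts, geom)
        assert out["r_norm"].max() == 1.0
        assert (out["r_norm"] <= 1.0).all()

    def test_anterior_offset_maps_to_pi_over_two(self):
        geom = _geom()
        pts = pd.DataFrame({"roi_id": ["a", "far"],
                            "x": [geom.centroid[0], geom.centroid[0] + 3],
                            "y": [geom.centroid[1] + 1.5, geom.centroid[1]]})
        out = polar_activation_map(pts, geom)
        assert out.loc[out.roi_id == "a", "theta"].iloc[0] == pytest.approx(np.pi / 2)

    def test_empty_point_set_gives_empty_map(self):
        out = polar_activation_map(pd.DataFrame(columns=["roi_id", "x", "y"]), _geom())
        assert out.empty

    @given(dx=st.floats(-50, 50), dy=st.floats(-50, 50), s=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_r_norm_invariant_to_translation_and_uniform_scaling(self, dx, dy, s):
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        boundary = np.column_stack([np.cos(ang) * 3, np.sin(ang) * 2])
        rng = np.random.default_rng(9)
        pts = pd.DataFrame({"roi_id": range(10),
                            "x": rng.uniform(-1, 1, 10),
                            "y": rng.uniform(-1, 1, 10)})
        base = polar_activation_map(pts, bulb_geometry(boundary))
        moved = pts.copy()
        moved["x"] = pts["x"] * s + dx
        moved["y"] = pts["y"] * s + dy
        out = polar_activation_map(moved, bulb_geometry(boundary * s + [dx, dy]))
        assert np.allclose(out["r_norm"], base["r_norm"], atol=1e-9)

    @given(phi=st.floats(-3.0, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_theta_equivariant_under_frame_rotation(self, phi):
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        boundary = np.column_stack([np.cos(ang) * 3, np.sin(ang) * 3])
        rng = np.random.default_rng(4)
        xy = rng.uniform(-1, 1, (8, 2))
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        base = polar_activation_map(
            pd.DataFrame({"roi_id": range(8), "x": xy[:, 0], "y": xy[:, 1]}),
            bulb_geometry(boundary),
        )
        xy_r = xy @ rot.T
        out = polar_activation_map(
            pd.DataFrame({"roi_id": range(8), "x": xy_r[:, 0], "y": xy_r[:, 1]}),
            bulb_geometry(boundary @ rot.T),
        )
        dtheta = np.angle(np.exp(1j * (out["theta"] - base["theta"] - phi)))
        assert np.allclose(dtheta, 0.0, atol=1e-9)


class TestFractionResponsiveMap:
    def _summary(self, responsive):
        return pd.DataFrame(
            {"roi_id": [f"r{i}" for i in range(len(responsive))],
             "odor": "CS+", "responsive": responsive}
        )

    def _coords(self, xs, ys):
        return pd.DataFrame(
            {"roi_id": [f"r{i}" for i in range(len(xs))], "x": xs, "y": ys}
        )

    def test_all_responsive_fills_occupied_bins_with_one(self):
        out = fraction_responsive_map(
            self._summary([True] * 4), self._coords([0, 1, 9, 10], [0, 1, 9, 10]),
            bins=(2, 2),
        )
        assert (out["fraction"] == 1.0).all()

    def test_none_responsive_fills_occupied_bins_with_zero(self):
        out = fraction_responsive_map(
            self._summary([False] * 4), self._coords([0, 1, 9, 10], [0, 1, 9, 10]),
            bins=(2, 2),
        )
        assert (out["fraction"] == 0.0).all()

    def test_hand_placed_rois_give_half_in_both_bins(self):
        out = fraction_responsive_map(
            self._summary([True, False, True, False]),
            self._coords([1, 1, 9, 9], [1, 1, 1, 1]),
            bins=(2, 1), extent=(0, 10, 0, 2),
        )
        assert len(out) == 2
        assert (out["fraction"] == 0.5).all()

    def test_empty_bins_absent_rather_than_zero(self):
        out = fraction_responsive_map(
            self._summary([True, True]), self._coords([1, 1], [1, 1]),
            bins=(4, 4), extent=(0, 10, 0, 10),
        )
        assert len(out) == 1  # only the occupied bin appears
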