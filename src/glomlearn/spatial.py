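"""Bulb-centered polar activation maps and spatial responsiveness summaries.

Activation coordinates are re-centered on the area centroid of a manually
traced bulb boundary, converted to polar form, and the radius is normalized
to the farthest activation observed for that animal so maps are comparable
across animals. The axis convention is +x lateral, +y anterior, with the
angle measured counter-clockwise from +x in (-pi, pi].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .datatypes import BulbGeometry
from .errors import GeometryError

__all__ = [
    "bulb_centroid",
    "bulb_geometry",
    "polar_activation_map",
    "fraction_responsive_map",
]


def bulb_centroid(boundary) -> tuple[float, float]:
    """Area (shoelace) centroid of the traced boundary polygon.

    This is the centroid of the enclosed region, not the vertex mean, so
    unevenly spaced tracing points do not skew it.
    """
    verts = np.asarray(boundary, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise GeometryError("boundary needs at least 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise GeometryError("boundary polygon is degenerate")
    c = poly.centroid
    return float(c.x), float(c.y)


def bulb_geometry(boundary) -> BulbGeometry:
    """Boundary + centroid + maximum centroid-to-vertex radius."""
    cx, cy = bulb_centroid(boundary)
    verts = np.asarray(boundary, dtype=float)
    radius = float(np.hypot(verts[:, 0] - cx, verts[:, 1] - cy).max())
    return BulbGeometry(boundary=verts, centroid=(cx, cy), max_radius=radius)


def polar_activation_map(
    points: pd.DataFrame, geometry: BulbGeometry
) -> pd.DataFrame:
    """Normalized polar coordinates of activation points.

    Parameters
    ----------
    points
        Table with ``roi_id, x, y`` and optionally ``odor``.
    geometry
        Bulb geometry providing the centroid.

    Returns
    -------
    DataFrame with ``roi_id, r_norm, theta`` (+ ``odor`` if present).
    ``r_norm`` divides each centroid distance by the maximum distance in this
    point set, so the farthest activation sits exactly at 1; theta lies in
    (-pi, pi]. An empty input returns an empty table.
    """
    cols = ["roi_id", "r_norm", "theta"]
    has_odor = "odor" in points.columns
    if has_odor:
        cols.append("odor")
    if points.empty:
        return pd.DataFrame(columns=cols)
    dx = points["x"].to_numpy(float) - geometry.centroid[0]
    dy = points["y"].to_numpy(float) - geometry.centroid[1]
    r = np.hypot(dx, dy)
    rmax = r.max()
    r_norm = r / rmax if rmax > 0 else np.zeros_like(r)
    theta = np.arctan2(dy, dx)
    theta[theta == -np.pi] = np.pi  # range (-pi, pi]
    out = pd.DataFrame({"roi_id": points["roi_id"].to_numpy(),
                        "r_norm": r_norm, "theta": theta})
    if has_odor:
        out["odor"] = points["odor"].to_numpy()
    return out


def fraction_responsive_map(
    summaries: pd.DataFrame,
    coords: pd.DataFrame,
    bins: tuple[int, int] = (16, 16),
    extent: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Fraction of responsive ROIs per spatial bin.

    Parameters
    ----------
    summaries
        Response summary with ``roi_id`` and boolean ``responsive`` (rows for
        multiple odors are OR-ed per ROI).
    coords
        ``roi_id, x, y`` positions.
    bins
        Grid size ``(nx, ny)``.
    extent
        ``(xmin, xmax, ymin, ymax)``; defaults to the data range.

    Returns
    -------
    Long-format table ``ix, iy, n_rois, fraction`` listing occupied bins
    only — empty bins are absent rather than reported as 0.
    """
    resp = summaries.groupby("roi_id")["responsive"].any()
    merged = coords.merge(resp.rename("responsive"), on="roi_id")
    x = merged["x"].to_numpy(float)
    y = merged["y"].to_numpy(float)
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    xmin, xmax, ymin, ymax = extent
    nx, ny = bins
    if nx < 1 or ny < 1 or xmax <= xmin or ymax <= ymin:
        raise GeometryError("bin grid is degenerate")
    ix = np.clip(((x - xmin) / (xmax - xmin) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((y - ymin) / (ymax - ymin) * ny).astype(int), 0, ny - 1)
    df = pd.DataFrame({"ix": ix, "iy": iy,
                       "responsive": merged["responsive"].to_numpy()})
    grouped = df.groupby(["ix", "iy"])["responsive"].agg(["size", "mean"])
    grouped = grouped.rename(columns={"size": "n_rois", "mean": "fraction"})
    return grouped.reset_index()
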