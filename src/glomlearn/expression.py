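"""Transcript colocalization, TH density profiles, bias statistic, volumes.

Three families of quantification live here:

* **Pixel-proximity colocalization** between two transcripts: the directed
  count of Gene2 pixels within a fixed radius of each Gene1 pixel
  (one-to-many associations allowed), normalized by the geometric mean
  ``sqrt(n1 * n2)`` of the two genes' total pixel counts so the score is
  comparable across sections with different expression levels.
* **Zone density profiles and expression bias**: cell counts binned into
  ordered dorsal glomerular-layer zones tagged by the odor (CS+/CS-) whose
  responsive territory they cover, and the bias statistic
  ``(mean CS+ zones - mean CS- zones) / SD(all zones)`` computed on the
  per-animal zone vector (sections averaged first). Positive values mean
  expression is biased toward the rewarded odor's territory.
* **Frustum volume and soma density**: a glomerulus modeled as stacked
  conjoined frusta, ``V = sum (pi h / 3)(R^2 + R r + r^2)``, and TH+ soma
  density as total count across the z-stack divided by that volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .datatypes import DensityProfile, FrustumStack, PointMap
from .errors import DataError, GeometryError, ParameterError

__all__ = [
    "ColocResult",
    "colocalization_score",
    "zone_density_profile",
    "expression_bias",
    "frustum_volume",
    "glomerulus_th_density",
]


@dataclass
class ColocResult:
    gene_pair: tuple[str, str]
    radius: float
    raw_count: int
    normalized: float


def colocalization_score(
    point_map: PointMap, gene1: str, gene2: str, radius: float,
    symmetrize: bool = False,
) -> ColocResult:
    """Directed pixel-proximity colocalization of gene2 around gene1.

    ``raw_count`` sums, over every Gene1 pixel, the number of Gene2 pixels
    at Euclidean distance <= radius (inclusive; a pixel carrying both labels
    pairs with itself at distance 0). ``normalized = raw / sqrt(n1 * n2)``.

    The count is written directionally (gene2 neighbors around each gene1
    pixel) but equals the number of unordered (gene1, gene2) pixel pairs
    within the radius, so swapping the genes leaves both the raw and the
    normalized score unchanged. ``symmetrize=True`` averages the two
    directions anyway, as an explicit no-op guard for capped variants.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    p1 = point_map.coords(gene1)
    p2 = point_map.coords(gene2)
    if symmetrize:
        fwd = colocalization_score(point_map, gene1, gene2, radius)
        rev = colocalization_score(point_map, gene2, gene1, radius)
        return ColocResult(
            (gene1, gene2), radius,
            raw_count=(fwd.raw_count + rev.raw_count) // 2,
            normalized=(fwd.normalized + rev.normalized) / 2.0,
        )
    tree = cKDTree(p2)
    counts = tree.query_ball_point(p1, r=radius, return_length=True)
    raw = int(np.sum(counts))
    norm = raw / float(np.sqrt(len(p1) * len(p2)))
    return ColocResult((gene1, gene2), radius, raw, norm)


def zone_density_profile(
    point_map: PointMap, zones: list[Polygon] | list[np.ndarray],
    zone_tags, section_id: str = "section",
    label: str | None = None,
) -> DensityProfile:
    """Bin cell centroids into ordered zone polygons.

    Zones must be pairwise non-overlapping (shared boundaries allowed). A
    centroid lying exactly on a boundary is assigned to the lowest-indexed
    zone that covers it. ``label`` restricts to points with that label.

    Returns a :class:`DensityProfile` with per-zone counts and polygon areas
    (density = count/area downstream).
    """
    polys = [z if isinstance(z, Polygon) else Polygon(np.asarray(z, float))
             for z in zones]
    for p in polys:
        if not p.is_valid or p.area == 0:
            raise GeometryError("degenerate zone polygon")
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i].intersection(polys[j])
            if inter.area > 1e-9 * min(polys[i].area, polys[j].area):
                raise GeometryError(f"zones {i} and {j} overlap")
    pts = point_map.points
    if label is not None:
        pts = pts[pts["label"] == label]
    counts = np.zeros(len(polys))
    for x, y in pts[["x", "y"]].to_numpy(float):
        pt = Point(x, y)
        for i, poly in enumerate(polys):
            if poly.covers(pt):  # lowest index wins boundary ties
                counts[i] += 1
                break
    areas = np.array([p.area for p in polys])
    return DensityProfile(
        section_id=section_id, zone_counts=counts,
        zone_tags=tuple(zone_tags), zone_areas_um2=areas,
    )


def expression_bias(profiles: list[DensityProfile]) -> float:
    """Reward-odor expression bias from per-section zone vectors.

    Sections are averaged into one per-animal zone vector first; then

        bias = (mean over CS+ zones - mean over CS- zones) / SD(all zones)

    with the sample SD (ddof=1) over the zone vector. Positive = biased
    toward the CS+ (rewarded) territory. If the zone vector has zero SD the
    result is 0 when the CS+/CS- means are equal and NaN (undefined marker)
    otherwise.
    """
    if not profiles:
        raise DataError("need at least one density profile")
    tags = profiles[0].zone_tags
    if any(p.zone_tags != tags for p in profiles):
        raise DataError("all profiles must share the same zone ordering/tags")
    if "CS+" not in tags or "CS-" not in tags:
        raise DataError("need at least one CS+ and one CS- zone")
    if len(tags) < 2:
        raise DataError("need at least 2 zones")
    stack = np.vstack([p.values for p in profiles])
    zone_vector = stack.mean(axis=0)
    tags_arr = np.asarray(tags)
    diff = zone_vector[tags_arr == "CS+"].mean() - zone_vector[tags_arr == "CS-"].mean()
    sd = zone_vector.std(ddof=1)
    if sd == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / sd)


def frustum_volume(stack: FrustumStack) -> float:
    """Volume (um^3) of conjoined frusta: sum (pi h / 3)(R^2 + R r + r^2)."""
    total = 0.0
    for r_top, r_bot, h in stack.segments:
        total += (np.pi * h / 3.0) * (r_top**2 + r_top * r_bot + r_bot**2)
    return float(total)


def glomerulus_th_density(counts_per_section, volume_um3: float) -> float:
    """TH+ somata per um^3: total count across the z-stack over the volume."""
    counts = np.asarray(counts_per_section, dtype=float)
    if np.any(counts < 0):
        raise DataError("soma counts must be >= 0")
    if volume_um3 <= 0:
        raise GeometryError("volume must be > 0")
    return float(counts.sum() / volume_um3)
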