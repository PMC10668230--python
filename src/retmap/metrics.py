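"""Quantitative map measures: Map Quality, polarity, magnification, VFD, 1D profiles.

All global measures compare the visual-field lattice with the collicular
lattice of the largest ordered submap.  Field coordinates are first rotated
(default 20°) to account for the oblique projection of the nasotemporal axis
onto the rostrocaudal axis seen in wild-type maps.  With the conventions
used throughout this package, azimuth phase increases toward temporal retina
(nasal visual field) while the rostrocaudal coordinate increases caudally,
so a correctly ordered map has azimuth *decreasing* along the rostrocaudal
axis (nasal field maps to rostral colliculus after the retina->field flip)
and elevation increasing mediolaterally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .filtering import PixelMask
from .imaging import PhaseMap
from .lattice import LatticeMap

__all__ = [
    "MapMetrics",
    "map_quality",
    "polarity",
    "magnification",
    "vfd",
    "field_footprint",
    "profile_1d",
    "Profile1D",
]

#: sign of the expected field-axis vs collicular-axis correlation in an
#: ordered map, per axis pair (see module docstring)
EXPECTED_SIGN = {"RC": -1.0, "ML": +1.0}


@dataclass
class MapMetrics:
    """Summary measures for one (sub/part)map."""

    n_nodes_whole: int = 0
    n_nodes_submap: int = 0
    map_quality: float = np.nan     # %
    rc_polarity: float = np.nan     # %
    ml_polarity: float = np.nan     # %
    azimuthal_magnification: float = np.nan   # deg/mm
    elevational_magnification: float = np.nan # deg/mm
    vfd: float = np.nan             # % of field area
    rotation: float = 20.0          # deg

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def map_quality(whole: LatticeMap, submap: LatticeMap) -> float:
    """Percent of nodes retained in the largest ordered submap.

    The raw float is returned; report rounded to the nearest integer.
    """
    if whole.n_nodes == 0:
        raise ValueError("whole map has no nodes")
    if submap.n_nodes > whole.n_nodes:
        raise ValueError("submap has more nodes than the whole map")
    return 100.0 * submap.n_nodes / whole.n_nodes


def _rotated_field(lm: LatticeMap, rotation: float) -> np.ndarray:
    th = np.deg2rad(rotation)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    ctr = lm.vis_nodes.mean(axis=0)
    return (lm.vis_nodes - ctr) @ R.T + ctr


def polarity(lm: LatticeMap, axis: str = "RC", rotation: float = 20.0) -> float:
    """Percent of edges projecting in the correct relative order along an axis.

    100 = perfect order, 50 = random, 0 = perfectly reversed.  Edges with a
    zero component along either axis are excluded from the denominator.
    """
    if lm.n_edges == 0:
        raise ValueError("lattice has no edges")
    if axis not in EXPECTED_SIGN:
        raise ValueError("axis must be 'RC' or 'ML'")
    fld = _rotated_field(lm, rotation)
    k = 0 if axis == "RC" else 1  # azimuth vs RC(x), elevation vs ML(y)
    df = fld[lm.edges[:, 1], k] - fld[lm.edges[:, 0], k]
    dc = lm.coll_nodes[lm.edges[:, 1], k] - lm.coll_nodes[lm.edges[:, 0], k]
    use = (df != 0) & (dc != 0)
    if not use.any():
        raise ValueError("no edges with nonzero components along the axis")
    ok = np.sign(df[use] * dc[use]) == np.sign(EXPECTED_SIGN[axis])
    return 100.0 * float(np.mean(ok))


def magnification(lm: LatticeMap, axis: str = "azimuthal", rotation: float = 20.0,
                  delta_um: float = 80.0, min_frac: float = 0.1) -> float:
    """Median per-edge field-to-colliculus length ratio along an axis, deg/mm.

    Each edge contributes |rotated field component (deg)| / |collicular
    component (mm)|; edges whose collicular component is below
    ``min_frac``·Δ are excluded (the ratio blows up on near-degenerate
    edges) and the median is reported — a robust summary of the same
    per-edge comparison.
    """
    if axis not in ("azimuthal", "elevational"):
        raise ValueError("axis must be 'azimuthal' or 'elevational'")
    if lm.n_edges == 0:
        raise ValueError("lattice has no edges")
    fld = _rotated_field(lm, rotation)
    k = 0 if axis == "azimuthal" else 1
    df = np.abs(fld[lm.edges[:, 1], k] - fld[lm.edges[:, 0], k])
    dc_um = np.abs(lm.coll_nodes[lm.edges[:, 1], k] - lm.coll_nodes[lm.edges[:, 0], k])
    use = dc_um >= min_frac * delta_um
    if not use.any():
        raise ValueError("no edges with a usable collicular component")
    return float(np.median(df[use] / (dc_um[use] / 1000.0)))


def field_footprint(points: np.ndarray, alpha_radius: Optional[float] = None):
    """Concave footprint (alpha shape) of a set of visual-field nodes.

    Keeps Delaunay triangles with circumradius <= ``alpha_radius`` (default
    2x the median node spacing) and unions them; falls back to the convex
    hull for fewer than 10 nodes or a degenerate alpha complex.  Crescent-
    shaped caudal footprints are followed where a convex hull would
    overestimate.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return Polygon()
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    half_spacing = 0.5 * float(np.median(d[:, 1]))
    if len(points) < 10:
        if not isinstance(hull, Polygon):
            return Polygon()
        return hull.buffer(half_spacing)
    if alpha_radius is None:
        # 2x the upper-quartile nearest-neighbour spacing: tight enough to
        # follow crescent-shaped footprints, loose enough not to fragment
        # sparse (few-node) partmaps into slivers
        alpha_radius = 2.0 * float(np.percentile(d[:, 1], 75))
    try:
        tri = Delaunay(points)
    except Exception:
        return hull if isinstance(hull, Polygon) else Polygon()
    simp = tri.simplices
    a, b, c = points[simp[:, 0]], points[simp[:, 1]], points[simp[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = la * lb * lc / np.where(area2 > 0, 2 * area2, np.inf)
    keep = circum_r <= alpha_radius
    if not keep.any():
        shape = hull if isinstance(hull, Polygon) else Polygon()
    else:
        polys = [Polygon([tuple(a[i]), tuple(b[i]), tuple(c[i])]) for i in np.nonzero(keep)[0]]
        shape = unary_union(polys)
    # half-spacing support correction: node centres sample the interior of
    # the mapped region, so the raw shape underestimates it by about half a
    # node spacing all round
    return shape.buffer(half_spacing)


def vfd(rostral: LatticeMap, caudal: LatticeMap,
        alpha_radius: Optional[float] = None) -> float:
    """Visual field duplication: % of mapped field represented in both partmaps.

    The field footprint of each partmap is the alpha shape of its visual
    nodes; VFD = 100 · area(intersection) / area(union).  A partmap with
    fewer than 3 visual nodes has an empty footprint (VFD 0, with warning).
    """
    fr = field_footprint(rostral.vis_nodes, alpha_radius)
    fc = field_footprint(caudal.vis_nodes, alpha_radius)
    if fr.is_empty or fc.is_empty:
        warnings.warn("a partmap footprint is empty; VFD set to 0", stacklevel=2)
        return 0.0
    union = fr.union(fc).area
    if union <= 0:
        return 0.0
    return 100.0 * fr.intersection(fc).area / union


# ---------------------------------------------------------------------------
# 1D profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile1D:
    """Azimuth-vs-position samples along a straight collicular track."""

    track_origin_um: np.ndarray      # point on the fitted line
    track_dir: np.ndarray            # unit vector along the line
    angle_deg: float                 # track angle to the rostrocaudal axis
    arc_mm: np.ndarray               # arc length of sampled pixels along the track
    azimuth_deg: np.ndarray          # azimuth phase of the sampled pixels
    elevation_target: float          # requested field elevation (deg, centred)
    field_points: np.ndarray         # back-projected (azimuth, elevation) of track pixels

    def save_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.arc_mm, self.azimuth_deg]),
                   delimiter=",", header="arc_mm,azimuth_deg", comments="")


def profile_1d(pm: PhaseMap, mask: PixelMask, elevation: float = 0.0,
               tol: float = 2.5) -> Profile1D:
    """1D nasotemporal profile at a fixed field elevation.

    Finds the eligible pixels whose reported elevation is within ``tol``
    degrees of the target (given relative to the field centre), fits a
    straight line to their collicular positions (total least squares), and
    samples the azimuth phase of eligible pixels within one pixel-width of
    the line against arc length.
    """
    el_centered = pm.elevation - pm.elevation_span_deg / 2.0
    sel = mask.eligible & np.isfinite(el_centered) & (np.abs(el_centered - elevation) <= tol)
    ys, xs = np.nonzero(sel)
    if len(ys) < 2:
        raise ValueError("fewer than 2 eligible pixels at the requested elevation")
    pts = (np.column_stack([xs, ys]) + 0.5) * pm.pixel_size_um
    ctr = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - ctr, full_matrices=False)
    direction = vt[0] / np.linalg.norm(vt[0])
    angle = float(np.degrees(np.arctan2(direction[1], direction[0])))
    if angle > 90:
        angle -= 180
    elif angle < -90:
        angle += 180
    # eligible pixels within one pixel-width of the fitted line
    eys, exs = np.nonzero(mask.eligible & np.isfinite(pm.azimuth))
    epts = (np.column_stack([exs, eys]) + 0.5) * pm.pixel_size_um
    rel = epts - ctr
    along = rel @ direction
    perp = np.abs(rel[:, 0] * direction[1] - rel[:, 1] * direction[0])
    near = perp <= pm.pixel_size_um
    order = np.argsort(along[near])
    arc = along[near][order] / 1000.0
    azi = pm.azimuth[eys[near][order], exs[near][order]]
    fieldpts = np.column_stack([azi, el_centered[eys[near][order], exs[near][order]]])
    return Profile1D(ctr, direction, abs(angle), arc, azi, elevation, fieldpts)
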