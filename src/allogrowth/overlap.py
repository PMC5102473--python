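"""Species-level overlap diagnostics in the (log10 mass, log10 rate) plane.

Group-mean regression lines can be cleanly separated while the underlying
species cloud is not.  These tools quantify that: convex hulls of each
group's points, counts of every group's points inside every hull,
parallelograms bounded by extreme regression residuals (which contain the
hulls and so show even more overlap), nearest-regression-line assignment,
and pooled endotherm/ectotherm comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point

from .allometry import LogLogFit, RatePoint, fit_loglog, prediction_band

__all__ = [
    "HullPolygon",
    "Parallelogram",
    "convex_hull",
    "point_in_hull",
    "hull_membership_matrix",
    "residual_parallelogram",
    "nearest_line_classification",
    "pooled_overlap",
    "group_coordinates",
]

#: boundary tolerance in log10 units for point-in-polygon tests
BOUNDARY_TOL = 1e-9


@dataclass
class HullPolygon:
    """Convex hull of a group's points; may be a degenerate segment/point."""

    group: str
    vertices: np.ndarray  # (n, 2), counter-clockwise for true polygons
    degenerate: bool
    geometry: shapely.Geometry

    def contains(self, xy) -> bool:
        return point_in_hull(self, xy)


def group_coordinates(
    points: Sequence[RatePoint],
    dependent: str = "kC",
    independent: str = "M",
    include_excluded: bool = True,
) -> np.ndarray:
    """Log10 (mass, rate) coordinates for a group of points."""
    pts = [p for p in points if include_excluded or not p.excluded]
    return np.column_stack(
        [
            np.log10([p.mass(independent) for p in pts]),
            np.log10([p.rate(dependent) for p in pts]),
        ]
    )


def convex_hull(coords: np.ndarray, group: str = "") -> HullPolygon:
    """Smallest enclosing convex polygon of a planar point set.

    Collinear sets (or fewer than 3 points) give a degenerate hull whose
    geometry is a segment or a single point.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("need a non-empty (n, 2) coordinate array")
    geom = MultiPoint(coords).convex_hull
    if geom.geom_type == "Polygon":
        verts = np.asarray(geom.exterior.coords)[:-1]
        # shapely returns CW for convex_hull exteriors; normalise to CCW
        area = 0.5 * np.sum(
            verts[:, 0] * np.roll(verts[:, 1], -1)
            - np.roll(verts[:, 0], -1) * verts[:, 1]
        )
        if area < 0:
            verts = verts[::-1]
        return HullPolygon(group=group, vertices=verts, degenerate=False, geometry=geom)
    # LineString (collinear) or Point (all coincident)
    verts = np.asarray(geom.coords)
    return HullPolygon(group=group, vertices=verts, degenerate=True, geometry=geom)


def point_in_hull(hull: HullPolygon, xy) -> bool:
    """Membership test; boundary points (within tolerance) count as inside."""
    return hull.geometry.distance(Point(float(xy[0]), float(xy[1]))) <= BOUNDARY_TOL


def hull_membership_matrix(
    groups: Mapping[str, Sequence[RatePoint]],
    dependent: str = "kC",
    independent: str = "M",
    include_excluded: bool = True,
) -> pd.DataFrame:
    """Count each group's points inside each group's convex hull.

    Rows index the groups supplying data points, columns the groups
    supplying hulls; the diagonal necessarily equals the group sizes.
    """
    names = list(groups)
    coords = {
        g: group_coordinates(groups[g], dependent, independent, include_excluded)
        for g in names
    }
    hulls = {g: convex_hull(coords[g], g) for g in names}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for g_pts in names:
        for g_hull in names:
            geom = hulls[g_hull].geometry
            pts = shapely.points(coords[g_pts])
            dist = shapely.distance(geom, pts)
            mat.loc[g_pts, g_hull] = int(np.sum(dist <= BOUNDARY_TOL))
    return mat


@dataclass
class Parallelogram:
    """Regression-slope band through the extreme residuals of a group."""

    group: str
    slope: float
    intercept_range: tuple[float, float]
    x_range: tuple[float, float]

    @property
    def vertices(self) -> np.ndarray:
        (i_lo, i_hi), (x0, x1), b = self.intercept_range, self.x_range, self.slope
        return np.array(
            [
                [x0, i_lo + b * x0],
                [x1, i_lo + b * x1],
                [x1, i_hi + b * x1],
                [x0, i_hi + b * x0],
            ]
        )

    def contains(self, xy, tol: float = BOUNDARY_TOL) -> bool:
        x, y = float(xy[0]), float(xy[1])
        if not (self.x_range[0] - tol <= x <= self.x_range[1] + tol):
            return False
        i = y - self.slope * x
        return self.intercept_range[0] - tol <= i <= self.intercept_range[1] + tol


def residual_parallelogram(fit: LogLogFit, group: str = "") -> Parallelogram:
    """Parallelogram bounded by the regression line shifted through the
    largest positive and most negative residuals, over the data's x-range."""
    r_min, r_max = float(fit.residuals.min()), float(fit.residuals.max())
    return Parallelogram(
        group=group,
        slope=fit.slope,
        intercept_range=(fit.intercept + r_min, fit.intercept + r_max),
        x_range=(float(fit.x.min()), float(fit.x.max())),
    )


def nearest_line_classification(
    groups: Mapping[str, Sequence[RatePoint]],
    fits: Mapping[str, LogLogFit],
    dependent: str = "kC",
    independent: str = "M",
    distance: str = "perpendicular",
    include_excluded: bool = True,
) -> pd.DataFrame:
    """Assign each point to the group whose regression line is nearest.

    ``distance`` is perpendicular Euclidean distance in the log-log plane by
    default; ``"vertical"`` uses |y - (a + b x)|.  Ties go to the point's
    own group when it is among the tied lines, else to the first group in
    iteration order.  Returns a (point-group x nearest-line-group) count
    matrix whose row sums equal group sizes.
    """
    names = list(groups)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for g_pts in names:
        coords = group_coordinates(groups[g_pts], dependent, independent,
                                   include_excluded)
        for x, y in coords:
            dists = {}
            for g_line in names:
                f = fits[g_line]
                dy = abs(y - (f.intercept + f.slope * x))
                if distance == "perpendicular":
                    dists[g_line] = dy / np.hypot(1.0, f.slope)
                else:
                    dists[g_line] = dy
            dmin = min(dists.values())
            tied = [g for g in names if dists[g] <= dmin + 1e-12]
            winner = g_pts if g_pts in tied else tied[0]
            mat.loc[g_pts, winner] += 1
    return mat


def _hull_area_overlap(h1: HullPolygon, h2: HullPolygon, n_grid: int = 512) -> float:
    """Fraction of the smaller hull's area covered by the intersection,
    estimated on an n_grid x n_grid rasterisation of the joint bounding box."""
    if h1.degenerate or h2.degenerate:
        return 0.0
    xs = np.concatenate([h1.vertices[:, 0], h2.vertices[:, 0]])
    ys = np.concatenate([h1.vertices[:, 1], h2.vertices[:, 1]])
    gx = np.linspace(xs.min(), xs.max(), n_grid)
    gy = np.linspace(ys.min(), ys.max(), n_grid)
    X, Y = np.meshgrid(gx, gy)
    in1 = shapely.contains_xy(h1.geometry, X.ravel(), Y.ravel())
    in2 = shapely.contains_xy(h2.geometry, X.ravel(), Y.ravel())
    denom = min(in1.sum(), in2.sum())
    if denom == 0:
        return 0.0
    return float(np.sum(in1 & in2) / denom)


def pooled_overlap(
    points: Sequence[RatePoint],
    dependent: str = "kC",
    independent: str = "M",
    grid_size: int = 200,
) -> dict:
    """Pool points by thermoregulation label and quantify the overlap.

    Returns the endotherm/ectotherm hulls, their area-overlap fraction
    (relative to the smaller hull), per-pool regressions, and prediction
    bands on a shared mass grid.
    """
    pools: dict[str, list[RatePoint]] = {}
    for p in points:
        if p.thermo not in ("endotherm", "ectotherm"):
            raise ValueError(f"{p.taxon}: thermo label required for pooling")
        pools.setdefault(p.thermo, []).append(p)
    hulls = {
        t: convex_hull(group_coordinates(pts, dependent, independent), t)
        for t, pts in pools.items()
    }
    fits = {t: fit_loglog(pts, dependent, independent) for t, pts in pools.items()}
    all_x = np.concatenate([f.x for f in fits.values()])
    grid = np.linspace(all_x.min(), all_x.max(), grid_size)
    bands = {t: prediction_band(f, grid) for t, f in fits.items()}
    if len(hulls) == 2:
        h = list(hulls.values())
        frac = _hull_area_overlap(h[0], h[1])
    else:
        frac = np.nan
    band_overlap = None
    if len(bands) == 2:
        b1, b2 = bands.values()
        lo = np.maximum(b1.lower, b2.lower)
        hi = np.minimum(b1.upper, b2.upper)
        band_overlap = float(np.mean(hi > lo))
    return {
        "hulls": hulls,
        "fits": fits,
        "bands": bands,
        "hull_overlap_fraction": frac,
        "band_overlap_fraction": band_overlap,
    }
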