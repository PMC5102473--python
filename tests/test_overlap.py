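"""Convex hulls, membership matrices, parallelograms, nearest-line
classification, and pooled-group overlap."""

import numpy as np
import pytest

from allogrowth.allometry import fit_loglog
from allogrowth.overlap import (
    convex_hull,
    group_coordinates,
    hull_membership_matrix,
    nearest_line_classification,
    point_in_hull,
    pooled_overlap,
    residual_parallelogram,
)

from conftest import make_points


def brute_force_extreme_points(coords):
    """O(n^3) oracle: a point is a hull vertex iff it is NOT a convex
    combination of two others on a segment through it, i.e. iff it is an
    extreme point — tested by whether it lies strictly inside the hull of
    the rest via linear programming on triangles."""
    coords = np.asarray(coords, float)
    n = len(coords)
    extreme = []
    for i in range(n):
        p = coords[i]
        inside = False
        for j in range(n):
            for k in range(j + 1, n):
                for l in range(k + 1, n):
                    if i in (j, k, l):
                        continue
                    a, b, c = coords[j], coords[k], coords[l]
                    # barycentric coordinates of p in triangle abc
                    T = np.column_stack([b - a, c - a])
                    det = np.linalg.det(T)
                    if abs(det) < 1e-12:
                        continue
                    lam = np.linalg.solve(T, p - a)
                    if lam[0] > 1e-9 and lam[1] > 1e-9 and lam.sum() < 1 - 1e-9:
                        inside = True
                        break
                if inside:
                    break
            if inside:
                break
        if not inside:
            extreme.append(i)
    return {tuple(coords[i]) for i in extreme}


def point_in_polygon_oracle(poly, xy, tol=1e-9):
    """Ray-casting + boundary-distance oracle independent of shapely."""
    x, y = xy
    n = len(poly)
    # boundary proximity
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        ab = b - a
        t = np.clip(np.dot(xy - a, ab) / max(np.dot(ab, ab), 1e-300), 0, 1)
        if np.linalg.norm(a + t * ab - xy) <= tol:
            return True
    crossings = 0
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        if (a[1] > y) != (b[1] > y):
            xint = a[0] + (y - a[1]) * (b[0] - a[0]) / (b[1] - a[1])
            if xint > x:
                crossings += 1
    return crossings % 2 == 1


class TestConvexHull:
    def test_triangle_is_its_own_hull(self):
        pts = np.array([[0, 0], [1, 0], [0, 1]], float)
        hull = convex_hull(pts)
        assert not hull.degenerate
        assert {tuple(v) for v in hull.vertices} == {(0, 0), (1, 0), (0, 1)}

    def test_matches_brute_force_extreme_points(self, rng):
        coords = rng.uniform(0, 1, (25, 2))
        hull = convex_hull(coords)
        assert {tuple(v) for v in hull.vertices} == brute_force_extreme_points(
            coords
        )

    def test_collinear_degenerates_to_segment(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        hull = convex_hull(pts)
        assert hull.degenerate
        assert {tuple(v) for v in hull.vertices} == {(0.0, 0.0), (3.0, 3.0)}
        assert point_in_hull(hull, (1.5, 1.5))
        assert not point_in_hull(hull, (1.5, 1.6))

    def test_idempotent(self, rng):
        coords = rng.uniform(0, 1, (30, 2))
        h1 = convex_hull(coords)
        h2 = convex_hull(h1.vertices)
        assert {tuple(v) for v in h1.vertices} == {tuple(v) for v in h2.vertices}

    def test_ccw_orientation(self, rng):
        verts = convex_hull(rng.uniform(0, 1, (20, 2))).vertices
        area2 = np.sum(
            verts[:, 0] * np.roll(verts[:, 1], -1)
            - np.roll(verts[:, 0], -1) * verts[:, 1]
        )
        assert area2 > 0


class TestMembershipMatrix:
    def _random_groups(self, rng, n_groups=3, n=15):
        groups = {}
        for gi in range(n_groups):
            cx, cy = rng.uniform(0, 3, 2)
            x = rng.normal(cx, 0.8, n)
            y = rng.normal(cy, 0.8, n)
            groups[f"g{gi}"] = make_points(x, y, group=f"g{gi}",
                                           taxon_prefix=f"g{gi}_")
        return groups

    def test_diagonal_equals_group_sizes(self, default_groups):
        mat = hull_membership_matrix(default_groups)
        for g, pts in default_groups.items():
            assert mat.loc[g, g] == len(pts)

    def test_matches_point_in_polygon_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            groups = self._random_groups(rng)
            mat = hull_membership_matrix(groups)
            from allogrowth.overlap import convex_hull as ch

            for g_hull, pts_h in groups.items():
                poly = ch(group_coordinates(pts_h)).vertices
                if len(poly) < 3:
                    continue
                for g_pts, pts_p in groups.items():
                    coords = group_coordinates(pts_p)
                    count = sum(
                        point_in_polygon_oracle(poly, c) for c in coords
                    )
                    assert mat.loc[g_pts, g_hull] == count

    def test_disjoint_clusters_have_zero_off_diagonal(self):
        a = make_points([0.0, 0.1, 0.2, 0.1], [0.0, 0.2, 0.0, 0.1], group="a")
        b = make_points([5.0, 5.1, 5.2, 5.1], [5.0, 5.2, 5.0, 5.1], group="b")
        mat = hull_membership_matrix({"a": a, "b": b})
        assert mat.loc["a", "b"] == 0
        assert mat.loc["b", "a"] == 0

    def test_membership_monotone_in_added_points(self, rng):
        groups = self._random_groups(rng)
        mat0 = hull_membership_matrix(groups)
        extra = make_points([1.5], [1.5], group="g0", taxon_prefix="x")
        groups2 = dict(groups)
        groups2["g0"] = groups["g0"] + extra
        mat1 = hull_membership_matrix(groups2)
        # the enlarged hull's column never loses members
        assert (mat1["g0"] >= mat0["g0"]).all()


class TestParallelogram:
    def test_zero_height_for_exact_line(self):
        pts = make_points([0, 1, 2, 3], [0.5, 1.0, 1.5, 2.0])
        fit = fit_loglog(pts)
        para = residual_parallelogram(fit)
        lo, hi = para.intercept_range
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_contains_group_hull(self, default_groups):
        for g, pts in default_groups.items():
            fit = fit_loglog(pts)
            para = residual_parallelogram(fit, g)
            hull = convex_hull(group_coordinates(pts), g)
            for v in hull.vertices:
                assert para.contains(v, tol=1e-9)

    def test_counts_at_least_hull_counts(self, default_groups):
        """Containment implies parallelogram membership >= hull membership."""
        mat = hull_membership_matrix(default_groups)
        paras = {
            g: residual_parallelogram(fit_loglog(pts), g)
            for g, pts in default_groups.items()
        }
        for g_pts, pts in default_groups.items():
            coords = group_coordinates(pts)
            for g_hull, para in paras.items():
                count = sum(para.contains(c) for c in coords)
                assert count >= mat.loc[g_pts, g_hull]


class TestNearestLine:
    def test_single_group_all_own(self, default_groups):
        g = "mammals"
        sub = {g: default_groups[g]}
        fits = {g: fit_loglog(sub[g])}
        mat = nearest_line_classification(sub, fits)
        assert mat.loc[g, g] == len(sub[g])

    def test_horizontal_lines_simple_geometry(self):
        # two flat groups at y=0 and y=10; a probe point at y=2 in group "hi"
        lo = make_points([0, 1, 2, 3], [0, 0, 0, 0], group="lo",
                         taxon_prefix="lo")
        hi = make_points([0, 1, 2, 3], [1, 1, 1, 1], group="hi",
                         taxon_prefix="hi")
        probe = make_points([1.5], [0.2], group="hi", taxon_prefix="probe")
        groups = {"lo": lo, "hi": hi + probe}
        fits = {g: fit_loglog(p if g == "lo" else hi) for g, p in
                [("lo", lo), ("hi", hi)]}
        mat = nearest_line_classification(groups, fits)
        assert mat.loc["hi", "lo"] == 1  # the probe is nearer the lo line
        assert mat.loc["hi", "hi"] == 4

    def test_row_sums_equal_group_sizes(self, default_groups):
        fits = {g: fit_loglog(p) for g, p in default_groups.items()}
        mat = nearest_line_classification(default_groups, fits)
        for g, pts in default_groups.items():
            assert mat.loc[g].sum() == len(pts)


class TestPooledOverlap:
    def test_disjoint_pools_have_zero_overlap(self):
        endo = make_points([0, 1, 2, 0.5, 1.5], [10, 10.5, 11, 10.2, 10.8],
                           group="e")
        ecto = make_points([0, 1, 2, 0.5, 1.5], [0, 0.5, 1, 0.2, 0.8],
                           group="c")
        for p in endo:
            p.thermo = "endotherm"
        for p in ecto:
            p.thermo = "ectotherm"
        res = pooled_overlap(endo + ecto)
        assert res["hull_overlap_fraction"] == 0.0

    def test_identical_pools_fully_overlap(self, rng):
        x = rng.uniform(0, 3, 20)
        y = rng.normal(0, 1, 20)
        a = make_points(x, y, group="a", taxon_prefix="a")
        b = make_points(x, y, group="b", taxon_prefix="b")
        for p in a:
            p.thermo = "endotherm"
        for p in b:
            p.thermo = "ectotherm"
        res = pooled_overlap(a + b)
        assert res["hull_overlap_fraction"] == pytest.approx(1.0, abs=0.01)

    def test_default_scenario_shows_fallacy_geometry(self, default_points):
        """Hulls overlap while the pooled regressions stay separated."""
        res = pooled_overlap(default_points)
        assert res["hull_overlap_fraction"] > 0.05
        f_endo = res["fits"]["endotherm"]
        f_ecto = res["fits"]["ectotherm"]
        # regression intercepts separated by more than both CI half-widths
        assert f_endo.intercept > f_ecto.intercept + 0.3

    def test_missing_labels_rejected(self):
        pts = make_points([0, 1, 2], [0, 1, 2])
        with pytest.raises(ValueError, match="thermo"):
            pooled_overlap(pts)
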