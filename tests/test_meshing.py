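import math

import numpy as np
import pytest

import beamfab as bf
from beamfab.geometry import ContourError, MeshError
from beamfab.meshing import triangulate_polygon
from beamfab.synthetic import FixtureSpec

from conftest import circle_contour


def _circumcircle_violations(points, tris):
    """Brute-force Delaunay check for a constrained triangulation of a
    simple polygon: a vertex strictly inside a triangle's circumcircle
    only counts as a violation if it is visible from the triangle
    (the line of sight does not cross a constrained boundary edge)."""
    n = len(points)
    boundary = [(points[i], points[(i + 1) % n]) for i in range(n)]
    scale = float(np.ptp(points, axis=0).max())
    tol = 1e-9 * scale**4

    def incircle(pa, pb, pc, pd):
        m = np.array(
            [
                [pa[0] - pd[0], pa[1] - pd[1],
                 (pa[0] - pd[0]) ** 2 + (pa[1] - pd[1]) ** 2],
                [pb[0] - pd[0], pb[1] - pd[1],
                 (pb[0] - pd[0]) ** 2 + (pb[1] - pd[1]) ** 2],
                [pc[0] - pd[0], pc[1] - pd[1],
                 (pc[0] - pd[0]) ** 2 + (pc[1] - pd[1]) ** 2],
            ]
        )
        return np.linalg.det(m)

    def crosses(p, q, a, b):
        """Proper segment intersection (shared endpoints don't count)."""
        def orient(o, x, y):
            return (x[0] - o[0]) * (y[1] - o[1]) - (x[1] - o[1]) * (y[0] - o[0])

        d1, d2 = orient(a, b, p), orient(a, b, q)
        d3, d4 = orient(p, q, a), orient(p, q, b)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    violations = 0
    for t in tris:
        pa, pb, pc = points[t[0]], points[t[1]], points[t[2]]
        cen = (pa + pb + pc) / 3
        for j in range(n):
            if j in t:
                continue
            pd = points[j]
            if incircle(pa, pb, pc, pd) <= tol:
                continue
            if any(crosses(cen, pd, a, b) for a, b in boundary):
                continue  # occluded by a constrained edge
            violations += 1
    return violations


class TestTriangulatePolygon:
    def test_convex_cap_is_delaunay(self):
        c = circle_contour(10.0, n=60)
        tris = triangulate_polygon(c.points)
        assert len(tris) == 58  # n - 2 triangles for a simple polygon
        assert _circumcircle_violations(c.points, tris) == 0

    def test_nonconvex_cap_respects_constraints(self):
        small = bf.make_scalp_bolus(
            bf.FixtureSpec(params={
                "semi_axis_x_mm": 30.0, "semi_axis_y_mm": 24.0,
                "shell_thickness_mm": 8.0, "n_arc_points": 48,
                "perturbation_mm": 1.0,
            }),
            seed=5,
        )
        cap = bf.resample_contour(small.contours[0], 2.0)
        pts = cap.points if cap.is_ccw() else cap.points[::-1]
        assert len(pts) <= 200
        tris = triangulate_polygon(pts)
        assert len(tris) == len(pts) - 2
        # all triangle centroids inside the polygon
        from shapely.geometry import Point, Polygon

        poly = Polygon(pts)
        for t in tris:
            cen = pts[list(t)].mean(axis=0)
            assert poly.contains(Point(cen))
        assert _circumcircle_violations(pts, tris) == 0

    def test_collinear_vertices_yield_no_degenerate_triangles(self):
        sq = bf.resample_contour(
            bf.Contour(0.0, [[0, 0], [10, 0], [10, 10], [0, 10]]), 1.0
        )
        tris = triangulate_polygon(sq.points)
        areas = []
        for t in tris:
            a, b, c = sq.points[list(t)]
            u, v = b - a, c - a
            areas.append(abs(u[0] * v[1] - u[1] * v[0]) / 2)
        assert len(tris) == sq.n_points - 2
        assert min(areas) > 1e-9
        assert sum(areas) == pytest.approx(100.0, rel=1e-9)


class TestStackToMesh:
    def test_square_prism_volume(self, square_contour):
        s = bf.ContourStack(
            [
                bf.Contour(float(z), square_contour.points)
                for z in range(0, 11, 2)
            ]
        )
        m = bf.stack_to_mesh(s, 1.0)
        assert bf.mesh_volume(m) == pytest.approx(1000.0, rel=1e-3)

    def test_cone_frustum_volume(self, cone_stack):
        m = bf.stack_to_mesh(cone_stack, 0.5)
        analytic = math.pi * 20 / 3 * (10**2 + 10 * 0.5 + 0.5**2)
        assert bf.mesh_volume(m) == pytest.approx(analytic, rel=0.01)

    def test_bolus_mesh_is_watertight(self, bolus_mesh):
        rep = bf.validate_mesh(bolus_mesh)
        assert rep["watertight"] and rep["oriented"] and rep["outward"]
        assert rep["euler_characteristics"] == [2]
        assert not rep["degenerate_facets"]

    def test_refinement_convergence(self, cone_stack):
        v1 = bf.mesh_volume(bf.stack_to_mesh(cone_stack, 1.0))
        v2 = bf.mesh_volume(bf.stack_to_mesh(cone_stack, 0.5))
        assert abs(v2 / v1 - 1) < 0.005

    def test_single_slice_rejected(self, square_contour):
        with pytest.raises(ContourError):
            bf.stack_to_mesh(bf.ContourStack([square_contour]))

    def test_self_intersecting_contour_rejected(self):
        bowtie = bf.Contour(0.0, [[0, 0], [10, 10], [10, 0], [0, 10]])
        s = bf.ContourStack([bowtie, bf.Contour(2.0, bowtie.points)])
        with pytest.raises(ContourError, match="self-intersecting"):
            bf.stack_to_mesh(s)


class TestGridToMesh:
    def test_constant_thickness_box(self):
        g = bf.CompensatorGrid(
            np.full((11, 11), 20.0), pixel_spacing_mm=(2.0, 2.0)
        )
        m = bf.grid_to_mesh(g)
        assert bf.mesh_volume(m) == pytest.approx(20.0 * 20 * 20, rel=1e-9)
        rep = bf.validate_mesh(m)
        assert rep["watertight"] and rep["outward"]

    def test_linear_ramp_prismatoid_identity(self):
        ramp = np.tile(np.linspace(0.0, 10.0, 21), (21, 1))
        g = bf.CompensatorGrid(ramp, pixel_spacing_mm=(1.0, 1.0))
        m = bf.grid_to_mesh(g)
        footprint = 20.0 * 20.0
        assert bf.mesh_volume(m) == pytest.approx(5.0 * footprint, rel=1e-9)

    def test_random_field_volume_matches_per_triangle_oracle(
        self, compensator_grid
    ):
        m = bf.grid_to_mesh(compensator_grid)
        # oracle: sum over top triangles of mean vertex height x area
        g = compensator_grid
        h = g.thickness_mm
        sr, sc = g.pixel_spacing_mm
        total = 0.0
        for r in range(g.n_rows - 1):
            for c in range(g.n_cols - 1):
                cell = sr * sc / 2
                total += cell * (h[r, c] + h[r, c + 1] + h[r + 1, c + 1]) / 3
                total += cell * (h[r, c] + h[r + 1, c + 1] + h[r + 1, c]) / 3
        assert bf.mesh_volume(m) == pytest.approx(total, rel=1e-9)

    def test_beam_axis_flip_preserves_volume(self, compensator_grid):
        up = bf.grid_to_mesh(compensator_grid, beam_axis="+z")
        down = bf.grid_to_mesh(compensator_grid, beam_axis="-z")
        assert bf.mesh_volume(down) == pytest.approx(bf.mesh_volume(up))
        assert down.bounds()[1][2] == pytest.approx(0.0)

    def test_watertight(self, compensator_grid):
        rep = bf.validate_mesh(bf.grid_to_mesh(compensator_grid))
        assert rep["watertight"] and rep["oriented"] and rep["outward"]
        assert rep["euler_characteristics"] == [2]


class TestMeshToPrintable:
    def test_half_scale_stl_volume(self, compensator_grid, tmp_path):
        m = bf.grid_to_mesh(compensator_grid)
        out = tmp_path / "comp.stl"
        bf.mesh_to_printable(m, out, scale_factors=(0.5, 0.5, 0.5))
        back = bf.read_stl(out)
        assert bf.mesh_volume(back) == pytest.approx(
            0.125 * bf.mesh_volume(m), rel=1e-5
        )

    def test_round_trip_facet_count(self, bolus_mesh, tmp_path):
        out = tmp_path / "bolus.stl"
        bf.mesh_to_printable(bolus_mesh, out)
        assert bf.read_stl(out).n_facets == bolus_mesh.n_facets

    def test_open_mesh_refused_with_edge_list(self, cube_mesh, tmp_path):
        open_mesh = bf.TriangleMesh(cube_mesh.vertices, cube_mesh.facets[:-1])
        with pytest.raises(MeshError, match="open edges"):
            bf.mesh_to_printable(open_mesh, tmp_path / "bad.stl")
        bf.mesh_to_printable(open_mesh, tmp_path / "ok.stl", allow_open=True)
        assert (tmp_path / "ok.stl").exists()
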