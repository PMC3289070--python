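"""Delaunay/alpha-complex filtration, surface extraction and solid angles.

Closed-form values for regular simplices and brute-force oracles
(empty-circumsphere scan, Monte-Carlo ray sampling, convex-hull
comparison) check the geometric core.
"""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from alphadna import (
    alpha_complex,
    curvature_from_solid_angle,
    delaunay_3d,
    select_alpha,
    solid_angle,
    surface_atoms,
    vertex_degree,
)

from conftest import regular_tetrahedron

TETRA_VERTEX_ANGLE = 3.0 * math.acos(1.0 / 3.0) - math.pi  # ~0.55129 sr


def icosahedron(circumradius: float = 3.0) -> np.ndarray:
    phi = (1 + np.sqrt(5)) / 2
    raw = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            raw += [(0, a, b), (a, b, 0), (b, 0, a)]
    pts = np.array(raw)
    return pts * circumradius / np.linalg.norm(pts[0])


class TestDelaunay:
    def test_minimal_simplex_counts(self):
        tri = delaunay_3d(regular_tetrahedron())
        assert len(tri.tetrahedra) == 1
        assert len(tri.faces) == 4
        assert len(tri.edges) == 6

    def test_regular_tetrahedron_filtration_closed_forms(self):
        tri = delaunay_3d(regular_tetrahedron())
        assert tri.tet_filtration[0] == pytest.approx(3.0 / 8.0, abs=1e-12)
        assert tri.face_filtration == pytest.approx(np.full(4, 1.0 / 3.0), abs=1e-12)
        assert tri.edge_filtration == pytest.approx(np.full(6, 0.25), abs=1e-12)

    def test_unit_cube_tessellation_volume(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        tri = delaunay_3d(corners)
        vol = 0.0
        for tet in tri.tetrahedra:
            a, b, c, d = corners[tet]
            vol += abs(np.dot(b - a, np.cross(c - a, d - a))) / 6.0
        assert vol == pytest.approx(1.0, abs=1e-12)

    def test_empty_circumsphere_property_on_random_cloud(self):
        rng = np.random.default_rng(11)
        direction = rng.normal(size=(200, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        pts = direction * 10 * rng.random((200, 1)) ** (1 / 3)
        tri = delaunay_3d(pts)
        # brute force: no point strictly inside any tetrahedron circumsphere
        for tet, r2 in zip(tri.tetrahedra, tri.tet_filtration):
            a = pts[tet[0]]
            d = pts[tet[1:]] - a
            rhs = 0.5 * np.einsum("ij,ij->i", d, d)
            center = a + np.linalg.solve(d, rhs)
            d2 = np.einsum("nj,nj->n", pts - center, pts - center)
            d2[tet] = np.inf
            assert d2.min() >= r2 - 1e-7

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            delaunay_3d(np.zeros((3, 3)))
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            delaunay_3d(coplanar)


class TestAlphaComplex:
    def test_infinite_alpha_is_full_complex_with_hull_boundary(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(60, 3)) * 5
        tri = delaunay_3d(pts)
        shape = alpha_complex(tri, np.inf)
        assert len(shape.tetrahedra) == len(tri.tetrahedra)
        hull_vertices = set(ConvexHull(pts).vertices.tolist())
        assert set(surface_atoms(shape)) == hull_vertices
        # boundary facet area equals the hull area
        area = 0.0
        for f in shape.boundary_facets:
            a, b, c = pts[list(f)]
            area += 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        assert area == pytest.approx(ConvexHull(pts).area, rel=1e-9)

    def test_membership_thresholds_on_regular_tetrahedron(self):
        tri = delaunay_3d(regular_tetrahedron())
        below = alpha_complex(tri, 0.3)  # edges (0.25) in, faces (1/3) and tet (3/8) out
        assert len(below.tetrahedra) == 0
        assert len(below.complex_faces) == 0
        assert len(below.complex_edges) == 6
        above = alpha_complex(tri, 0.4)
        assert len(above.tetrahedra) == 1
        assert len(above.complex_faces) == 4

    def test_negative_alpha_errors(self):
        tri = delaunay_3d(regular_tetrahedron())
        with pytest.raises(ValueError):
            alpha_complex(tri, -0.1)

    def test_filtration_monotone_nesting(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 3)) * 4
        tri = delaunay_3d(pts)
        values = sorted(tri.tet_filtration)[:: max(1, len(tri.tet_filtration) // 6)]
        shapes = [alpha_complex(tri, a) for a in values]
        for small, big in zip(shapes, shapes[1:]):
            small_tets = {tuple(t) for t in small.tetrahedra.tolist()}
            big_tets = {tuple(t) for t in big.tetrahedra.tolist()}
            assert small_tets <= big_tets
            assert small.complex_edges <= big.complex_edges


class TestSelectAlpha:
    def test_single_tetrahedron(self):
        tri = delaunay_3d(regular_tetrahedron())
        assert select_alpha(tri) == pytest.approx(0.375, abs=1e-9)

    def test_two_clusters_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3)) + np.array([20.0, 0, 0])
        tri = delaunay_3d(np.vstack([a, b]))
        alpha = select_alpha(tri)

        def solid_ok(x):
            tets = tri.tetrahedra[tri.tet_filtration <= x]
            if len(tets) == 0:
                return False
            covered = set(tets.ravel().tolist())
            if len(covered) != tri.n_points:
                return False
            parent = {v: v for v in covered}

            def find(v):
                while parent[v] != v:
                    parent[v] = parent[parent[v]]
                    v = parent[v]
                return v

            for tet in tets:
                for v in tet[1:]:
                    parent[find(int(tet[0]))] = find(int(v))
            return len({find(v) for v in covered}) == 1

        candidates = sorted(tri.tet_filtration)
        expected = next(c for c in candidates if solid_ok(c))
        assert alpha == pytest.approx(expected, rel=1e-12)
        # monotonicity: strictly smaller alpha fails the condition
        smaller = [c for c in candidates if c < expected]
        if smaller:
            assert not solid_ok(smaller[-1])

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(50, 3)) * 6
        from scipy.spatial.transform import Rotation

        moved = pts @ Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix().T + 5.0
        assert select_alpha(delaunay_3d(pts)) == pytest.approx(
            select_alpha(delaunay_3d(moved)), abs=1e-9
        )


class TestSurfaceAndAngles:
    def test_all_four_tetrahedron_vertices_are_surface(self):
        tri = delaunay_3d(regular_tetrahedron())
        shape = alpha_complex(tri, 0.4)
        assert surface_atoms(shape) == {0, 1, 2, 3}

    def test_icosahedron_center_is_interior(self):
        pts = np.vstack([icosahedron(3.0), [[0, 0, 0]]])
        shape = alpha_complex(delaunay_3d(pts), np.inf)
        surf = surface_atoms(shape)
        assert surf == set(range(12))
        assert solid_angle(shape, 12) == pytest.approx(4 * math.pi, abs=1e-9)

    def test_dense_cloud_surface_equals_boundary_facet_scan(self):
        rng = np.random.default_rng(23)
        d = rng.normal(size=(150, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts = d * 8 * rng.random((150, 1)) ** (1 / 3)
        tri = delaunay_3d(pts)
        shape = alpha_complex(tri, select_alpha(tri))
        # brute force: count complex tets per face directly
        from itertools import combinations

        counts = {}
        for tet in shape.tetrahedra:
            for f in combinations(sorted(tet.tolist()), 3):
                counts[f] = counts.get(f, 0) + 1
        expected = {v for f, c in counts.items() if c == 1 for v in f}
        assert set(surface_atoms(shape)) == expected

    def test_empty_complex_errors(self):
        tri = delaunay_3d(regular_tetrahedron())
        with pytest.raises(ValueError):
            surface_atoms(alpha_complex(tri, 0.1))

    def test_regular_tetrahedron_vertex_solid_angle(self):
        tri = delaunay_3d(regular_tetrahedron())
        shape = alpha_complex(tri, np.inf)
        for v in range(4):
            assert solid_angle(shape, v) == pytest.approx(TETRA_VERTEX_ANGLE, abs=1e-9)
        total = sum(solid_angle(shape, v) for v in range(4))
        assert total < 4 * math.pi

    def test_solid_angle_matches_monte_carlo(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(4, 3))
        shape = alpha_complex(delaunay_3d(pts), np.inf)
        omega = solid_angle(shape, 0)
        # MC oracle: fraction of random rays from vertex 0 that enter the tet
        n = 1_000_000
        rays = rng.normal(size=(n, 3))
        rays /= np.linalg.norm(rays, axis=1, keepdims=True)
        # ray enters iff its direction is a positive combination of the edges
        edges = (pts[1:] - pts[0]).T  # 3x3
        coeffs = np.linalg.solve(edges[None, :, :], rays[:, :, None])[:, :, 0]
        frac = np.mean(np.all(coeffs > 0, axis=1))
        estimate = 4 * math.pi * frac
        sigma = 4 * math.pi * math.sqrt(frac * (1 - frac) / n)
        assert abs(omega - estimate) < 3 * sigma

    def test_solid_angle_errors_for_uncovered_vertex(self):
        tri = delaunay_3d(regular_tetrahedron())
        shape = alpha_complex(tri, 0.3)  # no tetrahedra
        with pytest.raises(ValueError):
            solid_angle(shape, 0)

    @pytest.mark.parametrize(
        "omega,kappa", [(0.0, 1.0), (2 * math.pi, 0.0), (4 * math.pi, -1.0)]
    )
    def test_curvature_endpoints(self, omega, kappa):
        assert curvature_from_solid_angle(omega) == pytest.approx(kappa, abs=1e-12)

    def test_curvature_domain(self):
        with pytest.raises(ValueError):
            curvature_from_solid_angle(-0.5)
        with pytest.raises(ValueError):
            curvature_from_solid_angle(4 * math.pi + 0.1)

    def test_vertex_degrees(self):
        tri = delaunay_3d(regular_tetrahedron())
        shape = alpha_complex(tri, np.inf)
        assert all(vertex_degree(shape, v) == 3 for v in range(4))

        pts = np.vstack([icosahedron(3.0), [[0, 0, 0]]])
        hull_shape = alpha_complex(delaunay_3d(pts), np.inf)
        assert all(vertex_degree(hull_shape, v) == 5 for v in range(12))
        with pytest.raises(ValueError):
            vertex_degree(hull_shape, 12)  # interior vertex

    def test_handshake_lemma(self):
        rng = np.random.default_rng(41)
        pts = rng.normal(size=(80, 3)) * 5
        tri = delaunay_3d(pts)
        shape = alpha_complex(tri, select_alpha(tri))
        degrees = sum(vertex_degree(shape, v) for v in surface_atoms(shape))
        assert degrees == 2 * len(shape.boundary_edges)
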