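"""Alpha-shape geometry of atomic point sets.

The alpha complex is the subcomplex of the 3-D Delaunay triangulation
whose simplices have an empty circumscribing sphere of squared radius
at most alpha.  The molecular surface is taken from the *regularized*
shape (the union of complex tetrahedra): boundary facets are triangles
incident to exactly one complex tetrahedron, surface atoms are their
vertices, and per-vertex solid angles — summed Van Oosterom–Strackee
angles of the incident complex tetrahedra — give a knob/cleft curvature
through kappa = cos(Omega/4).

Filtration values follow the standard convention: a tetrahedron's value
is its squared circumradius; a lower-dimensional simplex takes the
squared radius of its own smallest circumscribing sphere when that
sphere is empty (the Gabriel case) and otherwise inherits the smallest
filtration value among its cofacets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay as _SciDelaunay
from scipy.spatial import QhullError
from scipy.spatial import cKDTree as _cKDTree

__all__ = [
    "Triangulation",
    "AlphaShape",
    "delaunay_3d",
    "alpha_complex",
    "select_alpha",
    "surface_atoms",
    "solid_angle",
    "curvature_from_solid_angle",
    "vertex_degree",
]

_GABRIEL_TOL = 1e-9


@dataclass
class Triangulation:
    """3-D Delaunay triangulation with alpha-filtration values (A^2)."""

    points: np.ndarray                       # (n, 3)
    tetrahedra: np.ndarray                   # (m, 4) sorted vertex indices
    faces: np.ndarray                        # (f, 3)
    edges: np.ndarray                        # (e, 2)
    tet_filtration: np.ndarray               # (m,)
    face_filtration: np.ndarray              # (f,)
    edge_filtration: np.ndarray              # (e,)
    face_tets: dict[tuple[int, int, int], list[int]]
    _face_index: dict[tuple[int, int, int], int] = field(default_factory=dict)
    _edge_index: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def max_filtration(self) -> float:
        return float(self.tet_filtration.max())

    def filtration(self, simplex: tuple[int, ...]) -> float:
        """Filtration value of a simplex given as a vertex-index tuple."""
        s = tuple(sorted(simplex))
        if len(s) == 1:
            return 0.0
        if len(s) == 2:
            return float(self.edge_filtration[self._edge_index[s]])
        if len(s) == 3:
            return float(self.face_filtration[self._face_index[s]])
        if len(s) == 4:
            hit = np.all(self.tetrahedra == np.array(s), axis=1)
            idx = np.nonzero(hit)[0]
            if len(idx) == 0:
                raise KeyError(f"not a Delaunay tetrahedron: {s}")
            return float(self.tet_filtration[idx[0]])
        raise KeyError(f"not a simplex of the triangulation: {simplex}")


def _circumsphere_tetra(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised circumcenters and squared radii of (m,4,3) tetrahedra."""
    a = p[:, 0, :]
    d = p[:, 1:, :] - a[:, None, :]                      # (m,3,3)
    rhs = 0.5 * np.einsum("mij,mij->mi", d, d)           # (m,3)
    centers = a + np.linalg.solve(d, rhs[..., None])[..., 0]
    r2 = np.einsum("mi,mi->m", centers - a, centers - a)
    return centers, r2


def _min_sphere_face(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smallest circumscribing spheres of (f,3,3) triangles.

    The center is the triangle's circumcenter (in the triangle plane)
    and the squared radius its squared circumradius.
    """
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    n2 = np.einsum("fi,fi->f", n, n)
    ab2 = np.einsum("fi,fi->f", ab, ab)
    ac2 = np.einsum("fi,fi->f", ac, ac)
    num = np.cross(ab2[:, None] * ac - ac2[:, None] * ab, n)
    centers = a + num / (2.0 * n2)[:, None]
    r2 = np.einsum("fi,fi->f", centers - a, centers - a)
    return centers, r2


def _empty_sphere_mask(
    points: np.ndarray, simplices: np.ndarray, centers: np.ndarray, r2: np.ndarray
) -> np.ndarray:
    """For each simplex, True when its smallest sphere is empty of other points."""
    tree = _cKDTree(points)
    radii = np.sqrt(np.maximum(r2, 0.0)) + 1e-7
    hits = tree.query_ball_point(centers, radii)
    out = np.empty(len(simplices), dtype=bool)
    for i, near in enumerate(hits):
        own = set(int(v) for v in simplices[i])
        empty = True
        for j in near:
            if j in own:
                continue
            d2 = float(np.dot(points[j] - centers[i], points[j] - centers[i]))
            if d2 < r2[i] - _GABRIEL_TOL:
                empty = False
                break
        out[i] = empty
    return out


def delaunay_3d(points: np.ndarray) -> Triangulation:
    """Delaunay triangulation with alpha-filtration values for all simplices.

    Raises
    ------
    ValueError
        For fewer than 4 points or degenerate (coplanar/collinear) input.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(points) < 4:
        raise ValueError("need at least 4 points for a 3-D triangulation")
    try:
        tri = _SciDelaunay(points)
    except QhullError as exc:
        raise ValueError(f"degenerate point set: {exc}") from exc
    if tri.simplices.shape[1] != 4:
        raise ValueError("degenerate point set: coplanar input")
    tets = np.sort(tri.simplices, axis=1)
    # Qhull can emit slivers of essentially zero volume on near-degenerate
    # input; those have unstable circumspheres and are dropped.
    vol6 = np.einsum(
        "mi,mi->m",
        points[tets[:, 1]] - points[tets[:, 0]],
        np.cross(points[tets[:, 2]] - points[tets[:, 0]], points[tets[:, 3]] - points[tets[:, 0]]),
    )
    tets = tets[np.abs(vol6) > 1e-12]
    if len(tets) == 0:
        raise ValueError("degenerate point set: no proper tetrahedra")

    _, tet_r2 = _circumsphere_tetra(points[tets])

    face_tets: dict[tuple[int, int, int], list[int]] = {}
    for ti, tet in enumerate(tets):
        for f in combinations(tet, 3):
            face_tets.setdefault(tuple(int(v) for v in f), []).append(ti)
    faces = np.array(sorted(face_tets), dtype=int).reshape(-1, 3)
    face_index = {tuple(f): i for i, f in enumerate(faces.tolist())}

    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for e in combinations(f, 2):
            edge_faces.setdefault(tuple(int(v) for v in e), []).append(fi)
    edges = np.array(sorted(edge_faces), dtype=int).reshape(-1, 2)
    edge_index = {tuple(e): i for i, e in enumerate(edges.tolist())}

    # Faces: Gabriel faces keep their own squared circumradius, attached
    # faces inherit the smallest incident-tetrahedron value.
    f_centers, f_r2 = _min_sphere_face(points[faces])
    f_gabriel = _empty_sphere_mask(points, faces, f_centers, f_r2)
    face_filt = np.empty(len(faces))
    for fi, f in enumerate(faces.tolist()):
        inherited = min(tet_r2[ti] for ti in face_tets[tuple(f)])
        face_filt[fi] = f_r2[fi] if f_gabriel[fi] else inherited

    e_centers = 0.5 * (points[edges[:, 0]] + points[edges[:, 1]])
    e_r2 = 0.25 * np.einsum(
        "ei,ei->e", points[edges[:, 1]] - points[edges[:, 0]], points[edges[:, 1]] - points[edges[:, 0]]
    )
    e_gabriel = _empty_sphere_mask(points, edges, e_centers, e_r2)
    edge_filt = np.empty(len(edges))
    for ei, e in enumerate(edges.tolist()):
        inherited = min(face_filt[fi] for fi in edge_faces[tuple(e)])
        edge_filt[ei] = e_r2[ei] if e_gabriel[ei] else inherited

    return Triangulation(
        points=points,
        tetrahedra=tets,
        faces=faces,
        edges=edges,
        tet_filtration=tet_r2,
        face_filtration=face_filt,
        edge_filtration=edge_filt,
        face_tets=face_tets,
        _face_index=face_index,
        _edge_index=edge_index,
    )


@dataclass
class AlphaShape:
    """The alpha complex at a fixed alpha, with regularized boundary data."""

    alpha: float
    triangulation: Triangulation
    tetrahedra: np.ndarray                       # complex tetrahedra, (k, 4)
    complex_faces: set[tuple[int, int, int]]     # filtration-based membership
    complex_edges: set[tuple[int, int]]
    boundary_facets: set[tuple[int, int, int]]
    boundary_edges: set[tuple[int, int]]
    surface_vertices: frozenset[int]
    _vertex_tets: dict[int, list[int]] = field(default_factory=dict)

    def incident_tetrahedra(self, vertex: int) -> np.ndarray:
        idx = self._vertex_tets.get(int(vertex), [])
        return self.tetrahedra[idx] if idx else np.empty((0, 4), dtype=int)


def alpha_complex(tri: Triangulation, alpha: float) -> AlphaShape:
    """Alpha complex: simplices with filtration <= alpha.

    ``alpha = inf`` yields the full Delaunay complex, whose regularized
    boundary is the convex hull.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    in_tet = tri.tet_filtration <= alpha
    tets = tri.tetrahedra[in_tet]
    complex_faces = {
        tuple(f) for f, v in zip(tri.faces.tolist(), tri.face_filtration) if v <= alpha
    }
    complex_edges = {
        tuple(e) for e, v in zip(tri.edges.tolist(), tri.edge_filtration) if v <= alpha
    }

    counts: dict[tuple[int, int, int], int] = {}
    for tet in tets:
        for f in combinations(tet.tolist(), 3):
            counts[f] = counts.get(f, 0) + 1
    boundary_facets = {f for f, c in counts.items() if c == 1}
    boundary_edges = {e for f in boundary_facets for e in combinations(f, 2)}
    surface_vertices = frozenset(v for f in boundary_facets for v in f)

    vertex_tets: dict[int, list[int]] = {}
    for ti, tet in enumerate(tets):
        for v in tet.tolist():
            vertex_tets.setdefault(v, []).append(ti)

    return AlphaShape(
        alpha=float(alpha),
        triangulation=tri,
        tetrahedra=tets,
        complex_faces=complex_faces,
        complex_edges=complex_edges,
        boundary_facets=boundary_facets,
        boundary_edges=boundary_edges,
        surface_vertices=surface_vertices,
        _vertex_tets=vertex_tets,
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def select_alpha(tri: Triangulation) -> float:
    """Smallest alpha giving one solid connected component covering all points.

    Scans the tetrahedron filtration values in increasing order and
    returns the first value at which the regularized shape (complex
    tetrahedra only) is a single connected component whose vertex set
    is every input point.  The maximum filtration value always
    qualifies, so the scan terminates.
    """
    order = np.argsort(tri.tet_filtration, kind="stable")
    uf = _UnionFind(tri.n_points)
    covered = np.zeros(tri.n_points, dtype=bool)
    n_covered = 0
    n_components = 0
    values = tri.tet_filtration[order]
    i = 0
    m = len(order)
    while i < m:
        # add every tetrahedron sharing this filtration value
        v = values[i]
        while i < m and values[i] <= v:
            tet = tri.tetrahedra[order[i]]
            for x in tet.tolist():
                if not covered[x]:
                    covered[x] = True
                    n_covered += 1
                    n_components += 1
            for x in tet.tolist()[1:]:
                if uf.union(int(tet[0]), x):
                    n_components -= 1
            i += 1
        if n_covered == tri.n_points and n_components == 1:
            return float(v)
    return float(tri.max_filtration())


def surface_atoms(shape: AlphaShape) -> frozenset[int]:
    """Vertex indices on the regularized boundary (the surface atoms)."""
    if len(shape.tetrahedra) == 0:
        raise ValueError("alpha complex contains no tetrahedra")
    return shape.surface_vertices


def _tet_vertex_solid_angle(v: np.ndarray, others: np.ndarray) -> float:
    """Van Oosterom–Strackee solid angle at vertex ``v`` of one tetrahedron."""
    r = others - v
    n1, n2, n3 = np.linalg.norm(r, axis=1)
    num = abs(np.linalg.det(r))
    den = (
        n1 * n2 * n3
        + np.dot(r[0], r[1]) * n3
        + np.dot(r[0], r[2]) * n2
        + np.dot(r[1], r[2]) * n1
    )
    ang = 2.0 * np.arctan2(num, den)
    return float(ang if ang >= 0 else ang + 4.0 * np.pi)


def solid_angle(shape: AlphaShape, vertex: int) -> float:
    """Interior solid angle (steradians) covered by complex tetrahedra.

    0 for an infinitely sharp spike, 4*pi for a fully buried vertex.

    Raises
    ------
    ValueError
        If the vertex belongs to no complex tetrahedron.
    """
    tets = shape.incident_tetrahedra(vertex)
    if len(tets) == 0:
        raise ValueError(f"vertex {vertex} belongs to no complex tetrahedron")
    pts = shape.triangulation.points
    total = 0.0
    for tet in tets:
        others = np.array([x for x in tet if x != vertex], dtype=int)
        total += _tet_vertex_solid_angle(pts[vertex], pts[others])
    return min(total, 4.0 * np.pi)


def curvature_from_solid_angle(omega: float) -> float:
    """Map a solid angle to the knob/cleft curvature kappa = cos(Omega/4).

    Omega = 0 maps to +1 (knob), 2*pi to 0 (flat), 4*pi to -1 (cleft).
    """
    if not (-1e-9 <= omega <= 4.0 * np.pi + 1e-9):
        raise ValueError(f"solid angle {omega} outside [0, 4*pi]")
    return float(np.cos(np.clip(omega, 0.0, 4.0 * np.pi) / 4.0))


def vertex_degree(shape: AlphaShape, vertex: int) -> int:
    """Number of boundary edges linking a surface atom to other surface atoms."""
    if vertex not in shape.surface_vertices:
        raise ValueError(f"vertex {vertex} is not a surface atom")
    return sum(1 for e in shape.boundary_edges if vertex in e)
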