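"""3D cage meshes of icosahedral capsid lattices on the four Archimedean tilings.

The builder follows the canonical Caspar-Klug construction: the chosen planar
tiling is generated with unit edge length, clipped to the (h, k) facet
triangle whose corners sit on hexagon centres, replicated over the 20 faces
of an icosahedron, and welded into a closed polyhedral surface.  Hexagons
centred on the twelve five-fold vertices lose one wedge and collapse to
pentagons.  A ``sphericity`` parameter in [0, 1] linearly interpolates every
vertex radius between the flat-facet polyhedron (0) and the circumscribing
sphere (1).

Planar tilings
--------------
The hexagonal, trihexagonal and snub hexagonal tilings are all decorations of
the unit-edge triangular lattice: hexagon centres occupy the sublattice
spanned by the step vectors (1,1), (2,0) and (2,1) respectively (the snub
case is chiral: (1,2) gives the dextro form); each sublattice point carries a
hexagon through its six unit-lattice neighbours and every unit triangle not
incident to a sublattice point is kept as a minor-protein triangle.  The
rhombitrihexagonal tiling (lattice constant ``1 + sqrt(3)``) is decorated
directly with hexagons, edge squares and corner triangles.  The area of each
tiling's unit cell divided by the hexagon area reproduces the lattice area
factors 1, 4/3, 7/3 and ``4/3 + 2*sqrt(3)/3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry.polygon import orient as _shapely_orient

from .lattice import CapsidArchitecture, TilingClass, as_tiling, generalized_t

SQRT3 = math.sqrt(3.0)

_U1 = np.array([1.0, 0.0])
_U2 = np.array([0.5, SQRT3 / 2.0])
_R60 = np.array([[0.5, -SQRT3 / 2.0], [SQRT3 / 2.0, 0.5]])

#: hexagon-centre sublattice steps on the unit triangular lattice
_SUBLATTICE_STEP = {
    ("hexagonal", "none"): (1, 1),
    ("trihexagonal", "none"): (2, 0),
    ("snub_hexagonal", "laevo"): (2, 1),
    ("snub_hexagonal", "dextro"): (1, 2),
}

FACE_TYPES = ("pentagon", "hexagon", "triangle", "square")

_TYPE_BY_SIDES = {3: "triangle", 4: "square", 5: "pentagon", 6: "hexagon"}


@dataclass
class CageMesh:
    """A closed polygonal capsid cage.

    ``vertices`` is an (N, 3) float array; each entry of ``faces`` is a
    cyclically ordered tuple of vertex indices, counter-clockwise seen from
    outside, typed in ``face_types``.
    """

    vertices: np.ndarray
    faces: list[tuple[int, ...]]
    face_types: list[str]
    architecture: CapsidArchitecture | None
    sphericity: float
    radius: float
    is_dual: bool = False
    #: intrinsic (developable, sphericity-0) area of each face, set for primal
    #: cages; pentagons carry exactly 5/6 of a hexagon-equivalent area
    face_flat_areas: list[float] | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return len(edge_set(self))


def edge_set(mesh: CageMesh) -> set[tuple[int, int]]:
    """Undirected edges, each counted once across shared faces."""
    edges: set[tuple[int, int]] = set()
    for face in mesh.faces:
        for i, a in enumerate(face):
            b = face[(i + 1) % len(face)]
            edges.add((a, b) if a < b else (b, a))
    return edges


def euler_characteristic(mesh: CageMesh) -> int:
    return mesh.n_vertices - mesh.n_edges + mesh.n_faces


def is_closed(mesh: CageMesh) -> bool:
    """True when every edge is shared by exactly two faces."""
    count: dict[tuple[int, int], int] = {}
    for face in mesh.faces:
        for i, a in enumerate(face):
            b = face[(i + 1) % len(face)]
            key = (a, b) if a < b else (b, a)
            count[key] = count.get(key, 0) + 1
    return all(c == 2 for c in count.values())


def face_census(mesh: CageMesh) -> dict[str, int]:
    """Counts of faces by type; primal cages always carry exactly 12 pentagons."""
    census = {t: 0 for t in FACE_TYPES}
    for t in mesh.face_types:
        census[t] = census.get(t, 0) + 1
    return {t: n for t, n in census.items() if n}


def face_area(mesh: CageMesh, face_index: int) -> float:
    """Area of one (possibly non-planar) face via centroid fan triangulation."""
    pts = mesh.vertices[list(mesh.faces[face_index])]
    c = pts.mean(axis=0)
    total = 0.0
    for i in range(len(pts)):
        a, b = pts[i], pts[(i + 1) % len(pts)]
        total += 0.5 * np.linalg.norm(np.cross(a - c, b - c))
    return total


def surface_area(mesh: CageMesh) -> float:
    return sum(face_area(mesh, i) for i in range(mesh.n_faces))


def face_planarity(mesh: CageMesh, face_index: int) -> float:
    """Max deviation of a face's vertices from its best-fit plane (units of the mesh)."""
    pts = mesh.vertices[list(mesh.faces[face_index])]
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    normal = vt[-1]
    return float(np.abs((pts - c) @ normal).max())


# ---------------------------------------------------------------------------
# planar tilings


def _unit_lattice_tiling(step: tuple[int, int], window) -> list[tuple[str, np.ndarray]]:
    """Hexagon/triangle tilings decorated on the unit triangular lattice.

    ``step`` is the hexagon-centre sublattice vector in lattice coordinates.
    Returns a list of ``(face_type, (n, 2) CCW coordinate array)``.
    """
    p, q = step
    n_index = p * p + p * q + q * q

    def is_sub(i: int, j: int) -> bool:
        return ((p + q) * i + q * j) % n_index == 0 and (-q * i + p * j) % n_index == 0

    xmin, ymin, xmax, ymax = window
    hex_dirs = [np.array([math.cos(m * math.pi / 3.0), math.sin(m * math.pi / 3.0)]) for m in range(6)]
    polys: list[tuple[str, np.ndarray]] = []
    jmin = math.floor(ymin / (SQRT3 / 2.0)) - 2
    jmax = math.ceil(ymax / (SQRT3 / 2.0)) + 2
    for j in range(jmin, jmax + 1):
        imin = math.floor(xmin - 0.5 * j) - 2
        imax = math.ceil(xmax - 0.5 * j) + 2
        for i in range(imin, imax + 1):
            base = i * _U1 + j * _U2
            if is_sub(i, j):
                polys.append(("hexagon", np.array([base + d for d in hex_dirs])))
            # unit up-triangle (i,j), (i+1,j), (i,j+1)
            if not (is_sub(i, j) or is_sub(i + 1, j) or is_sub(i, j + 1)):
                polys.append(("triangle", np.array([base, base + _U1, base + _U2])))
            # unit down-triangle (i+1,j), (i+1,j+1), (i,j+1)
            if not (is_sub(i + 1, j) or is_sub(i + 1, j + 1) or is_sub(i, j + 1)):
                polys.append(("triangle", np.array([base + _U1, base + _U1 + _U2, base + _U2])))
    return polys


def _rhombitrihexagonal_tiling(window) -> list[tuple[str, np.ndarray]]:
    """The 3.4.6.4 tiling: hexagons on a ``1 + sqrt(3)`` lattice, squares on
    lattice edges, triangles at triangle centroids; unit edge everywhere."""
    a = 1.0 + SQRT3
    A1, A2 = a * _U1, a * _U2
    xmin, ymin, xmax, ymax = window
    hex_verts = [
        np.array([math.cos(math.radians(30 + 60 * m)), math.sin(math.radians(30 + 60 * m))])
        for m in range(6)
    ]

    def triangle_at(corners: list[np.ndarray]) -> np.ndarray:
        g = sum(corners) / 3.0
        return np.array([c + (g - c) / np.linalg.norm(g - c) for c in corners])

    polys: list[tuple[str, np.ndarray]] = []
    nmin = math.floor(ymin / (a * SQRT3 / 2.0)) - 2
    nmax = math.ceil(ymax / (a * SQRT3 / 2.0)) + 2
    for n in range(nmin, nmax + 1):
        mmin = math.floor(xmin / a - 0.5 * n) - 2
        mmax = math.ceil(xmax / a - 0.5 * n) + 2
        for m in range(mmin, mmax + 1):
            L = m * A1 + n * A2
            polys.append(("hexagon", np.array([L + v for v in hex_verts])))
            for direction in (A1, A2, A2 - A1):
                u = direction / a
                nvec = np.array([-u[1], u[0]])
                c0 = L + (SQRT3 / 2.0) * u
                polys.append(
                    ("square", np.array([c0 - nvec / 2, c0 + u - nvec / 2, c0 + u + nvec / 2, c0 + nvec / 2]))
                )
            polys.append(("triangle", triangle_at([L, L + A1, L + A2])))
            polys.append(("triangle", triangle_at([L + A1, L + A1 + A2, L + A2])))
    return polys


def _planar_tiling(tiling: TilingClass, window) -> tuple[list[tuple[str, np.ndarray]], np.ndarray]:
    """Tiling polygons covering ``window`` plus the hexagon-centre lattice vector ``c1``."""
    if tiling.label == "rhombitrihexagonal":
        return _rhombitrihexagonal_tiling(window), (1.0 + SQRT3) * _U1
    step = _SUBLATTICE_STEP[(tiling.label, tiling.chirality)]
    c1 = step[0] * _U1 + step[1] * _U2
    return _unit_lattice_tiling(step, window), c1


# ---------------------------------------------------------------------------
# clipping to the Caspar-Klug facet triangle


def _point_line_distance(pt: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    r = pt - a
    return abs(float(d[0] * r[1] - d[1] * r[0])) / float(np.hypot(d[0], d[1]))


@dataclass
class _Fragment:
    source: int
    ftype: str
    coords: np.ndarray  # (n, 2) CCW
    area2d: float = 0.0
    cut: list[bool] = field(default_factory=list)  # per edge i -> i+1


def _clip_fragments(
    polys: list[tuple[str, np.ndarray]],
    corners: list[np.ndarray],
    tol: float = 1e-7,
) -> list[_Fragment]:
    tri = _ShapelyPolygon([tuple(c) for c in corners])
    sides = [(corners[i], corners[(i + 1) % 3]) for i in range(3)]
    fragments: list[_Fragment] = []
    txmin, tymin, txmax, tymax = tri.bounds
    for source, (ftype, coords) in enumerate(polys):
        if (
            coords[:, 0].max() < txmin - tol
            or coords[:, 0].min() > txmax + tol
            or coords[:, 1].max() < tymin - tol
            or coords[:, 1].min() > tymax + tol
        ):
            continue
        source_poly = _ShapelyPolygon(coords)
        inter = tri.intersection(source_poly)
        if inter.is_empty:
            continue
        source_ring = source_poly.exterior
        pieces = inter.geoms if inter.geom_type in ("MultiPolygon", "GeometryCollection") else [inter]
        for piece in pieces:
            if piece.geom_type != "Polygon" or piece.area < 1e-9:
                continue
            ring = np.asarray(_shapely_orient(piece, 1.0).exterior.coords[:-1])
            keep = [
                i for i in range(len(ring)) if np.linalg.norm(ring[i] - ring[i - 1]) > 1e-9
            ]
            ring = ring[keep]
            if len(ring) < 3:
                continue
            frag = _Fragment(source=source, ftype=ftype, coords=ring, area2d=float(piece.area))
            for i in range(len(ring)):
                a, b = ring[i], ring[(i + 1) % len(ring)]
                mid = 0.5 * (a + b)
                on_boundary = any(
                    _point_line_distance(a, *s) < tol
                    and _point_line_distance(b, *s) < tol
                    and _point_line_distance(mid, *s) < tol
                    for s in sides
                )
                if on_boundary:
                    # a genuine tiling edge may run along the facet boundary
                    # (h = k lattices inscribe hexagons in the facet triangle);
                    # only clipping-introduced edges count as cuts
                    on_source = (
                        source_ring.distance(_ShapelyPoint(a)) < tol
                        and source_ring.distance(_ShapelyPoint(b)) < tol
                        and source_ring.distance(_ShapelyPoint(mid)) < tol
                    )
                    frag.cut.append(not on_source)
                else:
                    frag.cut.append(False)
            fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# icosahedron scaffold


def icosahedron(radius: float = 1.0) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Regular icosahedron with circumradius ``radius``, two opposite vertices
    on the z axis, faces counter-clockwise from outside; deterministic."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            raw.append((0.0, s1 * 1.0, s2 * phi))
            raw.append((s1 * 1.0, s2 * phi, 0.0))
            raw.append((s1 * phi, 0.0, s2 * 1.0))
    verts = np.array(sorted(set(raw)))
    verts = verts / np.linalg.norm(verts[0]) * radius
    # rotate (0, 1, phi) direction onto +z
    t = math.atan2(1.0, phi)
    rot = np.array(
        [[1.0, 0.0, 0.0], [0.0, math.cos(t), -math.sin(t)], [0.0, math.sin(t), math.cos(t)]]
    )
    verts = verts @ rot.T
    hull = ConvexHull(verts)
    faces = []
    for simplex in hull.simplices:
        a, b, c = (int(i) for i in simplex)
        normal = np.cross(verts[b] - verts[a], verts[c] - verts[a])
        centroid = (verts[a] + verts[b] + verts[c]) / 3.0
        if np.dot(normal, centroid) < 0:
            b, c = c, b
        # canonical rotation: smallest index first
        tri = (a, b, c)
        shift = tri.index(min(tri))
        faces.append(tri[shift:] + tri[:shift])
    faces.sort()
    return verts, faces


# ---------------------------------------------------------------------------
# assembly


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_cage(
    arch: CapsidArchitecture,
    sphericity: float = 0.0,
    radius: float = 1.0,
    chirality: str | None = None,
) -> CageMesh:
    """Build the closed 3D cage mesh for a capsid architecture.

    Parameters
    ----------
    arch:
        Architecture from :func:`capsidkit.lattice.generalized_t`.
    sphericity:
        0 places every vertex on the flat icosahedron facets; 1 projects all
        vertices onto the circumscribing sphere; intermediate values
        interpolate each vertex radius linearly.
    radius:
        Circumradius of the cage (dimensionless by default; nm in practice).
    chirality:
        Override the snub-lattice handedness (``laevo``/``dextro``).
    """
    if not 0.0 <= sphericity <= 1.0:
        raise ValueError("sphericity must lie in [0, 1]")
    if not radius > 0.0:
        raise ValueError("radius must be positive")
    tiling = arch.tiling
    if chirality is not None:
        if tiling.label != "snub_hexagonal":
            raise ValueError("chirality only applies to the snub hexagonal lattice")
        tiling = TilingClass(tiling.label, tiling.area_factor, chirality)

    # Caspar-Klug triangle: corners at hexagon centres 0, h*c1 + k*c2, rot60 thereof
    probe_window = (-1.0, -1.0, 1.0, 1.0)
    if tiling.label == "rhombitrihexagonal":
        c1 = (1.0 + SQRT3) * _U1
    else:
        p, q = _SUBLATTICE_STEP[(tiling.label, tiling.chirality)]
        c1 = p * _U1 + q * _U2
    c2 = _R60 @ c1
    p0 = np.zeros(2)
    p1 = arch.h * c1 + arch.k * c2
    p2 = _R60 @ p1
    corners = [p0, p1, p2]
    allpts = np.array(corners)
    window = (
        allpts[:, 0].min() - 3.0,
        allpts[:, 1].min() - 3.0,
        allpts[:, 0].max() + 3.0,
        allpts[:, 1].max() + 3.0,
    )
    polys, _ = _planar_tiling(tiling, window)
    fragments = _clip_fragments(polys, corners)
    if not fragments:  # pragma: no cover - defensive
        raise RuntimeError("tiling clipping produced no fragments")

    ico_verts, ico_faces = icosahedron(radius)
    side2d = float(np.linalg.norm(p1))
    basis = np.column_stack([p1 - p0, p2 - p0])
    basis_inv = np.linalg.inv(basis)

    raw_points: list[np.ndarray] = []
    instances: list[tuple[list[int], list[bool], str, float]] = []
    for a_i, b_i, c_i in ico_faces:
        A, B, C = ico_verts[a_i], ico_verts[b_i], ico_verts[c_i]
        for frag in fragments:
            st = (basis_inv @ (frag.coords - p0).T).T  # (n, 2) barycentric-ish
            pts3 = A[None, :] + st[:, :1] * (B - A)[None, :] + st[:, 1:2] * (C - A)[None, :]
            idx = list(range(len(raw_points), len(raw_points) + len(pts3)))
            raw_points.extend(pts3)
            instances.append((idx, frag.cut, frag.ftype, frag.area2d))

    pts = np.asarray(raw_points)
    edge3d = float(np.linalg.norm(ico_verts[ico_faces[0][1]] - ico_verts[ico_faces[0][0]])) / side2d
    weld_tol = 1e-6 * edge3d
    tree = cKDTree(pts)
    uf = _UnionFind(len(pts))
    for i, j in tree.query_pairs(weld_tol):
        uf.union(i, j)
    root_to_vid: dict[int, int] = {}
    vid_of = np.empty(len(pts), dtype=int)
    welded: list[np.ndarray] = []
    for i in range(len(pts)):
        r = uf.find(i)
        if r not in root_to_vid:
            root_to_vid[r] = len(welded)
            welded.append(pts[r])
        vid_of[i] = root_to_vid[r]
    vertices = np.asarray(welded)

    # fragment loops in welded ids
    loops: list[tuple[list[int], list[bool], str, float]] = []
    for idx, cut, ftype, area2d in instances:
        ids = [int(vid_of[i]) for i in idx]
        keep_ids: list[int] = []
        keep_cut: list[bool] = []
        for i in range(len(ids)):
            if ids[i] != ids[(i + 1) % len(ids)]:
                keep_ids.append(ids[i])
                keep_cut.append(cut[i])
        if len(keep_ids) >= 3:
            loops.append((keep_ids, keep_cut, ftype, area2d))

    # merge fragments across facet boundaries via shared cut edges
    fuf = _UnionFind(len(loops))
    cut_edge_owner: dict[tuple[int, int], int] = {}
    for li, (ids, cut, _, _a) in enumerate(loops):
        for i, is_cut in enumerate(cut):
            if not is_cut:
                continue
            a, b = ids[i], ids[(i + 1) % len(ids)]
            key = (a, b) if a < b else (b, a)
            if key in cut_edge_owner:
                fuf.union(cut_edge_owner[key], li)
            else:
                cut_edge_owner[key] = li

    groups: dict[int, list[int]] = {}
    for li in range(len(loops)):
        groups.setdefault(fuf.find(li), []).append(li)

    area_scale = edge3d * edge3d  # 2D tiling area -> 3D facet area
    faces: list[tuple[int, ...]] = []
    flat_areas: list[float] = []
    for members in groups.values():
        directed: dict[tuple[int, int], int] = {}
        flat_areas.append(area_scale * sum(loops[li][3] for li in members))
        for li in members:
            ids = loops[li][0]
            for i in range(len(ids)):
                a, b = ids[i], ids[(i + 1) % len(ids)]
                if directed.get((b, a), 0) > 0:
                    directed[(b, a)] -= 1
                else:
                    directed[(a, b)] = directed.get((a, b), 0) + 1
        succ: dict[int, int] = {}
        for (a, b), n in directed.items():
            for _ in range(n):
                if a in succ:  # pragma: no cover - defensive
                    raise RuntimeError("non-simple merged face boundary")
                succ[a] = b
        if not succ:  # pragma: no cover - defensive
            raise RuntimeError("merged face lost its boundary")
        start = min(succ)
        loop = [start]
        nxt = succ[start]
        while nxt != start:
            loop.append(nxt)
            nxt = succ[nxt]
        if len(loop) != len(succ):  # pragma: no cover - defensive
            raise RuntimeError("merged face boundary split into several loops")
        faces.append(tuple(loop))

    # suppress degree-2 bend vertices (crossings of tiling edges with facet edges)
    incident: dict[int, set[int]] = {}
    for fi, face in enumerate(faces):
        for v in face:
            incident.setdefault(v, set()).add(fi)
    keep_vertex = {v for v, fs in incident.items() if len(fs) >= 3}
    faces = [tuple(v for v in face if v in keep_vertex) for face in faces]
    if any(len(face) < 3 for face in faces):  # pragma: no cover - defensive
        raise RuntimeError("face degenerated after bend-vertex suppression")

    used = sorted({v for face in faces for v in face})
    remap = {v: i for i, v in enumerate(used)}
    vertices = vertices[used]
    faces = [tuple(remap[v] for v in face) for face in faces]
    face_types = [_TYPE_BY_SIDES.get(len(face), f"{len(face)}-gon") for face in faces]

    vertices = _apply_sphericity(vertices, sphericity, radius)
    return CageMesh(
        vertices=vertices,
        faces=faces,
        face_types=face_types,
        architecture=arch,
        sphericity=sphericity,
        radius=radius,
        is_dual=False,
        face_flat_areas=flat_areas,
    )


def _apply_sphericity(vertices: np.ndarray, sphericity: float, radius: float) -> np.ndarray:
    r0 = np.linalg.norm(vertices, axis=1)
    target = (1.0 - sphericity) * r0 + sphericity * radius
    return vertices * (target / r0)[:, None]


def build_cage_hk(
    h: int,
    k: int,
    tiling,
    sphericity: float = 0.0,
    radius: float = 1.0,
    chirality: str | None = None,
) -> CageMesh:
    """Convenience wrapper: build a cage straight from (h, k, lattice)."""
    return build_cage(generalized_t(h, k, as_tiling(tiling)), sphericity, radius, chirality)


def dual_mesh(mesh: CageMesh) -> CageMesh:
    """Laves-lattice dual: one vertex per face (centroid, radially placed per
    the parent's sphericity) and one face per vertex."""
    f = mesh.sphericity
    cents = np.array([mesh.vertices[list(face)].mean(axis=0) for face in mesh.faces])
    r0 = np.linalg.norm(cents, axis=1)
    target = (1.0 - f) * r0 + f * mesh.radius
    dual_vertices = cents * (target / r0)[:, None]

    owner: dict[tuple[int, int], int] = {}
    nxt: dict[tuple[int, int], int] = {}
    for fi, face in enumerate(mesh.faces):
        for i, a in enumerate(face):
            b = face[(i + 1) % len(face)]
            owner[(a, b)] = fi
            nxt[(fi, a)] = b
    vertex_faces: dict[int, int] = {}
    for fi, face in enumerate(mesh.faces):
        for v in face:
            vertex_faces.setdefault(v, fi)

    dual_faces: list[tuple[int, ...]] = []
    for v in sorted(vertex_faces):
        start = vertex_faces[v]
        cycle = [start]
        current = start
        while True:
            u = nxt[(current, v)]
            current = owner[(u, v)]
            if current == start:
                break
            cycle.append(current)
        dual_faces.append(tuple(cycle))

    # enforce outward counter-clockwise orientation via Newell normals
    oriented: list[tuple[int, ...]] = []
    for face in dual_faces:
        pts = dual_vertices[list(face)]
        normal = np.zeros(3)
        for i in range(len(pts)):
            a, b = pts[i], pts[(i + 1) % len(pts)]
            normal += np.cross(a, b)
        oriented.append(face if np.dot(normal, pts.mean(axis=0)) > 0 else face[::-1])

    types = [_TYPE_BY_SIDES.get(len(face), f"{len(face)}-gon") for face in oriented]
    return CageMesh(
        vertices=dual_vertices,
        faces=oriented,
        face_types=types,
        architecture=mesh.architecture,
        sphericity=mesh.sphericity,
        radius=mesh.radius,
        is_dual=not mesh.is_dual,
    )


# ---------------------------------------------------------------------------
# mesh writers

_FORMATS = ("obj", "off", "bild")


def write_mesh(mesh: CageMesh, fmt: str, path) -> None:
    """Write the mesh as Wavefront OBJ, OFF, or Chimera BILD.

    Vertex order and face indices are stable across runs.
    """
    fmt = fmt.strip().lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
    path = Path(path)
    if fmt == "obj":
        lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += ["f " + " ".join(str(i + 1) for i in face) for face in mesh.faces]
    elif fmt == "off":
        lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} {mesh.n_edges}"]
        lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += [f"{len(face)} " + " ".join(str(i) for i in face) for face in mesh.faces]
    else:  # bild
        lines = [".comment capsid cage"]
        for face, ftype in zip(mesh.faces, mesh.face_types):
            coords = " ".join(
                f"{c:.9g}" for i in face for c in mesh.vertices[i]
            )
            lines.append(f".polygon {coords}")
    path.write_text("\n".join(lines) + "\n")


def read_off(path) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Minimal OFF reader (round-trip verification of :func:`write_mesh`)."""
    tokens = Path(path).read_text().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array([[float(tokens[pos + 3 * i + j]) for j in range(3)] for i in range(nv)])
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        n = int(tokens[pos])
        faces.append(tuple(int(tokens[pos + 1 + j]) for j in range(n)))
        pos += 1 + n
    return verts, faces
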