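"""Cage meshes: known polyhedra, closure, duality, symmetry, writers."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from capsidkit.cage import (
    build_cage_hk,
    dual_mesh,
    edge_set,
    euler_characteristic,
    face_census,
    face_planarity,
    icosahedron,
    is_closed,
    read_off,
    write_mesh,
)

# (lattice, h, k) -> expected face census; the four (1,0) cages are the
# classic Archimedean/Platonic solids, T=3 is the truncated icosahedron
KNOWN_CENSUS = {
    ("hexagonal", 1, 0): {"pentagon": 12},
    ("hexagonal", 1, 1): {"pentagon": 12, "hexagon": 20},
    ("hexagonal", 2, 0): {"pentagon": 12, "hexagon": 30},
    ("hexagonal", 2, 1): {"pentagon": 12, "hexagon": 60},
    ("trihexagonal", 1, 0): {"pentagon": 12, "triangle": 20},
    ("snub_hexagonal", 1, 0): {"pentagon": 12, "triangle": 80},
    ("rhombitrihexagonal", 1, 0): {"pentagon": 12, "triangle": 20, "square": 30},
}

KNOWN_VEF = {
    ("hexagonal", 1, 0): (20, 30, 12),  # pentagonal dodecahedron
    ("trihexagonal", 1, 0): (30, 60, 32),  # icosidodecahedron
    ("snub_hexagonal", 1, 0): (60, 150, 92),  # snub dodecahedron
    ("rhombitrihexagonal", 1, 0): (60, 120, 62),  # rhombicosidodecahedron
}


def test_known_face_censuses(cage_meshes):
    for key, expected in KNOWN_CENSUS.items():
        assert face_census(cage_meshes[key]) == expected, key


def test_known_vertex_edge_face_counts(cage_meshes):
    for key, (v, e, f) in KNOWN_VEF.items():
        mesh = cage_meshes[key]
        assert (mesh.n_vertices, mesh.n_edges, mesh.n_faces) == (v, e, f), key


def test_all_cages_closed_with_euler_two(cage_meshes):
    for key, mesh in cage_meshes.items():
        assert is_closed(mesh), key
        assert euler_characteristic(mesh) == 2, key
        assert face_census(mesh).get("pentagon") == 12, key


def test_hexagonal_capsomer_count_is_10T_plus_2(cage_meshes):
    for (lat, h, k), mesh in cage_meshes.items():
        if lat != "hexagonal":
            continue
        census = face_census(mesh)
        t = h * h + h * k + k * k
        assert census["pentagon"] + census.get("hexagon", 0) == 10 * t + 2


def test_no_unwelded_vertex_pairs(cage_meshes):
    for key, mesh in cage_meshes.items():
        dmin = cKDTree(mesh.vertices).query(mesh.vertices, k=2)[0][:, 1].min()
        assert dmin > 1e-8 * mesh.radius, key


def test_sphericity_one_vertices_equidistant():
    mesh = build_cage_hk(2, 1, "hexagonal", sphericity=1.0, radius=30.0)
    radii = np.linalg.norm(mesh.vertices, axis=1)
    assert np.ptp(radii) / 30.0 < 1e-6


def test_sphericity_interpolates_radii_linearly():
    flat = build_cage_hk(1, 1, "hexagonal", sphericity=0.0)
    half = build_cage_hk(1, 1, "hexagonal", sphericity=0.5)
    r0 = np.linalg.norm(flat.vertices, axis=1)
    r5 = np.linalg.norm(half.vertices, axis=1)
    assert np.allclose(r5, 0.5 * r0 + 0.5, atol=1e-12)


def test_faces_inside_facets_planar_at_sphericity_zero(cage_meshes):
    # faces that do not wrap an icosahedron edge are exactly flat; the
    # twelve vertex pentagons and edge-wrapping faces are intrinsically bent
    mesh = cage_meshes[("hexagonal", 1, 1)]  # truncated icosahedron
    for i, ftype in enumerate(mesh.face_types):
        if ftype == "hexagon":
            assert face_planarity(mesh, i) < 1e-6
    # the (1,0) pentagons of the dodecahedron are planar by symmetry
    dodeca = cage_meshes[("hexagonal", 1, 0)]
    for i in range(dodeca.n_faces):
        assert face_planarity(dodeca, i) < 1e-6


def test_flat_area_ratios_match_lattice_area_factors(cage_meshes):
    sqrt3 = math.sqrt(3.0)
    lattice_const = {
        "hexagonal": sqrt3,
        "trihexagonal": 2.0,
        "snub_hexagonal": math.sqrt(7.0),
        "rhombitrihexagonal": 1.0 + sqrt3,
    }
    alphas = {
        "hexagonal": 1.0,
        "trihexagonal": 4.0 / 3.0,
        "snub_hexagonal": 7.0 / 3.0,
        "rhombitrihexagonal": 4.0 / 3.0 + 2.0 * sqrt3 / 3.0,
    }
    ico_edge = 4.0 / math.sqrt(10.0 + 2.0 * math.sqrt(5.0))
    totals = {}
    for lat in lattice_const:
        mesh = build_cage_hk(2, 1, lat)
        unit_edge = ico_edge / (lattice_const[lat] * math.sqrt(7.0))
        totals[lat] = sum(mesh.face_flat_areas) / unit_edge**2
    base = totals["hexagonal"]
    for lat, alpha in alphas.items():
        assert totals[lat] / base == pytest.approx(alpha, rel=0.02)


def test_pentagon_flat_area_is_five_sixths_of_hexagon(cage_meshes):
    mesh = cage_meshes[("hexagonal", 2, 1)]
    pent = [a for a, t in zip(mesh.face_flat_areas, mesh.face_types) if t == "pentagon"]
    hexa = [a for a, t in zip(mesh.face_flat_areas, mesh.face_types) if t == "hexagon"]
    assert pent[0] == pytest.approx(5.0 / 6.0 * hexa[0], rel=1e-9)


def test_vertex_set_invariant_under_icosahedral_rotations():
    # a 5-fold rotation about z (vertex axis) and a 3-fold rotation about a
    # face axis generate the full 60-element icosahedral rotation group
    mesh = build_cage_hk(2, 1, "snub_hexagonal", sphericity=1.0)
    verts = mesh.vertices
    ico_v, ico_f = icosahedron(1.0)
    face_axis = ico_v[list(ico_f[0])].mean(axis=0)
    face_axis /= np.linalg.norm(face_axis)
    for rotvec in ([0.0, 0.0, 2.0 * np.pi / 5.0], face_axis * 2.0 * np.pi / 3.0):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        dist, _ = cKDTree(verts).query(verts @ rot.T)
        assert dist.max() < 1e-6


def _icosahedral_rotations():
    ico_v, ico_f = icosahedron(1.0)
    face_axis = ico_v[list(ico_f[0])].mean(axis=0)
    face_axis /= np.linalg.norm(face_axis)
    gens = [
        Rotation.from_rotvec([0.0, 0.0, 2.0 * np.pi / 5.0]).as_matrix(),
        Rotation.from_rotvec(face_axis * 2.0 * np.pi / 3.0).as_matrix(),
    ]
    group = [np.eye(3)]
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for r in frontier:
            for g in gens:
                cand = g @ r
                if not any(np.allclose(cand, m, atol=1e-9) for m in group):
                    group.append(cand)
                    nxt.append(cand)
        frontier = nxt
    assert len(group) == 60
    return group


def _congruent_under_some_rotation(a, b, rotations):
    tree = cKDTree(a)
    return any(tree.query(b @ rot.T)[0].max() < 1e-6 for rot in rotations)


def test_snub_chirality_produces_mirror_cages():
    laevo = build_cage_hk(1, 0, "snub_hexagonal", sphericity=1.0)
    dextro = build_cage_hk(1, 0, "snub_hexagonal", sphericity=1.0, chirality="dextro")
    rotations = _icosahedral_rotations()
    # x = 0 is a mirror plane of the icosahedron in this orientation
    mirrored = dextro.vertices * np.array([-1.0, 1.0, 1.0])
    # the mirror image of the dextro cage is congruent to the laevo cage ...
    assert _congruent_under_some_rotation(laevo.vertices, mirrored, rotations)
    # ... but no proper rotation maps dextro onto laevo (genuinely chiral)
    assert not _congruent_under_some_rotation(laevo.vertices, dextro.vertices, rotations)


def test_invalid_build_parameters_rejected():
    with pytest.raises(ValueError):
        build_cage_hk(1, 0, "hexagonal", sphericity=1.5)
    with pytest.raises(ValueError):
        build_cage_hk(1, 0, "hexagonal", radius=0.0)
    with pytest.raises(ValueError):
        build_cage_hk(1, 0, "hexagonal", chirality="laevo")  # not a chiral lattice


def test_dual_of_dodecahedron_is_icosahedron(cage_meshes):
    dual = dual_mesh(cage_meshes[("hexagonal", 1, 0)])
    assert (dual.n_vertices, dual.n_faces) == (12, 20)
    assert face_census(dual) == {"triangle": 20}
    assert euler_characteristic(dual) == 2
    assert is_closed(dual)


def test_dual_counts_and_involution(cage_meshes):
    for key, mesh in cage_meshes.items():
        dual = dual_mesh(mesh)
        assert dual.n_vertices == mesh.n_faces, key
        assert dual.n_faces == mesh.n_vertices, key
        assert euler_characteristic(dual) == 2, key
        assert dual_mesh(dual).n_faces == mesh.n_faces, key


def test_mesh_writers_round_trip(cage_meshes, tmp_path):
    mesh = cage_meshes[("hexagonal", 1, 0)]
    off = tmp_path / "cage.off"
    write_mesh(mesh, "off", off)
    verts, faces = read_off(off)
    assert len(verts) == 20 and len(faces) == 12
    assert {len(f) for f in faces} == {5}
    assert off.read_text().splitlines()[1] == "20 12 30"

    obj = tmp_path / "cage.obj"
    write_mesh(mesh, "obj", obj)
    lines = obj.read_text().splitlines()
    assert sum(l.startswith("v ") for l in lines) == mesh.n_vertices
    assert sum(l.startswith("f ") for l in lines) == mesh.n_faces

    bild = tmp_path / "cage.bild"
    write_mesh(mesh, "bild", bild)
    assert sum(
        l.startswith(".polygon") for l in bild.read_text().splitlines()
    ) == mesh.n_faces

    with pytest.raises(ValueError):
        write_mesh(mesh, "stl", tmp_path / "cage.stl")


def test_writers_deterministic(cage_meshes, tmp_path):
    mesh_a = build_cage_hk(2, 1, "hexagonal", sphericity=0.3, radius=30.0)
    mesh_b = build_cage_hk(2, 1, "hexagonal", sphericity=0.3, radius=30.0)
    pa, pb = tmp_path / "a.obj", tmp_path / "b.obj"
    write_mesh(mesh_a, "obj", pa)
    write_mesh(mesh_b, "obj", pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_trimesh_confirms_watertight_topology(cage_meshes, tmp_path):
    # independent oracle: triangulated cage is watertight with Euler number 2
    trimesh = pytest.importorskip("trimesh")
    mesh = cage_meshes[("hexagonal", 2, 1)]
    tris = []
    for face in mesh.faces:
        for i in range(1, len(face) - 1):
            tris.append((face[0], face[i], face[i + 1]))
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=tris, process=True)
    assert tm.is_watertight
    assert tm.euler_number == 2
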