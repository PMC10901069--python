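"""Force-equilibrium remeshing and tetrahedral mesh construction."""

import numpy as np
import pytest

from scan2fem import ElectrodeSet, MeshConfig
from scan2fem.belt_mesh import FemMesh, build_fem_mesh, mesh_quality, remesh_surface
from scan2fem.distmesh import _unique_edges, fibonacci_sphere, remesh_convex
from scan2fem.errors import BackendMissingError, ElectrodeOverlapError

from conftest import cylinder_model, ring_electrodes


def boundary_edge_incidence(mesh: FemMesh) -> dict:
    bf = mesh.surface_tris
    e = np.sort(np.vstack([bf[:, [0, 1]], bf[:, [1, 2]], bf[:, [2, 0]]]), axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    vals, freq = np.unique(counts, return_counts=True)
    return dict(zip(vals.tolist(), freq.tolist()))


def test_sphere_uniform_h_edge_lengths():
    """Classic distmesh property: uniform sizing gives uniform edges."""
    R, h = 50.0, 5.0
    n = int(8 * np.pi * R**2 / (np.sqrt(3) * h**2)) + 2

    def project(p):
        return p * (R / np.linalg.norm(p, axis=1))[:, None]

    pts, tris, _ = remesh_convex(
        project, lambda p: np.full(len(np.atleast_2d(p)), h), fibonacci_sphere(n, R)
    )
    edges = _unique_edges(tris)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    assert abs(lengths.mean() - h) / h < 0.15
    assert np.mean(np.abs(lengths - h) <= 0.15 * h) > 0.9


def test_refining_h_quadruples_triangles():
    R = 50.0

    def project(p):
        return p * (R / np.linalg.norm(p, axis=1))[:, None]

    counts = []
    for h in (10.0, 5.0):
        n = int(8 * np.pi * R**2 / (np.sqrt(3) * h**2)) + 2
        _, tris, _ = remesh_convex(
            project, lambda p: np.full(len(np.atleast_2d(p)), h),
            fibonacci_sphere(n, R), max_iter=120,
        )
        counts.append(len(tris))
    ratio = counts[1] / counts[0]
    assert 4 * 0.7 < ratio < 4 * 1.3


def test_single_electrode_disc_area():
    """Uniform fine remesh resolves the 5 mm disc: area within 5% of πr²."""
    model = cylinder_model(40.0, (-10.0, 10.0))
    es = ElectrodeSet(np.array([[40.0, 0.0, 0.0]]), np.array([1]),
                      frozenset(range(2, 33)))
    cfg = MeshConfig(h_electrode=0.8, h_background=0.8, electrode_radius=5.0)
    labeled = remesh_surface(model, es, cfg, max_iter=60)
    area = labeled.electrode_area(1)
    assert abs(area - np.pi * 25.0) / (np.pi * 25.0) < 0.05


def test_phantom_32_disjoint_connected_patches(cyl_model):
    cfg = MeshConfig(h_electrode=2.0, h_background=10.0, electrode_radius=5.0)
    labeled = remesh_surface(cyl_model, ring_electrodes(), cfg, max_iter=60)
    assert len(labeled.electrode_faces) == 32
    all_faces = np.concatenate([v for v in labeled.electrode_faces.values()])
    assert len(all_faces) == len(set(all_faces.tolist())), "patches overlap"
    # connectivity: each patch's faces form one edge-connected component
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    for lab, fidx in labeled.electrode_faces.items():
        tris = labeled.faces[fidx]
        edges = {}
        for k, t in enumerate(tris):
            for pair in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edges.setdefault(tuple(sorted(pair)), []).append(k)
        links = [(a, b) for ks in edges.values() if len(ks) == 2 for a, b in [ks]]
        if len(tris) > 1:
            i, j = zip(*links)
            adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(len(tris), len(tris)))
            n_comp, _ = connected_components(adj, directed=False)
            assert n_comp == 1, f"electrode {lab} patch is disconnected"


def test_background_edge_length_near_target(cyl_model):
    cfg = MeshConfig(h_electrode=2.0, h_background=10.0, electrode_radius=5.0)
    labeled = remesh_surface(cyl_model, ring_electrodes(), cfg, max_iter=80)
    edges = _unique_edges(labeled.faces)
    mids = 0.5 * (labeled.vertices[edges[:, 0]] + labeled.vertices[edges[:, 1]])
    d = np.linalg.norm(
        mids[:, None, :] - ring_electrodes().positions[None, :, :], axis=2
    ).min(axis=1)
    far = d > 3 * cfg.electrode_radius
    lengths = np.linalg.norm(
        labeled.vertices[edges[:, 0]] - labeled.vertices[edges[:, 1]], axis=1
    )
    median = np.median(lengths[far])
    assert abs(median - cfg.h_background) / cfg.h_background < 0.2


def test_overlapping_electrodes_raise(cyl_model):
    pts = np.array([[100.0, 0.0, 0.0], [100.0, 3.0, 0.0]])
    es = ElectrodeSet(pts, [1, 2], frozenset(range(3, 33)))
    cfg = MeshConfig(h_electrode=2.0, h_background=10.0, electrode_radius=5.0)
    with pytest.raises(ElectrodeOverlapError):
        remesh_surface(cyl_model, es, cfg)


def test_fem_cylinder_volume_within_2pct():
    model = cylinder_model(150.0, (-40.0, 40.0))
    cfg = MeshConfig(h_electrode=5.0, h_background=10.0, electrode_radius=6.0)
    labeled = remesh_surface(model, None, cfg, max_iter=100)
    mesh = build_fem_mesh(labeled, cfg)
    analytic = np.pi * 150.0**2 * 80.0
    assert abs(mesh.total_volume() - analytic) / analytic < 0.02
    assert (mesh.tet_volumes() > 0).all()
    assert mesh_quality(mesh)["z_extent_mm"] <= 80.0 + cfg.h_background


def test_fem_boundary_watertight(electrode_mesh):
    """Every boundary edge is shared by exactly two boundary triangles."""
    incidence = boundary_edge_incidence(electrode_mesh)
    assert set(incidence) == {2}


def test_label_transfer_preserves_patches(tube_model):
    cfg = MeshConfig(h_electrode=3.0, h_background=15.0, electrode_radius=5.0, seed=2)
    labeled = remesh_surface(tube_model, ring_electrodes(103.0), cfg, max_iter=60)
    mesh = build_fem_mesh(labeled, cfg)
    assert set(mesh.electrode_facets) == set(labeled.electrode_faces)
    for lab in labeled.electrode_faces:
        vol_nodes = mesh.nodes[np.unique(mesh.electrode_facets[lab])]
        # volume patch nodes are surface nodes (up to the mesher's
        # anti-degeneracy jitter) and stay within the disc neighborhood
        from scipy.spatial import cKDTree

        d, _ = cKDTree(labeled.vertices).query(vol_nodes)
        assert d.max() < 0.2
        center = labeled.electrode_centers[lab]
        assert np.linalg.norm(vol_nodes - center, axis=1).max() < (
            cfg.electrode_radius + cfg.h_electrode
        )
        # and matching patch areas
        tris = mesh.nodes[mesh.electrode_facets[lab]]
        area = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
        ).sum()
        assert abs(area - labeled.electrode_area(lab)) / labeled.electrode_area(lab) < 0.10


def test_electrode_facet_areas_near_disc(electrode_mesh):
    r = 5.0
    for lab, tris_idx in electrode_mesh.electrode_facets.items():
        tris = electrode_mesh.nodes[tris_idx]
        area = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
        ).sum()
        assert abs(area - np.pi * r**2) / (np.pi * r**2) < 0.10


def test_mesh_quality_statistics():
    regular = FemMesh(
        np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ),
        np.array([[0, 1, 2, 3]]),
        {},
        np.empty((0, 3), dtype=np.int64),
    )
    assert np.isclose(mesh_quality(regular)["mean_quality"], 1.0)
    sliver = FemMesh(
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 1e-3]]),
        np.array([[0, 1, 2, 3]]),
        {},
        np.empty((0, 3), dtype=np.int64),
    )
    assert mesh_quality(sliver)["mean_quality"] < 0.1


def test_mesh_config_validation():
    with pytest.raises(ValueError):
        MeshConfig(h_electrode=0.0)
    with pytest.raises(ValueError):
        MeshConfig(h_electrode=6.0, h_background=5.0)
    with pytest.raises(ValueError):
        MeshConfig(h_electrode=2.0, electrode_radius=1.0)


def test_external_backend_requests_fail_loudly(cyl_model):
    cfg = MeshConfig(h_electrode=5.0, h_background=10.0, electrode_radius=6.0,
                     backend="gmsh")
    labeled = remesh_surface(cyl_model, None, cfg, max_iter=10)
    with pytest.raises(BackendMissingError, match="gmsh"):
        build_fem_mesh(labeled, cfg)
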