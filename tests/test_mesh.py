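import numpy as np
import pytest

from sdtrack import synthetic
from sdtrack.errors import (
    InsufficientMarginError,
    MeshParseError,
)
from sdtrack.mesh import (
    TriMesh,
    curvature_proxy,
    extract_patch,
    geodesic_distances,
    geodesic_from,
    shortest_path,
    smooth_laplacian_edge_preserving,
    upsample_4split,
)
from sdtrack.meshio import read_surface, write_surface

OFF_TETRA = """OFF
4 4 6
0 0 0
1 0 0
0 1 0
0 0 1
3 0 2 1
3 0 1 3
3 0 3 2
3 1 2 3
"""


class TestSurfaceIO:
    def test_off_tetrahedron(self, tmp_path):
        p = tmp_path / "tet.off"
        p.write_text(OFF_TETRA)
        m = read_surface(str(p))
        assert m.n_vertices == 4 and m.n_faces == 4

    def test_freesurfer_ascii_header_echo(self, tmp_path):
        mesh = synthetic.make_mesh("plane", width=4, height=2, spacing=1.0)
        assert mesh.n_vertices == 15
        p = tmp_path / "surf.asc"
        write_surface(mesh, str(p), format="freesurfer_ascii")
        txt = p.read_text().splitlines()
        assert txt[1].split() == ["15", "16"]
        m = read_surface(str(p), format="freesurfer_ascii")
        assert m.n_vertices == 15 and m.n_faces == 16

    def test_face_index_out_of_range_names_line(self, tmp_path):
        bad = OFF_TETRA.replace("3 1 2 3", "3 1 2 99")
        p = tmp_path / "bad.off"
        p.write_text(bad)
        with pytest.raises(MeshParseError, match="out of range"):
            read_surface(str(p))

    @pytest.mark.parametrize("fmt", ["off", "freesurfer_ascii"])
    def test_round_trip(self, tmp_path, tetrahedron, fmt):
        p = tmp_path / f"m.{fmt}"
        write_surface(tetrahedron, str(p), format=fmt)
        m = read_surface(str(p), format=fmt)
        assert np.allclose(m.vertices, tetrahedron.vertices, atol=1e-6)
        assert (m.faces == tetrahedron.faces).all()

    def test_ply_scalar_channel(self, tmp_path, tetrahedron):
        tetrahedron.scalar = np.array([0.0, 25.0, 50.0, 100.0])
        p = tmp_path / "m.ply"
        write_surface(tetrahedron, str(p), format="ply")
        txt = p.read_text()
        assert "property float quality" in txt
        assert "100.0" in txt

    def test_empty_mesh_rejected(self, tmp_path):
        empty = TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty mesh"):
            write_surface(empty, str(tmp_path / "e.off"))


class TestUpsample:
    def test_tetrahedron_counts_and_euler(self, tetrahedron):
        m1 = upsample_4split(tetrahedron, 1)
        assert m1.n_vertices == 10 and m1.n_faces == 16
        m2 = upsample_4split(tetrahedron, 2)
        assert m2.n_vertices == 34 and m2.n_faces == 64
        # Euler characteristic of a closed genus-0 surface stays 2
        for m in (tetrahedron, m1, m2):
            E = len(m.edges)
            assert m.n_vertices - E + m.n_faces == 2

    def test_patch_scale_vertex_count(self):
        # doubling the vertex count twice: a ~9.2k-vertex patch lands within
        # 5% of 144,185 after two 4-split iterations (boundary edges shift
        # the exact count)
        mesh = synthetic.make_mesh("plane", width=100, height=90, spacing=1.0)
        assert mesh.n_vertices == 101 * 91  # 9191
        up = upsample_4split(mesh, 2, scheme="midpoint")
        assert abs(up.n_vertices - 144185) / 144185 < 0.05
        assert up.n_faces == 16 * mesh.n_faces

    @pytest.mark.parametrize("scheme", ["butterfly", "midpoint"])
    def test_planar_input_stays_planar(self, scheme):
        mesh = synthetic.make_mesh("plane", width=10, height=10, spacing=1.0)
        up = upsample_4split(mesh, 2, scheme=scheme)
        assert np.abs(up.vertices[:, 2]).max() < 1e-12

    def test_original_vertices_unmoved(self, tetrahedron):
        up = upsample_4split(tetrahedron, 1)
        assert np.allclose(up.vertices[:4], tetrahedron.vertices)

    def test_butterfly_rounds_sphere(self):
        # interpolating stencil keeps new vertices near the sphere, unlike
        # plain midpoints which fall inside it
        ico = synthetic.make_mesh("icosphere", subdivision=3, radius=50.0)
        bf = upsample_4split(ico, 1, scheme="butterfly")
        mp = upsample_4split(ico, 1, scheme="midpoint")
        r_bf = np.linalg.norm(bf.vertices[ico.n_vertices:], axis=1)
        r_mp = np.linalg.norm(mp.vertices[ico.n_vertices:], axis=1)
        assert np.abs(r_bf - 50).mean() < np.abs(r_mp - 50).mean()


class TestSmoothing:
    def test_flat_grid_is_fixed_point(self):
        mesh = synthetic.make_mesh("plane", width=10, height=10, spacing=1.0)
        sm = smooth_laplacian_edge_preserving(mesh, iterations=3, step=0.5)
        assert np.abs(sm.vertices - mesh.vertices).max() < 1e-9

    def test_noisy_sphere_curvature_and_edges(self):
        ico = synthetic.make_mesh("icosphere", subdivision=3, radius=50.0)
        rng = np.random.default_rng(3)
        noisy = TriMesh(
            ico.vertices * (1 + rng.normal(0, 0.5, ico.n_vertices)[:, None] / 50.0),
            ico.faces.copy(),
        )
        L0 = noisy.edge_lengths
        var0 = curvature_proxy(noisy).var()
        sm = smooth_laplacian_edge_preserving(noisy, iterations=5, step=0.3)
        var1 = curvature_proxy(sm).var()
        assert var1 < var0
        L1 = sm.edge_lengths
        assert np.abs((L1 - L0) / L0).mean() < 0.01
        assert abs(sm.area() - noisy.area()) / noisy.area() < 0.02

    def test_step_validation(self, tetrahedron):
        with pytest.raises(ValueError, match="step must be positive"):
            smooth_laplacian_edge_preserving(tetrahedron, step=0.0)


class TestGeodesics:
    def test_straight_edge_chain(self, plane_grid):
        # two vertices 10 mm apart along a grid axis
        a = 10 * 21 + 5
        b = 10 * 21 + 15
        g = geodesic_from(plane_grid, a)
        assert g.dist[b] == pytest.approx(10.0)
        path = shortest_path(g, b)
        assert path[0] == a and path[-1] == b

    def test_icosphere_pole_to_pole(self):
        ico = synthetic.make_mesh("icosphere", subdivision=4, radius=50.0)
        north = int(np.argmax(ico.vertices[:, 2]))
        south = int(np.argmin(ico.vertices[:, 2]))
        g = geodesic_from(ico, north)
        analytic = np.pi * 50.0
        assert abs(g.dist[south] - analytic) / analytic < 0.10
        assert g.dist[south] >= np.linalg.norm(
            ico.vertices[north] - ico.vertices[south]
        )

    def test_path_length_equals_distance(self, plane_grid):
        g = geodesic_from(plane_grid, 0)
        rng = np.random.default_rng(0)
        for t in rng.integers(0, plane_grid.n_vertices, 20):
            path = shortest_path(g, int(t))
            seg = plane_grid.vertices[path]
            length = np.linalg.norm(np.diff(seg, axis=0), axis=1).sum()
            assert length == pytest.approx(g.dist[t], abs=1e-9)

    def test_identity_path(self, plane_grid):
        g = geodesic_from(plane_grid, 17)
        assert shortest_path(g, 17) == [17]

    def test_disconnected_component_unreachable(self, tetrahedron):
        far = TriMesh(
            np.vstack([tetrahedron.vertices, tetrahedron.vertices + 100.0]),
            np.vstack([tetrahedron.faces, tetrahedron.faces + 4]),
        )
        g = geodesic_from(far, 0)
        assert np.isinf(g.dist[4:]).all()
        with pytest.raises(ValueError, match="unreachable"):
            shortest_path(g, 5)

    def test_bulk_matches_single_source(self, plane_grid):
        d = geodesic_distances(plane_grid, [0, 5])
        g0 = geodesic_from(plane_grid, 0)
        assert np.allclose(d[0], g0.dist)

    def test_source_out_of_range(self, tetrahedron):
        with pytest.raises(IndexError):
            geodesic_from(tetrahedron, 99)


class TestExtractPatch:
    def test_boundary_beyond_radius(self, plane_dataset, plane_patch):
        ds = plane_dataset
        evs = [plane_patch.electrodes[lab] for lab in ds.electrodes.labels]
        d = geodesic_distances(plane_patch.mesh, evs)
        dmin = d.min(axis=0)
        assert (dmin[plane_patch.boundary] > plane_patch.radius).all()

    def test_insufficient_margin(self, plane_grid):
        # electrode 5 mm from the parent boundary cannot carry a 30 mm patch
        with pytest.raises(InsufficientMarginError, match="insufficient margin"):
            extract_patch(plane_grid, [5 * 21 + 5], radius=30.0)

    def test_single_electrode_disk_area(self):
        mesh = synthetic.make_mesh(
            "plane", width=80, height=80, spacing=1.0, diagonal="alternating"
        )
        center = 40 * 81 + 40
        patch = extract_patch(mesh, {"E1": center}, radius=30.0)
        area = patch.mesh.area()
        assert abs(area - np.pi * 30**2) / (np.pi * 30**2) < 0.15

    def test_connected(self, plane_patch):
        from scipy.sparse.csgraph import connected_components

        n, _ = connected_components(plane_patch.mesh.adjacency, directed=False)
        assert n == 1

    def test_electrode_indices_remapped(self, plane_dataset, plane_patch):
        ds = plane_dataset
        for lab, pv in plane_patch.electrodes.items():
            parent = plane_patch.parent_vertices[pv]
            orig = dict(zip(ds.electrodes.labels, ds.electrodes.vertex_ids))[lab]
            assert parent == orig
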