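import numpy as np
import pytest
import trimesh

from volmap.mesh import (
    ElectrodeSet,
    MeshValidationError,
    TriSurfaceMesh,
    attach_electrodes,
    build_phantom_geometry,
    fibonacci_directions,
    geodesic_distance,
    geodesic_distances,
    icosphere_surface,
    load_mesh,
    node_volume_weights,
    read_electrodes_csv,
    save_mesh,
    tetrahedralize,
    winding_number,
    write_electrodes_csv,
)
from volmap.fem import tet_volumes

from conftest import micro_spec


def unit_cube_surface():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriSurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))


class TestSurfaceValidation:
    def test_unit_cube_area_and_volume(self):
        m = unit_cube_surface().validate()
        assert m.area == pytest.approx(6.0)
        assert m.enclosed_volume == pytest.approx(1.0)

    def test_flipped_triangle_names_offender(self):
        m = unit_cube_surface()
        m.triangles[4] = m.triangles[4][::-1]
        with pytest.raises(MeshValidationError, match="orientation.*4"):
            m.validate()

    def test_open_surface_rejected(self):
        m = unit_cube_surface()
        m = TriSurfaceMesh(m.vertices, m.triangles[:-1])
        with pytest.raises(MeshValidationError):
            m.validate()

    def test_degenerate_triangle_rejected(self):
        m = unit_cube_surface()
        m.triangles[2, 1] = m.triangles[2, 0]
        with pytest.raises(MeshValidationError, match="degenerate"):
            m.validate()


class TestMeshIO:
    @pytest.mark.parametrize("ext", [".vtk", ".vtu"])
    def test_surface_roundtrip(self, tmp_path, ext):
        m = icosphere_surface(30.0, 12.0)
        p = tmp_path / f"s{ext}"
        save_mesh(m, p)
        m2 = load_mesh(p, role=m.role)
        np.testing.assert_allclose(m2.vertices, m.vertices, atol=1e-12)
        np.testing.assert_array_equal(m2.triangles, m.triangles)

    @pytest.mark.parametrize("ext", [".vtk", ".vtu"])
    def test_volume_roundtrip(self, tmp_path, ext, micro_phantom):
        _, _, vol, _ = micro_phantom
        p = tmp_path / f"v{ext}"
        save_mesh(vol, p)
        v2 = load_mesh(p)
        np.testing.assert_allclose(v2.vertices, vol.vertices, atol=1e-12)
        np.testing.assert_array_equal(v2.tetrahedra, vol.tetrahedra)
        np.testing.assert_array_equal(v2.heart_node_mask, vol.heart_node_mask)

    def test_off_read_unit_cube(self, tmp_path):
        box = trimesh.creation.box(extents=(1, 1, 1))
        p = tmp_path / "cube.off"
        box.export(str(p))
        m = load_mesh(p)
        assert m.area == pytest.approx(6.0)

    def test_electrode_csv_roundtrip(self, tmp_path):
        el = ElectrodeSet(np.random.default_rng(0).normal(size=(8, 3)),
                          np.arange(8))
        p = tmp_path / "el.csv"
        write_electrodes_csv(p, el)
        pos = read_electrodes_csv(p)
        np.testing.assert_allclose(pos, el.positions, rtol=1e-8)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_mesh("/nonexistent/mesh.vtk")


class TestWindingNumber:
    def test_inside_outside(self):
        s = icosphere_surface(10.0, 4.0)
        pts = np.array([[0, 0, 0], [3, 3, 3], [20, 0, 0], [0, 15, 0]],
                       dtype=float)
        wn = winding_number(s, pts)
        np.testing.assert_allclose(wn[:2], 1.0, atol=1e-6)
        np.testing.assert_allclose(wn[2:], 0.0, atol=1e-6)


@pytest.fixture(scope="module")
def spheres_mesh():
    torso = icosphere_surface(60.0, 6.0)
    outer = icosphere_surface(20.0, 5.0, role="epicardium")
    inner = icosphere_surface(12.0, 5.0, role="endocardium")
    return torso, outer, inner, tetrahedralize(torso, outer, inner, 6.0)


class TestTetrahedralize:
    def test_total_volume_matches_sphere(self, spheres_mesh):
        torso, _, _, mesh = spheres_mesh
        total = tet_volumes(mesh.vertices, mesh.tetrahedra).sum()
        assert total == pytest.approx(torso.enclosed_volume, rel=0.02)
        assert total == pytest.approx(4 / 3 * np.pi * 60.0**3, rel=0.02)

    def test_heart_shell_containment(self, spheres_mesh):
        _, outer, inner, mesh = spheres_mesh
        hp = mesh.vertices[mesh.heart_nodes]
        assert len(hp) > 0
        r = np.linalg.norm(hp, axis=1)
        assert np.all(r <= 20.0 + 1e-6)
        assert np.all(r >= 12.0 - 1e-6)

    def test_mean_edge_near_target(self, spheres_mesh):
        _, _, _, mesh = spheres_mesh
        e = mesh.edge_list()
        L = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]],
                           axis=1)
        assert abs(L.mean() - 6.0) / 6.0 < 0.25

    def test_weights_match_bruteforce_accumulation(self, spheres_mesh):
        _, _, _, mesh = spheres_mesh
        w = node_volume_weights(mesh)
        # independent per-tet accumulation loop
        ref = np.zeros(len(mesh.vertices))
        for tet in mesh.heart_tets():
            a, b, c, d = mesh.vertices[tet]
            v = abs(np.dot(np.cross(b - a, c - a), d - a)) / 6.0
            for n in tet:
                ref[n] += v / 4.0
        np.testing.assert_allclose(w.weights, ref, rtol=1e-12, atol=1e-12)
        assert w.total_volume == pytest.approx(ref.sum(), rel=1e-9)

    def test_heart_outside_torso_rejected(self):
        torso = icosphere_surface(20.0, 6.0)
        outer = icosphere_surface(30.0, 8.0, role="epicardium")
        with pytest.raises(MeshValidationError):
            tetrahedralize(torso, outer, None, 6.0)


class TestGeodesics:
    def test_identity_zero(self, micro_phantom):
        _, _, vol, _ = micro_phantom
        assert geodesic_distance(vol, 5, 5) == 0.0

    def test_flat_grid_within_edge_inflation(self):
        # 10x10 planar grid; path corner to corner vs straight line
        n = 10
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        tris = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
        mesh = TriSurfaceMesh(verts, np.array(tris))
        # corners joined along the triangulation's diagonal direction
        d = geodesic_distance(mesh, n - 1, n * (n - 1))
        straight = np.sqrt(2) * (n - 1)
        assert d >= straight - 1e-9
        assert d <= 1.10 * straight

    def test_icosphere_antipodal_half_circumference(self):
        s = icosphere_surface(50.0, 5.0)
        top = int(np.argmax(s.vertices[:, 2]))
        bottom = int(np.argmin(s.vertices[:, 2]))
        d = geodesic_distance(s, top, bottom)
        assert d == pytest.approx(np.pi * 50.0, rel=0.10)

    def test_symmetry_and_triangle_inequality(self, micro_phantom):
        _, _, vol, _ = micro_phantom
        rng = np.random.default_rng(3)
        nodes = rng.choice(len(vol.vertices), size=9, replace=False)
        for a, b, c in nodes.reshape(3, 3):
            dab = geodesic_distance(vol, int(a), int(b))
            dba = geodesic_distance(vol, int(b), int(a))
            dac = geodesic_distance(vol, int(a), int(c))
            dcb = geodesic_distance(vol, int(c), int(b))
            assert dab == pytest.approx(dba, rel=1e-12)
            assert dab <= dac + dcb + 1e-9

    def test_geodesic_at_least_euclidean(self, micro_phantom):
        _, _, vol, _ = micro_phantom
        d = geodesic_distances(vol, 0)
        eu = np.linalg.norm(vol.vertices - vol.vertices[0], axis=1)
        assert np.all(d >= eu - 1e-9)


class TestPhantomGeometry:
    def test_default_electrode_count(self, micro_phantom):
        _, _, _, el = micro_phantom
        assert len(el) == 128
        assert len(np.unique(el.attached_vertex)) == 128

    def test_deterministic_rebuild(self):
        spec = micro_spec()
        t1, v1, e1 = build_phantom_geometry(spec)
        t2, v2, e2 = build_phantom_geometry(spec)
        np.testing.assert_array_equal(v1.vertices, v2.vertices)
        np.testing.assert_array_equal(v1.tetrahedra, v2.tetrahedra)
        np.testing.assert_array_equal(e1.attached_vertex, e2.attached_vertex)

    def test_eccentric_heart_inside_torso(self, micro_phantom):
        spec, _, vol, _ = micro_phantom
        hp = vol.vertices[vol.heart_nodes]
        assert np.all(np.linalg.norm(hp, axis=1) < spec.torso_radius_mm)

    def test_truncation_removes_basal_cap(self, micro_phantom):
        spec, _, vol, _ = micro_phantom
        hp = vol.vertices[vol.heart_nodes]
        z_rel = hp[:, 2] - spec.heart_offset_mm[2]
        assert np.all(z_rel < spec.heart_truncation_z_mm)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            build_phantom_geometry(micro_spec(heart_inner_radius_mm=80.0))

    def test_fibonacci_directions_unit_and_spread(self):
        d = fibonacci_directions(64)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        # quasi-uniform: nearest-neighbour angles concentrated
        dots = d @ d.T - 2 * np.eye(64)
        nn = np.degrees(np.arccos(np.clip(dots.max(axis=1), -1, 1)))
        assert nn.max() < 40.0

    def test_attach_electrodes_distinct_under_collision(self):
        verts = np.array([[0., 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        pos = np.array([[0.1, 0, 0], [0.2, 0, 0]])  # both nearest vertex 0
        att = attach_electrodes(pos, verts)
        assert len(set(att.tolist())) == 2
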