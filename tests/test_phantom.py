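import numpy as np
import pytest

from volmap.fem import boundary_faces
from volmap.mesh import TetVolumeMesh, node_volume_weights
from volmap.phantom import (
    ActivationGroundTruth,
    PhantomSpec,
    VmField,
    add_noise,
    compute_sources,
    forward_solve,
    simulate_activation,
    synthesize_vm,
)
from volmap.transfer import analytic_sphere_green

from conftest import micro_spec, random_compatible_sources


class TestActivation:
    def test_origin_has_zero_lat(self, micro_phantom):
        spec, _, vol, _ = micro_phantom
        origin = int(vol.heart_nodes[0])
        gt = simulate_activation(vol, origin, 0.8)
        assert gt.lat_true[0] == 0.0
        assert np.all(gt.lat_true >= 0)
        assert np.all(np.isfinite(gt.lat_true))

    def test_matches_independent_dijkstra(self, micro_phantom):
        # networkx as an implementation-independent shortest-path oracle
        import networkx as nx

        _, _, vol, _ = micro_phantom
        origin = int(vol.heart_nodes[3])
        gt = simulate_activation(vol, origin, 0.5)
        G = nx.Graph()
        e = vol.edge_list()
        keep = vol.heart_node_mask[e].all(axis=1)
        for a, b in e[keep]:
            G.add_edge(int(a), int(b),
                       weight=float(np.linalg.norm(vol.vertices[a] - vol.vertices[b])))
        dist = nx.single_source_dijkstra_path_length(G, origin)
        ref = np.array([dist[int(n)] for n in vol.heart_nodes]) / 0.5
        np.testing.assert_allclose(gt.lat_true, ref, rtol=1e-9, atol=1e-9)

    def test_velocity_scaling(self, micro_phantom):
        _, _, vol, _ = micro_phantom
        origin = int(vol.heart_nodes[0])
        lat1 = simulate_activation(vol, origin, 0.4).lat_true
        lat2 = simulate_activation(vol, origin, 0.8).lat_true
        np.testing.assert_allclose(lat1, 2.0 * lat2, rtol=1e-12)

    def test_non_heart_origin_rejected(self, micro_phantom):
        _, _, vol, _ = micro_phantom
        non_heart = int(np.flatnonzero(~vol.heart_node_mask)[0])
        with pytest.raises(ValueError, match="not a heart node"):
            simulate_activation(vol, non_heart, 0.8)


class TestVmTemplate:
    def test_max_slope_at_lat(self):
        spec = micro_spec(sample_rate_hz=1000.0, duration_ms=100.0)
        gt = ActivationGroundTruth(0, np.array([50.0, 20.0, 0.0]))
        vm = synthesize_vm(gt, spec)
        dv = np.gradient(vm.values, axis=1)
        assert abs(int(np.argmax(dv[0])) - 50) <= 1
        assert abs(int(np.argmax(dv[1])) - 20) <= 1

    def test_rest_and_plateau_exact(self):
        spec = micro_spec(sample_rate_hz=1000.0, duration_ms=100.0)
        gt = ActivationGroundTruth(0, np.array([50.0]))
        v = synthesize_vm(gt, spec).values[0]
        u = spec.upstroke_duration_ms
        assert np.all(np.abs(v[: int(50 - u / 2)]) < 1e-9)
        assert np.all(np.abs(v[int(50 + u / 2) + 1:] - 1.0) < 1e-9)
        assert np.all(np.diff(v) >= -1e-12)

    def test_identical_lats_identical_traces(self):
        spec = micro_spec(sample_rate_hz=1000.0, duration_ms=50.0)
        gt = ActivationGroundTruth(0, np.zeros(4))
        v = synthesize_vm(gt, spec).values
        assert np.all(v == v[0])

    def test_duration_too_short_rejected(self):
        spec = micro_spec(duration_ms=40.0)
        gt = ActivationGroundTruth(0, np.array([100.0]))
        with pytest.raises(ValueError, match="duration"):
            synthesize_vm(gt, spec)


class TestSources:
    def test_uniform_vm_zero_sources(self, micro_phantom):
        _, _, vol, _ = micro_phantom
        P = len(vol.heart_nodes)
        vm = VmField(np.full((P, 4), 0.7), 1000.0)
        f = compute_sources(vm, vol)
        assert np.abs(f).max() < 1e-12

    def test_existence_condition(self, micro_phantom, micro_weights):
        spec, _, vol, _ = micro_phantom
        gt = simulate_activation(vol, int(vol.heart_nodes[0]), 0.8)
        f = compute_sources(synthesize_vm(gt, spec), vol)
        wh = micro_weights.heart_weights
        net = np.abs(wh @ f)
        scale = np.abs(wh[:, None] * f).sum(axis=0).max()
        assert np.all(net < 1e-8 * scale)

    def test_linear_in_sigma(self, micro_phantom):
        spec, _, vol, _ = micro_phantom
        gt = simulate_activation(vol, int(vol.heart_nodes[0]), 0.8)
        vm = synthesize_vm(gt, spec)
        f1 = compute_sources(vm, vol, sigma_i=1.0)
        f2 = compute_sources(vm, vol, sigma_i=2.0)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_linear_ramp_on_bar_matches_divergence_oracle(self):
        # structured bar of cubes split into tets; Vm = x (linear ramp)
        nx_, ny_, nz_ = 5, 3, 3
        xs = np.arange(nx_, dtype=float)
        grid = np.stack(np.meshgrid(xs, np.arange(ny_, dtype=float),
                                    np.arange(nz_, dtype=float),
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        # tiny jitter keeps the Delaunay free of degenerate cospherical tets
        grid += np.random.default_rng(0).uniform(-1e-3, 1e-3, grid.shape)
        from scipy.spatial import Delaunay

        tets = Delaunay(grid).simplices
        mesh = TetVolumeMesh(grid, tets,
                             np.ones(len(grid), dtype=bool)).orient()
        vm = VmField(grid[:, [0]].repeat(2, axis=1), 1000.0)
        f = compute_sources(vm, mesh, sigma_i=1.0)
        w = node_volume_weights(mesh)
        # oracle: weak-form load is the boundary flux of sigma * grad(Vm) =
        # sigma * x-component of the lumped outward area normals
        faces = boundary_faces(mesh.tetrahedra)
        flux = np.zeros(len(grid))
        for tri in faces:
            p0, p1, p2 = grid[tri]
            nvec = np.cross(p1 - p0, p2 - p0) / 2.0
            for n in tri:
                flux[n] += nvec[0] / 3.0
        expected = -flux / w.weights  # no-flux closure turns outflow into sinks
        np.testing.assert_allclose(f[:, 0], expected, atol=1e-8)
        interior = (grid[:, 0] > 0.5) & (grid[:, 0] < nx_ - 1.5) & \
                   (grid[:, 1] > 0.5) & (grid[:, 1] < ny_ - 1.5) & \
                   (grid[:, 2] > 0.5) & (grid[:, 2] < nz_ - 1.5)
        assert np.abs(f[interior, 0]).max() < 1e-9


class TestForwardSolve:
    def test_zero_source_zero_signal(self, micro_phantom, micro_weights, micro_solver):
        _, _, vol, el = micro_phantom
        P = len(vol.heart_nodes)
        g = forward_solve(np.zeros((P, 3)), vol, el, micro_weights,
                          solver=micro_solver)
        assert np.abs(g).max() < 1e-12

    def test_zero_electrode_mean(self, micro_phantom, micro_weights, micro_solver):
        _, _, vol, el = micro_phantom
        rng = np.random.default_rng(0)
        f = random_compatible_sources(micro_weights, 4, rng)
        g = forward_solve(f, vol, el, micro_weights, solver=micro_solver)
        assert np.abs(g.mean(axis=0)).max() < 1e-12

    def test_incompatible_source_rejected(self, micro_phantom, micro_weights, micro_solver):
        _, _, vol, el = micro_phantom
        P = len(vol.heart_nodes)
        with pytest.raises(ValueError, match="incompatible"):
            forward_solve(np.ones((P, 1)), vol, el, micro_weights,
                          solver=micro_solver)

    def test_source_sink_pair_matches_sphere_series(self):
        # concentric phantom so the insulated-sphere series applies
        from volmap.mesh import build_phantom_geometry

        spec = micro_spec(heart_offset_mm=(0.0, 0.0, 0.0),
                          heart_truncation_z_mm=None,
                          torso_radius_mm=200.0,
                          heart_inner_radius_mm=40.0,
                          torso_volume_edge_mm=45.0,
                          heart_volume_edge_mm=13.0)
        _, vol, el = build_phantom_geometry(spec)
        w = node_volume_weights(vol)
        hn = vol.heart_nodes
        rng = np.random.default_rng(1)
        ia, ib = rng.choice(len(hn), 2, replace=False)
        f = np.zeros((len(hn), 1))
        f[ia, 0] = 1.0 / w.weights[hn[ia]]
        f[ib, 0] = -1.0 / w.weights[hn[ib]]
        g = forward_solve(f, vol, el, w)[:, 0]
        ypos = vol.vertices[el.attached_vertex]
        pair = vol.vertices[[hn[ia], hn[ib]]]
        ga = np.array([
            np.diff(analytic_sphere_green(y, pair, 200.0, 150)[::-1])[0]
            for y in ypos
        ])
        ga -= ga.mean()
        assert np.linalg.norm(g - ga) / np.linalg.norm(ga) < 0.05


class TestNoise:
    def test_exact_target_snr(self, micro_phantom):
        rng = np.random.default_rng(2)
        g = rng.standard_normal((16, 400))
        gn = add_noise(g, 20.0, seed=5)
        snr = 10 * np.log10(np.mean(g**2) / np.mean((gn - g) ** 2))
        assert abs(snr - 20.0) < 0.5

    def test_seed_reproducibility(self):
        g = np.random.default_rng(0).standard_normal((8, 100))
        np.testing.assert_array_equal(add_noise(g, 20, 3), add_noise(g, 20, 3))
        assert not np.array_equal(add_noise(g, 20, 3), add_noise(g, 20, 4))

    def test_high_snr_small_perturbation(self):
        g = np.random.default_rng(0).standard_normal((8, 100))
        gn = add_noise(g, 60.0, 1)
        assert np.linalg.norm(gn - g) / np.linalg.norm(g) < 0.002

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="zero-power"):
            add_noise(np.zeros((4, 10)), 20.0, 0)


class TestEndToEndInvariants:
    def test_time_equivariance(self, micro_phantom, micro_weights, micro_solver):
        spec, _, vol, el = micro_phantom
        origin = int(vol.heart_nodes[0])
        gt = simulate_activation(vol, origin, spec.conduction_velocity_mm_ms)
        k = 25  # shift in samples (= ms at 1 kHz)
        gt2 = ActivationGroundTruth(origin, gt.lat_true + k)
        g1 = forward_solve(compute_sources(synthesize_vm(gt, spec), vol),
                           vol, el, micro_weights, solver=micro_solver)
        g2 = forward_solve(compute_sources(synthesize_vm(gt2, spec), vol),
                           vol, el, micro_weights, solver=micro_solver)
        np.testing.assert_allclose(g2[:, k:], g1[:, :-k], atol=1e-12)

    def test_amplitude_linearity(self, micro_phantom, micro_weights, micro_solver):
        spec, _, vol, el = micro_phantom
        gt = simulate_activation(vol, int(vol.heart_nodes[0]),
                                 spec.conduction_velocity_mm_ms)
        vm = synthesize_vm(gt, spec)
        f1 = compute_sources(vm, vol, sigma_i=1.0)
        f2 = compute_sources(vm, vol, sigma_i=2.0)
        g1 = forward_solve(f1, vol, el, micro_weights, solver=micro_solver)
        g2 = forward_solve(f2, vol, el, micro_weights, solver=micro_solver)
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-9, atol=1e-12)
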