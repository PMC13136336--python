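import numpy as np
import pytest

from volmap import fem
from volmap.mesh import build_phantom_geometry, node_volume_weights
from volmap.phantom import PhantomSpec
from volmap.transfer import assemble_green_transfer


def micro_spec(**kw):
    """Very coarse phantom (few hundred nodes) for fast unit tests."""
    defaults = dict(
        torso_radius_mm=150.0,
        heart_outer_radius_mm=60.0,
        heart_inner_radius_mm=25.0,
        heart_offset_mm=(55.0, 0.0, 0.0),
        torso_edge_mm=55.0,
        heart_surface_edge_mm=25.0,
        torso_volume_edge_mm=70.0,
        heart_volume_edge_mm=18.0,
        duration_ms=280.0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def micro_phantom():
    spec = micro_spec()
    torso, vol, el = build_phantom_geometry(spec)
    return spec, torso, vol, el


@pytest.fixture(scope="session")
def micro_weights(micro_phantom):
    _, _, vol, _ = micro_phantom
    return node_volume_weights(vol)


@pytest.fixture(scope="session")
def micro_solver(micro_phantom):
    _, _, vol, _ = micro_phantom
    return fem.NeumannPoissonSolver(vol.vertices, vol.tetrahedra)


@pytest.fixture(scope="session")
def micro_B(micro_phantom, micro_solver):
    _, _, vol, el = micro_phantom
    return assemble_green_transfer(vol, el, micro_solver)


def random_compatible_sources(weights, n_samples, rng):
    """Random nodal source fields satisfying the existence condition."""
    wh = weights.heart_weights
    f = rng.standard_normal((len(wh), n_samples))
    f -= wh[:, None] * (wh @ f) / (wh @ wh)
    return f
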