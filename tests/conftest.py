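import numpy as np
import pytest

from engulf.core_mesh import (
    ForesporeGeometry,
    GlycanStrand,
    MeshState,
    SimulationConfig,
    build_lateral_wall,
    build_septal_disc,
)


@pytest.fixture
def cfg():
    return SimulationConfig(l0=25.0, seed=0)


@pytest.fixture
def geom():
    return ForesporeGeometry(cell_radius=150.0)


@pytest.fixture
def disc(cfg, geom):
    return build_septal_disc(geom, cfg)


@pytest.fixture
def wall(cfg, geom):
    return build_lateral_wall(geom, cfg)


def single_bead_mesh(position=(0.0, 0.0, 0.0)):
    """Minimal free-bead mesh for integrator tests."""
    return MeshState(
        positions=np.asarray([position], dtype=float),
        strand_id=np.zeros(1, dtype=np.int64),
        index_on_strand=np.zeros(1, dtype=np.int64),
        mobile=np.ones(1, dtype=bool),
        strands=[],
        gly_a=np.zeros(0, dtype=np.int64),
        gly_b=np.zeros(0, dtype=np.int64),
        gly_rest=np.zeros(0),
        pep_a=np.zeros(0, dtype=np.int64),
        pep_b=np.zeros(0, dtype=np.int64),
        pep_orient=np.zeros(0, dtype=np.int8),
        pep_rest=np.zeros(0),
        pep_intact=np.zeros(0, dtype=bool),
        anchor_bead=np.zeros(0, dtype=np.int64),
        anchor_point=np.zeros((0, 3)),
        anchor_rest=np.zeros(0),
        anchor_intact=np.zeros(0, dtype=bool),
        leading_edge=[0],
    )


def strand_mesh(positions, closed=False, peptide_pairs=(), pep_rest=None):
    """Mesh holding one glycan strand plus optional peptide bonds, with all
    rest lengths taken from the given coordinates."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    ids = list(range(n))
    pairs = [(ids[i], ids[(i + 1) % n]) for i in range(n if closed else n - 1)]
    ga = np.array([p[0] for p in pairs], dtype=np.int64)
    gb = np.array([p[1] for p in pairs], dtype=np.int64)
    grest = np.linalg.norm(pos[gb] - pos[ga], axis=1)
    pa = np.array([p[0] for p in peptide_pairs], dtype=np.int64)
    pb = np.array([p[1] for p in peptide_pairs], dtype=np.int64)
    if pep_rest is None:
        prest = (
            np.linalg.norm(pos[pb] - pos[pa], axis=1) if len(pa) else np.zeros(0)
        )
    else:
        prest = np.asarray(pep_rest, dtype=float)
    return MeshState(
        positions=pos,
        strand_id=np.zeros(n, dtype=np.int64),
        index_on_strand=np.arange(n, dtype=np.int64),
        mobile=np.ones(n, dtype=bool),
        strands=[GlycanStrand(id=0, bead_ids=ids, closed=closed, row_index=0)],
        gly_a=ga,
        gly_b=gb,
        gly_rest=grest,
        pep_a=pa,
        pep_b=pb,
        pep_orient=np.ones(len(pa), dtype=np.int8),
        pep_rest=prest,
        pep_intact=np.ones(len(pa), dtype=bool),
        anchor_bead=np.zeros(0, dtype=np.int64),
        anchor_point=np.zeros((0, 3)),
        anchor_rest=np.zeros(0),
        anchor_intact=np.zeros(0, dtype=bool),
        leading_edge=ids,
    )


def numeric_gradient(energy_fn, positions, eps=1e-5):
    """Central finite-difference gradient of a scalar energy in the bead
    coordinates."""
    pos = positions.copy()
    g = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for c in range(3):
            pos[i, c] += eps
            ep = energy_fn(pos)
            pos[i, c] -= 2 * eps
            em = energy_fn(pos)
            pos[i, c] += eps
            g[i, c] = (ep - em) / (2 * eps)
    return g


def assert_force_is_neg_gradient(mesh, energy_fn, force, rtol=1e-6, eps=1e-5):
    """The analytic force must equal minus the numeric energy gradient."""
    def e_of(pos):
        saved = mesh.positions
        mesh.positions = pos
        try:
            return energy_fn()
        finally:
            mesh.positions = saved

    g = numeric_gradient(e_of, mesh.positions, eps=eps)
    scale = max(np.abs(g).max(), 1e-12)
    np.testing.assert_allclose(force, -g, atol=rtol * scale * 10, rtol=rtol * 100)


@pytest.fixture
def icosphere():
    """Factory for unit icosphere meshes (positions, triangles) at a given
    subdivision level; an independent closed-surface oracle."""
    import trimesh

    def make(subdivisions=2, radius=100.0):
        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)

    return make
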