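"""Force terms and overdamped Langevin integration for the wall meshwork.

Each bead obeys ``zeta dr/dt = F_spr + F_bend + F_pep + F_stoch + F_dp +
F_wall`` with uniform drag ``zeta = 4 pi eta_med l0``.  All conservative
terms are exact gradients of the energies returned by the matching
``*_energy`` helpers, which the test suite checks by central finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_mesh import MeshState, SimulationConfig, WallSurface

__all__ = [
    "ForceField",
    "StepSizeError",
    "glycan_spring_force",
    "glycan_bending_force",
    "peptide_force",
    "pressure_force",
    "wall_exclusion_force",
    "thermal_force",
    "compute_forces",
    "langevin_step",
    "spring_energy",
    "bending_energy",
    "peptide_energy",
    "wall_energy",
    "pressure_energy_closed",
    "enclosed_volume",
    "triangle_pressure_force",
    "total_energy",
    "relax",
]


class StepSizeError(RuntimeError):
    """Raised when one Euler-Maruyama step would move a bead further than
    half a bead spacing (instability guard)."""


@dataclass
class ForceField:
    """Per-bead force accumulator with a per-term breakdown (pN)."""

    terms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        it = iter(self.terms.values())
        out = next(it).copy()
        for t in it:
            out += t
        return out

    def add(self, name: str, arr: np.ndarray) -> None:
        if name in self.terms:
            self.terms[name] = self.terms[name] + arr
        else:
            self.terms[name] = arr


def _pair_spring(
    pos: np.ndarray, a: np.ndarray, b: np.ndarray, rest: np.ndarray, k: float
) -> np.ndarray:
    """Hookean pair forces; equal and opposite on each bond by construction."""
    f = np.zeros_like(pos)
    if len(a) == 0:
        return f
    d = pos[b] - pos[a]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise FloatingPointError("coincident bonded beads")
    coef = k * (r - rest) / r
    fv = coef[:, None] * d
    np.add.at(f, a, fv)
    np.add.at(f, b, -fv)
    return f


def glycan_spring_force(mesh: MeshState, cfg: SimulationConfig) -> np.ndarray:
    return _pair_spring(mesh.positions, mesh.gly_a, mesh.gly_b, mesh.gly_rest, cfg.kgly)


def peptide_force(mesh: MeshState, cfg: SimulationConfig) -> np.ndarray:
    m = mesh.pep_intact
    f = _pair_spring(
        mesh.positions, mesh.pep_a[m], mesh.pep_b[m], mesh.pep_rest[m], cfg.kpep
    )
    # junction anchors are peptide springs to fixed old-wall points
    am = mesh.anchor_intact
    if am.any():
        bead = mesh.anchor_bead[am]
        d = mesh.anchor_point[am] - mesh.positions[bead]
        r = np.linalg.norm(d, axis=1)
        rest = mesh.anchor_rest[am]
        safe = np.where(r > 1e-12, r, 1.0)
        coef = cfg.kpep * (r - rest) / safe
        coef = np.where(r > 1e-12, coef, 0.0)
        np.add.at(f, bead, coef[:, None] * d)
    return f


def glycan_bending_force(mesh: MeshState, cfg: SimulationConfig) -> np.ndarray:
    """Discrete worm-like-chain bending: E = (lp kBT / l0) sum (1 - cos th).

    The gradient of cos(theta) for the triple (i, j, k) with u = rj - ri,
    v = rk - rj follows the standard angular-force formulas.
    """
    f = np.zeros_like(mesh.positions)
    triples = mesh.bending_triples()
    if len(triples) == 0:
        return f
    kb = cfg.kappa_bend
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    pos = mesh.positions
    u = pos[j] - pos[i]
    v = pos[k] - pos[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    c = np.clip(c, -1.0, 1.0)
    # d(cos)/du and d(cos)/dv
    dcdu = v / (nu * nv)[:, None] - (c / nu**2)[:, None] * u
    dcdv = u / (nu * nv)[:, None] - (c / nv**2)[:, None] * v
    # E = kb (1 - cos), F = -dE/dr = kb * dcos/dr
    fi = -kb * dcdu
    fk = kb * dcdv
    fj = -(fi + fk)
    np.add.at(f, i, fi)
    np.add.at(f, j, fj)
    np.add.at(f, k, fk)
    return f


def triangle_pressure_force(
    pos: np.ndarray, triangles: np.ndarray, delta_p: float
) -> np.ndarray:
    """Pressure load on a triangulated surface.

    Each triangle contributes ``delta_p * A * n_hat`` split equally over its
    three vertices; the area vector is half the edge cross product, so the
    sum over any closed surface vanishes identically.
    """
    f = np.zeros_like(pos)
    if len(triangles) == 0 or delta_p == 0.0:
        return f
    p0 = pos[triangles[:, 0]]
    p1 = pos[triangles[:, 1]]
    p2 = pos[triangles[:, 2]]
    area_vec = 0.5 * np.cross(p1 - p0, p2 - p0)
    share = (delta_p / 3.0) * area_vec
    for c in range(3):
        np.add.at(f, triangles[:, c], share)
    return f


def pressure_force(mesh: MeshState, cfg: SimulationConfig) -> np.ndarray:
    return triangle_pressure_force(mesh.positions, mesh.triangles, cfg.delta_p)


def wall_exclusion_force(
    mesh: MeshState, wall: WallSurface, cfg: SimulationConfig
) -> np.ndarray:
    """Half-harmonic repulsion pushing penetrating beads back inside."""
    d = wall.signed_distance(mesh.positions)
    f = np.zeros_like(mesh.positions)
    out = d > 0
    if out.any():
        n_in = wall.inward_normal(mesh.positions[out])
        f[out] = cfg.k_wall * d[out, None] * n_in
    return f


def thermal_force(
    mesh: MeshState, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. Gaussian forces, variance 2 kBT zeta / dt per component."""
    if cfg.kBT == 0.0:
        return np.zeros_like(mesh.positions)
    sigma = np.sqrt(2.0 * cfg.kBT * cfg.zeta / cfg.dt)
    f = rng.normal(0.0, sigma, size=mesh.positions.shape)
    f[~mesh.mobile] = 0.0
    return f


def compute_forces(
    mesh: MeshState,
    cfg: SimulationConfig,
    wall: WallSurface | None = None,
    rng: np.random.Generator | None = None,
) -> ForceField:
    ff = ForceField()
    ff.add("spring", glycan_spring_force(mesh, cfg))
    ff.add("bend", glycan_bending_force(mesh, cfg))
    ff.add("pep", peptide_force(mesh, cfg))
    ff.add("pressure", pressure_force(mesh, cfg))
    if wall is not None:
        ff.add("wall", wall_exclusion_force(mesh, wall, cfg))
    if rng is not None:
        ff.add("stoch", thermal_force(mesh, cfg, rng))
    return ff


def langevin_step(
    mesh: MeshState, forces: ForceField | np.ndarray, cfg: SimulationConfig
) -> MeshState:
    """Euler-Maruyama update ``r += (F / zeta) dt`` (noise already in F)."""
    F = forces.total if isinstance(forces, ForceField) else forces
    dr = (cfg.dt / cfg.zeta) * F
    dr[~mesh.mobile] = 0.0
    dmax = np.max(np.linalg.norm(dr, axis=1)) if len(dr) else 0.0
    if dmax > 0.5 * cfg.l0:
        raise StepSizeError(
            f"max displacement {dmax:.3g} nm exceeds 0.5*l0={0.5 * cfg.l0:.3g} nm"
        )
    mesh.positions += dr
    mesh.time += cfg.dt
    return mesh


def relax(
    mesh: MeshState,
    cfg: SimulationConfig,
    wall: WallSurface | None,
    n_steps: int,
    rng: np.random.Generator | None = None,
) -> MeshState:
    """Run ``n_steps`` Langevin steps in place."""
    for _ in range(n_steps):
        ff = compute_forces(mesh, cfg, wall=wall, rng=rng)
        langevin_step(mesh, ff, cfg)
    return mesh


# ------------------------------ energies -----------------------------------


def spring_energy(mesh: MeshState, cfg: SimulationConfig) -> float:
    d = np.linalg.norm(mesh.positions[mesh.gly_b] - mesh.positions[mesh.gly_a], axis=1)
    return float(0.5 * cfg.kgly * np.sum((d - mesh.gly_rest) ** 2))


def peptide_energy(mesh: MeshState, cfg: SimulationConfig) -> float:
    m = mesh.pep_intact
    d = np.linalg.norm(
        mesh.positions[mesh.pep_b[m]] - mesh.positions[mesh.pep_a[m]], axis=1
    )
    e = 0.5 * cfg.kpep * np.sum((d - mesh.pep_rest[m]) ** 2)
    am = mesh.anchor_intact
    if am.any():
        da = np.linalg.norm(
            mesh.anchor_point[am] - mesh.positions[mesh.anchor_bead[am]], axis=1
        )
        e += 0.5 * cfg.kpep * np.sum((da - mesh.anchor_rest[am]) ** 2)
    return float(e)


def bending_energy(mesh: MeshState, cfg: SimulationConfig) -> float:
    triples = mesh.bending_triples()
    if len(triples) == 0:
        return 0.0
    pos = mesh.positions
    u = pos[triples[:, 1]] - pos[triples[:, 0]]
    v = pos[triples[:, 2]] - pos[triples[:, 1]]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return float(cfg.kappa_bend * np.sum(1.0 - np.clip(c, -1.0, 1.0)))


def wall_energy(mesh: MeshState, wall: WallSurface, cfg: SimulationConfig) -> float:
    d = wall.signed_distance(mesh.positions)
    return float(0.5 * cfg.k_wall * np.sum(np.maximum(d, 0.0) ** 2))


def enclosed_volume(pos: np.ndarray, triangles: np.ndarray) -> float:
    """Signed volume of a closed triangulated surface (divergence theorem)."""
    p0 = pos[triangles[:, 0]]
    p1 = pos[triangles[:, 1]]
    p2 = pos[triangles[:, 2]]
    return float(np.sum(np.einsum("ij,ij->i", p0, np.cross(p1, p2))) / 6.0)


def pressure_energy_closed(
    pos: np.ndarray, triangles: np.ndarray, delta_p: float
) -> float:
    """Potential -delta_p * V for a closed surface; its negative gradient is
    exactly ``triangle_pressure_force``."""
    return -delta_p * enclosed_volume(pos, triangles)


def total_energy(
    mesh: MeshState, cfg: SimulationConfig, wall: WallSurface | None = None
) -> float:
    """Total conservative energy excluding the pressure term (which is only
    a potential for closed surfaces) -- used by relaxation tests."""
    e = spring_energy(mesh, cfg) + peptide_energy(mesh, cfg) + bending_energy(mesh, cfg)
    if wall is not None:
        e += wall_energy(mesh, wall, cfg)
    return e
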