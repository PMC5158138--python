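"""Force terms, energies and the overdamped integrator."""

import numpy as np
import pytest

from engulf import mechanics as mech
from engulf.core_mesh import SimulationConfig

from conftest import (
    assert_force_is_neg_gradient,
    single_bead_mesh,
    strand_mesh,
)


def small_random_mesh(seed=0, n=6):
    """Gently perturbed open strand with a couple of peptide bonds."""
    rng = np.random.default_rng(seed)
    base = np.column_stack([np.arange(n) * 10.0, np.zeros(n), np.zeros(n)])
    pos = base + rng.normal(0, 1.0, base.shape)
    mesh = strand_mesh(pos, closed=False, peptide_pairs=[(0, 3), (1, 4)])
    # stretch away from rest so forces are nonzero
    mesh.positions = mesh.positions + rng.normal(0, 0.8, mesh.positions.shape)
    return mesh


class TestSpringForces:
    def test_bond_at_rest_length_gives_zero(self, cfg):
        mesh = strand_mesh([[0, 0, 0], [cfg.l0, 0, 0]])
        f = mech.glycan_spring_force(mesh, cfg)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_stretched_glycan_bond_hooke(self):
        cfg = SimulationConfig(kgly=200.0, l0=25.0)
        mesh = strand_mesh([[0, 0, 0], [25.0, 0, 0]])
        mesh.positions[1, 0] = 25.1  # stretch by 0.1 nm at 200 pN/nm
        f = mech.glycan_spring_force(mesh, cfg)
        assert f[0, 0] == pytest.approx(20.0, rel=1e-9)
        assert f[1, 0] == pytest.approx(-20.0, rel=1e-9)

    def test_stretched_peptide_bond_hooke(self):
        cfg = SimulationConfig(kpep=25.0, d_pep=2.0)
        mesh = strand_mesh(
            [[0, 0, 0], [10, 0, 0], [0, 3, 0], [10, 3, 0]],
            peptide_pairs=[(0, 2)],
            pep_rest=[2.0],
        )
        f = mech.peptide_force(mesh, cfg)  # bond at 3 nm, rest 2 nm
        assert f[0, 1] == pytest.approx(25.0, rel=1e-9)
        assert f[2, 1] == pytest.approx(-25.0, rel=1e-9)

    def test_pair_forces_sum_to_zero(self, cfg):
        mesh = small_random_mesh(3)
        for term in (mech.glycan_spring_force, mech.peptide_force):
            f = term(mesh, cfg)
            np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_spring_force_is_energy_gradient(self, cfg, seed):
        mesh = small_random_mesh(seed)
        assert_force_is_neg_gradient(
            mesh, lambda: mech.spring_energy(mesh, cfg), mech.glycan_spring_force(mesh, cfg)
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_peptide_force_is_energy_gradient(self, cfg, seed):
        mesh = small_random_mesh(seed)
        assert_force_is_neg_gradient(
            mesh, lambda: mech.peptide_energy(mesh, cfg), mech.peptide_force(mesh, cfg)
        )

    def test_severed_peptide_contributes_nothing(self, cfg):
        mesh = small_random_mesh(0)
        f_all = mech.peptide_force(mesh, cfg)
        mesh.pep_intact[:] = False
        f_none = mech.peptide_force(mesh, cfg)
        assert np.abs(f_all).max() > 0
        np.testing.assert_allclose(f_none, 0.0)


class TestBending:
    def test_collinear_triple_has_zero_bending_force(self, cfg):
        mesh = strand_mesh([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        f = mech.glycan_bending_force(mesh, cfg)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_right_angle_restores_collinearity(self, cfg):
        mesh = strand_mesh([[0, 0, 0], [10, 0, 0], [10, 10, 0]])
        f = mech.glycan_bending_force(mesh, cfg)
        # end beads are pushed to open the angle: outer product with the
        # opening direction is positive
        assert f[0, 1] < 0  # bead 0 pulled toward -y (straightening)
        assert f[2, 0] > 0  # bead 2 pushed toward +x
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bending_force_is_energy_gradient(self, cfg, seed):
        mesh = small_random_mesh(seed)
        assert_force_is_neg_gradient(
            mesh,
            lambda: mech.bending_energy(mesh, cfg),
            mech.glycan_bending_force(mesh, cfg),
        )

    def test_closed_hoop_energy_matches_continuum(self):
        # worm-like chain: E = lp kBT L / (2 R^2) for a circle
        cfg = SimulationConfig(l0=25.0, lp=1960.0, kBT=4.1)
        R, n = 400.0, 100
        ang = 2 * np.pi * np.arange(n) / n
        pos = np.column_stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n)])
        mesh = strand_mesh(pos, closed=True)
        cfg2 = SimulationConfig(l0=float(2 * R * np.sin(np.pi / n)), lp=1960.0, kBT=4.1)
        e = mech.bending_energy(mesh, cfg2)
        L = n * cfg2.l0
        continuum = cfg2.lp * cfg2.kBT * L / (2 * R**2)
        assert e == pytest.approx(continuum, rel=0.02)


class TestPressure:
    def test_flat_patch_total_force(self):
        # 100 nm^2 at 86.31 kPa -> 8.631 pN along the normal
        delta_p = 0.08631
        pos = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], dtype=float)
        tris = np.array([[0, 1, 2], [0, 2, 3]])
        f = mech.triangle_pressure_force(pos, tris, delta_p)
        total = f.sum(axis=0)
        assert np.linalg.norm(total) == pytest.approx(8.631, rel=1e-12)

    def test_closed_sphere_forces_sum_to_zero(self, icosphere):
        pos, tris = icosphere(2)
        delta_p = 0.08631
        f = mech.triangle_pressure_force(pos, tris, delta_p)
        area = mech.enclosed_volume(pos, tris)  # proxy scale
        np.testing.assert_allclose(
            f.sum(axis=0), 0.0, atol=1e-9 * delta_p * abs(area)
        )

    def test_sphere_pressure_converges_quadratically(self, icosphere):
        delta_p = 0.08631
        errs = []
        for sub in (0, 1, 2, 3):
            pos, tris = icosphere(sub)
            f = mech.triangle_pressure_force(pos, tris, delta_p)
            p0 = pos[tris[:, 0]]
            p1 = pos[tris[:, 1]]
            p2 = pos[tris[:, 2]]
            area = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1).sum() / 2
            per_area = np.linalg.norm(f, axis=1).sum() / area
            errs.append(abs(per_area - delta_p) / delta_p)
        assert errs[-1] < 0.01
        assert all(a > b for a, b in zip(errs[:-1], errs[1:]))

    def test_pressure_force_is_volume_gradient_on_closed_mesh(self, icosphere):
        pos, tris = icosphere(1)
        delta_p = 0.05

        def energy(p):
            return mech.pressure_energy_closed(p, tris, delta_p)

        from conftest import numeric_gradient

        f = mech.triangle_pressure_force(pos, tris, delta_p)
        g = numeric_gradient(energy, pos, eps=1e-4)
        # the energy is ~1e5 pN nm, so central differences carry ~1e-7 pN
        # of rounding noise; forces are O(100) pN
        np.testing.assert_allclose(f, -g, rtol=1e-6, atol=1e-5)


class TestWall:
    def test_inside_bead_feels_nothing(self, cfg, wall):
        mesh = single_bead_mesh([wall.R - 3.0, 0.0, -5.0])
        f = mech.wall_exclusion_force(mesh, wall, cfg)
        np.testing.assert_allclose(f, 0.0)

    def test_penetrating_bead_pushed_back(self, wall):
        cfg = SimulationConfig(k_wall=100.0)
        mesh = single_bead_mesh([wall.R + 1.0, 0.0, -5.0])
        f = mech.wall_exclusion_force(mesh, wall, cfg)
        assert f[0, 0] == pytest.approx(-100.0, rel=1e-9)

    def test_wall_force_is_energy_gradient(self, cfg, wall):
        mesh = single_bead_mesh([wall.R + 2.0, 1.0, -5.0])
        assert_force_is_neg_gradient(
            mesh,
            lambda: mech.wall_energy(mesh, wall, cfg),
            mech.wall_exclusion_force(mesh, wall, cfg),
            eps=1e-6,
        )


class TestThermal:
    def test_zero_temperature_is_silent(self):
        cfg = SimulationConfig(kBT=0.0)
        mesh = single_bead_mesh()
        f = mech.thermal_force(mesh, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(f, 0.0)

    def test_moments_match_fluctuation_dissipation(self, cfg):
        rng = np.random.default_rng(42)
        mesh = single_bead_mesh()
        samples = np.array(
            [mech.thermal_force(mesh, cfg, rng)[0] for _ in range(40_000)]
        ).ravel()
        var_expected = 2 * cfg.kBT * cfg.zeta / cfg.dt
        se = np.sqrt(var_expected / len(samples))
        assert abs(samples.mean()) < 4 * se
        assert samples.var() == pytest.approx(var_expected, rel=0.02)

    def test_same_seed_reproduces_forces(self, cfg):
        mesh = single_bead_mesh()
        f1 = mech.thermal_force(mesh, cfg, np.random.default_rng(7))
        f2 = mech.thermal_force(mesh, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(f1, f2)


class TestIntegrator:
    def test_no_force_no_motion(self):
        cfg = SimulationConfig(kBT=0.0)
        mesh = single_bead_mesh([1.0, 2.0, 3.0])
        before = mesh.positions.copy()
        mech.langevin_step(mesh, np.zeros((1, 3)), cfg)
        np.testing.assert_array_equal(mesh.positions, before)
        assert mesh.time == cfg.dt

    def test_constant_force_exact_displacement(self, cfg):
        mesh = single_bead_mesh()
        F = np.array([[3.0, 0.0, 0.0]])
        mech.langevin_step(mesh, F, cfg)
        assert mesh.positions[0, 0] == pytest.approx(
            3.0 * cfg.dt / cfg.zeta, rel=1e-12
        )

    def test_instability_guard_trips(self, cfg):
        mesh = single_bead_mesh()
        F = np.array([[1e12, 0.0, 0.0]])
        with pytest.raises(mech.StepSizeError):
            mech.langevin_step(mesh, F, cfg)

    def test_equipartition_in_harmonic_trap(self):
        # positional variance of an overdamped bead in a k-trap is kBT/k
        k = 1.0
        cfg = SimulationConfig(kBT=4.1, l0=25.0)
        cfg.dt = 0.02 * cfg.zeta / k
        mesh = single_bead_mesh()
        rng = np.random.default_rng(123)
        n_steps, burn = 100_000, 5_000
        out = np.empty((n_steps, 3))
        for i in range(n_steps):
            F = -k * mesh.positions + mech.thermal_force(mesh, cfg, rng)
            mech.langevin_step(mesh, F, cfg)
            out[i] = mesh.positions[0]
        var = out[burn:].var(axis=0).mean()
        assert var == pytest.approx(cfg.kBT / k, rel=0.05)

    def test_zero_temperature_relaxation_decreases_energy(self, cfg, geom):
        from engulf.core_mesh import build_septal_disc

        cfg0 = SimulationConfig(l0=25.0, kBT=0.0)
        mesh = build_septal_disc(geom, cfg0)
        rng = np.random.default_rng(5)
        mesh.positions += rng.normal(0, 2.0, mesh.positions.shape)
        energies = [mech.total_energy(mesh, cfg0)]
        for _ in range(40):
            ff = mech.ForceField()
            ff.add("spring", mech.glycan_spring_force(mesh, cfg0))
            ff.add("pep", mech.peptide_force(mesh, cfg0))
            ff.add("bend", mech.glycan_bending_force(mesh, cfg0))
            mech.langevin_step(mesh, ff, cfg0)
            energies.append(mech.total_energy(mesh, cfg0))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)
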