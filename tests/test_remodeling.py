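"""3D insertion-degradation dynamics: rules, invariants and variants."""

import copy

import numpy as np
import pytest

from engulf.core_mesh import ConfigurationError, ForesporeGeometry, SimulationConfig, validate_mesh
from engulf.remodeling import (
    EngulfmentSimulation,
    RemodelingConfig,
    locate_leading_edge,
    random_peptide_degradation,
    run_engulfment,
)

TEST_RUN = dict(min_hoop_radius_fraction=0.2, steps_per_event=6, record_every=25)


def mk_cfg(**kw):
    return SimulationConfig(l0=24.0, d_pep=10.0, seed=1, **kw)


def mk_geom():
    return ForesporeGeometry(cell_radius=120.0)


class TestRemodelingConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigurationError):
            RemodelingConfig(prep=1.2)
        with pytest.raises(ConfigurationError):
            RemodelingConfig(VIDC=0.0)

    def test_coupled_mode_forbids_delay_parameters(self):
        with pytest.raises(ConfigurationError):
            RemodelingConfig(coupled=True, tau_delay=5.0)
        RemodelingConfig(coupled=False, tau_delay=5.0, ppcut=0.1)  # fine


class TestLeadingEdge:
    def test_fresh_disc_leading_edge_is_outermost_hoop(self):
        cfg, geom = mk_cfg(), mk_geom()
        sim = EngulfmentSimulation(cfg, RemodelingConfig(), geom, seed=0)
        ring = locate_leading_edge(sim.mesh)
        assert set(ring) == set(sim.mesh.strands[-1].bead_ids)

    def test_ring_ordering_is_angular_sort(self):
        cfg, geom = mk_cfg(), mk_geom()
        sim = EngulfmentSimulation(cfg, RemodelingConfig(NIDC=3), geom, seed=0)
        # advance a bit so the leading edge lives on junction anchors
        for _ in range(200):
            sim._idc_event(sim.idcs[sim.events % 3])
            sim.events += 1
        ring = locate_leading_edge(sim.mesh)
        ang = np.arctan2(
            sim.mesh.positions[ring, 1], sim.mesh.positions[ring, 0]
        )
        assert np.all(np.diff(ang) > 0)  # strictly sorted about the axis


class TestInsertionRules:
    def test_processivity_success_fraction(self):
        # an isolated complex facing an old-wall gap continues with ppro
        successes = 0
        trials = 10_000
        rng_cfg = RemodelingConfig(prep=1.0, ppro=0.7, NIDC=1, f0=0.0)
        sim = EngulfmentSimulation(mk_cfg(), rng_cfg, mk_geom(), seed=0)
        idc = sim.idcs[0]
        for t in range(trials):
            # reset: polymerizing in row 1, gap directly ahead
            j = (idc.sector + idc.direction) % sim.M
            sim.occ[1, :] = 0
            sim.bead_at[1, :] = -1
            sim.anchor_exists[1, j] = False
            idc.mode, idc.row = "polymerizing", 1
            before = sim.mesh.n_beads
            sim._idc_event(idc)
            if sim.mesh.n_beads > before:
                successes += 1
            idc.sector = 5  # park away from previous insertions
            idc.direction = 1
        frac = successes / trials
        assert frac == pytest.approx(0.7, abs=0.02)

    def test_stalled_without_complexes(self):
        sim, trace, info = run_engulfment(
            mk_cfg(), RemodelingConfig(NIDC=0), mk_geom(), seed=0,
            max_time_s=100.0, **TEST_RUN,
        )
        assert np.ptp(trace.E) == pytest.approx(0.0, abs=1e-9)

    def test_make_before_break(self):
        # a junction anchor is only severed once the bridging bead of the
        # next hoop exists at that sector
        cfg, geom = mk_cfg(), mk_geom()
        rcfg = RemodelingConfig(prep=1.0, ppro=1.0, NIDC=5, f0=0.05)
        sim = EngulfmentSimulation(cfg, rcfg, geom, seed=3)
        for step in range(2000):
            idc = sim.idcs[step % 5]
            sim._idc_event(idc)
            cut = (~sim.mesh.anchor_intact).nonzero()[0]
            for ai in cut:
                bead = sim.mesh.anchor_bead[ai]
                k, j = np.argwhere(sim.bead_at == bead)[0]
                assert sim.occ[k + 1, j] == 1, "junction cut before replacement"

    def test_mesh_stays_valid_during_remodeling(self):
        cfg, geom = mk_cfg(), mk_geom()
        rcfg = RemodelingConfig(prep=1.0, ppro=1.0, NIDC=4, f0=0.02)
        sim = EngulfmentSimulation(cfg, rcfg, geom, seed=2)
        for step in range(1500):
            sim._idc_event(sim.idcs[step % 4])
            if step % 300 == 299:
                assert validate_mesh(sim.mesh).ok

    def test_flux_bookkeeping_matches_nidc_vidc(self):
        cfg, geom = mk_cfg(), mk_geom()
        rcfg = RemodelingConfig(prep=1.0, ppro=1.0, NIDC=5, VIDC=30.0, f0=0.0)
        sim, trace, info = run_engulfment(cfg, rcfg, geom, seed=1, stop_E=80.0, **TEST_RUN)
        from engulf.observables import insertion_flux

        # over the active time (events during which every complex kept
        # inserting) the per-glycan flux equals NIDC * VIDC * n_bundle
        inserted = info["length_inserted_total_nm"]
        n_beads_inserted = inserted / (cfg.l0 * cfg.n_bundle)
        active_time = n_beads_inserted * sim.event_interval
        flux = insertion_flux(inserted, active_time)
        assert flux == pytest.approx(rcfg.NIDC * rcfg.VIDC * cfg.n_bundle, rel=0.01)


class TestPhenotypes:
    def test_wild_type_engulfs_symmetrically(self):
        rcfg = RemodelingConfig(prep=1.0, ppro=1.0, NIDC=5, VIDC=30.0, f0=0.2)
        sim, trace, info = run_engulfment(
            mk_cfg(), rcfg, mk_geom(), seed=4, stop_E=90.0, max_time_s=3e5, **TEST_RUN
        )
        # engulfment completes and is non-decreasing after the initial
        # septum-curving phase
        assert trace.E[-1] >= 90.0
        tail = trace.E[len(trace) // 4 :]
        assert np.all(np.diff(tail) > -1.5)
        assert info["le_spread_nm"] <= sim.row_spacing + 1e-9

    def test_reduced_repair_engulfs_asymmetrically(self):
        spreads = {p: [] for p in (1.0, 0.7)}
        for p in spreads:
            for s in range(5):
                rcfg = RemodelingConfig(prep=p, ppro=p, NIDC=5, VIDC=30.0, f0=0.2)
                _, _, info = run_engulfment(
                    mk_cfg(), rcfg, mk_geom(), seed=30 + s, stop_E=90.0,
                    max_time_s=3e5, **TEST_RUN,
                )
                spreads[p].append(info["le_spread_nm"])
        assert np.mean(spreads[0.7]) > np.mean(spreads[1.0])

    def test_fully_reproducible_under_seed(self):
        rcfg = RemodelingConfig(prep=0.8, ppro=0.8, NIDC=3, f0=0.1)
        traces = []
        for _ in range(2):
            _, tr, _ = run_engulfment(
                mk_cfg(), rcfg, mk_geom(), seed=11, stop_E=70.0, **TEST_RUN
            )
            traces.append(tr)
        np.testing.assert_array_equal(traces[0].E, traces[1].E)
        np.testing.assert_array_equal(traces[0].V, traces[1].V)


class TestDecoupledDegradation:
    def _run(self, tau, seed=7, ppcut=0.0):
        rcfg = RemodelingConfig(
            prep=1.0, ppro=1.0, NIDC=5, VIDC=2.0, coupled=False,
            tau_delay=tau, ppcut=ppcut, f0=0.01,
        )
        return run_engulfment(
            mk_cfg(), rcfg, mk_geom(), seed=seed, stop_E=95.0,
            max_time_s=1e6, **TEST_RUN,
        )

    def test_zero_delay_separation_is_one_spacing(self):
        sim, trace, info = self._run(0.0)
        sep = info["id_separation"]
        tail = sep[len(sep) // 2 :, 1]
        # separation stays within about one bead spacing of the synthesis site
        assert tail.mean() <= 4 * sim.cfg.l0

    def test_separation_non_decreasing_in_delay(self):
        # printed delays 0, 0.9, 9, 18 min with a slowed insertion clock
        means = []
        for tau in (0.0, 54.0, 540.0, 1080.0):
            sim, trace, info = self._run(tau)
            sep = info["id_separation"]
            means.append(sep[len(sep) // 2 :, 1].mean())
        assert all(b >= a - 5.0 for a, b in zip(means[:-1], means[1:]))
        assert means[-1] > means[0]

    def test_erroneous_vertical_cut_fraction(self):
        sim, trace, info = self._run(1e-6, ppcut=0.1, seed=9)
        n_vert_cut = int((~sim.mesh.pep_intact).sum())
        n_events = n_vert_cut + int((~sim.mesh.anchor_intact).sum())
        assert n_events > 50
        # binomial 3-sigma interval around ppcut = 0.1
        p_hat = n_vert_cut / n_events
        assert abs(p_hat - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n_events)

    def test_coupled_run_has_no_separation_trace(self):
        rcfg = RemodelingConfig(coupled=True)
        sim = EngulfmentSimulation(mk_cfg(), rcfg, mk_geom(), seed=0)
        with pytest.raises(ConfigurationError):
            sim.id_separation()


class TestRandomDegradation:
    def _engulfed_sim(self):
        rcfg = RemodelingConfig(NIDC=5, VIDC=30.0, f0=0.05)
        sim, trace, info = run_engulfment(
            mk_cfg(), rcfg, mk_geom(), seed=3, stop_E=70.0, **TEST_RUN
        )
        # settle the mesh so later volume drift is degradation, not leftover
        # relaxation
        sim.relax(n_steps=400, thermal=False)
        return sim

    def test_zero_rate_keeps_bonds_and_volume(self):
        sim = self._engulfed_sim()
        rcfg = RemodelingConfig(NIDC=5, prpep=0.0)
        rec, _ = random_peptide_degradation(
            sim.mesh, sim.cfg, rcfg, sim.wall, duration_s=30.0,
            profile_fn=sim.profile, n_substeps=20, relax_steps=10, seed=0,
        )
        assert rec[0, 2] == rec[-1, 2]
        assert abs(rec[-1, 1] - rec[0, 1]) / rec[0, 1] < 0.02

    def test_survival_follows_poisson_thinning(self):
        sim = self._engulfed_sim()
        rate = 2.2  # 1/min
        rcfg = RemodelingConfig(NIDC=5, prpep=rate)
        duration = 60.0
        rec, _ = random_peptide_degradation(
            sim.mesh, sim.cfg, rcfg, sim.wall, duration_s=duration,
            profile_fn=sim.profile, n_substeps=20, relax_steps=2, seed=1,
        )
        n0 = rec[0, 2]
        expected = np.exp(-rate / 60.0 * duration)
        p_hat = rec[-1, 2] / n0
        assert abs(p_hat - expected) < 3 * np.sqrt(expected * (1 - expected) / n0)

    def test_volume_deviation_monotone_in_rate(self):
        base = self._engulfed_sim()
        devs = []
        for rate in (0.0, 2.2, 22.0):
            sim = copy.deepcopy(base)
            rcfg = RemodelingConfig(NIDC=5, prpep=rate)
            rec, _ = random_peptide_degradation(
                sim.mesh, sim.cfg, rcfg, sim.wall, duration_s=45.0,
                profile_fn=sim.profile, n_substeps=20, relax_steps=10, seed=2,
            )
            devs.append(abs(rec[-1, 1] - rec[0, 1]))
        assert devs[0] <= devs[1] <= devs[2] + 1e-12
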