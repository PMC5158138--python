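"""Insertion-degradation complexes remodeling the 3D wall mesh.

The engulfment engine couples two layers:

* a stochastic insertion layer on a (row x angular sector) lattice
  congruent with the 2D leading-edge model: each complex (IDC) tracks the
  leading edge with a fixed circumferential handedness, appends one
  bead-length of new glycan per event (one event every ``l0 / VIDC``
  seconds), continues across old-wall template gaps with probability
  ``ppro`` and re-initiates at exposed strand ends with probability
  ``prep``;
* the bead-spring mechanics of :mod:`engulf.mechanics`, relaxed by a
  fixed number of Langevin steps between remodeling events (a
  quasi-static approximation; the trace's clock is the event clock set by
  the insertion speed).

Each inserted bead is cross-linked by relaxed peptides to both templates:
the previous germ-wall hoop below it and the old-wall anchor site of its
row.  In coupled mode the junction anchor of the hoop *behind* the
insertion site is severed in the same event (make-before-break); in
decoupled mode anchors are severed after an exponential delay of mean
``tau_delay``, and with probability ``ppcut`` the erroneous vertical
peptide is cut instead of the targeted junction.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .core_mesh import (
    ConfigurationError,
    ForesporeGeometry,
    GlycanStrand,
    MeshState,
    SimulationConfig,
    build_lateral_wall,
    build_septal_disc,
)
from .mechanics import compute_forces, langevin_step
from .observables import (
    EngulfmentTrace,
    mean_id_separation,
    percent_engulfment,
    volume_surface_by_revolution,
)

__all__ = [
    "RemodelingConfig",
    "IDCState",
    "EngulfmentSimulation",
    "run_engulfment",
    "locate_leading_edge",
    "random_peptide_degradation",
]

NM_PER_UM = 1e3


@dataclass
class RemodelingConfig:
    """Stochastic remodeling parameters.

    prep, ppro: repair and processivity probabilities; NIDC: number of
    complexes; VIDC: per-complex insertion speed, nm/s; tau_delay:
    synthesis-to-degradation delay, s (decoupled mode); ppcut: erroneous
    vertical-cut probability; prpep: random peptide degradation rate,
    1/min; coupled: simultaneous insertion+degradation.
    """

    prep: float = 1.0
    ppro: float = 1.0
    NIDC: int = 5
    VIDC: float = 30.0
    tau_delay: float = 0.0
    ppcut: float = 0.0
    prpep: float = 0.0
    coupled: bool = True
    f0: float = 0.01  # old-wall template hole fraction

    def __post_init__(self) -> None:
        for p in (self.prep, self.ppro, self.ppcut):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.NIDC < 0 or self.VIDC <= 0 or self.tau_delay < 0 or self.prpep < 0:
            raise ConfigurationError("rates must be >= 0 and VIDC > 0")
        if self.coupled and (self.tau_delay != 0 or self.ppcut != 0):
            raise ConfigurationError("coupled mode forces tau_delay = ppcut = 0")


@dataclass
class IDCState:
    id: int
    sector: int
    direction: int  # +1 / -1 about the long axis
    mode: str = "idle"  # "polymerizing" | "idle"
    row: int = 0
    current_strand_id: int = -1
    lap: int = 0
    length_inserted_total: float = 0.0  # nm, single-glycan basis

    @property
    def angular_position(self) -> float:
        return self.sector  # converted to radians by the simulation


class EngulfmentSimulation:
    """Template-mechanism engulfment of a forespore by wall remodeling.

    The old wall is a static surface with per-(row, sector) anchor sites
    (missing with probability ``f0``); germ-wall hoops grow row by row
    from the septal disc toward the pole, held to the old wall by
    junction anchors until degradation releases them.
    """

    def __init__(
        self,
        cfg: SimulationConfig,
        rcfg: RemodelingConfig,
        geom: ForesporeGeometry,
        seed: int | None = None,
        row_spacing: float | None = None,
        steps_per_event: int = 10,
        min_hoop_radius_fraction: float = 0.3,
    ):
        self.cfg = cfg
        self.rcfg = rcfg
        self.geom = geom
        self.rng = np.random.default_rng(cfg.seed if seed is None else seed)
        self.wall = build_lateral_wall(geom, cfg)
        self.mesh = build_septal_disc(geom, cfg)
        self.steps_per_event = steps_per_event
        self.row_spacing = row_spacing if row_spacing is not None else cfg.d_pep

        R = geom.cell_radius
        self.M = max(8, int(round(2 * np.pi * R / cfg.l0)))
        s = self.row_spacing * np.arange(1, int(self.wall.meridian_length / self.row_spacing) + 1)
        rz = self.wall.meridian_point(s)
        keep = rz[:, 0] >= min_hoop_radius_fraction * R
        self.row_arc = s[keep]
        self.row_rz = rz[keep]
        self.n_rows = len(self.row_arc)
        if self.n_rows < 2:
            raise ConfigurationError("geometry yields fewer than 2 template rows")
        # old-wall anchor sites; row index 1..n_rows in the occupancy grid
        self.anchor_exists = self.rng.random((self.n_rows + 1, self.M)) >= rcfg.f0
        self.anchor_exists[0] = True

        self.occ = np.zeros((self.n_rows + 1, self.M), dtype=np.uint8)
        self.occ[0] = 1  # septal junction ring (disc edge) is the founding row
        self.h = np.zeros(self.M, dtype=np.int64)
        self.defect = np.zeros_like(self.occ)
        self.sealed = np.zeros_like(self.occ)
        self.bead_at = -np.ones((self.n_rows + 1, self.M), dtype=np.int64)
        self.anchor_idx = -np.ones((self.n_rows + 1, self.M), dtype=np.int64)
        self.vertical_pep_idx = -np.ones((self.n_rows + 1, self.M), dtype=np.int64)

        self.idcs = [
            IDCState(id=a, sector=(a * self.M) // max(rcfg.NIDC, 1) % self.M,
                     direction=1 if a % 2 == 0 else -1, lap=self.M)
            for a in range(rcfg.NIDC)
        ]
        self.time = 0.0
        self.event_interval = cfg.l0 / rcfg.VIDC / max(rcfg.NIDC, 1)
        self._sever_queue: list[tuple[float, int, int]] = []  # (t, row, sector)
        self.events = 0
        self.aborted = None

    # ------------------------------ geometry -------------------------------

    def _sector_angle(self, j: int) -> float:
        return 2 * np.pi * j / self.M

    def _site_position(self, k: int, j: int) -> np.ndarray:
        r, z = self.row_rz[k - 1]
        a = self._sector_angle(j)
        # place the bead just inside the wall surface
        rr = r - 0.5
        return np.array([rr * np.cos(a), rr * np.sin(a), z])

    # ------------------------------ mesh growth ----------------------------

    def _add_bead(self, k: int, j: int, strand_id: int | None, idc: IDCState) -> int:
        mesh = self.mesh
        pos = self._site_position(k, j)
        bead = mesh.n_beads
        mesh.positions = np.vstack([mesh.positions, pos])
        mesh.mobile = np.append(mesh.mobile, True)
        if strand_id is None or strand_id < 0:
            sid = len(mesh.strands)
            mesh.strands.append(
                GlycanStrand(id=sid, bead_ids=[bead], closed=False, row_index=k)
            )
            idc.current_strand_id = sid
        else:
            sid = strand_id
            strand = mesh.strands[sid]
            prev = strand.bead_ids[-1]
            strand.bead_ids.append(bead)
            rest = float(np.linalg.norm(mesh.positions[prev] - pos))
            mesh.gly_a = np.append(mesh.gly_a, prev)
            mesh.gly_b = np.append(mesh.gly_b, bead)
            mesh.gly_rest = np.append(mesh.gly_rest, rest)
        mesh.strand_id = np.append(mesh.strand_id, sid)
        mesh.index_on_strand = np.append(
            mesh.index_on_strand, len(mesh.strands[sid].bead_ids) - 1
        )
        # vertical peptide to the previous germ hoop (relaxed at creation)
        below = self.bead_at[k - 1, j] if k >= 2 else -1
        if k == 1:
            below = self._disc_edge_bead(j)
        if below >= 0:
            rest = float(np.linalg.norm(mesh.positions[below] - pos))
            mesh.pep_a = np.append(mesh.pep_a, below)
            mesh.pep_b = np.append(mesh.pep_b, bead)
            from .core_mesh import VERTICAL

            mesh.pep_orient = np.append(mesh.pep_orient, np.int8(VERTICAL))
            mesh.pep_rest = np.append(mesh.pep_rest, rest)
            mesh.pep_intact = np.append(mesh.pep_intact, True)
            self.vertical_pep_idx[k, j] = len(mesh.pep_a) - 1
        # horizontal junction to the old-wall anchor site (relaxed)
        if self.anchor_exists[k, j]:
            r, z = self.row_rz[k - 1]
            a = self._sector_angle(j)
            anchor_pt = np.array([r * np.cos(a), r * np.sin(a), z])
            mesh.anchor_bead = np.append(mesh.anchor_bead, bead)
            mesh.anchor_point = np.vstack([mesh.anchor_point, anchor_pt])
            mesh.anchor_rest = np.append(
                mesh.anchor_rest, float(np.linalg.norm(anchor_pt - pos))
            )
            mesh.anchor_intact = np.append(mesh.anchor_intact, True)
            self.anchor_idx[k, j] = len(mesh.anchor_bead) - 1
        self.bead_at[k, j] = bead
        self.occ[k, j] = 1
        self.h[j] = max(self.h[j], k)
        mesh.invalidate_triangulation()
        self._triples_dirty = True
        return bead

    def _disc_edge_bead(self, j: int) -> int:
        ids = self.mesh.leading_edge
        return ids[int(round(j / self.M * len(ids))) % len(ids)]

    def _sever_junction(self, k: int, j: int) -> None:
        """Degrade the junction of hoop k at sector j (make-before-break:
        called only once the bridging segment of hoop k+1 exists)."""
        if k < 1:
            return
        if not self.rcfg.coupled and self.rcfg.ppcut > 0 and self.rng.random() < self.rcfg.ppcut:
            vp = self.vertical_pep_idx[k, j]
            if vp >= 0:
                self.mesh.pep_intact[vp] = False  # erroneous vertical cut
            return
        ai = self.anchor_idx[k, j]
        if ai >= 0:
            self.mesh.anchor_intact[ai] = False

    # --------------------------- stochastic rules --------------------------

    def _idc_event(self, idc: IDCState) -> bool:
        """One action of one complex (rules congruent with the 2D model);
        returns True when a bead was inserted."""
        rng = self.rng
        M = self.M
        if idc.mode == "polymerizing":
            k = idc.row
            j = (idc.sector + idc.direction) % M
            if self.occ[k, j]:
                idc.mode = "idle"
                idc.lap = 0
                return False
            germ_ok = bool(self.occ[k - 1, j])
            wall_ok = bool(self.anchor_exists[k, j])
            if (germ_ok and wall_ok) or (germ_ok and rng.random() < self.rcfg.ppro):
                self._insert(idc, k, j, new_strand=False)
                return True
            self.defect[k, j] = 1
            idc.mode = "idle"
            idc.lap = 0
            return False
        # idle: walk the leading edge
        j = (idc.sector + idc.direction) % M
        idc.sector = j
        idc.lap += 1
        k = int(self.h[j]) + 1
        if k > self.n_rows:
            return False
        prev = (j - idc.direction) % M
        down_step = self.h[prev] > self.h[j]
        nucleate = idc.lap >= M and (self.h[j] == self.h.min() or idc.lap >= 2 * M)
        if not (down_step or nucleate):
            return False
        if self.defect[k, j]:
            p_res = self.rcfg.prep ** (1.0 + float(self.sealed[k, j]))
            if rng.random() >= p_res:
                if self.sealed[k, j] < 60:
                    self.sealed[k, j] += 1
                return False
        germ_ok = bool(self.occ[k - 1, j])
        wall_ok = bool(self.anchor_exists[k, j])
        if not germ_ok:
            return False
        if not wall_ok and rng.random() >= self.rcfg.ppro:
            return False
        self._insert(idc, k, j, new_strand=True)
        return True

    def _insert(self, idc: IDCState, k: int, j: int, new_strand: bool) -> None:
        sid = None if new_strand else idc.current_strand_id
        self._add_bead(k, j, sid, idc)
        idc.mode = "polymerizing"
        idc.row = k
        idc.sector = j
        idc.length_inserted_total += self.cfg.l0 * self.cfg.n_bundle
        # degradation of the junction behind the insertion site
        if k >= 2:
            if self.rcfg.coupled:
                self._sever_junction(k - 1, j)
            else:
                t = self.time + (
                    self.rng.exponential(self.rcfg.tau_delay)
                    if self.rcfg.tau_delay > 0
                    else 0.0
                )
                heapq.heappush(self._sever_queue, (t, k - 1, j))

    def delayed_degradation_step(self) -> int:
        """Sever all junctions whose exponential delay has elapsed
        (decoupled mode); returns the number of bonds cut."""
        if self.rcfg.coupled:
            raise ConfigurationError("delayed degradation requires coupled=False")
        n = 0
        while self._sever_queue and self._sever_queue[0][0] <= self.time:
            _, k, j = heapq.heappop(self._sever_queue)
            self._sever_junction(k, j)
            n += 1
        return n

    # ------------------------------ observables ----------------------------

    def profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Medial (r, z) profile in um of the full forespore boundary:
        disc rings (germ wall), grown cup hoops (germ wall), then the
        uncovered old-wall meridian ahead of the leading edge.  Returns
        (profile, covered-segment mask)."""
        mesh = self.mesh
        pts = []
        # disc rings, centre outward
        disc = [s for s in mesh.strands if s.row_index <= 0]
        disc.sort(key=lambda s: s.row_index)
        for s in disc:
            p = mesh.positions[s.bead_ids]
            pts.append([np.hypot(p[:, 0], p[:, 1]).mean(), p[:, 2].mean()])
        pts = [[0.0, pts[0][1]]] + pts  # close onto the axis
        n_covered_start = len(pts) - 1
        rows_present = 0
        for k in range(1, self.n_rows + 1):
            mask = self.bead_at[k] >= 0
            if mask.sum() < max(2, self.M // 4):
                break
            p = mesh.positions[self.bead_at[k][mask]]
            pts.append([np.hypot(p[:, 0], p[:, 1]).mean(), p[:, 2].mean()])
            rows_present = k
        covered_until = len(pts) - 1
        # uncovered wall ahead of the mean leading edge
        s_le = self.row_arc[rows_present - 1] if rows_present else 0.0
        s_rest = np.linspace(s_le, self.wall.meridian_length, 24)[1:]
        rz = self.wall.meridian_point(s_rest)
        for r, z in rz:
            pts.append([r, z])
        pts.append([0.0, pts[-1][1]])  # close onto the axis at the pole
        prof = np.asarray(pts) / NM_PER_UM
        covered = np.zeros(len(prof) - 1, dtype=bool)
        covered[:covered_until] = True
        return prof, covered

    def measure(self) -> tuple[float, float, float]:
        prof, covered = self.profile()
        V, S = volume_surface_by_revolution(prof, check=False)
        E = percent_engulfment(prof, covered)
        return V, S, E

    def le_spread(self) -> float:
        """Angular spread of leading-edge height, as arc length (nm)."""
        return float((self.h.max() - self.h.min()) * self.row_spacing)

    def id_separation(self) -> float:
        """Mean distance (nm) between each complex's synthesis site and the
        membrane leading edge in its wake.

        The engulfing membrane cannot pass an intact junction cross-link,
        so its local position is the oldest (lowest-row) unsevered anchor
        near the complex's sector; with zero delay that anchor sits one
        row behind the synthesis site and the separation is about one
        bead spacing.
        """
        if self.rcfg.coupled:
            raise ConfigurationError("ID separation is defined for decoupled runs")
        dists = []
        for idc in self.idcs:
            sid = idc.current_strand_id
            if sid < 0 or not self.mesh.strands[sid].bead_ids:
                continue
            site = self.mesh.positions[self.mesh.strands[sid].bead_ids[-1]]
            front = None
            for k in range(1, self.n_rows + 1):
                for dj in (0, 1, -1):
                    ai = self.anchor_idx[k, (idc.sector + dj) % self.M]
                    if ai >= 0 and self.mesh.anchor_intact[ai]:
                        front = self.mesh.positions[self.mesh.anchor_bead[ai]]
                        break
                if front is not None:
                    break
            if front is None:
                dists.append(0.0)
            else:
                dists.append(float(np.linalg.norm(site - front)))
        return float(np.mean(dists)) if dists else 0.0

    # ------------------------------ main loop ------------------------------

    def relax(self, n_steps: int | None = None, thermal: bool = True) -> None:
        n = self.steps_per_event if n_steps is None else n_steps
        rng = self.rng if thermal and self.cfg.kBT > 0 else None
        for _ in range(n):
            ff = compute_forces(self.mesh, self.cfg, wall=self.wall, rng=rng)
            langevin_step(self.mesh, ff, self.cfg)

    def run(
        self,
        stop_E: float = 95.0,
        max_time_s: float = np.inf,
        record_every: int = 10,
        max_quiet_events: int = 200_000,
    ) -> tuple[EngulfmentTrace, dict]:
        """Interleave remodeling events with Langevin relaxation until the
        engulfment threshold, the time budget, or the pole is reached."""
        rows = []
        sep_rows = []
        quiet = 0
        order = 0
        max_spread = 0.0

        def record():
            nonlocal max_spread
            max_spread = max(max_spread, self.le_spread())
            V, S, E = self.measure()
            rows.append((self.time, V, S, E))
            if not self.rcfg.coupled:
                sep_rows.append((self.time, self.id_separation()))
            return E

        E = record()
        while self.time < max_time_s:
            if not self.idcs:
                break
            idc = self.idcs[order % len(self.idcs)]
            order += 1
            inserted = self._idc_event(idc)
            self.events += 1
            self.time += self.event_interval
            if not self.rcfg.coupled:
                self.delayed_degradation_step()
            quiet = 0 if inserted else quiet + 1
            if inserted:
                self.relax()
            if self.events % record_every == 0:
                E = record()
                if E >= stop_E:
                    break
            if self.h.min() >= self.n_rows:
                E = record()
                break
            if quiet > max_quiet_events:
                self.aborted = "stalled: no insertion for too long"
                break
        if not rows or rows[-1][0] < self.time:
            record()
        arr = np.asarray(rows)
        t, idx = np.unique(arr[:, 0], return_index=True)
        trace = EngulfmentTrace(time=t, V=arr[idx, 1], S=arr[idx, 2], E=arr[idx, 3])
        info = {
            "le_spread_nm": max(max_spread, self.le_spread()),
            "le_spread_final_nm": self.le_spread(),
            "forespore_circumference_nm": 2 * np.pi * self.geom.cell_radius,
            "length_inserted_total_nm": sum(i.length_inserted_total for i in self.idcs),
            "elapsed_s": self.time,
            "events": self.events,
            "aborted": self.aborted,
            "id_separation": np.asarray(sep_rows) if sep_rows else None,
            "h": self.h.copy(),
        }
        return trace, info


def run_engulfment(
    cfg: SimulationConfig,
    rcfg: RemodelingConfig,
    geom: ForesporeGeometry,
    seed: int | None = None,
    **run_kwargs,
) -> tuple[EngulfmentSimulation, EngulfmentTrace, dict]:
    """Convenience wrapper: build a simulation, run it, return
    (simulation, trace, info)."""
    sim_kwargs = {}
    for k in ("row_spacing", "steps_per_event", "min_hoop_radius_fraction"):
        if k in run_kwargs:
            sim_kwargs[k] = run_kwargs.pop(k)
    sim = EngulfmentSimulation(cfg, rcfg, geom, seed=seed, **sim_kwargs)
    trace, info = sim.run(**run_kwargs)
    return sim, trace, info


def locate_leading_edge(mesh: MeshState, sim: EngulfmentSimulation | None = None) -> list[int]:
    """Ordered ring of junction beads: beads holding intact junction
    anchors to the old wall, sorted by angle about the long axis (fixed
    counter-clockwise handedness); for a fresh septal disc this is the
    outermost hoop."""
    intact = mesh.anchor_intact
    if not intact.any():
        ids = list(mesh.leading_edge)
    else:
        ids = list(map(int, np.unique(mesh.anchor_bead[intact])))
    p = mesh.positions[ids]
    ang = np.arctan2(p[:, 1], p[:, 0])
    return [ids[i] for i in np.argsort(ang)]


def random_peptide_degradation(
    mesh: MeshState,
    cfg: SimulationConfig,
    rcfg: RemodelingConfig,
    wall,
    duration_s: float,
    profile_fn,
    n_substeps: int = 50,
    relax_steps: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, MeshState]:
    """Poisson degradation of peptide cross-links with synthesis halted.

    Every intact peptide bond (including junction anchors) is severed as
    an independent Poisson process at rate ``prpep`` (1/min); the mesh
    relaxes between sub-steps.  Returns the (time_s, V_um3, bonds_intact)
    record and the final mesh.
    """
    rng = np.random.default_rng(seed)
    rate = rcfg.prpep / 60.0  # 1/s
    dt_sub = duration_s / n_substeps
    p_cut = 1.0 - np.exp(-rate * dt_sub)
    out = []

    def measure(t):
        prof, _ = profile_fn()
        V, _ = volume_surface_by_revolution(prof)
        out.append((t, V, int(mesh.pep_intact.sum() + mesh.anchor_intact.sum())))

    measure(0.0)
    for i in range(n_substeps):
        if p_cut > 0:
            cut = rng.random(len(mesh.pep_intact)) < p_cut
            mesh.pep_intact &= ~cut
            cut_a = rng.random(len(mesh.anchor_intact)) < p_cut
            mesh.anchor_intact &= ~cut_a
        for _ in range(relax_steps):
            ff = compute_forces(mesh, cfg, wall=wall, rng=None)
            langevin_step(mesh, ff, cfg)
        measure((i + 1) * dt_sub)
    return np.asarray(out), mesh
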