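"""2D stochastic model of glycan insertion at the engulfment leading edge.

The cell circumference is discretized into ``M`` periodic columns and new
glycan rows are stacked on a founding old-wall row.  The old-wall template
guiding insertion is a static random field with a fraction ``f0`` of holes
per row (the founding row is its row zero).  ``NIDC``
insertion-degradation complexes are autonomous agents on the ring, each
with a fixed circumferential direction, acting once per sweep in shuffled
order:

* a *polymerizing* complex advances one column per sweep and inserts
  there when its templates are present: the old-wall site of that row and
  the germ-wall site one row below.  Over a hole in the old-wall template
  it continues with probability ``ppro``; otherwise the strand terminates,
  leaving an exposed end defect at the unfilled site.  Where the
  germ-wall support itself is missing (a neglected defect site below) the
  new strand cannot be cross-linked and always terminates, so unrepaired
  defects propagate holes upward and stall their column.  Colliding with
  existing material in its row also terminates the strand;
* an *idle* complex walks along the ring, one column per sweep.  At a
  down-step of the height profile it re-initiates insertion from the
  exposed strand end: freely at a clean end (a collision leftover), but
  only with probability ``prep`` at a true end defect -- and every failed
  attempt degrades that end further, so the k-th retry succeeds with
  probability ``prep**(k+1)``.  A walker that completes a full fruitless
  lap of the ring nucleates a fresh strand in the leading-edge trough
  (a column of minimum height); only after two fruitless laps does it
  nucleate anywhere, abandoning sectors whose ends have degraded beyond
  repair.

In the perfect-repair, fully processive limit (``prep = ppro = 1``) no
end defect is ever left behind and nucleation is confined to the trough,
so rows complete strictly one after the other and the profile is exactly
flat at every stop time.  Below a repair threshold near 0.8 the compound
degradation of passed-over ends wins: stalled sectors decouple from the
advancing front and the leading edge roughens macroscopically, the
lattice analogue of asymmetric engulfment.

Runs stop the moment the mean height reaches ``H_target`` rows; the
summary statistics are the width (RMS height deviation, rows) and the
roughness (width over mean height).  A straightforward pure-Python
implementation of the same rules (:class:`LatticeState` /
:func:`lattice_step`) doubles as an independent cross-check of the
compiled kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "StallError",
    "init_lattice",
    "lattice_step",
    "run_to_height",
    "run_replicates",
    "roughness_width",
]


class StallError(RuntimeError):
    """No site was filled for the configured number of consecutive sweeps."""


@dataclass
class LatticeConfig:
    M: int = 1570
    H_target: int = 500
    prep: float = 1.0
    ppro: float = 1.0
    NIDC: int = 10
    f0: float = 0.01
    seed: int = 0
    max_idle_sweeps: int = 20_000

    def __post_init__(self) -> None:
        if self.M < 3 or self.H_target < 1 or self.NIDC < 0:
            raise ValueError("need M >= 3, H_target >= 1, NIDC >= 0")
        for p in (self.prep, self.ppro):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.f0 < 1.0:
            raise ValueError("f0 must lie in [0, 1)")

    @property
    def rows_alloc(self) -> int:
        # headroom above the stop height: stalled sectors force the rest of
        # the front to overshoot before the mean reaches the target
        return 2 * self.H_target + 4


@dataclass
class LatticeState:
    """Grid state for the pure-Python rule implementation.

    ``occ`` row 0 is the founding old-wall row; ``wall`` is the static
    old-wall template field (1 = template strand present).  Because rows
    only ever grow on top of filled sites, every column is contiguous and
    ``h`` (top filled germ row, 0 = none) fully describes the profile.
    """

    occ: np.ndarray  # (rows, M) uint8
    wall: np.ndarray  # (rows, M) uint8, static
    sealed: np.ndarray  # (rows, M) uint8: count of failed repairs at the end
    defect: np.ndarray  # (rows, M) uint8: strand-termination (end defect) sites
    h: np.ndarray  # (M,) int64
    mode: np.ndarray  # (NIDC,) 0 idle / 1 polymerizing
    row: np.ndarray
    col: np.ndarray
    dirn: np.ndarray
    lap: np.ndarray  # idle columns walked since last termination
    ticks: int = 0

    @property
    def M(self) -> int:
        return self.occ.shape[1]


def init_lattice(lcfg: LatticeConfig, rng: np.random.Generator | None = None) -> LatticeState:
    """Founding row complete except a Bernoulli(f0) hole per column; the
    old-wall template above it carries f0 holes per row as well.  The
    complexes start idle, uniformly spread, ready to nucleate."""
    rng = rng or np.random.default_rng(lcfg.seed)
    rows = lcfg.rows_alloc
    wall = (rng.random((rows, lcfg.M)) >= lcfg.f0).astype(np.uint8)
    occ = np.zeros((rows, lcfg.M), dtype=np.uint8)
    occ[0] = wall[0]
    n = max(lcfg.NIDC, 0)
    return LatticeState(
        occ=occ,
        wall=wall,
        sealed=np.zeros_like(occ),
        defect=np.zeros_like(occ),
        h=np.zeros(lcfg.M, dtype=np.int64),
        mode=np.zeros(n, dtype=np.int64),
        row=np.zeros(n, dtype=np.int64),
        col=(np.arange(n) * lcfg.M) // max(n, 1) % lcfg.M,
        dirn=np.array([1 if a % 2 == 0 else -1 for a in range(n)], dtype=np.int64),
        lap=np.full(n, lcfg.M, dtype=np.int64),
    )


def _templates(state: LatticeState, r: int, j: int) -> tuple[bool, bool]:
    """(germ support present, old-wall template present) for site (r, j).

    For row 1 the support below is the founding old-wall row, so a missing
    founding site counts as an old-wall gap rather than a germ gap.
    """
    below = bool(state.occ[r - 1, j])
    if r == 1:
        return True, bool(state.wall[r, j]) and below
    return below, bool(state.wall[r, j])


def lattice_step(
    state: LatticeState, lcfg: LatticeConfig, rng: np.random.Generator
) -> LatticeState:
    """One sweep: every complex acts once, in freshly shuffled order."""
    M = state.M
    rows_alloc = state.occ.shape[0]
    for a in rng.permutation(len(state.mode)):
        if state.mode[a] == 1:
            r, d = int(state.row[a]), int(state.dirn[a])
            j = (int(state.col[a]) + d) % M
            if state.occ[r, j]:
                state.mode[a] = 0  # collision: strand terminates
                state.lap[a] = 0
                continue
            germ_ok, wall_ok = _templates(state, r, j)
            if (germ_ok and wall_ok) or (germ_ok and rng.random() < lcfg.ppro):
                state.occ[r, j] = 1
                state.h[j] = max(state.h[j], r)
                state.col[a] = j
            else:
                state.defect[r, j] = 1  # exposed end defect left at (r, j)
                state.mode[a] = 0
                state.lap[a] = 0
        else:
            d = int(state.dirn[a])
            c = (int(state.col[a]) + d) % M
            state.col[a] = c
            state.lap[a] += 1
            r = int(state.h[c]) + 1
            if r >= rows_alloc:
                continue
            prev = (c - d) % M
            down_step = state.h[prev] > state.h[c]
            # after a fruitless lap, nucleate a fresh row in the leading-edge
            # trough; after two laps, anywhere (abandoning dead sectors)
            nucleate = state.lap[a] >= M and (
                state.h[c] == state.h.min() or state.lap[a] >= 2 * M
            )
            if not (down_step or nucleate):
                continue
            if state.defect[r, c]:
                # re-initiation at a true end defect needs prep, and every
                # failed attempt degrades the exposed end further
                p_res = lcfg.prep ** (1.0 + float(state.sealed[r, c]))
                if rng.random() >= p_res:
                    if state.sealed[r, c] < 60:
                        state.sealed[r, c] += 1
                    continue
            germ_ok, wall_ok = _templates(state, r, c)
            if not germ_ok:
                continue  # neglected hole below: cannot cross-link here
            if not wall_ok and rng.random() >= lcfg.ppro:
                continue
            state.occ[r, c] = 1
            state.h[c] = r
            state.mode[a], state.row[a] = 1, r
    state.ticks += 1
    return state


@njit(cache=True)
def _kernel(M, H_target, prep, ppro, NIDC, f0, seed, max_idle_sweeps, rows_alloc):
    np.random.seed(seed)
    wall = np.empty((rows_alloc, M), dtype=np.uint8)
    for r in range(rows_alloc):
        for i in range(M):
            wall[r, i] = 1 if np.random.random() >= f0 else 0
    occ = np.zeros((rows_alloc, M), dtype=np.uint8)
    for i in range(M):
        occ[0, i] = wall[0, i]
    sealed = np.zeros((rows_alloc, M), dtype=np.uint8)
    defect = np.zeros((rows_alloc, M), dtype=np.uint8)
    h = np.zeros(M, dtype=np.int64)
    hmax = 0
    hmin = 0
    cnt_min = M
    sum_h = 0
    target = M * H_target
    mode = np.zeros(NIDC, dtype=np.int64)
    row = np.zeros(NIDC, dtype=np.int64)
    col = np.empty(NIDC, dtype=np.int64)
    dirn = np.empty(NIDC, dtype=np.int64)
    lap = np.full(NIDC, M, dtype=np.int64)
    for a in range(NIDC):
        col[a] = (a * M) // NIDC % M
        dirn[a] = 1 if a % 2 == 0 else -1
    order = np.arange(NIDC)
    ticks = 0
    quiet_sweeps = 0
    while sum_h < target:
        for a in range(NIDC - 1, 0, -1):
            b = np.random.randint(0, a + 1)
            t = order[a]
            order[a] = order[b]
            order[b] = t
        ticks += 1
        swept_fill = False
        done = False
        for oi in range(NIDC):
            a = order[oi]
            filled = False
            fj = -1
            if mode[a] == 1:
                r = row[a]
                j = (col[a] + dirn[a]) % M
                if occ[r, j]:
                    mode[a] = 0
                    lap[a] = 0
                else:
                    below = occ[r - 1, j] == 1
                    if r == 1:
                        germ_ok = True
                        wall_ok = below and wall[r, j] == 1
                    else:
                        germ_ok = below
                        wall_ok = wall[r, j] == 1
                    if (germ_ok and wall_ok) or (
                        germ_ok and np.random.random() < ppro
                    ):
                        col[a] = j
                        fj = j
                        filled = True
                    else:
                        defect[r, j] = 1
                        mode[a] = 0
                        lap[a] = 0
            else:
                d = dirn[a]
                c = (col[a] + d) % M
                col[a] = c
                lap[a] += 1
                r = h[c] + 1
                if r < rows_alloc:
                    prev = (c - d) % M
                    down_step = h[prev] > h[c]
                    nucleate = lap[a] >= M and (
                        h[c] == hmin or lap[a] >= 2 * M
                    )
                    if down_step or nucleate:
                        ok = True
                        if defect[r, c] == 1:
                            p_res = prep ** (1.0 + sealed[r, c])
                            if np.random.random() >= p_res:
                                if sealed[r, c] < 60:
                                    sealed[r, c] += 1
                                ok = False
                        if ok:
                            below = occ[r - 1, c] == 1
                            if r == 1:
                                germ_ok = True
                                wall_ok = below and wall[r, c] == 1
                            else:
                                germ_ok = below
                                wall_ok = wall[r, c] == 1
                            if not germ_ok:
                                ok = False
                            elif not wall_ok and np.random.random() >= ppro:
                                ok = False
                        if ok:
                            mode[a] = 1
                            row[a] = r
                            fj = c
                            filled = True
            if filled:
                rr = row[a]
                occ[rr, fj] = 1
                if rr > h[fj]:
                    if h[fj] == hmin:
                        cnt_min -= 1
                    sum_h += rr - h[fj]
                    h[fj] = rr
                    if rr > hmax:
                        hmax = rr
                    if cnt_min == 0:
                        hmin = h[0]
                        for i in range(1, M):
                            if h[i] < hmin:
                                hmin = h[i]
                        cnt_min = 0
                        for i in range(M):
                            if h[i] == hmin:
                                cnt_min += 1
                swept_fill = True
                if sum_h >= target:
                    done = True
                    break
        if done:
            break
        if swept_fill:
            quiet_sweeps = 0
        else:
            quiet_sweeps += 1
            if quiet_sweeps > max_idle_sweeps:
                return h, ticks, 1
    return h, ticks, 0


def roughness_width(h: np.ndarray | LatticeState) -> tuple[float, float]:
    """Width W = RMS height deviation (rows); roughness = W / mean height."""
    if isinstance(h, LatticeState):
        h = h.h
    h = np.asarray(h, dtype=float)
    mean = h.mean()
    if mean == 0:
        raise ValueError("roughness undefined for zero mean height")
    width = float(np.sqrt(np.mean((h - mean) ** 2)))
    return width / float(mean), width


def run_to_height(lcfg: LatticeConfig) -> dict:
    """Run the compiled kernel until mean height reaches ``H_target``.

    The stop condition is checked after every single fill so the run halts
    exactly when the mean crosses the target.  Returns the final height
    profile together with roughness, width and the sweep count.
    """
    if lcfg.NIDC == 0:
        raise StallError("no insertion complexes: lattice cannot grow")
    h, ticks, flag = _kernel(
        lcfg.M,
        lcfg.H_target,
        lcfg.prep,
        lcfg.ppro,
        lcfg.NIDC,
        lcfg.f0,
        int(lcfg.seed) % (2**31),
        lcfg.max_idle_sweeps,
        lcfg.rows_alloc,
    )
    if flag:
        raise StallError(
            f"no site filled for {lcfg.max_idle_sweeps} consecutive sweeps"
        )
    rough, width = roughness_width(h)
    return {"h": h, "roughness": rough, "width": width, "steps": int(ticks)}


def run_replicates(lcfg: LatticeConfig, n_reps: int = 100) -> pd.DataFrame:
    """Replicate protocol: ``n_reps`` independently seeded runs per
    parameter set, one row (rep, roughness, width, steps) each."""
    seeds = np.random.SeedSequence(lcfg.seed).generate_state(n_reps) % (2**31)
    rows = []
    for rep, s in enumerate(seeds):
        sub = LatticeConfig(
            M=lcfg.M,
            H_target=lcfg.H_target,
            prep=lcfg.prep,
            ppro=lcfg.ppro,
            NIDC=lcfg.NIDC,
            f0=lcfg.f0,
            seed=int(s),
            max_idle_sweeps=lcfg.max_idle_sweeps,
        )
        res = run_to_height(sub)
        rows.append(
            {
                "rep": rep,
                "roughness": res["roughness"],
                "width": res["width"],
                "steps": res["steps"],
            }
        )
    return pd.DataFrame(rows)
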