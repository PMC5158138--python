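"""Domain types and constructors for the coarse-grained peptidoglycan meshwork.

The germ-cell wall of the engulfing forespore is modelled as a bead-spring
network: glycan strands are semi-flexible filaments of beads connected by
Hookean springs, cross-linked by peptide springs.  Units are fixed package
wide: length in nm, time in s, force in pN, energy in pN nm, pressure in
pN/nm^2.  ``kpa_to_pn_per_nm2`` converts printed kPa values (86.31 kPa =
0.08631 pN/nm^2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "Bead",
    "GlycanStrand",
    "PeptideBond",
    "AnchorBond",
    "MeshState",
    "ForesporeGeometry",
    "WallSurface",
    "ValidationReport",
    "ConfigurationError",
    "effective_persistence_length",
    "kpa_to_pn_per_nm2",
    "pn_per_nm2_to_kpa",
    "build_septal_disc",
    "build_lateral_wall",
    "validate_mesh",
    "load_config",
    "save_config",
    "save_mesh",
    "load_mesh",
    "zip_rings",
    "triangulate_mesh",
]

HORIZONTAL = 0  #: peptide bond between an old-wall template strand and a new strand
VERTICAL = 1  #: peptide bond between two new (germ-cell wall) strands


class ConfigurationError(ValueError):
    """Raised for inconsistent geometry or configuration input."""


def kpa_to_pn_per_nm2(p_kpa: float) -> float:
    """Convert a pressure from kPa to pN/nm^2 (1 kPa = 1e-3 pN/nm^2)."""
    return p_kpa * 1e-3


def pn_per_nm2_to_kpa(p: float) -> float:
    return p * 1e3


def effective_persistence_length(
    n_bundle: int, lp0: float, coupling: str = "strong"
) -> float:
    """Effective persistence length of a bundle of ``n_bundle`` glycans.

    Strongly cross-linked bundles stiffen as ``n^2 * lp0``; weakly coupled
    bundles only as ``n * lp0``.  With seven glycans per bundle and a
    single-strand persistence length of 40 nm the strong rule gives
    ~2 um (1960 nm).
    """
    if n_bundle < 1:
        raise ConfigurationError("n_bundle must be >= 1")
    if lp0 <= 0:
        raise ConfigurationError("lp0 must be > 0")
    if coupling == "strong":
        return n_bundle**2 * lp0
    if coupling == "weak":
        return n_bundle * lp0
    raise ConfigurationError(f"unknown coupling rule {coupling!r}")


@dataclass
class SimulationConfig:
    """Mechanical constants of the coarse-grained wall, in nm/pN/s units.

    Parameters
    ----------
    kgly : float
        Glycan (intra-strand) spring constant, pN/nm.
    kpep : float
        Peptide cross-link spring constant, pN/nm.
    lp : float or None
        Effective glycan persistence length, nm.  ``None`` derives it from
        ``n_bundle`` and ``lp0`` with the strong cross-linking rule.
    n_bundle : int
        Number of glycans represented by one simulated filament.
    lp0 : float
        Single-glycan persistence length, nm.
    l0 : float
        Equilibrium bead spacing along a strand, nm.
    d_pep : float
        Peptide equilibrium length, nm (2 nm).
    delta_p : float
        Turgor pressure difference forespore minus mother, pN/nm^2
        (86.31 kPa = 0.08631).
    eta_med : float
        Medium viscosity, pN s/nm^2.  The per-bead drag is derived as
        ``zeta = 4 pi eta_med l0`` and never stored.
    kBT : float
        Thermal energy, pN nm.
    dt : float or None
        Langevin time step, s.  ``None`` picks a stable step,
        ``0.1 * zeta / max(kgly, kpep, k_wall)``, well below the
        overdamped stability limit ``zeta / (2 k)``.
    k_wall : float
        Harmonic stiffness of the old-cell-wall excluded-volume repulsion,
        pN/nm.
    seed : int
        RNG seed.
    """

    kgly: float = 200.0
    kpep: float = 25.0
    lp: float | None = None
    n_bundle: int = 7
    lp0: float = 40.0
    l0: float = 25.0
    d_pep: float = 2.0
    delta_p: float = kpa_to_pn_per_nm2(86.31)
    eta_med: float = 1e-6
    kBT: float = 4.1
    dt: float | None = None
    k_wall: float = 100.0
    seed: int = 0
    bundle_coupling: str = "strong"

    def __post_init__(self) -> None:
        if self.lp is None:
            self.lp = effective_persistence_length(
                self.n_bundle, self.lp0, self.bundle_coupling
            )
        if self.dt is None:
            kmax = max(self.kgly, self.kpep, self.k_wall)
            self.dt = 0.1 * self.zeta / kmax
        for name in ("kgly", "kpep", "lp", "lp0", "l0", "d_pep", "eta_med",
                     "kBT", "dt", "k_wall"):
            if getattr(self, name) <= 0 and not (name == "kBT" and self.kBT == 0.0):
                raise ConfigurationError(f"{name} must be > 0")
        if self.delta_p < 0:
            raise ConfigurationError("delta_p must be >= 0")

    @property
    def zeta(self) -> float:
        """Per-bead drag coefficient ``4 pi eta_med l0``, pN s/nm."""
        return 4.0 * np.pi * self.eta_med * self.l0

    @property
    def kappa_bend(self) -> float:
        """Discrete bending modulus ``lp kBT / l0``, pN nm."""
        return self.lp * self.kBT / self.l0


@dataclass(frozen=True)
class Bead:
    id: int
    position: np.ndarray
    strand_id: int
    index_on_strand: int


@dataclass
class GlycanStrand:
    id: int
    bead_ids: list[int]
    closed: bool
    row_index: int

    def __post_init__(self) -> None:
        # arcs should end with >= 2 beads; a single bead is tolerated only
        # transiently, at the nucleation step of a growing strand
        if not self.bead_ids:
            raise ConfigurationError("strands need at least one bead")


@dataclass(frozen=True)
class PeptideBond:
    bead_a: int
    bead_b: int
    orientation: int  # HORIZONTAL or VERTICAL
    rest_length: float
    intact: bool


@dataclass(frozen=True)
class AnchorBond:
    """Junction cross-link between a germ-wall bead and the static old wall.

    The thick outer wall is a static surface rather than explicit strands,
    so the 'horizontal' junction peptides tie beads to fixed anchor points
    on it; severing an anchor releases the bead from the template.
    """

    bead: int
    point: np.ndarray
    rest_length: float
    intact: bool


@dataclass
class ForesporeGeometry:
    """Forespore-proximal geometry: radius, septum plane and pole cap.

    The long axis is +z, the septal plane is z = septum_position with the
    forespore at larger z, and the lateral wall is a cylinder of radius
    ``cell_radius`` capped by a hemisphere whose base sits at
    ``septum_position + forespore_cap_extent``.
    """

    cell_radius: float = 1.0e3 / 2.3
    septum_position: float = 0.0
    forespore_cap_extent: float = 0.0
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.long_axis = self.long_axis / np.linalg.norm(self.long_axis)
        if self.cell_radius <= 0:
            raise ConfigurationError("cell_radius must be > 0")
        if self.forespore_cap_extent < 0:
            raise ConfigurationError("forespore_cap_extent must be >= 0")

    @classmethod
    def from_inverse_radius(cls, inv_radius_per_um: float, **kw) -> "ForesporeGeometry":
        """Build from a printed inverse radius in 1/um (e.g. 2.3 um^-1)."""
        return cls(cell_radius=1.0e3 / inv_radius_per_um, **kw)


class WallSurface:
    """Static lateral wall: cylinder of radius R about +z plus a
    hemispherical pole cap.

    The allowed region is the inside; ``signed_distance`` is positive when
    a point penetrates beyond the wall surface and negative inside.
    """

    def __init__(self, geom: ForesporeGeometry):
        self.R = geom.cell_radius
        self.z0 = geom.septum_position
        self.cap_base_z = geom.septum_position + geom.forespore_cap_extent

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.hypot(p[:, 0], p[:, 1])
        d_cyl = r - self.R
        dz = p[:, 2] - self.cap_base_z
        d_cap = np.sqrt(r**2 + dz**2) - self.R
        return np.where(p[:, 2] > self.cap_base_z, d_cap, d_cyl)

    def inward_normal(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = np.zeros_like(p)
        r = np.hypot(p[:, 0], p[:, 1])
        on_cap = p[:, 2] > self.cap_base_z
        # cylinder part: toward the axis
        rr = np.where(r > 1e-12, r, 1.0)
        n[:, 0] = -p[:, 0] / rr
        n[:, 1] = -p[:, 1] / rr
        # cap part: toward the cap centre
        c = np.array([0.0, 0.0, self.cap_base_z])
        v = p - c
        vn = np.linalg.norm(v, axis=1)
        vn = np.where(vn > 1e-12, vn, 1.0)
        ncap = -v / vn[:, None]
        n[on_cap] = ncap[on_cap]
        return n

    # --- meridian parameterization (arc length from septum ring to apex) ---

    @property
    def meridian_length(self) -> float:
        return (self.cap_base_z - self.z0) + 0.5 * np.pi * self.R

    def meridian_point(self, s: np.ndarray | float) -> np.ndarray:
        """(radius, z) of the wall meridian at arc length ``s`` from the
        septal junction (r=R, z=z0) toward the pole apex."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        straight = self.cap_base_z - self.z0
        r = np.where(
            s <= straight,
            self.R,
            self.R * np.cos((s - straight) / self.R),
        )
        z = np.where(
            s <= straight,
            self.z0 + s,
            self.cap_base_z + self.R * np.sin((s - straight) / self.R),
        )
        return np.column_stack([r, z])


@dataclass
class MeshState:
    """Bead-spring state of the simulated germ-cell wall sac.

    Arrays are struct-of-arrays for vectorized mechanics; ``strands`` keeps
    the per-filament topology.  ``leading_edge`` is the ordered ring of
    junction bead ids separating germ-cell wall from the old-wall template.
    """

    positions: np.ndarray  # (N, 3) float
    strand_id: np.ndarray  # (N,) int
    index_on_strand: np.ndarray  # (N,) int
    mobile: np.ndarray  # (N,) bool
    strands: list[GlycanStrand]
    # glycan springs
    gly_a: np.ndarray
    gly_b: np.ndarray
    gly_rest: np.ndarray
    # peptide springs (bead-bead)
    pep_a: np.ndarray
    pep_b: np.ndarray
    pep_orient: np.ndarray
    pep_rest: np.ndarray
    pep_intact: np.ndarray
    # junction anchors (bead-wall)
    anchor_bead: np.ndarray
    anchor_point: np.ndarray  # (M, 3)
    anchor_rest: np.ndarray
    anchor_intact: np.ndarray
    leading_edge: list[int] = field(default_factory=list)
    time: float = 0.0
    interior_point: np.ndarray | None = None  # orients surface normals
    _triangles: np.ndarray | None = None
    _triples: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bead(self, i: int) -> Bead:
        return Bead(
            id=i,
            position=self.positions[i].copy(),
            strand_id=int(self.strand_id[i]),
            index_on_strand=int(self.index_on_strand[i]),
        )

    def bending_triples(self) -> np.ndarray:
        """(n, 3) interior bead triples of every strand (wrapping if closed);
        cached until the topology changes."""
        if self._triples is not None:
            return self._triples
        triples = []
        for s in self.strands:
            ids = s.bead_ids
            n = len(ids)
            if s.closed and n >= 3:
                for j in range(n):
                    triples.append((ids[j - 1], ids[j], ids[(j + 1) % n]))
            else:
                for j in range(1, n - 1):
                    triples.append((ids[j - 1], ids[j], ids[j + 1]))
        self._triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
        return self._triples

    @property
    def triangles(self) -> np.ndarray:
        if self._triangles is None:
            self._triangles = triangulate_mesh(self)
        return self._triangles

    def invalidate_triangulation(self) -> None:
        self._triangles = None
        self._triples = None


def _ring_positions(radius: float, n: int, z: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)]
    )


def zip_rings(
    ids_small: Sequence[int],
    ang_small: np.ndarray,
    ids_large: Sequence[int],
    ang_large: np.ndarray,
) -> list[tuple[int, int]]:
    """Injective nearest-angle pairing from the smaller ring into the larger.

    With uniformly spaced rings the proportional index map round(i*nl/ns)
    is strictly increasing, so exactly min(ns, nl) bonds result.
    """
    ns, nl = len(ids_small), len(ids_large)
    if ns > nl:
        return [(b, a) for a, b in zip_rings(ids_large, ang_large, ids_small, ang_small)]
    pairs = []
    used = set()
    order = np.argsort(ang_large)
    sorted_large = [ids_large[k] for k in order]
    sorted_ang = ang_large[order]
    for i in range(ns):
        a = ang_small[i] % (2 * np.pi)
        j = int(np.searchsorted(sorted_ang, a)) % nl
        # nearest of the two sorted neighbours, skipping used ones
        best, bestd = None, np.inf
        for off in range(nl):
            for cand in ((j + off) % nl, (j - off) % nl):
                if cand in used:
                    continue
                d = np.abs((sorted_ang[cand] - a + np.pi) % (2 * np.pi) - np.pi)
                if d < bestd:
                    best, bestd = cand, d
            if best is not None and off > 1:
                break
        used.add(best)
        pairs.append((ids_small[i], sorted_large[best]))
    return pairs


def build_septal_disc(geom: ForesporeGeometry, cfg: SimulationConfig) -> MeshState:
    """Flat disc of concentric closed glycan hoops spanning the septal plane.

    Rings sit at radii ``j * l0`` out to the cell radius; consecutive rings
    are peptide-bonded by nearest-angle pairing.  Every spring is built at
    its rest length so the stretch energy of a fresh disc is zero.  The
    outermost hoop is registered as the leading edge.
    """
    R, l0 = geom.cell_radius, cfg.l0
    n_rings = int(np.floor(R / l0 + 1e-9))
    if R < 2 * l0 or n_rings < 1:
        raise ConfigurationError(
            f"degenerate geometry: R={R} nm too small for l0={l0} nm"
        )
    z = geom.septum_position
    positions, strand_id, index_on_strand = [], [], []
    strands: list[GlycanStrand] = []
    gly_a, gly_b, gly_rest = [], [], []
    ring_ids, ring_angles = [], []
    next_id = 0
    for j in range(1, n_rings + 1):
        r = j * l0
        n = max(3, int(round(2 * np.pi * r / l0)))
        pos = _ring_positions(r, n, z)
        ids = list(range(next_id, next_id + n))
        next_id += n
        positions.append(pos)
        strand_id.extend([j - 1] * n)
        index_on_strand.extend(range(n))
        # disc rings count inward as negative rows; the outermost ring is
        # row 0 so that germ-wall hoops appended on the wall start at row 1
        strands.append(GlycanStrand(id=j - 1, bead_ids=ids, closed=True, row_index=j - n_rings))
        chord = 2 * r * np.sin(np.pi / n)
        for k in range(n):
            gly_a.append(ids[k])
            gly_b.append(ids[(k + 1) % n])
            gly_rest.append(chord)
        ring_ids.append(ids)
        ring_angles.append(2 * np.pi * np.arange(n) / n)
    positions = np.vstack(positions)
    pep_a, pep_b, pep_rest = [], [], []
    for j in range(n_rings - 1):
        pairs = zip_rings(ring_ids[j], ring_angles[j], ring_ids[j + 1], ring_angles[j + 1])
        for a, b in pairs:
            pep_a.append(a)
            pep_b.append(b)
            pep_rest.append(float(np.linalg.norm(positions[a] - positions[b])))
    n = len(positions)
    mesh = MeshState(
        positions=positions,
        strand_id=np.asarray(strand_id, dtype=np.int64),
        index_on_strand=np.asarray(index_on_strand, dtype=np.int64),
        mobile=np.ones(n, dtype=bool),
        strands=strands,
        gly_a=np.asarray(gly_a, dtype=np.int64),
        gly_b=np.asarray(gly_b, dtype=np.int64),
        gly_rest=np.asarray(gly_rest, dtype=float),
        pep_a=np.asarray(pep_a, dtype=np.int64),
        pep_b=np.asarray(pep_b, dtype=np.int64),
        pep_orient=np.full(len(pep_a), VERTICAL, dtype=np.int8),
        pep_rest=np.asarray(pep_rest, dtype=float),
        pep_intact=np.ones(len(pep_a), dtype=bool),
        anchor_bead=np.zeros(0, dtype=np.int64),
        anchor_point=np.zeros((0, 3), dtype=float),
        anchor_rest=np.zeros(0, dtype=float),
        anchor_intact=np.zeros(0, dtype=bool),
        leading_edge=list(ring_ids[-1]),
        time=0.0,
        interior_point=np.array([0.0, 0.0, z + 0.5 * R]),
    )
    return mesh


def build_lateral_wall(geom: ForesporeGeometry, cfg: SimulationConfig) -> WallSurface:
    """Static old-cell-wall surface (cylinder plus pole hemisphere)."""
    if geom.cell_radius < 2 * cfg.l0:
        raise ConfigurationError("degenerate geometry: R < 2*l0")
    return WallSurface(geom)


def triangulate_mesh(mesh: MeshState) -> np.ndarray:
    """Zipper triangulation between consecutive bead rows.

    Beads are grouped by their strand's row_index (several arcs may share
    a row); consecutive rows are stitched by angular order.  When the
    mesh carries an ``interior_point``, every triangle is wound so its
    area vector points away from it (out of the forespore).
    """
    pos = mesh.positions
    by_row: dict[int, list[int]] = {}
    for s in mesh.strands:
        by_row.setdefault(s.row_index, []).extend(s.bead_ids)
    rows = sorted(by_row)
    tris: list[tuple[int, int, int]] = []
    for lo, hi in zip(rows[:-1], rows[1:]):
        if hi - lo > 1:
            continue  # rows not adjacent (gap)
        a_ids, b_ids = by_row[lo], by_row[hi]
        if len(a_ids) < 2 or len(b_ids) < 2:
            continue
        ang_a = np.arctan2(pos[a_ids, 1], pos[a_ids, 0]) % (2 * np.pi)
        ang_b = np.arctan2(pos[b_ids, 1], pos[b_ids, 0]) % (2 * np.pi)
        tris.extend(_zip_triangles(a_ids, ang_a, b_ids, ang_b))
    t = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
    if len(t) and mesh.interior_point is not None:
        p0, p1, p2 = pos[t[:, 0]], pos[t[:, 1]], pos[t[:, 2]]
        normal = np.cross(p1 - p0, p2 - p0)
        outward = (p0 + p1 + p2) / 3.0 - np.asarray(mesh.interior_point)
        flip = np.einsum("ij,ij->i", normal, outward) < 0
        t[flip] = t[flip][:, [0, 2, 1]]
    return t


def _zip_triangles(a_ids, ang_a, b_ids, ang_b) -> list[tuple[int, int, int]]:
    """Zipper triangulation of the annulus between two angularly ordered
    rings, advancing whichever ring's next node comes first in angle.

    Triangles spanning an angular gap far beyond the typical node spacing
    (e.g. stitching across the open part of a partially grown hoop) are
    dropped, so incomplete rows only carry surface where material exists.
    """
    oa = np.argsort(ang_a)
    ob = np.argsort(ang_b)
    A = [a_ids[k] for k in oa]
    B = [b_ids[k] for k in ob]
    sa = ang_a[oa]
    sb = ang_b[ob]
    na, nb = len(A), len(B)
    tris = []
    i = j = 0
    # start both pointers at angle-aligned nodes
    while i < na or j < nb:
        next_a = sa[(i) % na] + (2 * np.pi if i >= na else 0.0)
        next_b = sb[(j) % nb] + (2 * np.pi if j >= nb else 0.0)
        a0, b0 = A[i % na], B[j % nb]
        if (next_a <= next_b and i < na) or j >= nb:
            a1 = A[(i + 1) % na]
            tris.append((a0, a1, b0))
            i += 1
        else:
            b1 = B[(j + 1) % nb]
            tris.append((a0, b1, b0))
            j += 1
    # drop triangles bridging large angular gaps
    ang_of = {}
    for ids, angs in ((A, sa), (B, sb)):
        for k, v in zip(ids, angs):
            ang_of[k] = v
    med = np.median(np.diff(np.sort(np.concatenate([sa, sb]))))
    max_span = max(10.0 * med, 4 * np.pi / max(na + nb, 1))
    kept = []
    for t in tris:
        aa = np.array([ang_of[v] for v in t])
        span = aa.max() - aa.min()
        span = min(span, 2 * np.pi - span)
        if span <= max_span:
            kept.append(t)
    return kept


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, msg: str) -> None:
        self.issues.append(msg)


def validate_mesh(mesh: MeshState) -> ValidationReport:
    """Check structural invariants; an empty report means a valid mesh."""
    rep = ValidationReport()
    n = mesh.n_beads
    if not np.all(np.isfinite(mesh.positions)):
        rep.add("non-finite bead positions")
    seen = set()
    for i in range(n):
        key = (int(mesh.strand_id[i]), int(mesh.index_on_strand[i]))
        if key in seen:
            rep.add(f"duplicate (strand, index) {key}")
        seen.add(key)
    for name, (aa, bb) in {
        "glycan": (mesh.gly_a, mesh.gly_b),
        "peptide": (mesh.pep_a, mesh.pep_b),
    }.items():
        if len(aa) and (aa.min() < 0 or bb.min() < 0 or aa.max() >= n or bb.max() >= n):
            bad = np.where((aa < 0) | (bb < 0) | (aa >= n) | (bb >= n))[0]
            for k in bad[:10]:
                rep.add(f"dangling {name} bond #{k} ({int(aa[k])}, {int(bb[k])})")
    if len(mesh.pep_a):
        same = mesh.pep_a == mesh.pep_b
        for k in np.where(same)[0][:10]:
            rep.add(f"self peptide bond #{k}")
    if len(mesh.anchor_bead) and (
        mesh.anchor_bead.min() < 0 or mesh.anchor_bead.max() >= n
    ):
        rep.add("dangling anchor bond")
    # connectivity over glycan + intact peptide bonds
    if n:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        ia = np.concatenate([mesh.gly_a, mesh.pep_a[mesh.pep_intact]])
        ib = np.concatenate([mesh.gly_b, mesh.pep_b[mesh.pep_intact]])
        ia = ia[(ia >= 0) & (ia < n) & (ib >= 0) & (ib < n)]
        ib = ib[: len(ia)]
        g = coo_matrix((np.ones(len(ia)), (ia, ib)), shape=(n, n))
        ncomp, _ = connected_components(g, directed=False)
        if ncomp > 1:
            rep.add(f"mesh has {ncomp} connected components")
    le = mesh.leading_edge
    if le:
        if len(set(le)) != len(le):
            rep.add("leading edge ring repeats beads")
        if any(i < 0 or i >= n for i in le):
            rep.add("leading edge references missing bead")
    else:
        rep.add("empty leading edge ring")
    return rep


# ------------------------------ I/O ---------------------------------------

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path) -> SimulationConfig:
    """Read a flat YAML mapping whose keys are SimulationConfig fields.

    Unknown keys raise; ``delta_p_kpa`` is accepted as a convenience and
    converted to pN/nm^2.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a flat key-value document")
    if "delta_p_kpa" in raw:
        raw["delta_p"] = kpa_to_pn_per_nm2(float(raw.pop("delta_p_kpa")))
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def save_mesh(mesh: MeshState, path_or_group) -> None:
    """Write a mesh snapshot to an HDF5 file or open group."""
    own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
    h = h5py.File(path_or_group, "w") if own else path_or_group
    try:
        g = h.create_group("beads")
        g.create_dataset("id", data=np.arange(mesh.n_beads))
        g.create_dataset("xyz", data=mesh.positions)
        g.create_dataset("strand", data=mesh.strand_id)
        g.create_dataset("index", data=mesh.index_on_strand)
        g.create_dataset("mobile", data=mesh.mobile)
        gs = h.create_group("strands")
        gs.create_dataset("id", data=np.array([s.id for s in mesh.strands]))
        gs.create_dataset("closed", data=np.array([s.closed for s in mesh.strands]))
        gs.create_dataset("row", data=np.array([s.row_index for s in mesh.strands]))
        offsets = np.cumsum([0] + [len(s.bead_ids) for s in mesh.strands])
        gs.create_dataset("offsets", data=offsets)
        gs.create_dataset(
            "bead_ids",
            data=np.concatenate([np.asarray(s.bead_ids) for s in mesh.strands])
            if mesh.strands
            else np.zeros(0, dtype=np.int64),
        )
        gp = h.create_group("peptide_bonds")
        gp.create_dataset("a", data=mesh.pep_a)
        gp.create_dataset("b", data=mesh.pep_b)
        gp.create_dataset("orientation", data=mesh.pep_orient)
        gp.create_dataset("rest_length", data=mesh.pep_rest)
        gp.create_dataset("intact", data=mesh.pep_intact)
        ga = h.create_group("anchors")
        ga.create_dataset("bead", data=mesh.anchor_bead)
        ga.create_dataset("point", data=mesh.anchor_point)
        ga.create_dataset("rest_length", data=mesh.anchor_rest)
        ga.create_dataset("intact", data=mesh.anchor_intact)
        gg = h.create_group("glycan_bonds")
        gg.create_dataset("a", data=mesh.gly_a)
        gg.create_dataset("b", data=mesh.gly_b)
        gg.create_dataset("rest_length", data=mesh.gly_rest)
        h.create_dataset("leading_edge", data=np.asarray(mesh.leading_edge, dtype=np.int64))
        h.attrs["time_s"] = mesh.time
    finally:
        if own:
            h.close()


def load_mesh(path_or_group) -> MeshState:
    own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
    h = h5py.File(path_or_group, "r") if own else path_or_group
    try:
        offsets = h["strands/offsets"][...]
        flat = h["strands/bead_ids"][...]
        strands = [
            GlycanStrand(
                id=int(sid),
                bead_ids=list(map(int, flat[offsets[k] : offsets[k + 1]])),
                closed=bool(cl),
                row_index=int(rw),
            )
            for k, (sid, cl, rw) in enumerate(
                zip(h["strands/id"][...], h["strands/closed"][...], h["strands/row"][...])
            )
        ]
        return MeshState(
            positions=h["beads/xyz"][...],
            strand_id=h["beads/strand"][...],
            index_on_strand=h["beads/index"][...],
            mobile=h["beads/mobile"][...].astype(bool),
            strands=strands,
            gly_a=h["glycan_bonds/a"][...],
            gly_b=h["glycan_bonds/b"][...],
            gly_rest=h["glycan_bonds/rest_length"][...],
            pep_a=h["peptide_bonds/a"][...],
            pep_b=h["peptide_bonds/b"][...],
            pep_orient=h["peptide_bonds/orientation"][...],
            pep_rest=h["peptide_bonds/rest_length"][...],
            pep_intact=h["peptide_bonds/intact"][...].astype(bool),
            anchor_bead=h["anchors/bead"][...],
            anchor_point=h["anchors/point"][...],
            anchor_rest=h["anchors/rest_length"][...],
            anchor_intact=h["anchors/intact"][...].astype(bool),
            leading_edge=list(map(int, h["leading_edge"][...])),
            time=float(h.attrs["time_s"]),
        )
    finally:
        if own:
            h.close()
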