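"""Geometric and kinetic observables of engulfment.

Volume, surface area and percent engulfment are computed from a medial
(r, z) profile by rotational symmetry, mirroring the experimental image
pipeline, so that simulated and measured traces are directly comparable
in a chi-square fit.  Also here: forespore pole curvature relative to a
spherical cap, peptide-strain bookkeeping, and glycan insertion-flux
estimates (the product of complex count and per-complex speed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EngulfmentTrace",
    "CurvatureReport",
    "volume_surface_by_revolution",
    "percent_engulfment",
    "fit_circle",
    "relative_curvature",
    "peptide_linear_fraction",
    "insertion_flux",
    "implied_complex_count",
    "mean_id_separation",
    "typical_strand_length_um",
]


@dataclass
class EngulfmentTrace:
    """Time series of forespore volume, surface area and engulfment.

    Units: time s, V um^3, S um^2, E percent in [0, 100]; the optional
    sigma columns carry per-point standard deviations in the same units.
    """

    time: np.ndarray
    V: np.ndarray
    S: np.ndarray
    E: np.ndarray
    sV: np.ndarray | None = None
    sS: np.ndarray | None = None
    sE: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("time", "V", "S", "E", "sV", "sS", "sE"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any((self.E < -1e-9) | (self.E > 100 + 1e-9)):
            raise ValueError("E must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.time, "V_um3": self.V, "S_um2": self.S, "E_percent": self.E}
        for k, v in (("sd_V", self.sV), ("sd_S", self.sS), ("sd_E", self.sE)):
            if v is not None:
                d[k] = v
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EngulfmentTrace":
        return cls(
            time=df["time_s"].to_numpy(),
            V=df["V_um3"].to_numpy(),
            S=df["S_um2"].to_numpy(),
            E=df["E_percent"].to_numpy(),
            sV=df["sd_V"].to_numpy() if "sd_V" in df else None,
            sS=df["sd_S"].to_numpy() if "sd_S" in df else None,
            sE=df["sd_E"].to_numpy() if "sd_E" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "EngulfmentTrace":
        return cls.from_frame(pd.read_csv(path))


def volume_surface_by_revolution(profile: np.ndarray, check: bool = True) -> tuple[float, float]:
    """Volume and lateral surface of the solid of revolution of an ordered
    (r, z) polyline about the z axis.

    Every segment is treated as a conical frustum, for which the formulas
    V = pi/3 (r0^2 + r0 r1 + r1^2) dz and S = pi (r0 + r1) slant are
    exact; a semicircular profile therefore converges to the sphere
    values as O(h^2).  The result is orientation-independent (|V|).
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
        raise ValueError("profile must be an ordered (n, 2) array of (r, z)")
    r, z = p[:, 0], p[:, 1]
    if np.any(r < -1e-12):
        raise ValueError("profile radii must be >= 0")
    if check and _self_intersects(p):
        raise ValueError("self-intersecting profile")
    r0, r1 = r[:-1], r[1:]
    dz = np.diff(z)
    V = np.pi / 3.0 * np.sum((r0**2 + r0 * r1 + r1**2) * dz)
    slant = np.hypot(np.diff(r), dz)
    S = np.pi * np.sum((r0 + r1) * slant)
    return abs(float(V)), float(S)


def _self_intersects(p: np.ndarray) -> bool:
    if len(p) < 4:
        return False
    try:
        from shapely.geometry import LineString

        return not LineString(p).is_simple
    except Exception:  # pragma: no cover - shapely is expected to be present
        return False


def percent_engulfment(
    profile: np.ndarray,
    covered: np.ndarray,
    center: np.ndarray | None = None,
) -> float:
    """Percent engulfment from a medial half-profile.

    ``profile`` is the ordered (r, z) boundary of the forespore from the
    axis on one end to the axis on the other; ``covered`` marks the
    segments wrapped by the mother membrane.  Engulfment is the total
    angle subtended at the forespore centroid by the covered segments,
    divided by the full angle, times 100 -- the same definition applied
    to micrograph contours.
    """
    p = np.asarray(profile, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    if len(covered) != len(p) - 1:
        raise ValueError("need one covered flag per profile segment")
    if center is None:
        center = _profile_centroid(p)
    d = p - center
    ang = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))  # angle from +z direction
    dtheta = np.abs(np.diff(ang))
    total = dtheta.sum()
    if total <= 0:
        raise ValueError("undefined forespore centre: degenerate profile")
    return float(np.clip(dtheta[covered].sum() / total * 100.0, 0.0, 100.0))


def _profile_centroid(p: np.ndarray) -> np.ndarray:
    """Area centroid of the revolved solid's cross-section (on the axis by
    symmetry); computed on the closed polygon (r, z) + mirrored side."""
    closed = np.vstack([p, p[::-1] * np.array([-1.0, 1.0])])
    x, y = closed[:, 0], closed[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        z_bar = p[:, 1].mean()
    else:
        z_bar = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    return np.array([0.0, z_bar])


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares circle fit (center, radius).

    Solves the linear system of the Kasa formulation; exact on noiseless
    circles with >= 3 non-collinear points.
    """
    q = np.asarray(points, dtype=float)
    if len(q) < 3:
        raise ValueError("need >= 3 points for a circle fit")
    A = np.column_stack([2 * q[:, 0], 2 * q[:, 1], np.ones(len(q))])
    b = (q**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("circle fit failed")
    return np.array([cx, cy]), float(np.sqrt(r2))


@dataclass
class CurvatureReport:
    kappa: float  # pole curvature, 1/um
    kappa0: float  # spherical-cap reference curvature, 1/um
    window_fraction: float

    @property
    def ratio(self) -> float:
        return self.kappa / self.kappa0


def relative_curvature(
    profile: np.ndarray, window_fraction: float = 0.2
) -> CurvatureReport:
    """Forespore pole curvature relative to the spherical cap with the
    same base radius and apex height.

    A circle is fit to the polar ``window_fraction`` of the (r, z)
    profile (largest z); the reference is the hemispherical cap on the
    profile's equatorial (maximum) radius, so a hemispherical pole gives
    a ratio of exactly one and a prolate (elongated) pole a ratio above
    one.
    """
    p = np.asarray(profile, dtype=float)
    z = p[:, 1]
    zcut = z.min() + (1.0 - window_fraction) * (z.max() - z.min())
    win = p[z >= zcut]
    if len(win) < 3:
        raise ValueError("pole window holds fewer than 3 points")
    _, R = fit_circle(win)
    R0 = p[:, 0].max()
    if R0 <= 0:
        raise ValueError("degenerate profile: zero equatorial radius")
    return CurvatureReport(kappa=1.0 / R, kappa0=1.0 / R0, window_fraction=window_fraction)


def peptide_linear_fraction(mesh, threshold: float = 1.0) -> float:
    """Fraction of intact peptide cross-links stretched less than
    ``threshold`` nm beyond rest (the linear-elastic regime for a 2 nm
    peptide is extension < 1 nm)."""
    exts = []
    m = mesh.pep_intact
    if m.any():
        d = np.linalg.norm(
            mesh.positions[mesh.pep_b[m]] - mesh.positions[mesh.pep_a[m]], axis=1
        )
        exts.append(d - mesh.pep_rest[m])
    am = mesh.anchor_intact
    if am.any():
        da = np.linalg.norm(
            mesh.anchor_point[am] - mesh.positions[mesh.anchor_bead[am]], axis=1
        )
        exts.append(da - mesh.anchor_rest[am])
    if not exts:
        return 1.0
    ext = np.concatenate(exts)
    return float(np.mean(ext < threshold))


def insertion_flux(length_inserted_total: float, elapsed_s: float) -> float:
    """Glycan insertion flux in nm/s on a per-single-glycan basis: total
    single-glycan length inserted over the active time.  Equals
    NIDC * VIDC * n_bundle when no complex ever pauses."""
    if elapsed_s <= 0:
        raise ValueError("elapsed time must be > 0")
    return length_inserted_total / elapsed_s


def implied_complex_count(
    flux_range_nm_s: tuple[float, float],
    speed_range_nm_s: tuple[float, float],
) -> tuple[int, int]:
    """Range of active complex counts implied by a flux estimate and a
    per-complex speed interval: dividing the flux bounds by the opposite
    speed bounds and rounding (110-117 nm/s over 20-40 nm/s gives 3-6)."""
    flo, fhi = sorted(flux_range_nm_s)
    slo, shi = sorted(speed_range_nm_s)
    if slo <= 0:
        raise ValueError("speeds must be > 0")
    return int(round(flo / shi)), int(round(fhi / slo))


def mean_id_separation(
    synthesis_sites: np.ndarray, junction_sites: np.ndarray
) -> float:
    """Mean over complexes of the Euclidean distance from each synthesis
    site to its nearest unsevered junction cross-link (nm)."""
    s = np.atleast_2d(np.asarray(synthesis_sites, dtype=float))
    j = np.atleast_2d(np.asarray(junction_sites, dtype=float))
    if len(j) == 0:
        raise ValueError("no intact junctions")
    d = np.linalg.norm(s[:, None, :] - j[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def typical_strand_length_um(inv_radius_per_um: float, fraction: float = 1.0 / 3.0) -> float:
    """Arc length of a given fraction of the cell circumference, from the
    printed inverse radius (2.3 um^-1 gives ~0.91 um for one third)."""
    if inv_radius_per_um <= 0:
        raise ValueError("inverse radius must be > 0")
    return fraction * 2.0 * np.pi / inv_radius_per_um
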