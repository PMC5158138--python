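"""Deterministic generators for every input the analysis tools consume.

Real inputs are membrane contours traced from medial-plane micrographs
and population-averaged engulfment traces; these generators emit the same
CSV contracts from known ground truth, so every analysis operation can be
round-trip tested without microscopy data.  A sporangium is emulated as a
capped-cylinder mother cell containing a spherical forespore whose
covered angle follows a prescribed engulfment schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import ContourFrame
from .observables import EngulfmentTrace

__all__ = [
    "FixtureSpec",
    "synth_contour_series",
    "synth_noisy_traces",
    "synth_intensity_painting",
    "synth_septum_series",
    "paint_le_fraction_amplitude",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic sporangium movie.

    ``E_schedule`` is piecewise-linear (time_min, percent) control points,
    non-decreasing for a wild-type-style fixture.  Schedules should stay
    above ~2 % so the two leading-edge points are distinct vertices
    (coincident points are the fully-engulfed convention).
    """

    forespore_radius_um: float = 0.43
    mother_radius_um: float = 0.5
    mother_length_um: float = 3.0
    E_schedule: list = field(default_factory=lambda: [(0.0, 25.0), (60.0, 100.0)])
    frame_interval_min: float = 5.0
    n_points: int = 96
    sigma_V: float = 0.02
    sigma_S: float = 0.1
    sigma_E: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        E = [e for _, e in self.E_schedule]
        if any(not 0 <= e <= 100 for e in E):
            raise ValueError("engulfment schedule must stay in [0, 100]")
        if self.forespore_radius_um >= self.mother_radius_um * 2.5:
            raise ValueError("impossible geometry: forespore larger than mother")

    def schedule(self, t: np.ndarray) -> np.ndarray:
        tt = np.array([p[0] for p in self.E_schedule])
        ee = np.array([p[1] for p in self.E_schedule])
        return np.interp(t, tt, ee)


def _circle(center, radius, n, phase=0.0):
    a = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(a), center[1] + radius * np.sin(a)])


def synth_contour_series(spec: FixtureSpec) -> tuple[dict, pd.DataFrame]:
    """Per-frame mother and forespore contours plus a ground-truth table.

    The forespore is a circle (a sphere in 3D) centred on the mother's
    long axis near one pole; the covered arc of angle E/100 * 2pi is
    centred on the direction toward the mother centroid.  Ground truth
    per frame: V, S (sphere values), E, gap arc length, the leading-edge
    vertex indices and the centroids.  Deterministic under the seed.
    """
    rho = spec.forespore_radius_um
    times = np.arange(0.0, spec.E_schedule[-1][0] + 1e-9, spec.frame_interval_min)
    E = spec.schedule(times)
    fs_center = np.array([0.0, 0.0])
    mother_center = np.array([spec.mother_length_um / 2.0 + 0.2, 0.0])
    n = spec.n_points
    series = []
    truth_rows = []
    for k, (t, e) in enumerate(zip(times, E)):
        # phase chosen so vertex 0 points at the mother centroid
        fs = _circle(fs_center, rho, n, phase=0.0)
        mother = _capped_cylinder(
            mother_center, spec.mother_radius_um, spec.mother_length_um, n
        )
        covered_angle = e / 100.0 * 2 * np.pi
        half = covered_angle / 2.0
        # vertex angles measured from the +x axis (toward the mother)
        ang = 2 * np.pi * np.arange(n) / n
        ang = (ang + np.pi) % (2 * np.pi) - np.pi
        covered = np.abs(ang) <= half + 1e-12
        if e >= 100.0 - 1e-9:
            i_le = j_le = 0
            gap_len = 0.0
            e_real = 100.0
        else:
            cov_idx = np.where(covered)[0]
            ordered = np.sort(((cov_idx + n // 2) % n))  # contiguous about 0
            i_le = int((ordered[0] - n // 2) % n)
            j_le = int((ordered[-1] - n // 2) % n)
            # ground truth uses the angle actually spanned by the chosen
            # leading-edge vertices, so analysis round trips are exact up
            # to the polygon-vs-circle difference
            realized = (ordered[-1] - ordered[0]) * 2 * np.pi / n
            e_real = realized / (2 * np.pi) * 100.0
            gap_len = rho * (2 * np.pi - realized)
        frames = {
            "forespore": ContourFrame(time=t, compartment="forespore", points=fs),
            "mother": ContourFrame(time=t, compartment="mother", points=mother),
        }
        series.append((k, frames))
        truth_rows.append(
            {
                "frame": k,
                "time_min": t,
                "E_percent": e_real,
                "E_schedule_percent": e,
                "V_um3": 4.0 / 3.0 * np.pi * rho**3,
                "S_um2": 4.0 * np.pi * rho**2,
                "gap_arc_um": gap_len,
                "le_i": i_le,
                "le_j": j_le,
                "fs_cx": fs_center[0],
                "fs_cy": fs_center[1],
                "mc_cx": mother_center[0],
                "mc_cy": mother_center[1],
            }
        )
    return {"cell0": series}, pd.DataFrame(truth_rows)


def _capped_cylinder(center, radius, length, n):
    """Closed stadium outline (rectangle with semicircular caps)."""
    half = length / 2.0
    n4 = max(n // 4, 4)
    top = np.column_stack([np.linspace(-half, half, n4), np.full(n4, radius)])
    a = np.linspace(np.pi / 2, -np.pi / 2, n4)
    cap_r = np.column_stack([half + radius * np.cos(a), radius * np.sin(a)])
    bottom = np.column_stack([np.linspace(half, -half, n4), np.full(n4, -radius)])
    a2 = np.linspace(-np.pi / 2, -3 * np.pi / 2, n4)
    cap_l = np.column_stack([-half + radius * np.cos(a2), radius * np.sin(a2)])
    pts = np.vstack([top, cap_r[1:], bottom[1:], cap_l[1:-1]])
    return pts + np.asarray(center)


def synth_noisy_traces(
    true_trace: EngulfmentTrace,
    sigma_V: float,
    sigma_S: float,
    sigma_E: float,
    seed: int = 0,
) -> EngulfmentTrace:
    """Experimental-style trace: i.i.d. Gaussian noise per channel added
    to the true trace, with the sigmas recorded for chi-square fitting."""
    if min(sigma_V, sigma_S, sigma_E) <= 0:
        raise ValueError("sigmas must be > 0")
    rng = np.random.default_rng(seed)
    nt = len(true_trace)
    return EngulfmentTrace(
        time=true_trace.time.copy(),
        V=true_trace.V + rng.normal(0, sigma_V, nt),
        S=true_trace.S + rng.normal(0, sigma_S, nt),
        E=np.clip(true_trace.E + rng.normal(0, sigma_E, nt), 0, 100),
        sV=np.full(nt, sigma_V),
        sS=np.full(nt, sigma_S),
        sE=np.full(nt, sigma_E),
    )


def synth_intensity_painting(
    cells: dict,
    baseline: float = 1.0,
    gaussians: list[tuple[float, float, float]] = (),
) -> dict:
    """Paint per-point intensities onto forespore contours.

    ``gaussians`` is a list of (centre_deg, sigma_deg, amplitude) angular
    peaks in the mother-forespore frame (0 deg toward the mother), added
    to a uniform baseline.  Negative intensities are clipped at zero with
    a warning.  Mother contours get the plain baseline.
    """
    import warnings

    from .contours import contour_angles

    painted = {}
    for cell_id, series in cells.items():
        new_series = []
        for k, comps in series:
            fs = comps["forespore"]
            mc = comps["mother"].centroid
            ang = contour_angles(fs, mc)
            inten = np.full(len(fs.points), float(baseline))
            for c0, sig, amp in gaussians:
                d = (ang - c0 + 180.0) % 360.0 - 180.0
                inten += amp * np.exp(-0.5 * (d / sig) ** 2)
            if np.any(inten < 0):
                warnings.warn("negative painted intensity clipped at 0")
                inten = np.clip(inten, 0, None)
            new_comps = dict(comps)
            new_comps["forespore"] = ContourFrame(
                time=fs.time,
                compartment="forespore",
                points=fs.points.copy(),
                intensity=inten,
            )
            mother = comps["mother"]
            new_comps["mother"] = ContourFrame(
                time=mother.time,
                compartment="mother",
                points=mother.points.copy(),
                intensity=np.full(len(mother.points), float(baseline)),
            )
            new_series.append((k, new_comps))
        painted[cell_id] = new_series
    return painted


def paint_le_fraction_amplitude(
    n_points: int,
    le_halfwidth_deg: float,
    sigma_deg: float,
    baseline: float,
    target_fraction: float,
) -> float:
    """Amplitude of a leading-edge-centred angular Gaussian such that the
    band within +/- ``le_halfwidth_deg`` of the peak holds
    ``target_fraction`` of the total painted intensity."""
    ang = np.linspace(-180.0, 180.0, n_points, endpoint=False)
    g = np.exp(-0.5 * (ang / sigma_deg) ** 2)
    inside = np.abs(ang) <= le_halfwidth_deg
    # solve f = (b*ni + A*gi) / (b*n + A*g_tot) for A
    b_in = baseline * inside.sum()
    b_tot = baseline * n_points
    g_in = g[inside].sum()
    g_tot = g.sum()
    denom = g_in - target_fraction * g_tot
    if denom <= 0:
        raise ValueError("target fraction unreachable with this peak width")
    return (target_fraction * b_tot - b_in) / denom


def synth_septum_series(
    n_frames: int,
    onset_frame: int,
    kappa_max: float = 2.3,
    n_points: int = 24,
    width_um: float = 1.0,
    noise_um: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Septal mid-profiles that stay flat until ``onset_frame`` and then
    curve with linearly ramping curvature up to ``kappa_max`` (1/um);
    optional Gaussian point noise sets the SNR for onset detection."""
    rng = np.random.default_rng(seed)
    x = np.linspace(-width_um / 2, width_um / 2, n_points)
    frames = []
    for k in range(n_frames):
        if k < onset_frame:
            kappa = 0.0
        else:
            ramp = (k - onset_frame + 1) / max(n_frames - onset_frame, 1)
            kappa = kappa_max * min(ramp * 2.0, 1.0)
        if kappa > 1e-9:
            R = 1.0 / kappa
            y = R - np.sqrt(np.maximum(R**2 - x**2, 0.0))
        else:
            y = np.zeros_like(x)
        pts = np.column_stack([x, y])
        if noise_um > 0:
            pts = pts + rng.normal(0, noise_um, pts.shape)
        frames.append(pts)
    return frames
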