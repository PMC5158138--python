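"""Quantification of membrane contours: kymographs, onset alignment,
gap arc length and leading-edge fluorescence fraction.

These operations consume already-extracted membrane polylines (one closed
polyline per compartment per frame), as produced by active-contour
tracing of medial-plane micrographs; raw image processing is outside this
package.  Angles live in the mother-forespore reference frame: origin at
the forespore centroid, 0 degrees pointing at the mother-cell centroid
(the septum midpoint), positive counter-clockwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .observables import fit_circle

__all__ = [
    "ContourFrame",
    "Kymograph",
    "load_contours",
    "save_contours",
    "contour_angles",
    "align_time_zero",
    "build_average_kymograph",
    "gap_arc_length",
    "gfp_le_fraction",
    "gfp_le_fraction_batch",
]


@dataclass
class ContourFrame:
    """One compartment's membrane polyline in one frame (closed implicitly).

    Coordinates in um; ``intensity`` (arbitrary units, optional) is
    sampled per vertex.
    """

    time: float  # min
    compartment: str  # "mother" | "forespore"
    points: np.ndarray  # (n, 2) um
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 8:
            raise ValueError("contours need >= 8 points")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if len(self.intensity) != len(self.points):
                raise ValueError("one intensity value per contour point")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class Kymograph:
    """Angle x time map of normalized membrane intensity."""

    angles_deg: np.ndarray  # bin centres in [-180, 180)
    times_min: np.ndarray
    grid: np.ndarray  # (time, angle), NaN where no data
    n_cells: int = 1


# ------------------------------ CSV contract -------------------------------

_COLUMNS = ["cell_id", "frame", "time_min", "compartment", "point_index", "x_um", "y_um"]


def save_contours(cells: dict, path) -> None:
    """Write {cell_id: [(frame_index, {compartment: ContourFrame})]} to the
    flat CSV contract (cell_id, frame, time_min, compartment, point_index,
    x_um, y_um[, intensity])."""
    rows = []
    for cell_id, series in cells.items():
        for frame_idx, comps in series:
            for comp, cf in comps.items():
                for i, (x, y) in enumerate(cf.points):
                    row = {
                        "cell_id": cell_id,
                        "frame": frame_idx,
                        "time_min": cf.time,
                        "compartment": comp,
                        "point_index": i,
                        "x_um": x,
                        "y_um": y,
                    }
                    if cf.intensity is not None:
                        row["intensity"] = cf.intensity[i]
                    rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_contours(path) -> dict:
    """Inverse of :func:`save_contours`."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV missing columns: {sorted(missing)}")
    cells: dict = {}
    for cell_id, cdf in df.groupby("cell_id"):
        series = []
        for frame_idx, fdf in cdf.groupby("frame"):
            comps = {}
            for comp, pdf in fdf.groupby("compartment"):
                pdf = pdf.sort_values("point_index")
                comps[comp] = ContourFrame(
                    time=float(pdf["time_min"].iloc[0]),
                    compartment=str(comp),
                    points=pdf[["x_um", "y_um"]].to_numpy(),
                    intensity=pdf["intensity"].to_numpy()
                    if "intensity" in pdf and pdf["intensity"].notna().all()
                    else None,
                )
            series.append((int(frame_idx), comps))
        series.sort(key=lambda t: t[0])
        cells[cell_id] = series
    return cells


# ------------------------------ operations ---------------------------------

def contour_angles(forespore: ContourFrame, mother_center: np.ndarray) -> np.ndarray:
    """Per-point angles (deg, [-180, 180)) of a forespore contour in the
    mother-forespore frame: 0 at the direction from the forespore centroid
    toward the mother centroid, increasing counter-clockwise."""
    c = forespore.centroid
    axis = np.asarray(mother_center, dtype=float) - c
    theta0 = np.arctan2(axis[1], axis[0])
    d = forespore.points - c
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]) - theta0)
    return (ang + 180.0) % 360.0 - 180.0


def septum_curvature(points: np.ndarray) -> float:
    """Unsigned curvature (1/um) of a septal mid-profile polyline.

    A parabola is fit to the central half of the profile in its chord
    frame and the apex curvature 2|c| reported.  Unlike an algebraic
    circle fit, this is unbiased for shallow (nearly flat) noisy arcs,
    which is exactly the regime that matters for onset detection.
    """
    p = np.asarray(points, dtype=float)
    n = len(p)
    mid = p[n // 4 : n - n // 4] if n >= 8 else p
    chord = mid[-1] - mid[0]
    L = np.linalg.norm(chord)
    if L < 1e-12 or len(mid) < 3:
        return 0.0
    t = chord / L
    nrm = np.array([-t[1], t[0]])
    x = (mid - mid[0]) @ t
    y = (mid - mid[0]) @ nrm
    A = np.column_stack([np.ones_like(x), x, x**2])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    b, c = coef[1], coef[2]
    kappa = 2.0 * abs(c) / (1.0 + b**2) ** 1.5
    return float(min(kappa, 1e6))


def align_time_zero(
    septum_profiles: list[np.ndarray],
    threshold: float = 0.5,
    baseline_frames: int = 3,
) -> int | None:
    """Index of the onset of septum curving (time zero of the common clock).

    Each element is the septal mid-profile polyline of one frame; the
    onset is the first frame whose circle-fit curvature exceeds the
    flat-septum baseline (median of the first ``baseline_frames``) by
    ``threshold`` (1/um).  Returns None when the septum never curves.
    """
    if len(septum_profiles) < 3:
        raise ValueError("need >= 3 frames spanning flat to curved")
    kappas = np.array([septum_curvature(p) for p in septum_profiles])
    base = float(np.median(kappas[:baseline_frames]))
    above = np.where(kappas > base + threshold)[0]
    return int(above[0]) if len(above) else None


def build_average_kymograph(
    cells: list[list[tuple[ContourFrame, np.ndarray]]],
    bin_deg: float = 1.0,
) -> Kymograph:
    """Average angle-time kymograph over cells aligned at time zero.

    Each cell is a list of (forespore ContourFrame with intensity,
    mother centroid) pairs, frame-aligned across cells.  Intensities are
    normalized per cell by that cell's mean contour intensity, resampled
    to the common angle grid by periodic cubic interpolation, then
    averaged across cells per (angle, time) bin; bins no cell covers are
    NaN (missing, never zero).
    """
    if not cells or not cells[0]:
        raise ValueError("no cells")
    n_frames = min(len(series) for series in cells)
    grid_angles = np.arange(-180.0, 180.0, bin_deg)
    acc = np.zeros((n_frames, len(grid_angles)))
    cnt = np.zeros_like(acc)
    times = None
    for series in cells:
        norm = np.mean(
            [f.intensity.mean() for f, _ in series[:n_frames] if f.intensity is not None]
        )
        if not np.isfinite(norm) or norm == 0:
            norm = 1.0
        if times is None:
            times = np.array([f.time for f, _ in series[:n_frames]])
        for t, (frame, mc) in enumerate(series[:n_frames]):
            if frame.intensity is None:
                continue
            ang = contour_angles(frame, mc)
            order = np.argsort(ang)
            a = ang[order]
            v = frame.intensity[order] / norm
            # deduplicate angles, then wrap for a periodic cubic spline
            a_u, idx = np.unique(a, return_index=True)
            v_u = v[idx]
            a_ext = np.concatenate([a_u, [a_u[0] + 360.0]])
            v_ext = np.concatenate([v_u, [v_u[0]]])
            spline = CubicSpline(a_ext, v_ext, bc_type="periodic")
            sampled = spline((grid_angles - a_u[0]) % 360.0 + a_u[0])
            acc[t] += sampled
            cnt[t] += 1
    with np.errstate(invalid="ignore"):
        grid = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return Kymograph(
        angles_deg=grid_angles, times_min=times, grid=grid, n_cells=len(cells)
    )


def gap_arc_length(
    forespore: ContourFrame,
    le_indices: tuple[int, int],
    mother_center: np.ndarray,
) -> tuple[float, float]:
    """Arc length (um) and subtended angle (rad) of the uncovered part of
    the forespore contour between the two leading-edge points.

    The uncovered arc is the one *not* containing the contour point
    nearest the mother centroid (the septum side is covered by
    definition).  Returns (0, 0) for a fully engulfed cell, signalled by
    identical leading-edge indices.
    """
    p = forespore.points
    i, j = le_indices
    n = len(p)
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError("leading-edge points are not on the contour")
    if i == j:
        return 0.0, 0.0
    seg = np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1)
    septum_idx = int(np.argmin(np.linalg.norm(p - np.asarray(mother_center), axis=1)))

    def arc(frm, to):  # indices walked forward cyclically, and their length
        idx = []
        k = frm
        while k != to:
            idx.append(k)
            k = (k + 1) % n
        return idx, float(seg[idx].sum())

    fwd_idx, fwd_len = arc(i, j)
    bwd_idx, bwd_len = arc(j, i)
    uncovered_idx, length = (
        (bwd_idx, bwd_len) if septum_idx in fwd_idx else (fwd_idx, fwd_len)
    )
    c = forespore.centroid
    rad = np.linalg.norm(p - c, axis=1).mean()
    angle = length / rad if rad > 0 else 0.0
    return length, float(angle)


def gfp_le_fraction(
    ile: float,
    imc: float,
    background: float = 0.0,
    npix_le: int = 1,
    npix_mc: int = 1,
) -> float:
    """Fraction of fluorescence at the leading edge,
    (ILE - bg) / ((ILE - bg) + (IMC - bg)), after per-region background
    subtraction; negative subtracted totals are clipped at zero with a
    warning."""
    le = ile - background * npix_le
    mc = imc - background * npix_mc
    if le < 0 or mc < 0:
        warnings.warn("background subtraction left a negative total; clipping at 0")
        le, mc = max(le, 0.0), max(mc, 0.0)
    tot = le + mc
    if tot == 0:
        raise ValueError("both compartments are zero after background subtraction")
    return le / tot


def gfp_le_fraction_batch(
    ile: np.ndarray,
    imc: np.ndarray,
    background: float = 0.0,
    npix_le: int = 1,
    npix_mc: int = 1,
) -> tuple[float, float]:
    """Per-sporangium fractions summarised as mean +/- SEM."""
    fr = np.array(
        [
            gfp_le_fraction(a, b, background, npix_le, npix_mc)
            for a, b in zip(np.atleast_1d(ile), np.atleast_1d(imc))
        ]
    )
    sem = float(fr.std(ddof=1) / np.sqrt(len(fr))) if len(fr) > 1 else 0.0
    return float(fr.mean()), sem
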