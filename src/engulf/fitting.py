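"""Chi-square comparison of simulated and experimental engulfment traces,
grid sweeps over the peptidoglycan spring constants, and phenotype
classification.

The quality-of-fit statistic sums, over experimental time points, the
standardized squared residuals of volume, surface area and engulfment:

    chi2 = sum_i [ (Vi_exp - Vi_sim)^2 / sd(Vi_exp)^2
                 + (Si_exp - Si_sim)^2 / sd(Si_exp)^2
                 + (Ei_exp - Ei_sim)^2 / sd(Ei_exp)^2 ]

Simulated traces are linearly interpolated to the experimental time
points, because the experimental standard deviations are defined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .observables import EngulfmentTrace

__all__ = ["FitResult", "chi2", "grid_sweep", "classify_phenotype", "PhenotypeCall"]


@dataclass
class FitResult:
    chi2: float
    chi2_V: float
    chi2_S: float
    chi2_E: float
    n_points: int
    params: dict = field(default_factory=dict)


def chi2(exp: EngulfmentTrace, sim: EngulfmentTrace, params: dict | None = None) -> FitResult:
    """Exact three-channel chi-square of a simulated against an
    experimental trace (see module docstring)."""
    for name, s in (("V", exp.sV), ("S", exp.sS), ("E", exp.sE)):
        if s is None or np.any(s <= 0):
            raise ValueError(f"experimental sigma_{name} must be > 0 at every point")
    if exp.time.min() < sim.time.min() - 1e-9 or exp.time.max() > sim.time.max() + 1e-9:
        raise ValueError("simulated trace does not cover the experimental time range")
    parts = {}
    for name, e, s, sd in (
        ("V", exp.V, sim.V, exp.sV),
        ("S", exp.S, sim.S, exp.sS),
        ("E", exp.E, sim.E, exp.sE),
    ):
        si = np.interp(exp.time, sim.time, s)
        parts[name] = float(np.sum((e - si) ** 2 / sd**2))
    return FitResult(
        chi2=sum(parts.values()),
        chi2_V=parts["V"],
        chi2_S=parts["S"],
        chi2_E=parts["E"],
        n_points=len(exp),
        params=params or {},
    )


def grid_sweep(
    kpep_values: Sequence[float],
    kgly_values: Sequence[float],
    exp: EngulfmentTrace,
    simulate: Callable[[float, float, int], EngulfmentTrace],
    reps: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Mean chi-square over seeds for every (kpep, kgly) grid cell.

    ``simulate(kpep, kgly, seed)`` runs one simulation and returns its
    trace.  Failed cells are marked missing (NaN) and excluded from the
    minimum, never silently imputed.  Returns the tidy per-replicate
    table and the argmin cell of the mean surface.
    """
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    rows = []
    for kpep in kpep_values:
        for kgly in kgly_values:
            for rep, s in enumerate(seeds):
                try:
                    sim = simulate(float(kpep), float(kgly), int(s))
                    fr = chi2(exp, sim, params={"kpep": kpep, "kgly": kgly})
                    rows.append(
                        {
                            "kpep": kpep,
                            "kgly": kgly,
                            "rep": rep,
                            "chi2": fr.chi2,
                            "chi2_V": fr.chi2_V,
                            "chi2_S": fr.chi2_S,
                            "chi2_E": fr.chi2_E,
                        }
                    )
                except Exception as err:  # failed cell: missing, logged
                    import logging

                    logging.getLogger(__name__).warning(
                        "sweep cell kpep=%s kgly=%s rep=%d failed: %s",
                        kpep,
                        kgly,
                        rep,
                        err,
                    )
                    rows.append(
                        {
                            "kpep": kpep,
                            "kgly": kgly,
                            "rep": rep,
                            "chi2": np.nan,
                            "chi2_V": np.nan,
                            "chi2_S": np.nan,
                            "chi2_E": np.nan,
                        }
                    )
    df = pd.DataFrame(rows)
    mean = df.groupby(["kpep", "kgly"])["chi2"].mean().dropna()
    if mean.empty:
        raise RuntimeError("every sweep cell failed")
    best = mean.idxmin()
    return df, (float(best[0]), float(best[1]))


@dataclass
class PhenotypeCall:
    label: str  # "symmetric" | "asymmetric" | "stalled"
    final_E: float
    le_spread: float
    spread_threshold: float
    completion_threshold: float


def classify_phenotype(
    trace: EngulfmentTrace,
    le_spread: float,
    forespore_circumference: float,
    completion_threshold: float = 95.0,
    asymmetry_fraction: float = 0.25,
    stall_dE: float = 1.0,
) -> PhenotypeCall:
    """Classify a completed run as stalled, asymmetric or symmetric.

    Stalled: final engulfment below ``completion_threshold`` with no
    progress over the last fifth of the trace (|dE| < ``stall_dE``).
    Asymmetric: the angular spread of leading-edge height (same length
    unit as the circumference) exceeds ``asymmetry_fraction`` of the
    forespore circumference.  The thresholds travel with the call.
    """
    final_E = float(trace.E[-1])
    tail = max(2, len(trace) // 5)
    dE = float(trace.E[-1] - trace.E[-tail])
    spread_threshold = asymmetry_fraction * forespore_circumference
    if final_E < completion_threshold and abs(dE) < stall_dE and le_spread <= spread_threshold:
        label = "stalled"
    elif le_spread > spread_threshold:
        label = "asymmetric"
    else:
        label = "symmetric"
    return PhenotypeCall(
        label=label,
        final_E=final_E,
        le_spread=float(le_spread),
        spread_threshold=float(spread_threshold),
        completion_threshold=float(completion_threshold),
    )
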