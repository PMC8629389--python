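"""Selection-condition metrics, δ-sweeps, and local-maximum detection.

Four conditions quantify when selection favors producers at intensity δ:

* A0  — absolute, vs neutral drift: ρ_C(δ) > ρ_C(0);
* A′  — absolute, local trend: ρ_C′(δ) > 0;
* R0  — relative to D: ρ_C(δ) > ρ_D(δ), equivalently the rare-mutation
  stationary fraction ρ_C/(ρ_C + ρ_D) exceeds its neutral value 1/2;
* R′  — relative trend: ρ_C′ ρ_D > ρ_C ρ_D′, equivalently
  (ρ_C/(ρ_C + ρ_D))′ > 0.

Inequalities are strict with zero tolerance; reports carry the raw
margins so callers can apply their own.  At δ = 0 all four are reported
False (the defining comparisons reduce to the neutral C/D symmetry).
Derivatives use central finite differences (one-sided at δ = 0) with the
step recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .models import EvolutionModel, mean_rho

__all__ = [
    "ConditionReport",
    "SweepResult",
    "Maximum",
    "evaluate_conditions",
    "sweep",
    "default_delta_grid",
    "find_local_maxima",
    "local_maxima",
]

_PLATEAU_TOL = 1e-14


@dataclass(frozen=True)
class ConditionReport:
    delta: float
    A0: bool
    Aprime: bool
    R0: bool
    Rprime: bool
    rho_C: float
    rho_D: float
    drho_C: float
    drho_D: float
    fd_step: float


@dataclass(frozen=True)
class Maximum:
    delta: float
    value: float
    refined: bool


@dataclass
class SweepResult:
    model: EvolutionModel
    grid: np.ndarray
    rho_C: np.ndarray
    rho_D: np.ndarray
    rho_C0: float
    rho_D0: float
    ratio_to_neutral: np.ndarray
    time_in_C: np.ndarray
    maxima: list[Maximum] = field(default_factory=list)
    components: dict | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("delta grid must be strictly increasing")
        if np.any((self.time_in_C < 0) | (self.time_in_C > 1)):
            raise ValueError("time_in_C must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "delta": self.grid,
            "scheme": self.model.scheme.kind,
            "rule": self.model.rule,
            "init": self.model.init,
            "mean_rho_C": self.rho_C,
            "mean_rho_D": self.rho_D,
            "ratio_to_neutral": self.ratio_to_neutral,
            "time_in_C": self.time_in_C,
        }
        if self.components is not None:
            data["rho_C_hub"] = self.components["hub"]
            data["rho_C_leaf"] = self.components["leaf"]
        return pd.DataFrame(data)


def default_delta_grid(N: int) -> np.ndarray:
    """Log-spaced default grid: 200 points on [1e-3, 10] for small
    populations, 400 points on [1e-4, 5] for large stars (resolves both
    fixation-probability peaks at N = 2000)."""
    if N > 200:
        return np.geomspace(1e-4, 5.0, 400)
    return np.geomspace(1e-3, 10.0, 200)


def _fd_step(delta: float, fd_step: float | None) -> float:
    if delta == 0:
        return fd_step if fd_step is not None else 1e-4
    if fd_step is None:
        return min(max(1e-4, 1e-3 * delta), delta / 2)
    if fd_step >= delta:
        raise ValueError(f"fd_step={fd_step} crosses zero selection intensity (delta={delta})")
    return fd_step


def evaluate_conditions(
    model: EvolutionModel, delta: float, fd_step: float | None = None
) -> ConditionReport:
    """Evaluate the four selection conditions at intensity ``delta``."""
    if delta < 0 or (fd_step is not None and fd_step <= 0):
        raise ValueError("delta must be >= 0 and fd_step > 0")
    h = _fd_step(delta, fd_step)
    at = mean_rho(model, delta)
    neutral = mean_rho(model, 0.0)
    if delta == 0:
        hi = mean_rho(model, h)
        drho_C = (hi.rho_C - at.rho_C) / h
        drho_D = (hi.rho_D - at.rho_D) / h
        return ConditionReport(delta, False, False, False, False, at.rho_C, at.rho_D, drho_C, drho_D, h)
    lo, hi = mean_rho(model, delta - h), mean_rho(model, delta + h)
    drho_C = (hi.rho_C - lo.rho_C) / (2 * h)
    drho_D = (hi.rho_D - lo.rho_D) / (2 * h)
    return ConditionReport(
        delta,
        at.rho_C > neutral.rho_C,
        drho_C > 0,
        at.rho_C > at.rho_D,
        drho_C * at.rho_D > at.rho_C * drho_D,
        at.rho_C,
        at.rho_D,
        drho_C,
        drho_D,
        h,
    )


def sweep(model: EvolutionModel, grid=None, *, refine: bool = False) -> SweepResult:
    """Mean fixation probabilities across a δ-grid, with peak detection."""
    if grid is None:
        grid = default_delta_grid(model.N)
    grid = np.asarray(grid, dtype=float)
    neutral = mean_rho(model, 0.0)
    results = [mean_rho(model, float(d)) for d in grid]
    rho_C = np.array([r.rho_C for r in results])
    rho_D = np.array([r.rho_D for r in results])
    components = None
    if results and results[0].components is not None:
        components = {
            "hub": np.array([r.components["hub"] for r in results]),
            "leaf": np.array([r.components["leaf"] for r in results]),
        }
    sr = SweepResult(
        model=model,
        grid=grid,
        rho_C=rho_C,
        rho_D=rho_D,
        rho_C0=neutral.rho_C,
        rho_D0=neutral.rho_D,
        ratio_to_neutral=rho_C / neutral.rho_C,
        time_in_C=rho_C / (rho_C + rho_D),
        components=components,
    )
    sr.maxima = find_local_maxima(sr, refine=refine)
    return sr


def local_maxima(
    grid,
    values,
    *,
    refine: bool = False,
    objective=None,
    plateau_tol: float = _PLATEAU_TOL,
) -> list[Maximum]:
    """Interior strict local maxima of a sampled curve.

    Consecutive values within ``plateau_tol`` are merged into a single
    plateau; a plateau is a maximum if strictly above both flanking
    runs.  Endpoints are never counted.  With ``refine`` and a callable
    ``objective``, each maximum is polished by golden-section search
    between its bracketing grid neighbors, making the location
    grid-independent.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.shape != values.shape:
        raise ValueError("grid and values must have the same shape")
    if grid.size < 3:
        return []
    # compress plateau runs
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, grid.size):
        if abs(values[i] - values[start]) > plateau_tol:
            runs.append((start, i - 1))
            start = i
    runs.append((start, grid.size - 1))
    out: list[Maximum] = []
    for k in range(1, len(runs) - 1):
        lo, hi = runs[k]
        if values[lo] > values[runs[k - 1][1]] and values[lo] > values[runs[k + 1][0]]:
            peak = (lo + hi) // 2
            delta_star, value, refined = float(grid[peak]), float(values[peak]), False
            if refine and objective is not None and 0 < peak < grid.size - 1:
                bracket = (grid[peak - 1], grid[peak], grid[peak + 1])
                try:
                    res = minimize_scalar(
                        lambda d: -objective(d), bracket=bracket, method="golden",
                        options={"xtol": 1e-10},
                    )
                    if res.success and -res.fun >= value:
                        delta_star, value, refined = float(res.x), float(-res.fun), True
                except ValueError:
                    pass  # degenerate bracket: keep the grid point
            out.append(Maximum(delta_star, value, refined))
    return out


def find_local_maxima(sr: SweepResult, *, refine: bool = False) -> list[Maximum]:
    """Local maxima of the mean producer fixation probability of a sweep."""
    objective = (lambda d: mean_rho(sr.model, float(d)).rho_C) if refine else None
    return local_maxima(sr.grid, sr.rho_C, refine=refine, objective=objective)
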