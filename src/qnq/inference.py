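"""Parameter calibration and global-optimisation fitting.

Death rates are calibrated analytically from CFU viability fractions
(exponential survival).  Full model fits minimise the sum of squared
biomass residuals between simulated and observed regrowth curves with a
differential-evolution optimiser (rand/1/bin), implemented here so the
strategy, population size and stopping rule are explicit and seeded.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .curves import od_to_biomass
from .model import ModelParams
from .scenarios import Scenario, run_long_starvation, run_short_starvation

__all__ = [
    "calibrate_death_rate",
    "DEConfig",
    "differential_evolution",
    "FitResult",
    "fit_parameters",
]

_PENALTY = 1e30


def calibrate_death_rate(surviving_fraction: float, duration_days: float) -> float:
    """Exponential death rate (per day) from a survival fraction.

    Solves ``exp(-d * duration) = surviving_fraction``.  The study's
    anchors are the 4-week CFU viabilities: 87% for Q and 3% for NQ cells.
    """
    if not 0.0 < surviving_fraction <= 1.0:
        raise ValueError(
            f"surviving_fraction must lie in (0, 1], got {surviving_fraction}"
        )
    if duration_days <= 0:
        raise ValueError(f"duration_days must be > 0, got {duration_days}")
    return -math.log(surviving_fraction) / duration_days


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution hyperparameters (rand/1/bin).

    ``npop`` defaults to 10x the number of free parameters.  The run stops
    early when the best objective improves by less than ``stall_tol``
    (relative) over ``stall_generations`` consecutive generations.
    """

    seed: int = 0
    npop: Optional[int] = None
    mutation: float = 0.8
    crossover: float = 0.9
    generations: int = 200
    stall_generations: int = 30
    stall_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.mutation <= 2.0:
            raise ValueError("mutation must lie in (0, 2]")
        if not 0.0 <= self.crossover <= 1.0:
            raise ValueError("crossover must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def differential_evolution(objective: Callable[[np.ndarray], float],
                           bounds: Sequence[tuple[float, float]],
                           config: DEConfig,
                           ) -> tuple[np.ndarray, float, list[float], int, bool]:
    """Minimise ``objective`` over a box with rand/1/bin DE.

    Returns ``(x_best, f_best, trace, n_evaluations, converged)`` where
    ``trace`` is the per-generation best objective (non-increasing) and
    ``converged`` reports whether the stall-based stopping rule fired
    before the generation budget ran out.  Fully deterministic under
    ``config.seed``.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if len(lo) == 0:
        raise ValueError("bounds must be non-empty")
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with low < high")
    dim = len(lo)
    npop = config.npop or 10 * dim
    if npop < 4:
        raise ValueError("population size must be >= 4 for rand/1/bin")
    rng = np.random.default_rng(config.seed)

    pop = lo + rng.random((npop, dim)) * (hi - lo)
    fitness = np.array([objective(x) for x in pop])
    n_eval = npop
    trace: list[float] = []
    converged = False
    stall = 0
    for _ in range(config.generations):
        for i in range(npop):
            r1, r2, r3 = _distinct_indices(rng, npop, i)
            mutant = pop[r1] + config.mutation * (pop[r2] - pop[r3])
            mutant = np.clip(mutant, lo, hi)
            cross = rng.random(dim) < config.crossover
            cross[rng.integers(dim)] = True  # guarantee one mutant coordinate
            trial = np.where(cross, mutant, pop[i])
            f_trial = objective(trial)
            n_eval += 1
            if f_trial <= fitness[i]:
                pop[i] = trial
                fitness[i] = f_trial
        best = float(fitness.min())
        if trace and best >= trace[-1] * (1.0 - config.stall_tol) - config.stall_tol:
            stall += 1
        else:
            stall = 0
        trace.append(best)
        if stall >= config.stall_generations:
            converged = True
            break
    i_best = int(np.argmin(fitness))
    return pop[i_best].copy(), float(fitness[i_best]), trace, n_eval, converged


def _distinct_indices(rng: np.random.Generator, npop: int, i: int):
    idx = rng.choice(npop - 1, size=3, replace=False)
    return tuple(j if j < i else j + 1 for j in idx)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a global fit."""

    best_params: ModelParams
    free_values: dict
    objective: float
    n_evaluations: int
    seed: int
    converged: bool
    bounds: dict
    trace: list = field(default_factory=list)

    def to_json(self, **extra) -> str:
        payload = {
            "free_values": self.free_values,
            "objective": self.objective,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "converged": self.converged,
            "bounds": self.bounds,
            "trace": list(self.trace),
            "best_params": asdict(self.best_params),
            **extra,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _observations(data: pd.DataFrame, sample_interval: float):
    """Index observed biomass by (culture_type, environment, week)."""
    obs = {}
    for (ct, env, week), grp in data.groupby(["culture_type", "environment", "week"]):
        idx = np.rint(grp["time_h"].to_numpy() / sample_interval).astype(int)
        biomass = od_to_biomass(grp["od"].to_numpy(), on_range="ignore")
        obs[(ct, env, int(week))] = (idx, biomass)
    return obs


def fit_parameters(data: pd.DataFrame,
                   free_params: dict,
                   fixed: Optional[ModelParams] = None,
                   optimizer: Optional[DEConfig] = None,
                   scenario_kwargs: Optional[dict] = None,
                   ) -> FitResult:
    """Fit selected model parameters to plate data by differential evolution.

    ``free_params`` maps parameter names (fields of :class:`ModelParams`)
    to finite (low, high) bounds; every other parameter is held at its
    value in ``fixed``.  For each candidate the scenarios present in the
    data (one per culture type x environment, long protocol for weeks >= 1
    and the short protocol for week 0) are re-simulated with the exact
    machinery of the scenarios module, and the objective is the sum of
    squared residuals in biomass (cells) over every observed point.
    Simulation failures contribute a large finite penalty.
    """
    if not free_params:
        raise ValueError("free_params must name at least one parameter to fit")
    if fixed is None:
        fixed = ModelParams()
    if optimizer is None:
        optimizer = DEConfig()
    scenario_kwargs = dict(scenario_kwargs or {})
    names = list(free_params)
    for name in names:
        if not hasattr(fixed, name):
            raise ValueError(f"unknown model parameter: {name!r}")
    bounds = [tuple(map(float, free_params[n])) for n in names]

    sample_interval = scenario_kwargs.get("sample_interval", 0.5)
    obs = _observations(data, sample_interval)
    groups = sorted({(ct, env) for ct, env, _ in obs})
    long_weeks = {
        (ct, env): max(w for c, e, w in obs if (c, e) == (ct, env) and w >= 1)
        for ct, env in groups
        if any(w >= 1 for c, e, w in obs if (c, e) == (ct, env))
    }
    short_groups = {(ct, env) for ct, env, w in obs if w == 0}
    n_failures = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal n_failures
        try:
            params = fixed.with_updates(**dict(zip(names, map(float, theta))))
        except ValueError:
            n_failures += 1
            return _PENALTY
        ssr = 0.0
        try:
            for (ct, env) in groups:
                predicted = {}
                if (ct, env) in long_weeks:
                    scen = Scenario(composition=ct, environment=env,
                                    starvation_weeks=long_weeks[(ct, env)],
                                    **scenario_kwargs)
                    for assay in run_long_starvation(scen, params):
                        predicted[assay.week] = assay.biomass
                if (ct, env) in short_groups:
                    scen = Scenario(composition=ct, environment=env,
                                    freezing=False, starvation_days=4,
                                    initial_od=0.4, **scenario_kwargs)
                    predicted[0] = run_short_starvation(scen, params).biomass
                for (c, e, week), (idx, biomass) in obs.items():
                    if (c, e) == (ct, env):
                        resid = biomass - predicted[week][idx]
                        ssr += float(resid @ resid)
        except Exception:
            n_failures += 1
            return _PENALTY
        return ssr

    x, f, trace, n_eval, converged = differential_evolution(objective, bounds, optimizer)
    if f >= _PENALTY:
        raise RuntimeError("every objective evaluation failed during the fit")
    if n_failures:
        warnings.warn(f"{n_failures} objective evaluation(s) penalised", stacklevel=2)
    free_values = dict(zip(names, map(float, x)))
    return FitResult(
        best_params=fixed.with_updates(**free_values),
        free_values=free_values,
        objective=f,
        n_evaluations=n_eval,
        seed=optimizer.seed,
        converged=converged,
        bounds={n: list(b) for n, b in zip(names, bounds)},
        trace=trace,
    )
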