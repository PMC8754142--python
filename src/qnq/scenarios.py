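"""Experimental protocols composed from model phases.

Two protocols are modelled:

* **Long starvation** — cultures of a given composition (Q monoculture, NQ
  monoculture, or a 3:1 Q:NQ mix) are optionally frozen, then starved for up
  to 6 weeks in sterile water (simple environment) or spent medium (complex
  environment).  Every week a sample is transferred to fresh rich medium and
  its regrowth followed for 24 h at 0.5 h resolution.

* **Short starvation** — freshly fractionated cells that spent only 4 days
  in stationary phase are resuspended in rich medium at OD 0.4 and regrown
  for 24 h.  After such a short starvation NQ cells resume growth *before*
  Q cells, inverting the lag ordering of the long protocol.

Transfer geometry follows the bench protocol: a 275 µl sample of the starved
culture is pelleted, resuspended in 550 µl fresh medium, and 200 µl placed in
a well, i.e. each well receives the cells from 0.1 ml of starved culture.
Since biomass is tracked per 200 µl well-equivalent of culture, the transfer
multiplies viable biomass by 0.5 and replaces the medium (recyclable pool
discarded with the supernatant; fresh resource added).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .curves import od_to_biomass
from .model import (
    COMPLEX,
    REGROWTH,
    SIMPLE,
    STARVATION,
    ModelParams,
    Phase,
    PopulationState,
    Trajectory,
    integrate_phase,
    lag_schedule,
)

__all__ = [
    "Scenario",
    "RegrowthAssay",
    "COMPOSITIONS",
    "TRANSFER_FACTOR",
    "apply_freezing",
    "initialize_culture",
    "sample_and_transfer",
    "run_long_starvation",
    "run_short_starvation",
]

#: Q biomass fraction for each culture composition at equal OD.
COMPOSITIONS = {"Q": 1.0, "NQ": 0.0, "mixed": 0.75}

#: Viable-biomass scaling of the 275 ul -> 550 ul -> 200 ul transfer:
#: cells per well = culture density (cells/ml) x 0.1 ml, i.e. half of the
#: per-200-ul-equivalent starved biomass.
TRANSFER_FACTOR = 0.5

#: Fresh YPD resource per well, in cell-equivalents.  Chosen so the regrowth
#: plateau matches the observed stationary biomass (~3.2e7 cells per well).
DEFAULT_FRESH_RESOURCE = 3.2e7


@dataclass(frozen=True)
class Scenario:
    """One experimental protocol.

    ``starvation_weeks`` applies to the long protocol; ``starvation_days``
    to the short one.  ``residual_nutrient_frac`` seeds the complex
    environment's recyclable pool with a fraction of the fresh-medium
    resource (spent medium retains some amino acids and metabolites).
    """

    composition: str = "mixed"
    environment: str = SIMPLE
    freezing: bool = True
    starvation_weeks: int = 6
    starvation_days: Optional[int] = None
    regrowth_hours: float = 24.0
    sample_interval: float = 0.5
    initial_od: float = 0.8
    fresh_resource: float = DEFAULT_FRESH_RESOURCE
    residual_nutrient_frac: float = 0.02
    freeze_survival_q: float = 0.40
    freeze_survival_nq: float = 0.10
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ValueError(
                f"unknown composition {self.composition!r}; "
                f"expected one of {sorted(COMPOSITIONS)}"
            )
        if self.environment not in (SIMPLE, COMPLEX):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.regrowth_hours <= 0 or self.sample_interval <= 0:
            raise ValueError("regrowth_hours and sample_interval must be > 0")
        if self.fresh_resource <= 0:
            raise ValueError("fresh_resource must be > 0")

    @property
    def is_short(self) -> bool:
        return self.starvation_days is not None


@dataclass(frozen=True)
class RegrowthAssay:
    """One weekly (or short-protocol) regrowth measurement."""

    week: int
    trajectory: Trajectory
    starting_state: PopulationState
    lags: tuple[float, float] = (0.0, 0.0)

    @property
    def times(self) -> np.ndarray:
        return self.trajectory.times

    @property
    def biomass(self) -> np.ndarray:
        return self.trajectory.biomass


def apply_freezing(state: PopulationState, survival_q: float,
                   survival_nq: float) -> PopulationState:
    """Kill a fraction of each subpopulation by freezing stress.

    Q cells tolerate freezing far better than NQ cells (default survivals
    40% vs 10%).  Killed biomass joins the recyclable pool — it can only be
    reused later in the complex environment.
    """
    state.validate()
    for name, frac in (("survival_q", survival_q), ("survival_nq", survival_nq)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    killed = (1.0 - survival_q) * state.q + (1.0 - survival_nq) * state.nq
    return PopulationState(
        q=survival_q * state.q,
        nq=survival_nq * state.nq,
        resource=state.resource,
        recyclable=state.recyclable + killed,
    )


def initialize_culture(scenario: Scenario, params: ModelParams) -> PopulationState:
    """Starting state of a starvation culture.

    Total viable biomass is the OD-equivalent cell count at the scenario's
    initial density, split by composition (mixed = 3:1 Q:NQ by volume at
    equal OD, i.e. 75% Q biomass).  Starvation medium carries no fresh
    resource; the complex environment seeds the recyclable pool with the
    spent medium's residual nutrients.
    """
    total = od_to_biomass(scenario.initial_od)
    q_frac = COMPOSITIONS[scenario.composition]
    recyclable = (
        scenario.residual_nutrient_frac * scenario.fresh_resource
        if scenario.environment == COMPLEX else 0.0
    )
    return PopulationState(
        q=q_frac * total,
        nq=(1.0 - q_frac) * total,
        resource=0.0,
        recyclable=recyclable,
    )


def sample_and_transfer(state: PopulationState, scenario: Scenario,
                        fresh_resource: Optional[float] = None) -> PopulationState:
    """Transfer a starved sample to a fresh-medium well.

    Viable biomass scales by :data:`TRANSFER_FACTOR` (0.1 ml of culture per
    well); the starvation supernatant — and with it the recyclable pool —
    is discarded; the well supplies ``fresh_resource`` cell-equivalents of
    fresh nutrients.
    """
    state.validate()
    if fresh_resource is None:
        fresh_resource = scenario.fresh_resource
    if fresh_resource <= 0:
        raise ValueError(f"fresh_resource must be > 0, got {fresh_resource}")
    return PopulationState(
        q=TRANSFER_FACTOR * state.q,
        nq=TRANSFER_FACTOR * state.nq,
        resource=fresh_resource,
        recyclable=0.0,
    )


def run_long_starvation(scenario: Scenario, params: ModelParams,
                        lag_jitter: tuple[float, float] = (0.0, 0.0),
                        ) -> list[RegrowthAssay]:
    """Simulate the long-starvation protocol with weekly regrowth assays.

    The starvation culture is integrated continuously; at each week
    boundary a non-destructive sample (275 µl of 5 ml, ~5% — ignored) is
    transferred to fresh medium and regrown for ``regrowth_hours`` with
    lags from :func:`lag_schedule` for that week.  ``lag_jitter`` adds a
    per-culture offset to (lag_q, lag_nq), used by the synthetic-data
    generator to emulate replicate variability.

    Returns one :class:`RegrowthAssay` per week 1..starvation_weeks.
    """
    if scenario.starvation_weeks < 1:
        raise ValueError("long protocol needs starvation_weeks >= 1")
    params.validate()
    state = initialize_culture(scenario, params)
    if scenario.freezing:
        state = apply_freezing(state, scenario.freeze_survival_q,
                               scenario.freeze_survival_nq)
    starve_phase = Phase(STARVATION, environment=scenario.environment)
    assays = []
    for week in range(1, scenario.starvation_weeks + 1):
        traj = integrate_phase(state, params, starve_phase, duration=7 * 24.0,
                               output_step=7 * 24.0)
        state = traj.final_state
        plated = sample_and_transfer(state, scenario)
        lag_q, lag_nq = lag_schedule(params, week)
        lags = (max(0.0, lag_q + lag_jitter[0]), max(0.0, lag_nq + lag_jitter[1]))
        regrow_phase = Phase(REGROWTH, environment=scenario.environment,
                             starvation_weeks=week, lags=lags)
        regrowth = integrate_phase(plated, params, regrow_phase,
                                   duration=scenario.regrowth_hours,
                                   output_step=scenario.sample_interval)
        assays.append(RegrowthAssay(week=week, trajectory=regrowth,
                                    starting_state=plated, lags=lags))
    return assays


def run_short_starvation(scenario: Scenario, params: ModelParams,
                         lag_jitter: tuple[float, float] = (0.0, 0.0),
                         ) -> RegrowthAssay:
    """Simulate the short-starvation (4-day stationary phase) regrowth assay.

    Cells are suspended directly in fresh rich medium at the scenario's
    initial density (default OD 0.4) and regrown for 24 h.  Lags come from
    the short-starvation gate parameters, under which NQ cells resume
    growth before Q cells.  No freezing and no starvation mortality are
    applied (cells are used immediately after fractionation).
    """
    params.validate()
    total = od_to_biomass(scenario.initial_od)
    q_frac = COMPOSITIONS[scenario.composition]
    state = PopulationState(
        q=q_frac * total,
        nq=(1.0 - q_frac) * total,
        resource=scenario.fresh_resource,
        recyclable=0.0,
    )
    lags = (max(0.0, params.lag_q_short + lag_jitter[0]),
            max(0.0, params.lag_nq_short + lag_jitter[1]))
    phase = Phase(REGROWTH, environment=scenario.environment, lags=lags)
    traj = integrate_phase(state, params, phase,
                           duration=scenario.regrowth_hours,
                           output_step=scenario.sample_interval)
    return RegrowthAssay(week=0, trajectory=traj, starting_state=state, lags=lags)
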