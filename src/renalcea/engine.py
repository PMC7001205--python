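"""Deterministic Markov cohort engine over duration-expanded (tunnel) states.

Each alive health state is expanded by years-in-state so that costs can
distinguish the initial year on a modality from subsequent years and so that
PD retraining (every 5 years on the modality) can be charged.  A cohort
starting 100% in the chosen first-line modality is propagated through annual
cycles; per-cycle undiscounted costs (state costs plus one-time transition
event costs) and QALYs are accrued along the way.

Within a cycle, competing events are composed in the fixed order
death -> transplant -> modality switch, as multiplicative risks:

    P(death)          = p_d
    P(transplant)     = (1 - p_d) * p_tx          (dialysis origins only)
    P(switch to s)    = (1 - p_d) * (1 - p_tx) * q_s

where q is the origin's annual switching row.  Transplanted patients only
stay (accumulating years post-transplant) or die.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .parameters import ModelConfig, check_valid
from .states import (
    ALIVE_STATES,
    DIALYSIS_STATES,
    HealthState,
    HomeHDMortalityMode,
    Perspective,
    RateConversion,
)


class ExpandedState(NamedTuple):
    """(health state, years in state) tunnel coordinate; DEATH carries no tunnel."""

    health: HealthState
    years_in_state: int


DEATH_STATE = ExpandedState(HealthState.DEATH, 0)


def rate_to_probability(
    rate_per_100py: float,
    convention: RateConversion = RateConversion.EXPONENTIAL,
) -> float:
    """Convert an event rate in cases per 100 person-years to an annual probability.

    EXPONENTIAL assumes a constant hazard over the year (p = 1 - exp(-r/100));
    LINEAR divides directly and caps at 1.
    """
    if rate_per_100py < 0:
        raise ValueError(f"rate must be >= 0, got {rate_per_100py}")
    if convention == RateConversion.EXPONENTIAL:
        return 1.0 - math.exp(-rate_per_100py / 100.0)
    return min(rate_per_100py / 100.0, 1.0)


class StateSpace:
    """Indexed enumeration of expanded states.

    Alive states are tracked to ``depth`` years-in-state.  When the counter
    would exceed the cap it wraps back by one retraining interval, which
    preserves both the initial/subsequent-year distinction (the wrap target
    is always >= 2 for depth > interval) and the 5-year retraining
    periodicity modulo the interval.  With the default depth equal to the
    horizon the wrap never fires.
    """

    def __init__(self, depth: int, retraining_interval: int):
        if depth < 1:
            raise ValueError("tunnel depth must be >= 1")
        self.depth = depth
        self.retraining_interval = retraining_interval
        self.states: list[ExpandedState] = [
            ExpandedState(h, y) for h in ALIVE_STATES for y in range(1, depth + 1)
        ]
        self.states.append(DEATH_STATE)
        self.index: dict[ExpandedState, int] = {s: i for i, s in enumerate(self.states)}
        self.n = len(self.states)
        self.death_index = self.index[DEATH_STATE]

    def next_year(self, years_in_state: int) -> int:
        nxt = years_in_state + 1
        if nxt <= self.depth:
            return nxt
        return max(2, self.depth - self.retraining_interval + 1) if self.depth > 1 else 1

    def entry(self, health: HealthState) -> ExpandedState:
        return ExpandedState(health, 1)

    def __iter__(self) -> Iterator[ExpandedState]:
        return iter(self.states)


def cycle_distribution(
    origin: ExpandedState, config: ModelConfig, space: StateSpace
) -> dict[ExpandedState, float]:
    """One-cycle destination distribution from an expanded state.

    Composes death, transplant and switching in the fixed event order.
    Self-transitions advance the years-in-state counter; any change of
    modality (or transplantation) restarts it at 1.
    """
    h, y = origin
    if h == HealthState.DEATH:
        raise ValueError("DEATH is absorbing; no cycle distribution")
    conv = config.conventions
    p_d = rate_to_probability(config.clinical.mortality_rates[h], conv.rate_conversion)

    dist: dict[ExpandedState, float] = {}
    if h == HealthState.TRANSPLANT:
        dist[ExpandedState(h, space.next_year(y))] = 1.0 - p_d
        dist[DEATH_STATE] = p_d
        return dist

    p_tx = config.clinical.transplant_rate
    dist[DEATH_STATE] = p_d
    if p_tx > 0:
        dist[ExpandedState(HealthState.TRANSPLANT, 1)] = (1.0 - p_d) * p_tx
    row = config.clinical.switch_row(h)
    residual = (1.0 - p_d) * (1.0 - p_tx)
    for dest_h, q in row.probabilities.items():
        if q == 0.0:
            continue
        dest = (
            ExpandedState(h, space.next_year(y))
            if dest_h == h
            else ExpandedState(dest_h, 1)
        )
        dist[dest] = dist.get(dest, 0.0) + residual * q

    if (
        h == HealthState.HOME_HD
        and conv.home_hd_mortality_mode == HomeHDMortalityMode.ZERO_ROUTED_VIA_HOSP
    ):
        # deteriorating home-HD patients are admitted and switched to
        # hospital HD before death: divert the death mass there
        mass = dist.pop(DEATH_STATE, 0.0)
        if mass:
            hosp = ExpandedState(HealthState.HOSP_HD, 1)
            dist[hosp] = dist.get(hosp, 0.0) + mass
    return dist


def transition_event_cost(
    origin: ExpandedState, destination: ExpandedState, config: ModelConfig
) -> float:
    """One-time cost charged on a specific transition.

    Accrual rules: access surgery for the new modality plus its training when
    a patient initiates a different dialysis modality; removal of the old
    access when leaving a modality for another dialysis or for
    transplantation -- except that hospital and home HD share the same
    vascular access, so switches between them charge training only; nothing
    is removed on death; the transplant operation is charged on entering the
    transplant state; PD retraining is charged on every PD self-transition
    completing a retraining interval.
    """
    if not config.conventions.include_event_costs:
        return 0.0
    ev = config.events
    h, y = origin
    h2, _ = destination

    if h2 == HealthState.DEATH:
        return 0.0
    if h == h2:
        if (
            h == HealthState.PD
            and ev.pd_retraining_interval >= 1
            and y % ev.pd_retraining_interval == 0
        ):
            return ev.pd_retraining
        return 0.0
    if h2 == HealthState.TRANSPLANT:
        return ev.access_surgery(h) + ev.transplant_operation
    # dialysis -> different dialysis
    hd_pair = {HealthState.HOSP_HD, HealthState.HOME_HD}
    if h in hd_pair and h2 in hd_pair:
        return ev.training[h2]  # same vascular access retained
    return ev.access_surgery(h) + ev.access_surgery(h2) + ev.training[h2]


def entry_event_cost(strategy: HealthState, config: ModelConfig) -> float:
    """Access surgery plus training charged when the cohort enters its
    first-line modality at model start."""
    conv = config.conventions
    if not (conv.include_event_costs and conv.include_entry_events):
        return 0.0
    return config.events.access_surgery(strategy) + config.events.training[strategy]


def state_annual_cost(
    state: ExpandedState, config: ModelConfig, perspective: Perspective | None = None
) -> float:
    """Annual cost of occupying an expanded state for one cycle."""
    h, y = state
    if h == HealthState.DEATH:
        return 0.0
    if h == HealthState.TRANSPLANT:
        ev = config.events
        return ev.posttx_followup_initial if y == 1 else ev.posttx_followup_subsequent
    profile = config.cost_profile(h, perspective)
    return (
        profile.annual_cost_initial_year
        if y == 1
        else profile.annual_cost_subsequent_year
    )


@dataclass
class TransitionModel:
    """Dense per-cycle transition matrix and event costs over a state space.

    ``event_flow_cost[i]`` pre-aggregates sum_j P[i, j] * event_cost(i, j):
    the expected one-time cost incurred by a patient leaving state i, which
    is all the cohort propagation needs.  The full ``event_costs`` matrix is
    retained for the patient-level simulator.
    """

    space: StateSpace
    matrix: np.ndarray  # (n, n) row-stochastic
    event_costs: np.ndarray  # (n, n) money per transition
    event_flow_cost: np.ndarray  # (n,)


def build_transition_model(config: ModelConfig, *, validated: bool = False) -> TransitionModel:
    """Assemble the expanded transition matrix and event-cost structure.

    The model is shared by all three strategies (only the starting state
    differs) and by the cohort and patient-level engines.
    """
    if not validated:
        check_valid(config)
    conv = config.conventions
    space = StateSpace(conv.effective_tunnel_depth(), config.events.pd_retraining_interval)
    n = space.n
    P = np.zeros((n, n))
    EC = np.zeros((n, n))
    for i, origin in enumerate(space.states):
        if origin == DEATH_STATE:
            P[i, i] = 1.0
            continue
        for dest, p in cycle_distribution(origin, config, space).items():
            j = space.index[dest]
            P[i, j] += p
            EC[i, j] = transition_event_cost(origin, dest, config)
    return TransitionModel(
        space=space, matrix=P, event_costs=EC, event_flow_cost=(P * EC).sum(axis=1)
    )


def state_cost_vector(
    space: StateSpace, config: ModelConfig, perspective: Perspective | None = None
) -> np.ndarray:
    return np.array([state_annual_cost(s, config, perspective) for s in space.states])


def utility_vector(space: StateSpace, config: ModelConfig) -> np.ndarray:
    return np.array([config.utilities.utility(s.health) for s in space.states])


@dataclass
class CohortTrace:
    """Per-cycle occupancy and undiscounted accruals for one strategy.

    ``occupancy[t]`` is the distribution at the beginning of cycle t
    (cycle 0 starts 100% in the strategy's initial modality, year 1).
    ``cycle_costs[t]`` holds the state costs of cycle t plus the event costs
    of the transitions that led into cycle t (entry events for t = 0).
    """

    strategy: HealthState
    perspective: Perspective
    space: StateSpace
    occupancy: np.ndarray  # (horizon, n)
    cycle_costs: np.ndarray  # (horizon,)
    cycle_qalys: np.ndarray  # (horizon,)

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready table: cycle, per-health-state occupancy, cost, QALY."""
        agg = {}
        for h in list(ALIVE_STATES) + [HealthState.DEATH]:
            cols = [i for i, s in enumerate(self.space.states) if s.health == h]
            agg[h.value] = self.occupancy[:, cols].sum(axis=1)
        df = pd.DataFrame(agg)
        df.insert(0, "cycle", np.arange(len(df)))
        df["cycle_cost"] = self.cycle_costs
        df["cycle_qalys"] = self.cycle_qalys
        return df


def run_cohort(
    strategy: HealthState,
    config: ModelConfig,
    perspective: Perspective | None = None,
    model: TransitionModel | None = None,
) -> CohortTrace:
    """Propagate the cohort for ``horizon_years`` annual cycles.

    With half-cycle correction enabled, state-cost and QALY accruals of the
    first and last cycle are half-weighted (trapezoidal membership);
    transition event costs are charged in full either way.
    """
    strategy = HealthState(strategy)
    if strategy not in DIALYSIS_STATES:
        raise ValueError(f"strategy must be a dialysis modality, got {strategy.value}")
    if model is None:
        model = build_transition_model(config)
    perspective = Perspective(perspective) if perspective else config.perspective
    space = model.space
    T = config.conventions.horizon_years

    c = state_cost_vector(space, config, perspective)
    u = utility_vector(space, config)
    weights = np.ones(T)
    if config.conventions.half_cycle_correction and T > 1:
        weights[0] = weights[-1] = 0.5

    occupancy = np.zeros((T, space.n))
    cycle_costs = np.zeros(T)
    cycle_qalys = np.zeros(T)
    occ = np.zeros(space.n)
    occ[space.index[space.entry(strategy)]] = 1.0
    occupancy[0] = occ
    cycle_costs[0] = entry_event_cost(strategy, config) + weights[0] * float(occ @ c)
    cycle_qalys[0] = weights[0] * float(occ @ u)
    for t in range(1, T):
        event_cost = float(occ @ model.event_flow_cost)
        occ = occ @ model.matrix
        occupancy[t] = occ
        cycle_costs[t] = event_cost + weights[t] * float(occ @ c)
        cycle_qalys[t] = weights[t] * float(occ @ u)
    return CohortTrace(
        strategy=strategy,
        perspective=perspective,
        space=space,
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )
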