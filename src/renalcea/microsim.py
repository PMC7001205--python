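"""Patient-level Monte-Carlo simulator: an independent oracle for the cohort engine.

Individual trajectories are sampled from exactly the same
:class:`~renalcea.engine.TransitionModel` (per-cycle distributions and
event costs) that the cohort engine propagates in expectation, so any
disagreement beyond Monte-Carlo error isolates a propagation bug rather
than a parameterization difference.  Accrual timing mirrors the cohort
convention: state cost and utility of the state occupied in cycle t are
discounted at t, and the event cost of the transition taken at the end of
cycle t is discounted at t+1 (entry events at t = 0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    TransitionModel,
    build_transition_model,
    entry_event_cost,
    state_cost_vector,
    utility_vector,
)
from .parameters import ModelConfig
from .states import DIALYSIS_STATES, HealthState, Perspective


@dataclass
class MicrosimSummary:
    """Monte-Carlo means with standard errors over simulated patients."""

    strategy: HealthState
    n: int
    mean_cost: float  # discounted USD per patient
    mean_qalys: float
    se_cost: float
    se_qalys: float
    mean_cost_undiscounted: float
    mean_qalys_undiscounted: float


def simulate_patients(
    strategy: HealthState,
    config: ModelConfig,
    n: int,
    seed: int,
    perspective: Perspective | None = None,
    model: TransitionModel | None = None,
) -> MicrosimSummary:
    """Simulate ``n`` independent patient trajectories for one strategy.

    Vectorized over patients: each cycle groups patients by expanded state
    and samples destinations from that state's categorical distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    strategy = HealthState(strategy)
    if strategy not in DIALYSIS_STATES:
        raise ValueError(f"strategy must be a dialysis modality, got {strategy.value}")
    if model is None:
        model = build_transition_model(config)
    perspective = Perspective(perspective) if perspective else config.perspective
    space = model.space
    conv = config.conventions
    T = conv.horizon_years
    rng = np.random.default_rng(seed)

    c = state_cost_vector(space, config, perspective)
    u = utility_vector(space, config)
    weights = np.ones(T)
    if conv.half_cycle_correction and T > 1:
        weights[0] = weights[-1] = 0.5
    disc = (1.0 + conv.discount_rate) ** -(np.arange(T + 1) + conv.discount_start)

    # per-row cumulative distributions for categorical sampling
    cum = np.cumsum(model.matrix, axis=1)

    state = np.full(n, space.index[space.entry(strategy)], dtype=np.int64)
    cost = np.full(n, entry_event_cost(strategy, config), dtype=float)
    cost_undisc = cost.copy()
    qaly = np.zeros(n)
    qaly_undisc = np.zeros(n)

    for t in range(T):
        w = weights[t]
        cost += disc[t] * w * c[state]
        cost_undisc += w * c[state]
        qaly += disc[t] * w * u[state]
        qaly_undisc += w * u[state]
        if t == T - 1:
            break
        alive = state != space.death_index
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        origins = state[idx]
        draws = rng.random(idx.size)
        new_state = state.copy()
        for s in np.unique(origins):
            members = idx[origins == s]
            dest = np.searchsorted(cum[s], draws[origins == s], side="right")
            dest = np.minimum(dest, space.n - 1)
            new_state[members] = dest
            ec = model.event_costs[s, dest]
            cost[members] += disc[t + 1] * ec
            cost_undisc[members] += ec
        state = new_state

    return MicrosimSummary(
        strategy=strategy,
        n=n,
        mean_cost=float(cost.mean()),
        mean_qalys=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qalys=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_cost_undiscounted=float(cost_undisc.mean()),
        mean_qalys_undiscounted=float(qaly_undisc.mean()),
    )
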