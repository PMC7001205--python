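"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Each draw resamples the uncertain parameters jointly — switch rows from
Dirichlet(observed counts), the home-HD stay probability from its Beta
(complement routed to hospital HD), every disutility and annual cost from
its Gamma — and reruns the cohort model for all three strategies.  Mortality
and transplant rates are registry-based and held fixed.  Acceptability
curves report, per willingness-to-pay threshold, the fraction of draws in
which each strategy attains the highest net monetary benefit
(NMB = threshold × QALYs − cost), ties split equally.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import discount_sum
from .engine import build_transition_model, run_cohort
from .parameters import ModelConfig, check_valid, get_parameter
from .states import DIALYSIS_STATES, HealthState, Perspective

#: Opportunity-cost willingness-to-pay band for the setting (USD/QALY).
WTP_PRIMARY = 18_609.0
WTP_UPPER = 20_223.0


def default_threshold_grid() -> np.ndarray:
    """0 to 60,000 USD/QALY in steps of 500, with the opportunity-cost
    thresholds 18,609 and 20,223 inserted exactly."""
    grid = np.arange(0.0, 60_000.0 + 1, 500.0)
    return np.unique(np.concatenate([grid, [WTP_PRIMARY, WTP_UPPER]]))


def sample_parameters(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """Draw one parameter set from the second-order distributions.

    Returns a new config; the input is never mutated.  Sampled disutilities
    are clipped to [0, 1]; Dirichlet rows are valid by construction.
    Initial- and subsequent-year costs are drawn independently.
    """
    out = config.copy()
    for row in out.clinical.switch_rows:
        if row.origin in out.psa.dirichlet_counts:
            counts = out.psa.dirichlet_counts[row.origin]
            dests = list(counts)
            draw = rng.dirichlet([counts[d] for d in dests])
            row.probabilities = {d: float(p) for d, p in zip(dests, draw)}
            row.counts = None  # probabilities no longer the count ratios
        elif row.origin == HealthState.HOME_HD:
            beta = out.psa.home_hd_stay
            stay = float(rng.beta(beta.alpha, beta.beta))
            row.probabilities = {
                HealthState.HOME_HD: stay,
                HealthState.HOSP_HD: 1.0 - stay,
                HealthState.PD: 0.0,
            }
    for name, spec in out.psa.gammas.items():
        value = float(rng.gamma(spec.shape, spec.scale))
        parts = name.split(".")
        if parts[0] == "disutility":
            out.utilities.disutilities[HealthState(parts[1])] = min(1.0, max(0.0, value))
        elif parts[0] == "cost":
            profile = out.cost_profile(HealthState(parts[3]), Perspective(parts[1]))
            if parts[2] == "initial":
                profile.annual_cost_initial_year = value
            else:
                profile.annual_cost_subsequent_year = value
        else:  # pragma: no cover - guarded by validate()
            raise KeyError(f"unknown PSA parameter {name!r}")
    return out


@dataclass
class PSASample:
    """One parameter draw with its per-strategy discounted outcomes."""

    draw: int
    costs: dict[HealthState, float]
    qalys: dict[HealthState, float]


def run_psa(
    config: ModelConfig,
    n_draws: int,
    seed: int,
    perspective: Perspective | None = None,
) -> pd.DataFrame:
    """Monte-Carlo over parameter uncertainty: ``n_draws`` model evaluations.

    Returns a tidy frame (draw, strategy, cost, qalys) reproducible under
    ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    check_valid(config)
    perspective = Perspective(perspective) if perspective else config.perspective
    rng = np.random.default_rng(seed)
    rate = config.conventions.discount_rate
    start = config.conventions.discount_start
    records = []
    for draw in range(n_draws):
        sampled = sample_parameters(config, rng)
        model = build_transition_model(sampled, validated=True)
        for strategy in DIALYSIS_STATES:
            trace = run_cohort(strategy, sampled, perspective, model=model)
            records.append(
                {
                    "draw": draw,
                    "strategy": strategy.value,
                    "cost": discount_sum(trace.cycle_costs, rate, start=start),
                    "qalys": discount_sum(trace.cycle_qalys, rate, start=start),
                }
            )
    return pd.DataFrame.from_records(records)


def _outcome_matrices(samples: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    wide_c = samples.pivot(index="draw", columns="strategy", values="cost")
    wide_q = samples.pivot(index="draw", columns="strategy", values="qalys")
    strategies = list(wide_c.columns)
    return strategies, wide_c.to_numpy(), wide_q.to_numpy()


def optimal_probabilities(samples: pd.DataFrame, wtp: float) -> dict[str, float]:
    """Fraction of draws in which each strategy has the greatest net monetary
    benefit at one threshold; ties split equally."""
    strategies, costs, qalys = _outcome_matrices(samples)
    nmb = wtp * qalys - costs
    best = nmb.max(axis=1, keepdims=True)
    winners = nmb >= best - 1e-9
    weights = winners / winners.sum(axis=1, keepdims=True)
    probs = weights.mean(axis=0)
    return dict(zip(strategies, probs.tolist()))


def ceac(samples: pd.DataFrame, thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a threshold grid.

    Tidy output: (threshold, strategy, probability); probabilities sum to 1
    at each threshold.
    """
    if samples.empty:
        raise ValueError("no PSA samples")
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any():
        raise ValueError("thresholds must be >= 0")
    strategies, costs, qalys = _outcome_matrices(samples)
    records = []
    for wtp in thresholds:
        nmb = wtp * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9
        probs = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
        records.extend(
            {"threshold": wtp, "strategy": s, "probability": float(p)}
            for s, p in zip(strategies, probs)
        )
    return pd.DataFrame.from_records(records)


def crossover_threshold(
    curve: pd.DataFrame,
    a: HealthState = HealthState.PD,
    b: HealthState = HealthState.HOME_HD,
) -> float | None:
    """Smallest grid threshold at which strategy ``b`` overtakes ``a`` on the
    acceptability curve, or None if it never does."""
    pa = curve[curve.strategy == a.value].set_index("threshold").probability
    pb = curve[curve.strategy == b.value].set_index("threshold").probability
    ahead = pb > pa
    return float(ahead.index[ahead.argmax()]) if ahead.any() else None


def incremental_scatter(
    samples: pd.DataFrame,
    comparator: HealthState = HealthState.HOME_HD,
    reference: HealthState = HealthState.PD,
) -> pd.DataFrame:
    """Per-draw incremental cost/QALY cloud (cost-effectiveness plane)."""
    strategies, costs, qalys = _outcome_matrices(samples)
    i, j = strategies.index(comparator.value), strategies.index(reference.value)
    return pd.DataFrame(
        {
            "draw": np.arange(costs.shape[0]),
            "incremental_cost": costs[:, i] - costs[:, j],
            "incremental_qalys": qalys[:, i] - qalys[:, j],
        }
    )
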