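"""Discounting, lifetime aggregation, incremental analysis and dominance.

Lifetime totals are per patient; the published cohort of 100,000 is a
presentation scale only.  Incremental comparisons are pairwise against the
reference first-line strategy (PD by default), not an efficiency frontier.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import CohortTrace, build_transition_model, run_cohort
from .parameters import ModelConfig
from .states import DIALYSIS_STATES, HealthState, Perspective


def discount_sum(series: Sequence[float], rate: float, *, start: int = 0) -> float:
    """Present value of an annual series: sum_t series[t] / (1+rate)^(t+start).

    The default ``start=0`` leaves the first cycle undiscounted (discounting
    applied to annual totals before aggregation); ``start=1`` discounts from
    the first cycle onward.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    arr = np.asarray(series, dtype=float)
    t = np.arange(len(arr)) + start
    return float((arr / (1.0 + rate) ** t).sum())


class DominanceLabel(str, Enum):
    REFERENCE = "REFERENCE"
    ICER = "ICER"
    DOMINATED = "DOMINATED"  # more costly and less effective than reference
    DOMINANT = "DOMINANT"  # less costly and more effective (cost-saving)
    EQUIVALENT = "EQUIVALENT"


class ThresholdClass(str, Enum):
    COST_SAVING = "COST_SAVING"
    COST_EFFECTIVE = "COST_EFFECTIVE"
    NOT_COST_EFFECTIVE = "NOT_COST_EFFECTIVE"


@dataclass
class StrategyResult:
    strategy: HealthState
    cost: float  # discounted lifetime cost, USD
    qalys: float  # discounted lifetime QALYs
    incremental_cost: float | None = None  # vs reference
    incremental_qalys: float | None = None
    icer: float | None = None  # USD per QALY gained; only when incr. QALYs > 0
    label: DominanceLabel = DominanceLabel.ICER


@dataclass
class CEAResult:
    perspective: Perspective
    reference: HealthState
    strategies: dict[HealthState, StrategyResult]

    def __getitem__(self, strategy: HealthState) -> StrategyResult:
        return self.strategies[HealthState(strategy)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, r in self.strategies.items():
            rows.append(
                {
                    "perspective": self.perspective.value,
                    "strategy": s.value,
                    "cost_usd": r.cost,
                    "incremental_cost_usd": r.incremental_cost,
                    "qalys": r.qalys,
                    "incremental_qalys": r.incremental_qalys,
                    "icer_usd_per_qaly": r.icer,
                    "label": r.label.value,
                }
            )
        return pd.DataFrame(rows)


def _classify(ic: float, iq: float) -> tuple[float | None, DominanceLabel]:
    if ic == 0 and iq == 0:
        return None, DominanceLabel.EQUIVALENT
    if iq > 0:
        if ic < 0:
            return None, DominanceLabel.DOMINANT
        return ic / iq, DominanceLabel.ICER
    # iq <= 0
    if ic >= 0:
        return None, DominanceLabel.DOMINATED
    return None, DominanceLabel.ICER  # cheaper and less effective: no ratio reported


def summarize(
    traces: Mapping[HealthState, CohortTrace],
    config: ModelConfig,
    reference: HealthState = HealthState.PD,
) -> CEAResult:
    """Discount and aggregate traces; attach pairwise incremental results.

    All traces must share the horizon and perspective.  Strategies more
    costly and less effective than the reference are labelled DOMINATED and
    carry no ICER.
    """
    reference = HealthState(reference)
    if reference not in traces:
        raise ValueError(f"reference strategy {reference.value} has no trace")
    horizons = {len(t.cycle_costs) for t in traces.values()}
    if len(horizons) != 1:
        raise ValueError(f"traces have mismatched horizons: {sorted(horizons)}")
    perspectives = {t.perspective for t in traces.values()}
    if len(perspectives) != 1:
        raise ValueError("traces mix perspectives")

    rate = config.conventions.discount_rate
    start = config.conventions.discount_start
    results: dict[HealthState, StrategyResult] = {}
    for strategy, trace in traces.items():
        results[strategy] = StrategyResult(
            strategy=strategy,
            cost=discount_sum(trace.cycle_costs, rate, start=start),
            qalys=discount_sum(trace.cycle_qalys, rate, start=start),
        )
    ref = results[reference]
    ref.label = DominanceLabel.REFERENCE
    for strategy, r in results.items():
        if strategy == reference:
            continue
        r.incremental_cost = r.cost - ref.cost
        r.incremental_qalys = r.qalys - ref.qalys
        r.icer, r.label = _classify(r.incremental_cost, r.incremental_qalys)
    return CEAResult(
        perspective=perspectives.pop(), reference=reference, strategies=results
    )


def classify_against_threshold(result: StrategyResult, wtp: float) -> ThresholdClass:
    """Judge a strategy against a willingness-to-pay threshold (USD/QALY)."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay threshold must be > 0")
    if result.label == DominanceLabel.DOMINANT:
        return ThresholdClass.COST_SAVING
    if result.icer is not None and result.icer < wtp:
        return ThresholdClass.COST_EFFECTIVE
    return ThresholdClass.NOT_COST_EFFECTIVE


def efficiency_frontier(result: CEAResult) -> list[HealthState]:
    """Auxiliary report: strategies on the cost-effectiveness frontier.

    Sorted by ascending cost; strictly dominated options are removed, then
    extended dominance is applied (ICERs along the frontier must increase).
    The headline comparisons stay pairwise against the reference strategy.
    """
    pts = sorted(result.strategies.values(), key=lambda r: (r.cost, -r.qalys))
    frontier: list[StrategyResult] = []
    for p in pts:
        if frontier and p.qalys <= frontier[-1].qalys:
            continue  # dominated: costs more, gains nothing
        frontier.append(p)
        # extended dominance: keep incremental ratios increasing
        while len(frontier) >= 3:
            a, b, c = frontier[-3:]
            icer_ab = (b.cost - a.cost) / (b.qalys - a.qalys)
            icer_bc = (c.cost - b.cost) / (c.qalys - b.qalys)
            if icer_bc < icer_ab:
                frontier.pop(-2)
            else:
                break
    return [p.strategy for p in frontier]


def run_base_case(
    config: ModelConfig,
    perspective: Perspective | None = None,
    reference: HealthState = HealthState.PD,
) -> CEAResult:
    """Run all three first-line strategies through the cohort engine and
    summarize; the transition model is built once and shared."""
    perspective = Perspective(perspective) if perspective else config.perspective
    model = build_transition_model(config)
    traces = {
        s: run_cohort(s, config, perspective, model=model) for s in DIALYSIS_STATES
    }
    return summarize(traces, config, reference=reference)
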