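"""One-way deterministic sensitivity analysis and tornado ordering.

Each parameter with a published 95% CI — the four state disutilities and the
six annual-cost aggregates of the active perspective — plus the discount
rate is set to each bound in turn while everything else stays at base, and
the full pipeline is re-run.  The outcome is the ICER of home HD versus PD;
incremental cost and QALYs at each bound are carried as secondary columns.

Mortality rates and the transplant rate are registry-derived and excluded
by construction (they carry no range in ``dsa_ranges``).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import run_base_case
from .parameters import ModelConfig, apply_parameter, get_parameter
from .states import HealthState, Perspective


@dataclass
class TornadoEntry:
    """One-way result for a single parameter: ICER at each CI bound."""

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    incr_cost_at_low: float
    incr_cost_at_high: float
    incr_qalys_at_low: float
    incr_qalys_at_high: float

    @property
    def swing(self) -> float:
        """|ICER(high) − ICER(low)|; infinite if either bound loses the ratio."""
        if self.icer_at_low is None or self.icer_at_high is None:
            return float("inf")
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_home_vs_pd(config: ModelConfig, perspective: Perspective):
    result = run_base_case(config, perspective)[HealthState.HOME_HD]
    # tornado outcome: the raw cost/QALY ratio, negative when home HD is
    # cost-saving; undefined only if the QALY gain vanishes
    icer = (
        result.incremental_cost / result.incremental_qalys
        if result.incremental_qalys > 0
        else None
    )
    return icer, result.incremental_cost, result.incremental_qalys


def one_way(
    config: ModelConfig,
    parameter: str,
    low: float,
    high: float,
    perspective: Perspective | None = None,
) -> TornadoEntry:
    """Re-run the pipeline with ``parameter`` at each bound; input unmutated.

    Bounds violating the parameter's own invariants (negative cost,
    disutility outside [0, 1], negative rate) fail before any model run.
    """
    if low > high:
        raise ValueError(f"low bound {low} exceeds high bound {high}")
    get_parameter(config, parameter)  # existence check
    perspective = Perspective(perspective) if perspective else config.perspective
    # apply_parameter validates each bound and deep-copies the config
    cfg_low = apply_parameter(config, parameter, low)
    cfg_high = apply_parameter(config, parameter, high)
    icer_low, ic_low, iq_low = _icer_home_vs_pd(cfg_low, perspective)
    icer_high, ic_high, iq_high = _icer_home_vs_pd(cfg_high, perspective)
    return TornadoEntry(
        parameter=parameter,
        low_value=low,
        high_value=high,
        icer_at_low=icer_low,
        icer_at_high=icer_high,
        incr_cost_at_low=ic_low,
        incr_cost_at_high=ic_high,
        incr_qalys_at_low=iq_low,
        incr_qalys_at_high=iq_high,
    )


def dsa_parameters(config: ModelConfig, perspective: Perspective) -> list[str]:
    """Parameters entering the tornado for a perspective: every ranged
    parameter that is perspective-free or belongs to this perspective."""
    other = (
        Perspective.SOCIETAL
        if perspective == Perspective.PROVIDER
        else Perspective.PROVIDER
    )
    return [p for p in config.dsa_ranges if f".{other.value}." not in p]


def tornado(
    config: ModelConfig,
    perspective: Perspective | None = None,
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, sorted by descending swing."""
    perspective = Perspective(perspective) if perspective else config.perspective
    if parameters is None:
        parameters = dsa_parameters(config, perspective)
    if not parameters:
        raise ValueError("no parameters with sensitivity ranges")
    entries = [
        one_way(config, p, *config.dsa_ranges[p], perspective) for p in parameters
    ]
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Plot-ready tornado table (one row per parameter, widest swing first)."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low_value,
                "high": e.high_value,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "swing": e.swing,
                "incr_cost_low": e.incr_cost_at_low,
                "incr_cost_high": e.incr_cost_at_high,
                "incr_qalys_low": e.incr_qalys_at_low,
                "incr_qalys_high": e.incr_qalys_at_high,
            }
            for e in entries
        ]
    )
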