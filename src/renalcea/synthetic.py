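"""Random and degenerate model configurations for property testing.

``random_config`` draws structurally valid parameter sets far from the
packaged baseline: every invariant (row sums, structural zeros, cost
ordering, moment-matched PSA distributions) holds by construction, so every
engine property can be exercised without the published numbers.
``edge_config`` produces named limit cases whose outcomes are known in
closed form.
"""
from __future__ import annotations

from enum import Enum

import numpy as np

from .parameters import (
    BetaSpec,
    ClinicalParams,
    Conventions,
    EventCostTable,
    GammaSpec,
    ModelConfig,
    PSADistributions,
    StateCostProfile,
    SwitchRow,
    UtilityParams,
    baseline_config,
)
from .states import (
    DIALYSIS_STATES,
    HealthState,
    Perspective,
    RateConversion,
)

_S = HealthState


def _switch_destinations(origin: HealthState) -> list[HealthState]:
    if origin == _S.HOME_HD:
        return [_S.HOME_HD, _S.HOSP_HD]  # HOME_HD -> PD structurally forbidden
    return [d for d in DIALYSIS_STATES]


def random_config(seed: int, scale_hints: dict | None = None) -> ModelConfig:
    """A seed-deterministic, structurally valid random parameterization.

    Mortality rates ~ U(0, 40) per 100 py, transplant rate ~ U(0, 0.2),
    switch rows from random Dirichlets respecting structural zeros,
    disutilities ~ U(0, 0.6), annual costs log-uniform over (1e3, 1e5) with
    initial year >= subsequent year.  PSA Gammas are moment-matched to the
    drawn means exactly (CV 20%); Dirichlet counts are drawn and the row
    probabilities set to counts/total exactly.

    ``scale_hints`` may override ``horizon`` and ``tunnel_depth`` to keep
    property tests fast.
    """
    hints = scale_hints or {}
    rng = np.random.default_rng(seed)

    switch_rows: list[SwitchRow] = []
    dirichlet_counts: dict[HealthState, dict[HealthState, int]] = {}
    for origin in DIALYSIS_STATES:
        dests = _switch_destinations(origin)
        counts = {d: int(rng.integers(1, 200)) for d in dests}
        total = sum(counts.values())
        probs = {d: counts[d] / total for d in dests}
        if origin == _S.HOME_HD:
            probs[_S.PD] = 0.0
        switch_rows.append(SwitchRow(origin=origin, probabilities=probs, counts=counts))
        if origin != _S.HOME_HD:
            dirichlet_counts[origin] = counts

    clinical = ClinicalParams(
        transplant_rate=float(rng.uniform(0, 0.2)),
        mortality_rates={s: float(rng.uniform(0, 40)) for s in (_S.PD, _S.HOSP_HD, _S.HOME_HD, _S.TRANSPLANT)},
        switch_rows=switch_rows,
    )

    def draw_cost_pair() -> tuple[float, float]:
        a, b = np.exp(rng.uniform(np.log(1e3), np.log(1e5), size=2))
        return float(max(a, b)), float(min(a, b))

    costs: list[StateCostProfile] = []
    gammas: dict[str, GammaSpec] = {}
    cv = 0.2  # coefficient of variation for moment-matched Gammas
    shape = 1.0 / cv**2
    for persp in Perspective:
        for state in DIALYSIS_STATES:
            initial, subsequent = draw_cost_pair()
            costs.append(StateCostProfile(state, persp, initial, subsequent))
            gammas[f"cost.{persp.value}.initial.{state.value}"] = GammaSpec(shape, initial / shape)
            gammas[f"cost.{persp.value}.subsequent.{state.value}"] = GammaSpec(shape, subsequent / shape)

    disutilities = {s: float(rng.uniform(0, 0.6)) for s in (_S.PD, _S.HOSP_HD, _S.HOME_HD, _S.TRANSPLANT)}
    disutilities[_S.DEATH] = 1.0
    for state, d in disutilities.items():
        if state != _S.DEATH and d > 0:
            gammas[f"disutility.{state.value}"] = GammaSpec(shape, d / shape)

    events = EventCostTable(
        pd_catheter_insert_remove=float(rng.uniform(0, 5000)),
        hd_catheter_insert_remove=float(rng.uniform(0, 5000)),
        hd_arteriovenostomy=float(rng.uniform(0, 10000)),
        hd_access_mix_ratio=float(rng.uniform(0, 1)),
        transplant_operation=float(rng.uniform(0, 20000)),
        posttx_followup_initial=float(rng.uniform(0, 3000)),
        posttx_followup_subsequent=float(rng.uniform(0, 1500)),
        training={s: float(rng.uniform(0, 15000)) for s in DIALYSIS_STATES},
        pd_retraining=float(rng.uniform(0, 3000)),
        pd_retraining_interval=int(rng.integers(2, 8)),
    )

    home_stay = switch_rows[2].probabilities[_S.HOME_HD]
    ess = 400.0
    psa = PSADistributions(
        dirichlet_counts=dirichlet_counts,
        home_hd_stay=BetaSpec(
            alpha=max(ess * home_stay, 1e-3), beta=max(ess * (1 - home_stay), 1e-3)
        ),
        gammas=gammas,
    )

    dsa_ranges = {name: (0.9 * spec.mean, min(1.1 * spec.mean, 1.0) if name.startswith("disutility") else 1.1 * spec.mean) for name, spec in gammas.items()}
    dsa_ranges["discount_rate"] = (0.0, 0.06)

    conventions = Conventions(
        discount_rate=float(rng.uniform(0, 0.06)),
        horizon_years=int(hints.get("horizon", 45)),
        tunnel_depth=hints.get("tunnel_depth"),
    )
    return ModelConfig(
        clinical=clinical,
        costs=costs,
        events=events,
        utilities=UtilityParams(disutilities=disutilities),
        psa=psa,
        dsa_ranges=dsa_ranges,
        conventions=conventions,
        perspective=Perspective.PROVIDER,
    )


class EdgeCase(str, Enum):
    IMMORTAL = "IMMORTAL"  # zero mortality everywhere
    INSTANT_DEATH = "INSTANT_DEATH"  # annual death probability 1
    NO_SWITCHING = "NO_SWITCHING"  # identity switch rows, no transplantation
    FREE_CARE = "FREE_CARE"  # all state and event costs zero


def edge_config(kind: EdgeCase | str) -> ModelConfig:
    """Named degenerate configurations with closed-form outcomes."""
    kind = EdgeCase(kind)
    config = baseline_config()
    if kind == EdgeCase.IMMORTAL:
        config.clinical.mortality_rates = {
            s: 0.0 for s in config.clinical.mortality_rates
        }
    elif kind == EdgeCase.INSTANT_DEATH:
        # LINEAR conversion turns 100/100 py into probability exactly 1
        config.conventions.rate_conversion = RateConversion.LINEAR
        config.clinical.mortality_rates = {
            s: 100.0 for s in config.clinical.mortality_rates
        }
    elif kind == EdgeCase.NO_SWITCHING:
        config.clinical.transplant_rate = 0.0
        for row in config.clinical.switch_rows:
            row.probabilities = {row.origin: 1.0}
            row.counts = None
        config.psa.dirichlet_counts = {}
    elif kind == EdgeCase.FREE_CARE:
        for profile in config.costs:
            profile.annual_cost_initial_year = 0.0
            profile.annual_cost_subsequent_year = 0.0
        ev = config.events
        ev.pd_catheter_insert_remove = 0.0
        ev.hd_catheter_insert_remove = 0.0
        ev.hd_arteriovenostomy = 0.0
        ev.transplant_operation = 0.0
        ev.posttx_followup_initial = 0.0
        ev.posttx_followup_subsequent = 0.0
        ev.training = {s: 0.0 for s in ev.training}
        ev.pd_retraining = 0.0
        config.psa.gammas = {
            k: v for k, v in config.psa.gammas.items() if k.startswith("disutility")
        }
        config.dsa_ranges = {
            k: v
            for k, v in config.dsa_ranges.items()
            if not k.startswith("cost.")
        }
    return config
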