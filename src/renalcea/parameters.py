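"""Model parameterization: types, validation, serialization and the packaged baseline.

The model is fully specified by a :class:`ModelConfig`: clinical transition
inputs (annual modality-switch rows, transplant rate, modality-specific
mortality rates), annual state costs for two analytic perspectives, one-time
event costs (access surgery, training, retraining, transplantation,
post-transplant follow-up), health-state disutilities, the distributions used
for probabilistic sensitivity analysis, the 95%-CI ranges used for one-way
sensitivity analysis, and the engine conventions (cycle length is fixed at
one year; discounting, horizon, tunnel depth, event ordering are explicit).

All monetary values are 2017 USD.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .states import (
    ALIVE_STATES,
    DIALYSIS_STATES,
    FORBIDDEN_SWITCHES,
    HealthState,
    HomeHDMortalityMode,
    Perspective,
    RateConversion,
)

SCHEMA_VERSION = 1

_PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# component types
# ---------------------------------------------------------------------------


@dataclass
class SwitchRow:
    """One row of the annual modality-switching matrix.

    Probabilities are conditional on surviving the cycle and not receiving a
    transplant.  ``counts`` carry the Dirichlet evidence (observed switch
    counts) backing the row, kept separate from the deterministic
    probabilities so the base case can use the published point estimates
    while the PSA samples from Dirichlet(counts).
    """

    origin: HealthState
    probabilities: dict[HealthState, float]
    counts: dict[HealthState, int] | None = None


@dataclass
class ClinicalParams:
    """Transition inputs: transplant rate, mortality rates, switching rows.

    ``transplant_rate`` is an annual probability applied identically to all
    dialysis states.  ``mortality_rates`` are in cases per 100 person-years
    and depend only on the current treatment modality.
    """

    transplant_rate: float
    mortality_rates: dict[HealthState, float]
    switch_rows: list[SwitchRow]

    def switch_row(self, origin: HealthState) -> SwitchRow:
        for row in self.switch_rows:
            if row.origin == origin:
                return row
        raise KeyError(f"no switch row for origin {origin.value}")


@dataclass
class StateCostProfile:
    """Annual cost of one dialysis state under one perspective, split into
    the initial year on the modality and each subsequent year."""

    state: HealthState
    perspective: Perspective
    annual_cost_initial_year: float
    annual_cost_subsequent_year: float


@dataclass
class EventCostTable:
    """One-time costs accrued on transitions.

    ``hd_access_mix_ratio`` is the fraction of HD access surgeries that are
    catheter insertions (the remainder are arteriovenostomies); the blended
    HD access surgery cost is the mix-weighted average.  PD patients are
    retrained every ``pd_retraining_interval`` years on the modality.
    """

    pd_catheter_insert_remove: float
    hd_catheter_insert_remove: float
    hd_arteriovenostomy: float
    hd_access_mix_ratio: float
    transplant_operation: float
    posttx_followup_initial: float
    posttx_followup_subsequent: float
    training: dict[HealthState, float]
    pd_retraining: float
    pd_retraining_interval: int

    @property
    def hd_access_surgery(self) -> float:
        """Blended HD access-surgery cost (catheter vs AV access mix)."""
        r = self.hd_access_mix_ratio
        return r * self.hd_catheter_insert_remove + (1.0 - r) * self.hd_arteriovenostomy

    def access_surgery(self, state: HealthState) -> float:
        """Insertion (equivalently removal) cost of the access for a modality."""
        if state == HealthState.PD:
            return self.pd_catheter_insert_remove
        if state in (HealthState.HOSP_HD, HealthState.HOME_HD):
            return self.hd_access_surgery
        raise ValueError(f"{state.value} has no dialysis access")


@dataclass
class UtilityParams:
    """Health-state disutilities; utility = 1 - disutility.  DEATH is fixed at 1."""

    disutilities: dict[HealthState, float]

    def utility(self, state: HealthState) -> float:
        if state == HealthState.DEATH:
            return 0.0
        return 1.0 - self.disutilities[state]


@dataclass
class GammaSpec:
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale


@dataclass
class BetaSpec:
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class PSADistributions:
    """Second-order distributions for probabilistic sensitivity analysis.

    Switch rows with observed counts are sampled Dirichlet(counts); the
    home-HD stay probability is Beta (its complement goes to hospital HD);
    every disutility and every annual cost (both perspectives, initial and
    subsequent year) is Gamma(shape, scale).  Mortality and transplant rates
    are registry-based and held fixed.
    """

    dirichlet_counts: dict[HealthState, dict[HealthState, int]]
    home_hd_stay: BetaSpec
    gammas: dict[str, GammaSpec]


@dataclass
class Conventions:
    """Engine conventions: everything about *how* the cohort is propagated.

    One-year cycles are implied throughout.  ``horizon_years`` caps the
    number of cycles; ``tunnel_depth`` caps the tracked years-in-state
    (``None`` tracks up to the horizon).  Events within a cycle are composed
    in the fixed order death -> transplant -> switch.
    """

    rate_conversion: RateConversion = RateConversion.EXPONENTIAL
    home_hd_mortality_mode: HomeHDMortalityMode = HomeHDMortalityMode.TABLE_RATE
    half_cycle_correction: bool = False
    # The published annual cost aggregates come from a bottom-up costing
    # study and already carry procedure and training costs, so charging the
    # one-time event layer on top double-counts; the base case therefore
    # accrues state costs only.  The full event layer (access surgery,
    # training, retraining, transplant operation) stays available behind
    # this flag.
    include_event_costs: bool = False
    include_entry_events: bool = True
    discount_rate: float = 0.03
    #: first exponent of the discount factor: 1 discounts every annual total
    #: including the first year's (end-of-year accounting); 0 leaves the
    #: first cycle undiscounted
    discount_start: int = 1
    horizon_years: int = 45
    tunnel_depth: int | None = None
    start_age: float = 60.0
    cohort_size: int = 100_000

    def effective_tunnel_depth(self) -> int:
        return self.horizon_years if self.tunnel_depth is None else self.tunnel_depth


@dataclass
class ModelConfig:
    """Complete parameterization of one model run."""

    clinical: ClinicalParams
    costs: list[StateCostProfile]
    events: EventCostTable
    utilities: UtilityParams
    psa: PSADistributions
    dsa_ranges: dict[str, tuple[float, float]]
    conventions: Conventions
    perspective: Perspective = Perspective.PROVIDER
    schema_version: int = SCHEMA_VERSION

    def cost_profile(
        self, state: HealthState, perspective: Perspective | None = None
    ) -> StateCostProfile:
        persp = perspective or self.perspective
        for p in self.costs:
            if p.state == state and p.perspective == persp:
                return p
        raise KeyError(f"no {persp.value} cost profile for {state.value}")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# parameter addressing (shared by DSA and the CLI override mechanism)
# ---------------------------------------------------------------------------


def get_parameter(config: ModelConfig, param_id: str) -> float:
    """Read a scalar model parameter by dotted id.

    Supported ids: ``discount_rate``, ``disutility.<STATE>``,
    ``cost.<PERSPECTIVE>.<initial|subsequent>.<STATE>``.
    """
    parts = param_id.split(".")
    if param_id == "discount_rate":
        return config.conventions.discount_rate
    if parts[0] == "disutility" and len(parts) == 2:
        return config.utilities.disutilities[HealthState(parts[1])]
    if parts[0] == "cost" and len(parts) == 4:
        profile = config.cost_profile(HealthState(parts[3]), Perspective(parts[1]))
        if parts[2] == "initial":
            return profile.annual_cost_initial_year
        if parts[2] == "subsequent":
            return profile.annual_cost_subsequent_year
    raise KeyError(f"unknown parameter id {param_id!r}")


def apply_parameter(config: ModelConfig, param_id: str, value: float) -> ModelConfig:
    """Return a deep copy of ``config`` with one scalar parameter replaced.

    If the parameter carries a PSA Gamma, its scale is re-matched to the new
    mean so the config stays self-consistent.
    """
    out = config.copy()
    if param_id in out.psa.gammas and value > 0:
        spec = out.psa.gammas[param_id]
        out.psa.gammas[param_id] = GammaSpec(spec.shape, value / spec.shape)
    if param_id in out.dsa_ranges:
        lo, hi = out.dsa_ranges[param_id]
        out.dsa_ranges[param_id] = (min(lo, value), max(hi, value))
    parts = param_id.split(".")
    if param_id == "discount_rate":
        if value < 0:
            raise ValueError("discount_rate must be >= 0")
        out.conventions.discount_rate = float(value)
        return out
    if parts[0] == "disutility" and len(parts) == 2:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"disutility must lie in [0, 1], got {value}")
        out.utilities.disutilities[HealthState(parts[1])] = float(value)
        return out
    if parts[0] == "cost" and len(parts) == 4:
        if value < 0:
            raise ValueError(f"cost must be >= 0, got {value}")
        profile = out.cost_profile(HealthState(parts[3]), Perspective(parts[1]))
        if parts[2] == "initial":
            profile.annual_cost_initial_year = float(value)
            return out
        if parts[2] == "subsequent":
            profile.annual_cost_subsequent_year = float(value)
            return out
    raise KeyError(f"unknown parameter id {param_id!r}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class Violation:
    """A machine-readable invariant breach: where, which rule, what was seen."""

    path: str
    rule: str
    observed: Any

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.rule} (observed {self.observed!r})"


class ConfigValidationError(ValueError):
    """Raised when a config with invariant violations is used or loaded."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid model configuration:\n"
            + "\n".join(f"  - {v}" for v in violations)
        )


def validate(config: ModelConfig) -> list[Violation]:
    """Check every structural invariant; returns an empty list iff valid.

    Never raises: all violations are collected and reported together.
    """
    v: list[Violation] = []
    cl = config.clinical

    if not 0.0 <= cl.transplant_rate <= 1.0:
        v.append(Violation("clinical.transplant_rate", "in [0, 1]", cl.transplant_rate))
    for state in ALIVE_STATES:
        rate = cl.mortality_rates.get(state)
        if rate is None:
            v.append(Violation(f"clinical.mortality_rates.{state.value}", "present", None))
        elif rate < 0:
            v.append(Violation(f"clinical.mortality_rates.{state.value}", ">= 0", rate))
    if HealthState.DEATH in cl.mortality_rates:
        v.append(
            Violation(
                "clinical.mortality_rates.DEATH",
                "absent (DEATH has no mortality rate)",
                cl.mortality_rates[HealthState.DEATH],
            )
        )

    seen_rows: set[HealthState] = set()
    for i, row in enumerate(cl.switch_rows):
        path = f"clinical.switch_rows[{i}]"
        if row.origin not in DIALYSIS_STATES:
            v.append(Violation(path, "origin is a dialysis state", row.origin))
            continue
        seen_rows.add(row.origin)
        total = sum(row.probabilities.values())
        if abs(total - 1.0) > _PROB_TOL:
            v.append(Violation(path, "probabilities sum to 1", total))
        for dest, p in row.probabilities.items():
            if p < 0:
                v.append(Violation(f"{path}.{dest.value}", ">= 0", p))
            if (row.origin, dest) in FORBIDDEN_SWITCHES and p != 0.0:
                v.append(
                    Violation(
                        f"{path}.{dest.value}",
                        "structurally forbidden transition has probability 0",
                        p,
                    )
                )
            if dest not in DIALYSIS_STATES:
                v.append(Violation(f"{path}.{dest.value}", "destination is dialysis", dest))
        if row.counts is not None:
            total_n = sum(row.counts.values())
            if total_n <= 0:
                v.append(Violation(f"{path}.counts", "positive total count", total_n))
            else:
                for dest, n in row.counts.items():
                    if n < 0:
                        v.append(Violation(f"{path}.counts.{dest.value}", ">= 0", n))
                    # printed probabilities are 3-dp roundings of counts/total
                    p = row.probabilities.get(dest, 0.0)
                    if abs(p - n / total_n) > 5e-4 + _PROB_TOL:
                        v.append(
                            Violation(
                                f"{path}.counts.{dest.value}",
                                "counts/total matches probability to 3 dp",
                                (n, total_n, p),
                            )
                        )
    missing = set(DIALYSIS_STATES) - seen_rows
    for state in sorted(missing, key=lambda s: s.value):
        v.append(Violation("clinical.switch_rows", f"row for {state.value} present", None))

    for persp in Perspective:
        for state in DIALYSIS_STATES:
            try:
                profile = config.cost_profile(state, persp)
            except KeyError:
                v.append(
                    Violation(f"costs[{persp.value}.{state.value}]", "profile present", None)
                )
                continue
            for attr in ("annual_cost_initial_year", "annual_cost_subsequent_year"):
                val = getattr(profile, attr)
                if val < 0:
                    v.append(
                        Violation(f"costs[{persp.value}.{state.value}].{attr}", ">= 0", val)
                    )

    ev = config.events
    for attr in (
        "pd_catheter_insert_remove",
        "hd_catheter_insert_remove",
        "hd_arteriovenostomy",
        "transplant_operation",
        "posttx_followup_initial",
        "posttx_followup_subsequent",
        "pd_retraining",
    ):
        if getattr(ev, attr) < 0:
            v.append(Violation(f"events.{attr}", ">= 0", getattr(ev, attr)))
    if not 0.0 <= ev.hd_access_mix_ratio <= 1.0:
        v.append(Violation("events.hd_access_mix_ratio", "in [0, 1]", ev.hd_access_mix_ratio))
    if ev.pd_retraining_interval < 1:
        v.append(Violation("events.pd_retraining_interval", ">= 1", ev.pd_retraining_interval))
    for state in DIALYSIS_STATES:
        cost = ev.training.get(state)
        if cost is None:
            v.append(Violation(f"events.training.{state.value}", "present", None))
        elif cost < 0:
            v.append(Violation(f"events.training.{state.value}", ">= 0", cost))

    for state in ALIVE_STATES:
        d = config.utilities.disutilities.get(state)
        if d is None:
            v.append(Violation(f"utilities.disutilities.{state.value}", "present", None))
        elif not 0.0 <= d <= 1.0:
            v.append(Violation(f"utilities.disutilities.{state.value}", "in [0, 1]", d))

    for name, spec in config.psa.gammas.items():
        if spec.shape <= 0 or spec.scale <= 0:
            v.append(Violation(f"psa.gammas.{name}", "shape and scale > 0", (spec.shape, spec.scale)))
        try:
            base = get_parameter(config, name)
        except KeyError:
            v.append(Violation(f"psa.gammas.{name}", "refers to an existing parameter", name))
            continue
        if base > 0 and abs(spec.mean - base) > 0.02 * base:
            v.append(
                Violation(
                    f"psa.gammas.{name}",
                    "Gamma mean within 2% of base value",
                    (spec.mean, base),
                )
            )
    for origin, counts in config.psa.dirichlet_counts.items():
        try:
            row = cl.switch_row(origin)
        except KeyError:
            v.append(Violation(f"psa.dirichlet_counts.{origin.value}", "switch row exists", None))
            continue
        if row.counts is not None and counts != row.counts:
            v.append(
                Violation(
                    f"psa.dirichlet_counts.{origin.value}",
                    "matches switch-row counts",
                    (counts, row.counts),
                )
            )
    if config.psa.home_hd_stay.alpha <= 0 or config.psa.home_hd_stay.beta <= 0:
        v.append(
            Violation(
                "psa.home_hd_stay",
                "Beta parameters > 0",
                (config.psa.home_hd_stay.alpha, config.psa.home_hd_stay.beta),
            )
        )

    for name, (lo, hi) in config.dsa_ranges.items():
        if lo > hi:
            v.append(Violation(f"dsa_ranges.{name}", "low <= high", (lo, hi)))
        try:
            base = get_parameter(config, name)
        except KeyError:
            v.append(Violation(f"dsa_ranges.{name}", "refers to an existing parameter", name))
            continue
        if not lo <= base <= hi:
            v.append(
                Violation(f"dsa_ranges.{name}", "base value within [low, high]", (lo, base, hi))
            )

    conv = config.conventions
    if conv.discount_rate < 0:
        v.append(Violation("conventions.discount_rate", ">= 0", conv.discount_rate))
    if conv.discount_start not in (0, 1):
        v.append(Violation("conventions.discount_start", "0 or 1", conv.discount_start))
    if conv.horizon_years < 1:
        v.append(Violation("conventions.horizon_years", ">= 1", conv.horizon_years))
    depth = conv.effective_tunnel_depth()
    if depth < 1:
        v.append(Violation("conventions.tunnel_depth", ">= 1", depth))
    if conv.cohort_size < 1:
        v.append(Violation("conventions.cohort_size", ">= 1", conv.cohort_size))

    return v


def check_valid(config: ModelConfig) -> ModelConfig:
    """Raise :class:`ConfigValidationError` listing all violations, if any."""
    violations = validate(config)
    if violations:
        raise ConfigValidationError(violations)
    return config


# ---------------------------------------------------------------------------
# packaged baseline (2017 USD; Hong Kong public healthcare setting)
# ---------------------------------------------------------------------------

_S = HealthState


def baseline_config(perspective: Perspective = Perspective.PROVIDER) -> ModelConfig:
    """The packaged base-case parameterization.

    Built from code constants on every call (idempotent, independent of any
    file on disk).  ``perspective`` selects the active analytic perspective;
    cost profiles for both perspectives are always present.
    """
    perspective = Perspective(perspective)
    clinical = ClinicalParams(
        transplant_rate=0.0794,
        mortality_rates={
            _S.PD: 15.21,
            _S.HOSP_HD: 19.45,
            _S.HOME_HD: 10.6,
            _S.TRANSPLANT: 2.00,
        },
        switch_rows=[
            SwitchRow(
                origin=_S.PD,
                probabilities={_S.PD: 0.888, _S.HOSP_HD: 0.106, _S.HOME_HD: 0.006},
                counts={_S.PD: 159, _S.HOSP_HD: 19, _S.HOME_HD: 1},
            ),
            SwitchRow(
                origin=_S.HOSP_HD,
                probabilities={_S.HOSP_HD: 0.784, _S.PD: 0.156, _S.HOME_HD: 0.060},
                counts={_S.HOSP_HD: 131, _S.PD: 26, _S.HOME_HD: 10},
            ),
            SwitchRow(
                origin=_S.HOME_HD,
                probabilities={_S.HOME_HD: 0.950, _S.HOSP_HD: 0.050, _S.PD: 0.0},
            ),
        ],
    )
    costs = [
        StateCostProfile(_S.PD, Perspective.PROVIDER, 15188.1, 10358.5),
        StateCostProfile(_S.HOSP_HD, Perspective.PROVIDER, 51289.4, 46272.2),
        StateCostProfile(_S.HOME_HD, Perspective.PROVIDER, 28635.7, 11157.4),
        StateCostProfile(_S.PD, Perspective.SOCIETAL, 24255.3, 19425.6),
        StateCostProfile(_S.HOSP_HD, Perspective.SOCIETAL, 57968.0, 52950.9),
        StateCostProfile(_S.HOME_HD, Perspective.SOCIETAL, 31030.6, 13552.3),
    ]
    events = EventCostTable(
        pd_catheter_insert_remove=3192.3,
        hd_catheter_insert_remove=2057.7,
        hd_arteriovenostomy=6384.6,
        hd_access_mix_ratio=0.3,
        transplant_operation=10278.8,
        posttx_followup_initial=1678.2,
        posttx_followup_subsequent=610.3,
        training={_S.PD: 1692.3, _S.HOSP_HD: 0.0, _S.HOME_HD: 12184.6},
        pd_retraining=1692.3,
        pd_retraining_interval=5,
    )
    utilities = UtilityParams(
        disutilities={
            _S.PD: 0.222,
            _S.HOSP_HD: 0.269,
            _S.HOME_HD: 0.222,
            _S.TRANSPLANT: 0.190,
            _S.DEATH: 1.0,
        }
    )
    # Beta for home-HD stay: mean 0.950 with an effective sample size of 412
    # (reconstructed parameterization; see docs/methods.md).
    psa = PSADistributions(
        dirichlet_counts={
            _S.PD: {_S.PD: 159, _S.HOSP_HD: 19, _S.HOME_HD: 1},
            _S.HOSP_HD: {_S.HOSP_HD: 131, _S.PD: 26, _S.HOME_HD: 10},
        },
        home_hd_stay=BetaSpec(alpha=412 * 0.950, beta=412 * 0.050),
        gammas={
            "disutility.PD": GammaSpec(4.06, 0.055),
            "disutility.HOSP_HD": GammaSpec(5.58, 0.048),
            "disutility.HOME_HD": GammaSpec(5.94, 0.037),
            "disutility.TRANSPLANT": GammaSpec(17.12, 0.011),
            "cost.SOCIETAL.initial.PD": GammaSpec(9.4, 2582.7),
            "cost.SOCIETAL.initial.HOSP_HD": GammaSpec(38.0, 1524.6),
            "cost.SOCIETAL.initial.HOME_HD": GammaSpec(73.2, 423.7),
            "cost.SOCIETAL.subsequent.PD": GammaSpec(6.3, 3082.0),
            "cost.SOCIETAL.subsequent.HOSP_HD": GammaSpec(31.6, 1677.0),
            "cost.SOCIETAL.subsequent.HOME_HD": GammaSpec(19.6, 690.0),
            "cost.PROVIDER.initial.PD": GammaSpec(58.0, 262.0),
            "cost.PROVIDER.initial.HOSP_HD": GammaSpec(40.6, 1264.7),
            "cost.PROVIDER.initial.HOME_HD": GammaSpec(153.0, 187.1),
            "cost.PROVIDER.subsequent.PD": GammaSpec(26.1, 397.1),
            "cost.PROVIDER.subsequent.HOSP_HD": GammaSpec(32.8, 1410.5),
            "cost.PROVIDER.subsequent.HOME_HD": GammaSpec(92.3, 120.9),
        },
    )
    dsa_ranges: dict[str, tuple[float, float]] = {
        "disutility.PD": (0.200, 0.243),
        "disutility.HOSP_HD": (0.249, 0.288),
        "disutility.HOME_HD": (0.194, 0.250),
        "disutility.TRANSPLANT": (0.100, 0.280),
        "cost.SOCIETAL.initial.PD": (23658.7, 24851.9),
        "cost.SOCIETAL.initial.HOSP_HD": (57240.6, 58695.5),
        "cost.SOCIETAL.initial.HOME_HD": (30477.6, 31583.5),
        "cost.SOCIETAL.subsequent.PD": (18842.4, 20008.9),
        "cost.SOCIETAL.subsequent.HOSP_HD": (52221.7, 53680.1),
        "cost.SOCIETAL.subsequent.HOME_HD": (13085.9, 14018.6),
        "cost.PROVIDER.initial.PD": (15037.8, 15338.5),
        "cost.PROVIDER.initial.HOSP_HD": (50666.1, 51912.6),
        "cost.PROVIDER.initial.HOME_HD": (28282.7, 28988.7),
        "cost.PROVIDER.subsequent.PD": (10205.6, 10511.4),
        "cost.PROVIDER.subsequent.HOSP_HD": (45647.1, 46897.4),
        "cost.PROVIDER.subsequent.HOME_HD": (10980.3, 11334.5),
        # conventional 0-5% span; no published interval for the discount rate
        "discount_rate": (0.0, 0.05),
    }
    return ModelConfig(
        clinical=clinical,
        costs=costs,
        events=events,
        utilities=utilities,
        psa=psa,
        dsa_ranges=dsa_ranges,
        conventions=Conventions(),
        perspective=perspective,
    )


# ---------------------------------------------------------------------------
# serialization (YAML mapping, versioned schema)
# ---------------------------------------------------------------------------


def _plain(obj: Any) -> Any:
    """Recursively replace enum members (as keys or values) by their value."""
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(x) for x in obj]
    return obj


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-scalar nested mapping; enum keys/values become their string names."""
    d = _plain(asdict(config))
    d["dsa_ranges"] = {k: list(v) for k, v in d["dsa_ranges"].items()}
    return d


class ConfigSchemaError(ValueError):
    """A config document that does not conform to the published schema."""


def _require(d: Mapping, key: str, where: str) -> Any:
    if key not in d:
        raise ConfigSchemaError(f"missing required field {where}.{key}")
    return d[key]


def config_from_dict(d: Mapping) -> ModelConfig:
    try:
        version = _require(d, "schema_version", "$")
        if version != SCHEMA_VERSION:
            raise ConfigSchemaError(f"unsupported schema_version {version!r}")
        cl = _require(d, "clinical", "$")
        rows = [
            SwitchRow(
                origin=HealthState(_require(r, "origin", "switch_rows[]")),
                probabilities={
                    HealthState(k): float(v)
                    for k, v in _require(r, "probabilities", "switch_rows[]").items()
                },
                counts=None
                if r.get("counts") is None
                else {HealthState(k): int(v) for k, v in r["counts"].items()},
            )
            for r in _require(cl, "switch_rows", "clinical")
        ]
        clinical = ClinicalParams(
            transplant_rate=float(_require(cl, "transplant_rate", "clinical")),
            mortality_rates={
                HealthState(k): float(v)
                for k, v in _require(cl, "mortality_rates", "clinical").items()
            },
            switch_rows=rows,
        )
        costs = [
            StateCostProfile(
                state=HealthState(_require(p, "state", "costs[]")),
                perspective=Perspective(_require(p, "perspective", "costs[]")),
                annual_cost_initial_year=float(p["annual_cost_initial_year"]),
                annual_cost_subsequent_year=float(p["annual_cost_subsequent_year"]),
            )
            for p in _require(d, "costs", "$")
        ]
        ev = _require(d, "events", "$")
        events = EventCostTable(
            pd_catheter_insert_remove=float(ev["pd_catheter_insert_remove"]),
            hd_catheter_insert_remove=float(ev["hd_catheter_insert_remove"]),
            hd_arteriovenostomy=float(ev["hd_arteriovenostomy"]),
            hd_access_mix_ratio=float(ev["hd_access_mix_ratio"]),
            transplant_operation=float(ev["transplant_operation"]),
            posttx_followup_initial=float(ev["posttx_followup_initial"]),
            posttx_followup_subsequent=float(ev["posttx_followup_subsequent"]),
            training={HealthState(k): float(v) for k, v in ev["training"].items()},
            pd_retraining=float(ev["pd_retraining"]),
            pd_retraining_interval=int(ev["pd_retraining_interval"]),
        )
        utilities = UtilityParams(
            disutilities={
                HealthState(k): float(v)
                for k, v in _require(d, "utilities", "$")["disutilities"].items()
            }
        )
        ps = _require(d, "psa", "$")
        psa = PSADistributions(
            dirichlet_counts={
                HealthState(k): {HealthState(kk): int(vv) for kk, vv in v.items()}
                for k, v in ps["dirichlet_counts"].items()
            },
            home_hd_stay=BetaSpec(**ps["home_hd_stay"]),
            gammas={k: GammaSpec(**v) for k, v in ps["gammas"].items()},
        )
        cv = _require(d, "conventions", "$")
        conventions = Conventions(
            rate_conversion=RateConversion(cv["rate_conversion"]),
            home_hd_mortality_mode=HomeHDMortalityMode(cv["home_hd_mortality_mode"]),
            half_cycle_correction=bool(cv["half_cycle_correction"]),
            include_event_costs=bool(cv["include_event_costs"]),
            include_entry_events=bool(cv["include_entry_events"]),
            discount_rate=float(cv["discount_rate"]),
            discount_start=int(cv["discount_start"]),
            horizon_years=int(cv["horizon_years"]),
            tunnel_depth=None if cv.get("tunnel_depth") is None else int(cv["tunnel_depth"]),
            start_age=float(cv["start_age"]),
            cohort_size=int(cv["cohort_size"]),
        )
        config = ModelConfig(
            clinical=clinical,
            costs=costs,
            events=events,
            utilities=utilities,
            psa=psa,
            dsa_ranges={k: (float(v[0]), float(v[1])) for k, v in d["dsa_ranges"].items()},
            conventions=conventions,
            perspective=Perspective(_require(d, "perspective", "$")),
        )
    except ConfigSchemaError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigSchemaError(f"malformed config document: {exc}") from exc
    return config


def save_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    """Load, schema-check and invariant-check a config document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping):
        raise ConfigSchemaError("config document is not a mapping")
    return check_valid(config_from_dict(doc))


# ---------------------------------------------------------------------------
# flattened parameter table
# ---------------------------------------------------------------------------


def parameter_table(config: ModelConfig) -> pd.DataFrame:
    """Flattened parameter table: mean, SD, CI bounds, distribution, shape/scale.

    SDs for Gamma-distributed parameters are derived from (shape, scale).
    """
    rows: list[dict[str, Any]] = []
    rows.append(
        {"parameter": "transplant_rate", "mean": config.clinical.transplant_rate,
         "distribution": "fixed"}
    )
    for state, rate in config.clinical.mortality_rates.items():
        rows.append(
            {"parameter": f"mortality_rate.{state.value}", "mean": rate,
             "distribution": "fixed", "units": "per 100 person-years"}
        )
    for row in config.clinical.switch_rows:
        dist = "Dirichlet" if row.counts else (
            "Beta" if row.origin == HealthState.HOME_HD else "fixed"
        )
        for dest, p in row.probabilities.items():
            rows.append(
                {"parameter": f"switch.{row.origin.value}.{dest.value}", "mean": p,
                 "distribution": dist}
            )
    for name, spec in config.psa.gammas.items():
        lo, hi = config.dsa_ranges.get(name, (None, None))
        rows.append(
            {"parameter": name, "mean": get_parameter(config, name), "sd": spec.sd,
             "ci_low": lo, "ci_high": hi, "distribution": "Gamma",
             "shape": spec.shape, "scale": spec.scale}
        )
    return pd.DataFrame(rows)
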