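"""Markov cohort model for lifetime cost-effectiveness of RA therapies.

The model follows an initial-therapy → palliative-care pathway over a
27-year horizon (ages 51–78) in 6-month cycles.  The cohort starts on the
assigned drug; at the end of the first cycle it splits by the best ACR
response category achieved at month 6.  Responders stay on the drug at the
HAQ level implied by their response (each category carries a HAQ improvement
from the arm's baseline HAQ), facing a per-cycle withdrawal risk that moves
them to palliative care; nonresponders switch to palliative care directly.
On palliative care HAQ progresses at a constant annual rate.  Death is
absorbing and acts on every alive state through an age-indexed (by default
flat) per-cycle probability.

Per-cycle accrual: QALYs = occupancy × utility(HAQ) × cycle length; costs by
category (medication, HAQ-dependent state costs, direct nonmedical,
indirect).  Both streams are discounted at an annual rate with cycle 0
undiscounted.  Utility maps linearly from HAQ (u = a − b·HAQ, clamped), the
common parameterisation in RA decision models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "UtilityMap",
    "ArmConfig",
    "ModelConfig",
    "CohortTrace",
    "ArmResult",
    "Incremental",
    "CEAResult",
    "haq_to_utility",
    "build_states",
    "iterate_occupancy",
    "run_cohort",
    "icer",
    "run_cea",
]

STATES = ("initial", "acr70", "acr50", "acr20", "palliative", "death")
RESPONDER_STATES = ("acr70", "acr50", "acr20")
COST_CATEGORIES = ("medication", "state", "nonmedical", "indirect")


@dataclass(frozen=True)
class UtilityMap:
    """Linear HAQ→utility mapping u = intercept − slope·HAQ, clamped."""

    intercept: float = 0.862
    slope: float = 0.327
    floor: float = -0.3

    def __call__(self, haq: float) -> float:
        return haq_to_utility(haq, self)


def haq_to_utility(haq: float, coeffs: UtilityMap) -> float:
    """Utility at a given HAQ disability level.

    HAQ must lie in [0, 3]; the result is clamped to [floor, 1].
    """
    if not (0.0 <= haq <= 3.0):
        raise DomainError(f"haq out of [0, 3]: {haq}")
    return float(min(1.0, max(coeffs.floor, coeffs.intercept - coeffs.slope * haq)))


@dataclass
class ArmConfig:
    """All per-arm model inputs (costs in the configured currency per cycle)."""

    name: str
    drug_cost_per_cycle: float
    #: exclusive probabilities of the best month-6 ACR category
    response: Dict[str, float]
    #: HAQ improvement from baseline while responding, by category
    delta_haq: Dict[str, float]
    baseline_haq: float
    #: annual HAQ progression while on palliative care
    haq_progression_per_year: float
    #: per-cycle probability that a responder stops the drug
    withdrawal_per_cycle: float
    palliative_drug_cost_per_cycle: float
    #: state (non-drug medical) cost per cycle: base + per_haq × HAQ
    state_cost_base_per_cycle: float
    state_cost_per_haq_per_cycle: float
    utility: UtilityMap = field(default_factory=UtilityMap)
    nonmedical_cost_per_cycle: float = 0.0
    indirect_cost_per_cycle: float = 0.0
    #: QALY decrement per on-treatment cycle from severe adverse events
    sae_disutility_per_cycle: float = 0.0
    #: observed responder-category counts (for PSA Dirichlet sampling)
    response_counts: Optional[Dict[str, float]] = None

    def validate(self) -> None:
        for cat in ("ACR70", "ACR50", "ACR20", "NONE"):
            p = self.response.get(cat)
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"arm {self.name}: response[{cat}] missing or out of [0, 1]"
                )
        total = sum(self.response.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"arm {self.name}: response probabilities sum to {total!r}, not 1"
            )
        if not (0.0 <= self.withdrawal_per_cycle <= 1.0):
            raise ConfigurationError(f"arm {self.name}: withdrawal out of [0, 1]")
        if not (0.0 <= self.baseline_haq <= 3.0):
            raise ConfigurationError(f"arm {self.name}: baseline HAQ out of [0, 3]")
        for key, val in (
            ("drug_cost_per_cycle", self.drug_cost_per_cycle),
            ("palliative_drug_cost_per_cycle", self.palliative_drug_cost_per_cycle),
            ("state_cost_base_per_cycle", self.state_cost_base_per_cycle),
            ("state_cost_per_haq_per_cycle", self.state_cost_per_haq_per_cycle),
            ("nonmedical_cost_per_cycle", self.nonmedical_cost_per_cycle),
            ("indirect_cost_per_cycle", self.indirect_cost_per_cycle),
        ):
            if val < 0:
                raise ConfigurationError(f"arm {self.name}: negative {key}")
        if self.utility.intercept > 1.0 + 1e-12:
            raise ConfigurationError(f"arm {self.name}: utility intercept above 1")

    def haq_in_state(self, state: str, cycle: int, cycle_length: float) -> float:
        """HAQ level occupied in a state during a given cycle (clamped to [0, 3])."""
        if state == "death":
            return 0.0
        if state == "initial":
            haq = self.baseline_haq
        elif state in RESPONDER_STATES:
            haq = self.baseline_haq - self.delta_haq[state.upper()]
        else:  # palliative: progresses from baseline after the first cycle
            years = max(0, cycle - 1) * cycle_length
            haq = self.baseline_haq + self.haq_progression_per_year * years
        return min(3.0, max(0.0, haq))


@dataclass
class ModelConfig:
    """Model-wide settings plus both arm configurations."""

    arms: Dict[str, ArmConfig]
    cycle_length: float = 0.5  # years
    horizon: float = 27.0  # years
    start_age: float = 51.0
    end_age: Optional[float] = 78.0
    discount_rate_costs: float = 0.05
    discount_rate_qalys: float = 0.05
    #: flat per-cycle death probability, or one value per cycle
    mortality_per_cycle: Union[float, Sequence[float]] = 0.0128
    wtp_per_qaly: float = 257_094.0  # 3 × per-capita GDP, CNY
    currency: str = "¥"
    half_cycle_correction: bool = False

    @property
    def n_cycles(self) -> int:
        ratio = self.horizon / self.cycle_length
        n = round(ratio)
        if abs(ratio - n) > 1e-9:
            raise ConfigurationError(
                f"horizon {self.horizon} is not a whole number of "
                f"{self.cycle_length}-year cycles"
            )
        return int(n)

    def validate(self) -> None:
        if self.cycle_length <= 0 or self.horizon <= 0:
            raise ConfigurationError("cycle_length and horizon must be positive")
        if self.end_age is not None:
            span = self.end_age - self.start_age
            if abs(span - self.horizon) > 1e-9:
                raise ConfigurationError(
                    f"horizon {self.horizon} != end_age - start_age = {span}"
                )
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ConfigurationError("discount rates must be >= 0")
        if self.wtp_per_qaly < 0:
            raise ConfigurationError("wtp_per_qaly must be >= 0")
        n = self.n_cycles
        q = self.mortality_schedule()
        if len(q) != n:
            raise ConfigurationError(
                f"mortality schedule has {len(q)} entries for {n} cycles"
            )
        if np.any((q < 0) | (q > 1)):
            raise ConfigurationError("mortality probabilities out of [0, 1]")
        for arm in self.arms.values():
            arm.validate()

    def mortality_schedule(self) -> np.ndarray:
        if np.isscalar(self.mortality_per_cycle):
            return np.full(self.n_cycles, float(self.mortality_per_cycle))
        return np.asarray(self.mortality_per_cycle, dtype=float)


def build_states(arm: ArmConfig, mortality: Sequence[float]):
    """State labels, initial distribution and per-cycle transition matrices.

    Returns ``(labels, init, transition)`` where ``transition(k)`` is the
    row-stochastic matrix applied at the end of cycle ``k``.
    """
    arm.validate()
    q = np.asarray(mortality, dtype=float)
    p70 = arm.response["ACR70"]
    p50 = arm.response["ACR50"]
    p20 = arm.response["ACR20"]
    pnone = arm.response["NONE"]
    w = arm.withdrawal_per_cycle
    init = np.zeros(len(STATES))
    init[0] = 1.0

    def transition(k: int) -> np.ndarray:
        qk = q[k]
        t = np.zeros((len(STATES), len(STATES)))
        # initial therapy: split by month-6 response, death competing
        t[0, 1:5] = (1 - qk) * np.array([p70, p50, p20, pnone])
        t[0, 5] = qk
        for i, _ in enumerate(RESPONDER_STATES, start=1):
            t[i, i] = (1 - qk) * (1 - w)
            t[i, 4] = (1 - qk) * w
            t[i, 5] = qk
        t[4, 4] = 1 - qk
        t[4, 5] = qk
        t[5, 5] = 1.0
        return t

    return list(STATES), init, transition


def iterate_occupancy(
    init: np.ndarray, transition: Callable[[int], np.ndarray], n_cycles: int
) -> np.ndarray:
    """Propagate a cohort: returns an ``(n_cycles + 1) × n_states`` matrix.

    Row ``k`` is the occupancy at the *start* of cycle ``k``; the final row
    is the terminal distribution.
    """
    occ = np.empty((n_cycles + 1, len(init)))
    occ[0] = init
    for k in range(n_cycles):
        occ[k + 1] = occ[k] @ transition(k)
    return occ


@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy and accrual for one arm."""

    arm: str
    state_labels: List[str]
    occupancy: np.ndarray  # (n_cycles + 1) × n_states
    #: undiscounted and discounted per-cycle cost by category (n_cycles rows)
    costs: Dict[str, np.ndarray]
    costs_discounted: Dict[str, np.ndarray]
    qalys: np.ndarray
    qalys_discounted: np.ndarray
    sae_qalys_discounted: np.ndarray
    cycle_length: float

    def to_frame(self) -> pd.DataFrame:
        n = self.occupancy.shape[0] - 1
        data = {"cycle": np.arange(n)}
        for j, s in enumerate(self.state_labels):
            data[f"occ_{s}"] = self.occupancy[:n, j]
        for cat in COST_CATEGORIES:
            data[f"cost_{cat}"] = self.costs[cat]
            data[f"cost_{cat}_disc"] = self.costs_discounted[cat]
        data["qalys"] = self.qalys
        data["qalys_disc"] = self.qalys_discounted
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ArmResult:
    """Lifetime discounted totals for one arm."""

    arm: str
    medication_cost: float
    state_cost: float
    nonmedical_cost: float
    indirect_cost: float
    qalys: float
    sae_qalys: float

    @property
    def direct_medical_cost(self) -> float:
        return self.medication_cost + self.state_cost

    @property
    def total_cost(self) -> float:
        return self.direct_medical_cost + self.nonmedical_cost + self.indirect_cost

    @property
    def total_qalys(self) -> float:
        return self.qalys


def run_cohort(config: ModelConfig, arm_label: str) -> CohortTrace:
    """Simulate one arm's cohort over the full horizon.

    Costs and QALYs accrue on start-of-cycle occupancy; the discount factor
    for cycle k is (1 + r)^(−k·cycle_length), so cycle 0 is undiscounted.
    With ``half_cycle_correction`` the accrual occupancy is the mean of the
    start- and end-of-cycle rows.
    """
    config.validate()
    if arm_label not in config.arms:
        raise ConfigurationError(f"unknown arm {arm_label!r}")
    arm = config.arms[arm_label]
    n = config.n_cycles
    cl = config.cycle_length
    mort = config.mortality_schedule()
    labels, init, transition = build_states(arm, mort)
    occ = iterate_occupancy(init, transition, n)

    acc = 0.5 * (occ[:-1] + occ[1:]) if config.half_cycle_correction else occ[:-1]

    cycles = np.arange(n)
    disc_c = (1 + config.discount_rate_costs) ** (-cycles * cl)
    disc_q = (1 + config.discount_rate_qalys) ** (-cycles * cl)

    # per-state, per-cycle HAQ, utility and cost schedules
    haq = np.zeros((n, len(labels)))
    util = np.zeros((n, len(labels)))
    med = np.zeros(len(labels))
    alive = np.ones(len(labels))
    alive[labels.index("death")] = 0.0
    for j, s in enumerate(labels):
        if s == "death":
            continue
        med[j] = (arm.palliative_drug_cost_per_cycle if s == "palliative"
                  else arm.drug_cost_per_cycle)
        for k in range(n):
            h = arm.haq_in_state(s, k, cl)
            haq[k, j] = h
            util[k, j] = haq_to_utility(h, arm.utility)

    costs = {
        "medication": (acc * med).sum(axis=1),
        "state": (acc * alive * (arm.state_cost_base_per_cycle
                                 + arm.state_cost_per_haq_per_cycle * haq)).sum(axis=1),
        "nonmedical": (acc * alive).sum(axis=1) * arm.nonmedical_cost_per_cycle,
        "indirect": (acc * alive).sum(axis=1) * arm.indirect_cost_per_cycle,
    }
    costs_disc = {cat: v * disc_c for cat, v in costs.items()}

    on_treatment = np.zeros(len(labels))
    for s in ("initial",) + RESPONDER_STATES:
        on_treatment[labels.index(s)] = 1.0
    sae_loss = (acc * on_treatment).sum(axis=1) * arm.sae_disutility_per_cycle
    qalys = (acc * util).sum(axis=1) * cl - sae_loss
    return CohortTrace(
        arm=arm_label,
        state_labels=labels,
        occupancy=occ,
        costs=costs,
        costs_discounted=costs_disc,
        qalys=qalys,
        qalys_discounted=qalys * disc_q,
        sae_qalys_discounted=sae_loss * disc_q,
        cycle_length=cl,
    )


def summarize_trace(trace: CohortTrace) -> ArmResult:
    return ArmResult(
        arm=trace.arm,
        medication_cost=float(trace.costs_discounted["medication"].sum()),
        state_cost=float(trace.costs_discounted["state"].sum()),
        nonmedical_cost=float(trace.costs_discounted["nonmedical"].sum()),
        indirect_cost=float(trace.costs_discounted["indirect"].sum()),
        qalys=float(trace.qalys_discounted.sum()),
        sae_qalys=float(trace.sae_qalys_discounted.sum()),
    )


@dataclass(frozen=True)
class Incremental:
    """Incremental block (first arm vs second arm)."""

    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    label: str  # "dominant", "dominated", "ICER", "equivalent", ...


def icer(result_a: ArmResult, result_b: ArmResult) -> Incremental:
    """Incremental cost-effectiveness of arm ``a`` versus arm ``b``.

    ``a`` cheaper and more effective → "dominant" (no ICER); the reverse →
    "dominated".  When ΔC and ΔQ share a sign the ICER ΔC/ΔQ is reported.
    """
    dc = result_a.total_cost - result_b.total_cost
    dq = result_a.total_qalys - result_b.total_qalys
    if dc == 0 and dq == 0:
        return Incremental(dc, dq, None, "equivalent")
    if dq == 0:
        return Incremental(dc, dq, None, "cost difference only")
    if dc < 0 and dq > 0:
        return Incremental(dc, dq, None, "dominant")
    if dc > 0 and dq < 0:
        return Incremental(dc, dq, None, "dominated")
    return Incremental(dc, dq, dc / dq, "ICER")


@dataclass
class CEAResult:
    """Full base-case comparison: per-arm totals plus the incremental block."""

    arm_results: Dict[str, ArmResult]
    incremental: Incremental
    currency: str = "¥"
    comparison: str = "tof vs ada"

    def summary_frame(self) -> pd.DataFrame:
        """Base-case table: one row per reported quantity, one column per arm."""
        arms = list(self.arm_results)
        rows = [
            ("Total costs", "total_cost"),
            ("Direct medical costs", "direct_medical_cost"),
            ("Medication costs", "medication_cost"),
            ("State costs", "state_cost"),
            ("Direct nonmedical costs", "nonmedical_cost"),
            ("Indirect costs", "indirect_cost"),
            ("Total QALYs", "total_qalys"),
            ("Severe adverse event QALYs", "sae_qalys"),
        ]
        data = {}
        for a in arms:
            r = self.arm_results[a]
            data[a] = [getattr(r, attr) for _, attr in rows]
        frame = pd.DataFrame(data, index=[label for label, _ in rows])
        inc = self.incremental
        extra = pd.DataFrame(
            {arms[0]: [inc.delta_cost, inc.delta_qalys,
                       inc.icer if inc.icer is not None else math.nan],
             arms[1]: [math.nan, math.nan, math.nan]},
            index=[f"Cost difference ({self.comparison})",
                   f"QALY difference ({self.comparison})",
                   f"ICER ({self.comparison})"],
        )
        out = pd.concat([frame, extra])
        out.attrs["icer_label"] = inc.label
        return out


def run_cea(config: ModelConfig, arm_a: str = "tof", arm_b: str = "ada") -> CEAResult:
    """Run both arms and assemble the base-case comparison (a vs b)."""
    res = {a: summarize_trace(run_cohort(config, a)) for a in (arm_a, arm_b)}
    inc = icer(res[arm_a], res[arm_b])
    return CEAResult(arm_results=res, incremental=inc, currency=config.currency,
                     comparison=f"{arm_a} vs {arm_b}")
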