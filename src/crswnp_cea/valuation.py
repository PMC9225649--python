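"""Discounted lifetime valuation of one arm: QALYs, life years, costs.

Year 1 (the decision tree) is valued undiscounted at time 0; Markov cycle k
(k = 1, 2, ...) is discounted by (1 + r)^-k.  Costs are grouped the way the
results table reports them: drug acquisition, disease management (state
management costs plus surgical episodes and post-operative follow-up),
adverse events, and - under the societal perspective - indirect productivity
losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace, HealthState
from .params import (
    ARM_DUPILUMAB,
    EconSettings,
    MarkovUtilities,
    ModelConfig,
    PERSPECTIVE_SOCIETAL,
    _check_arm,
    annual_ae_cost,
)
from .tree import TreeOutcome


def discount_factor(rate: float, t: int | np.ndarray) -> float | np.ndarray:
    """Present-value factor (1 + rate)^-t for an annual rate and cycle index."""
    return (1.0 + rate) ** -np.asarray(t, dtype=float)


@dataclass
class CostBreakdown:
    drug_acquisition: float
    disease_management: float
    adverse_events: float
    indirect: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.drug_acquisition
            + self.disease_management
            + self.adverse_events
            + self.indirect
        )

    @property
    def direct_total(self) -> float:
        return self.drug_acquisition + self.disease_management + self.adverse_events

    def as_dict(self) -> dict[str, float]:
        return {
            "drug_acquisition": self.drug_acquisition,
            "disease_management": self.disease_management,
            "adverse_events": self.adverse_events,
            "indirect": self.indirect,
            "total": self.total,
        }


@dataclass
class ArmResult:
    """Lifetime discounted outcomes for one strategy arm."""

    arm: str
    qalys: float
    life_years: float
    costs: CostBreakdown
    tree: TreeOutcome
    trace: CohortTrace

    def to_series(self) -> pd.Series:
        d = {"qalys": self.qalys, "life_years": self.life_years, **self.costs.as_dict()}
        return pd.Series(d, name=self.arm)


_STATE_UTILITY_ATTR = {
    HealthState.CONTROLLED: "u_controlled",
    HealthState.INADEQ_ELIG: "u_inadequate",
    HealthState.INADEQ_INELIG: "u_inadequate",
    HealthState.SURGERY: "u_surgery",
    HealthState.POSTOP_CONTROLLED: "u_postop_controlled",
    HealthState.POSTOP_UNCONTROLLED: "u_postop_uncontrolled",
    HealthState.DEATH: "u_death",
}

_STATE_COST_ATTR = {
    HealthState.CONTROLLED: "controlled",
    HealthState.INADEQ_ELIG: "inadequate",
    HealthState.INADEQ_INELIG: "inadequate",
    HealthState.SURGERY: None,  # the tunnel accrues the episode cost instead
    HealthState.POSTOP_CONTROLLED: "postop_controlled",
    HealthState.POSTOP_UNCONTROLLED: "postop_uncontrolled",
    HealthState.DEATH: "death",
}

_STATE_WORKDAYS_KEY = {
    HealthState.CONTROLLED: "controlled",
    HealthState.INADEQ_ELIG: "inadequate",
    HealthState.INADEQ_INELIG: "inadequate",
    HealthState.SURGERY: "surgery",
    HealthState.POSTOP_CONTROLLED: "postop_controlled",
    HealthState.POSTOP_UNCONTROLLED: "postop_uncontrolled",
    HealthState.DEATH: "death",
}


def state_utility_vector(u: MarkovUtilities) -> np.ndarray:
    return np.array([getattr(u, _STATE_UTILITY_ATTR[s]) for s in HealthState])


def _cycle_occupancy(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    """Occupancy attributed to each Markov cycle k >= 1 (rows 1..K).

    With the half-cycle correction, cycle k is valued at the mean of its
    start- and end-of-cycle occupancy; otherwise at the end-of-cycle row.
    """
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[1:]


def lifetime_qalys(
    tree: TreeOutcome,
    trace: CohortTrace,
    u: MarkovUtilities,
    econ: EconSettings,
    half_cycle: bool = False,
) -> float:
    """Undiscounted year-1 tree QALY plus the discounted sum of per-cycle
    occupancy-weighted state utilities."""
    uvec = state_utility_vector(u)
    occ = _cycle_occupancy(trace, half_cycle)
    k = np.arange(1, occ.shape[0] + 1)
    disc = discount_factor(econ.discount_rate_effects, k)
    return float(tree.qaly + disc @ (occ @ uvec))


def lifetime_life_years(
    tree: TreeOutcome, trace: CohortTrace, econ: EconSettings, half_cycle: bool = False
) -> float:
    """Discounted life years: one undiscounted tree year times its surviving
    mass, plus the discounted alive mass of every Markov cycle."""
    occ = _cycle_occupancy(trace, half_cycle)
    alive = 1.0 - occ[:, HealthState.DEATH]
    k = np.arange(1, occ.shape[0] + 1)
    disc = discount_factor(econ.discount_rate_effects, k)
    # the whole entering cohort lives the tree year (tree mortality, if
    # enabled, is applied at the year boundary)
    return float(1.0 + disc @ alive)


def lifetime_costs(
    tree: TreeOutcome, trace: CohortTrace, cfg: ModelConfig, arm: str
) -> CostBreakdown:
    """Discounted lifetime cost breakdown for one arm.

    Per Markov cycle: drug acquisition accrues on controlled occupancy
    (intervention arm only); disease management accrues the annual state
    costs, a surgical episode cost (CT + procedure) per unit of surgery-entry
    flow, and the annual follow-up tariff on post-operative occupancy;
    adverse events accrue on alive mass at the arm's annual rate; indirect
    productivity losses (societal perspective only) accrue on occupancies.
    Undiscounted year-1 tree costs are added on top.
    """
    _check_arm(arm)
    econ = cfg.econ
    half_cycle = cfg.switches.half_cycle_correction
    occ = _cycle_occupancy(trace, half_cycle)
    flows = trace.surgery_entries[1:]
    k = np.arange(1, occ.shape[0] + 1)
    disc_c = discount_factor(econ.discount_rate_costs, k)
    alive = 1.0 - occ[:, HealthState.DEATH]

    # drug acquisition while controlled (on sustained treatment)
    annual_drug = cfg.drug.annual_cost(arm)
    if arm == ARM_DUPILUMAB and annual_drug != 0.0:
        drug = float(disc_c @ (occ[:, HealthState.CONTROLLED] * annual_drug))
    else:
        drug = float(disc_c @ (alive * annual_drug)) if annual_drug else 0.0
    drug += tree.costs["drug_acquisition"]

    # disease management: state costs + surgery episodes + post-op follow-up
    sc = cfg.markov_state_costs
    cost_vec = np.array(
        [
            getattr(sc, _STATE_COST_ATTR[s]) if _STATE_COST_ATTR[s] is not None else 0.0
            for s in HealthState
        ]
    )
    dm_per_cycle = occ @ cost_vec
    dm_per_cycle = dm_per_cycle + flows * cfg.surgery_costs.episode_cost
    if cfg.switches.postop_followup_separate:
        postop = occ[:, HealthState.POSTOP_CONTROLLED] + occ[:, HealthState.POSTOP_UNCONTROLLED]
        dm_per_cycle = dm_per_cycle + postop * cfg.surgery_costs.annual_followup
    disease_management = float(disc_c @ dm_per_cycle)
    disease_management += tree.costs["therapy"] + tree.costs["medical"]

    # adverse events on alive mass
    ae_annual = annual_ae_cost(cfg.ae_items, arm)
    adverse = float(disc_c @ (alive * ae_annual)) if cfg.switches.ae_costs_lifetime else 0.0
    adverse += tree.costs["adverse_events"]

    # indirect productivity losses (societal perspective only)
    indirect = 0.0
    if econ.perspective == PERSPECTIVE_SOCIETAL:
        if not cfg.indirect.workdays_lost_per_year_by_state:
            raise ValueError(
                "societal perspective requires workdays-lost inputs per health state"
            )
        wd = np.array(
            [
                cfg.indirect.annual_cost(_STATE_WORKDAYS_KEY[s])
                for s in HealthState
            ]
        )
        indirect = float(disc_c @ (occ @ wd))

    return CostBreakdown(
        drug_acquisition=drug,
        disease_management=disease_management,
        adverse_events=adverse,
        indirect=indirect,
    )


def value_arm(
    cfg: ModelConfig, arm: str, tree: TreeOutcome, trace: CohortTrace
) -> ArmResult:
    """Assemble the lifetime discounted result for one arm."""
    qalys = lifetime_qalys(
        tree, trace, cfg.markov_utilities, cfg.econ, cfg.switches.half_cycle_correction
    )
    lys = lifetime_life_years(tree, trace, cfg.econ, cfg.switches.half_cycle_correction)
    costs = lifetime_costs(tree, trace, cfg, arm)
    return ArmResult(arm=arm, qalys=qalys, life_years=lys, costs=costs, tree=tree, trace=trace)
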