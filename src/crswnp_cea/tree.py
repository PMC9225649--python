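"""Year-1 decision tree: response assessments at weeks 24 and 52.

All patients start on their assigned strategy.  At week 24 a clinical check
(SNOT-22 improvement >= 8.9 and NPS improvement >= 1) splits the cohort;
week-24 responders are re-assessed at week 52.  The three terminal branches
are NR24 (non-responder at week 24), NR52 (responded at 24, lost response by
52) and R52 (responder at both).  At year end R52 patients enter the Markov
model controlled; all non-responders enter inadequately controlled, split
into surgery-eligible and -ineligible substates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import N_STATES, HealthState
from .params import (
    AEItem,
    ARM_DUPILUMAB,
    DrugCostSpec,
    ModelConfig,
    ResponseProbabilities,
    TreeCosts,
    TreeUtilities,
    _check_arm,
    annual_ae_cost,
)

BRANCHES = ("NR24", "NR52", "R52")

# time partition of the 52-week year, in weeks
_WEEKS_BASELINE = 12  # weeks 0-12 at baseline utility
_WEEKS_12_24 = 12  # weeks 12-24 at the treatment-specific utility
_WEEKS_24_52 = 28  # weeks 24-52 at the assessed-status utility


@dataclass
class TreeBranch:
    label: str
    probability: float
    arm: str


@dataclass
class TreeOutcome:
    """Expected year-1 results for one arm plus the Markov entry distribution."""

    arm: str
    branch_probabilities: dict[str, float]
    qaly: float
    costs: dict[str, float]  # therapy, medical, drug_acquisition, adverse_events
    entry_distribution: np.ndarray
    branch_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    def to_frame(self) -> pd.DataFrame:
        return self.branch_table.copy()


def branch_probabilities(resp: ResponseProbabilities, arm: str) -> dict[str, float]:
    """P(NR24), P(NR52), P(R52) from the week-24 marginal and the week-52
    conditional response probabilities."""
    p24 = resp.p24(arm)
    p52 = resp.p52_given_24(arm)
    return {
        "NR24": 1.0 - p24,
        "NR52": p24 * (1.0 - p52),
        "R52": p24 * p52,
    }


def year1_qaly(
    branch: str,
    u: TreeUtilities,
    arm: str,
    nr52_responder_utility: bool = True,
) -> float:
    """Time-weighted utility over the 52-week year for one terminal branch.

    Weeks 0-12 at baseline, weeks 12-24 at the treatment-specific utility,
    weeks 24-52 at the responder or non-responder utility according to the
    week-24 assessment.  NR52 patients respond until the week-52 assessment,
    so by default they accrue responder utility over weeks 24-52 (switchable).
    """
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}")
    if branch == "NR24":
        u_late = u.u_wk24plus_nonresponder
    elif branch == "NR52":
        u_late = u.u_wk24plus_responder if nr52_responder_utility else u.u_wk24plus_nonresponder
    else:
        u_late = u.u_wk24plus_responder
    return (
        _WEEKS_BASELINE * u.u_baseline
        + _WEEKS_12_24 * u.u_wk12_24(arm)
        + _WEEKS_24_52 * u_late
    ) / 52.0


def year1_costs(
    branch: str,
    tc: TreeCosts,
    drug: DrugCostSpec,
    ae: list[AEItem],
    arm: str,
) -> dict[str, float]:
    """Year-1 cost components (EUR) for one terminal branch.

    Therapy/medical costs key on eventual response status per half-year:
    NR24 pays non-responder costs in both halves, NR52 responder costs in the
    first half and non-responder costs in the second, R52 responder costs in
    both.  Drug acquisition (intervention arm only) covers the on-treatment
    fraction of the year: week-24 non-responders stop after 24/52 of the
    administrations.  Adverse events accrue at the arm's annual rate.
    """
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}")
    _check_arm(arm)
    status = {"NR24": (False, False), "NR52": (True, False), "R52": (True, True)}[branch]
    therapy = medical = 0.0
    for half, responder in zip((1, 2), status):
        t, m = tc.half_year(responder, half)
        therapy += t
        medical += m
    on_treatment_fraction = 24.0 / 52.0 if branch == "NR24" else 1.0
    drug_cost = drug.annual_cost(arm) * on_treatment_fraction if arm == ARM_DUPILUMAB else (
        drug.annual_cost(arm)
    )
    return {
        "therapy": therapy,
        "medical": medical,
        "drug_acquisition": drug_cost,
        "adverse_events": annual_ae_cost(ae, arm),
    }


def run_tree(cfg: ModelConfig, arm: str) -> TreeOutcome:
    """Evaluate the year-1 tree for one arm.

    Expected QALYs and costs are probability-weighted branch values.  The
    Markov entry distribution sends R52 mass to the controlled state and all
    non-responder mass to inadequately controlled, split by surgical
    eligibility.  With the tree-mortality switch on, one year of background
    mortality at the starting age is applied to the entry distribution.
    """
    _check_arm(arm)
    probs = branch_probabilities(cfg.response, arm)
    rows = []
    for label in BRANCHES:
        q = year1_qaly(
            label, cfg.tree_utilities, arm, cfg.switches.nr52_responder_utility
        )
        c = year1_costs(label, cfg.tree_costs, cfg.drug, cfg.ae_items, arm)
        rows.append({"branch": label, "probability": probs[label], "qaly": q, **c})
    table = pd.DataFrame(rows)
    weights = table["probability"].to_numpy()
    qaly = float(weights @ table["qaly"].to_numpy())
    costs = {
        k: float(weights @ table[k].to_numpy())
        for k in ("therapy", "medical", "drug_acquisition", "adverse_events")
    }

    entry = np.zeros(N_STATES)
    p_inelig = cfg.surgery_access.p_ineligible
    nonresp = probs["NR24"] + probs["NR52"]
    entry[HealthState.CONTROLLED] = probs["R52"]
    entry[HealthState.INADEQ_ELIG] = nonresp * (1.0 - p_inelig)
    entry[HealthState.INADEQ_INELIG] = nonresp * p_inelig

    if cfg.switches.tree_mortality:
        lt = cfg.resolve_life_table()
        q0 = lt.q_at(cfg.demographics.start_age)
        entry *= 1.0 - q0
        entry[HealthState.DEATH] = q0

    return TreeOutcome(
        arm=arm,
        branch_probabilities=probs,
        qaly=qaly,
        costs=costs,
        entry_distribution=entry,
        branch_table=table,
    )
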