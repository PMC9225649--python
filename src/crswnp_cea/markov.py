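"""Lifetime annual-cycle Markov cohort engine.

Six alive states plus death.  Controlled patients discontinue at 2%/year
(complement of the 98% sustained-response probability) and re-enter the
inadequately-controlled compartment, where a persistent 15.1% are ineligible
for surgery.  Eligible uncontrolled patients (pre- or post-operative) undergo
surgery at 1.9%/year while under 70.  Surgery is a one-cycle tunnel leading to
the post-operative controlled state, from which 40%/year relapse.  Background
mortality is applied first each cycle, from the life table, identically in
every alive state (no disease-specific excess mortality is modelled).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .params import ModelConfig


class HealthState(IntEnum):
    CONTROLLED = 0
    INADEQ_ELIG = 1
    INADEQ_INELIG = 2
    SURGERY = 3
    POSTOP_CONTROLLED = 4
    POSTOP_UNCONTROLLED = 5
    DEATH = 6


N_STATES = len(HealthState)

#: Map from state to the key used in cost/workdays mappings.
STATE_NAMES = {
    HealthState.CONTROLLED: "controlled",
    HealthState.INADEQ_ELIG: "inadequate",
    HealthState.INADEQ_INELIG: "inadequate",
    HealthState.SURGERY: "surgery",
    HealthState.POSTOP_CONTROLLED: "postop_controlled",
    HealthState.POSTOP_UNCONTROLLED: "postop_uncontrolled",
    HealthState.DEATH: "death",
}


def transition_row(
    state: HealthState, age: float, cfg: ModelConfig, q: float | None = None
) -> np.ndarray:
    """One row of the annual transition matrix at the given cohort age.

    Death (probability ``q`` from the life table) is applied first; the
    clinical transitions below act on the surviving mass.
    """
    if q is None:
        lt = cfg.resolve_life_table()
        q = lt.q_at(min(age, lt.max_age))
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"death probability must lie in [0, 1], got {q}")
    state = HealthState(state)
    sa = cfg.surgery_access
    row = np.zeros(N_STATES)
    row[HealthState.DEATH] = q
    alive = 1.0 - q
    if state == HealthState.DEATH:
        row[:] = 0.0
        row[HealthState.DEATH] = 1.0
        return row
    if state == HealthState.CONTROLLED:
        p_stay = cfg.sustained.annual_p_sustain
        p_disc = 1.0 - p_stay
        row[HealthState.CONTROLLED] = alive * p_stay
        # discontinuers re-enter the eligibility split
        row[HealthState.INADEQ_ELIG] = alive * p_disc * (1.0 - sa.p_ineligible)
        row[HealthState.INADEQ_INELIG] = alive * p_disc * sa.p_ineligible
    elif state in (HealthState.INADEQ_ELIG, HealthState.POSTOP_UNCONTROLLED):
        p_surg = sa.annual_p_surgery if age < sa.max_surgery_age else 0.0
        row[HealthState.SURGERY] = alive * p_surg
        row[state] = alive * (1.0 - p_surg)
    elif state == HealthState.INADEQ_INELIG:
        row[HealthState.INADEQ_INELIG] = alive
    elif state == HealthState.SURGERY:
        p_ok = sa.p_surgery_to_postop_controlled
        row[HealthState.POSTOP_CONTROLLED] = alive * p_ok
        row[HealthState.POSTOP_UNCONTROLLED] = alive * (1.0 - p_ok)
    elif state == HealthState.POSTOP_CONTROLLED:
        row[HealthState.POSTOP_CONTROLLED] = alive * sa.p_postop_stay_controlled
        row[HealthState.POSTOP_UNCONTROLLED] = alive * sa.p_postop_to_uncontrolled
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown health state {state!r}")
    return row


def transition_matrix(age: float, cfg: ModelConfig, q: float | None = None) -> np.ndarray:
    """Full row-stochastic transition matrix at one age."""
    return np.vstack([transition_row(s, age, cfg, q=q) for s in HealthState])


def step(
    occupancy: np.ndarray, age: float, cfg: ModelConfig, q: float | None = None
) -> tuple[np.ndarray, float]:
    """Advance the cohort one annual cycle.

    Returns the next occupancy vector and the surgery-entry flow (the
    proportion of the cohort entering the surgical tunnel this cycle).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (N_STATES,):
        raise ValueError(f"occupancy must have length {N_STATES}")
    if np.any(occupancy < -1e-12) or abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must be a distribution summing to 1")
    P = transition_matrix(age, cfg, q=q)
    nxt = occupancy @ P
    surgery_flow = float(nxt[HealthState.SURGERY])  # tunnel: all mass is new entries
    return nxt, surgery_flow


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of the cohort.

    Row 0 is the Markov entry distribution (end of the tree year); row k >= 1
    is the occupancy during Markov cycle k, after k annual transitions.  The
    attached age for row k is start_age + k, the age at which cycle k's
    transition probabilities were evaluated.
    """

    start_age: float
    occupancy: np.ndarray  # (K+1, N_STATES)
    surgery_entries: np.ndarray  # (K+1,), entry 0 is 0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0])

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + self.cycles

    @property
    def alive_mass(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, HealthState.DEATH]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[s.name.lower() for s in HealthState]
        )
        df.insert(0, "cycle", self.cycles)
        df.insert(1, "age", self.ages)
        df["surgery_entries"] = self.surgery_entries
        df["alive_mass"] = self.alive_mass
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_markov(
    entry: np.ndarray, cfg: ModelConfig, lt: LifeTable | None = None
) -> CohortTrace:
    """Iterate the cohort from the tree's entry distribution to the horizon.

    Cycle k uses the life-table death probability at age start_age + k and
    runs while that age stays within the horizon and the alive mass exceeds
    1e-9.  Ages beyond the life-table maximum use the absorbing final q = 1.
    """
    if lt is None:
        lt = cfg.resolve_life_table()
    start_age = cfg.demographics.start_age
    horizon = cfg.econ.horizon_max_age
    if horizon <= start_age:
        raise ValueError("horizon_max_age must exceed the cohort start age")
    entry = np.asarray(entry, dtype=float)
    if entry.shape != (N_STATES,):
        raise ValueError(f"entry distribution must have length {N_STATES}")
    if abs(entry.sum() - 1.0) > 1e-9 or np.any(entry < -1e-12):
        raise ValueError("entry distribution must sum to 1 with non-negative mass")

    rows = [entry]
    flows = [0.0]
    occ = entry
    k = 1
    while start_age + k <= horizon:
        age = start_age + k
        q = lt.q_at(min(age, lt.max_age))
        occ, flow = step(occ, age, cfg, q=q)
        rows.append(occ)
        flows.append(flow)
        if 1.0 - occ[HealthState.DEATH] < 1e-9:
            break
        k += 1
    return CohortTrace(start_age, np.vstack(rows), np.asarray(flows))
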