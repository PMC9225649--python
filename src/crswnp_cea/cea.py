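"""Incremental cost-utility analysis: ICUR, net monetary benefit, dominance."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .valuation import ArmResult

DOMINANCE_NONE = "none"
DOMINANCE_INTERVENTION = "intervention_dominates"
DOMINANCE_COMPARATOR = "comparator_dominates"


@dataclass
class CEAResult:
    """Incremental comparison of an intervention against a comparator.

    ``icur`` is the ratio delta_cost / delta_qaly, defined only when no
    strategy dominates and the QALY difference is non-zero.  The cost-
    effectiveness-plane quadrant is always labelled, because a bare negative
    ratio is ambiguous (cost-saving-and-effective looks identical to
    costlier-and-harmful).
    """

    delta_cost: float
    delta_qaly: float
    icur: Optional[float]
    dominance: str
    quadrant: str
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icur": self.icur,
            "dominance": self.dominance,
            "quadrant": self.quadrant,
            "note": self.note,
        }


def _quadrant(dc: float, dq: float) -> str:
    if dq > 0 and dc > 0:
        return "NE (costlier, more effective)"
    if dq > 0 and dc <= 0:
        return "SE (cost-saving, more effective)"
    if dq < 0 and dc >= 0:
        return "NW (costlier, less effective)"
    if dq < 0 and dc < 0:
        return "SW (cost-saving, less effective)"
    return "origin axis (equal effectiveness)"


def icur(intervention: ArmResult, comparator: ArmResult) -> CEAResult:
    """Incremental cost per QALY gained of the intervention vs the comparator."""
    dc = intervention.costs.total - comparator.costs.total
    dq = intervention.qalys - comparator.qalys
    quadrant = _quadrant(dc, dq)
    if dq == 0.0 and dc == 0.0:
        return CEAResult(dc, dq, None, DOMINANCE_NONE, quadrant, note="indifferent")
    if dq > 0 and dc <= 0:
        return CEAResult(dc, dq, None, DOMINANCE_INTERVENTION, quadrant)
    if dq < 0 and dc >= 0:
        return CEAResult(dc, dq, None, DOMINANCE_COMPARATOR, quadrant)
    if dq == 0.0:
        return CEAResult(
            dc, dq, None, DOMINANCE_NONE, quadrant, note="undefined ratio (zero QALY difference)"
        )
    return CEAResult(dc, dq, dc / dq, DOMINANCE_NONE, quadrant)


def nmb(result: ArmResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (EUR/QALY)."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * result.qalys - result.costs.total


def incremental_nmb(cea: CEAResult, wtp: float) -> float:
    """lambda * delta_QALY - delta_cost; >= 0 iff the intervention is
    preferred at threshold lambda."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * cea.delta_qaly - cea.delta_cost
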