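"""Model facade: build, run and summarise the cost-utility analysis.

:class:`CostUtilityModel` wraps a validated :class:`~crswnp_cea.params.ModelConfig`;
``fit()`` runs the year-1 decision tree and the lifetime Markov cohort for
both strategy arms and returns a :class:`CostUtilityResults` carrying the
per-arm discounted QALYs and cost breakdowns, the incremental comparison,
and entry points for sensitivity and scenario analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cea as _cea
from .lifetable import LifeTable
from .markov import run_markov
from .params import (
    ARM_BSC,
    ARM_DUPILUMAB,
    ARMS,
    ConfigError,
    ModelConfig,
    load_config,
    validate_config,
)
from .tree import run_tree
from .valuation import ArmResult, value_arm


def run_arm(cfg: ModelConfig, arm: str) -> ArmResult:
    """Run tree -> Markov -> valuation for a single arm."""
    tree = run_tree(cfg, arm)
    trace = run_markov(tree.entry_distribution, cfg)
    return value_arm(cfg, arm, tree, trace)


def evaluate_config(cfg: ModelConfig) -> tuple[ArmResult, ArmResult, _cea.CEAResult]:
    """Full two-arm evaluation: (intervention, comparator, incremental)."""
    dup = run_arm(cfg, ARM_DUPILUMAB)
    bsc = run_arm(cfg, ARM_BSC)
    return dup, bsc, _cea.icur(dup, bsc)


class CostUtilityModel:
    """Two-arm decision-tree + Markov cost-utility model.

    Parameters
    ----------
    config
        A complete model configuration.  Validation failures raise
        :class:`~crswnp_cea.params.ConfigError` immediately.
    life_table
        Optional pre-built life table overriding the config's specification.
    """

    def __init__(self, config: ModelConfig, life_table: Optional[LifeTable] = None):
        violations = validate_config(config)
        if violations:
            raise ConfigError(violations)
        self.config = config
        if life_table is not None:
            config._life_table_cache = life_table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostUtilityModel":
        """Build from a YAML/JSON configuration file (missing fields filled
        with packaged defaults)."""
        return cls(load_config(path))

    @classmethod
    def default(cls) -> "CostUtilityModel":
        """The packaged default fixture: published inputs plus clearly
        flagged placeholders for the unpublished ones."""
        from .synthetic import default_fixture

        return cls(default_fixture().config)

    def run_arm(self, arm: str) -> ArmResult:
        return run_arm(self.config, arm)

    def fit(self) -> "CostUtilityResults":
        dup, bsc, inc = evaluate_config(self.config)
        return CostUtilityResults(model=self, intervention=dup, comparator=bsc, cea=inc)

    # -- sensitivity / scenarios (delegating to the sensitivity module) -----

    def owsa(self, params=None):
        from .sensitivity import owsa

        return owsa(self.config, params)

    def psa(self, n: int = 1000, seed: int = 0):
        from .sensitivity import psa

        return psa(self.config, n, seed)

    def scenario(self, name: str, rate: float | None = None) -> "CostUtilityModel":
        from .sensitivity import scenario_compliance, scenario_societal

        if name == "societal":
            return CostUtilityModel(scenario_societal(self.config))
        if name == "compliance":
            return CostUtilityModel(
                scenario_compliance(self.config, 0.9695 if rate is None else rate)
            )
        raise ValueError(f"unknown scenario {name!r}; expected 'societal' or 'compliance'")


@dataclass
class CostUtilityResults:
    """Fitted results: per-arm lifetime outcomes plus the incremental analysis."""

    model: CostUtilityModel
    intervention: ArmResult
    comparator: ArmResult
    cea: _cea.CEAResult
    _arm_map: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._arm_map = {ARM_DUPILUMAB: self.intervention, ARM_BSC: self.comparator}

    def arm(self, arm: str) -> ArmResult:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        return self._arm_map[arm]

    def nmb(self, wtp: float) -> dict[str, float]:
        return {a: _cea.nmb(r, wtp) for a, r in self._arm_map.items()}

    def to_frame(self) -> pd.DataFrame:
        """Per-arm outcomes and cost components, one column per arm plus the
        difference column, mirroring the standard results-table layout."""
        a = self.intervention.to_series()
        b = self.comparator.to_series()
        df = pd.DataFrame({"dupilumab_bsc": a, "bsc": b})
        df["difference"] = df["dupilumab_bsc"] - df["bsc"]
        return df

    def summary(self) -> str:
        """Plain-text results table (whole euros, 2-decimal QALYs) with a
        watermark listing every placeholder input the run depended on."""
        from .report import render_summary

        return render_summary(self)


__all__ = [
    "CostUtilityModel",
    "CostUtilityResults",
    "run_arm",
    "evaluate_config",
]
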