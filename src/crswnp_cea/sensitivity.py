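"""Sensitivity and scenario analysis.

One-way deterministic analysis (tornado), probabilistic sensitivity analysis
with moment-matched Gamma/Beta/truncated-Normal distributions, the
cost-effectiveness acceptability curve, and the two scenario switches
(societal perspective; reduced compliance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cea import CEAResult
from .params import (
    ModelConfig,
    PERSPECTIVE_SOCIETAL,
    get_param,
    set_param,
)

# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class OWSAParam:
    """One parameter to vary between low and high bounds."""

    path: str
    base: float
    low: float
    high: float
    bound_source: str = "plus_minus_10pct"  # or "ci95"

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.path}: bounds must bracket the base value "
                f"({self.low} <= {self.base} <= {self.high})"
            )

    @classmethod
    def pm10(cls, cfg: ModelConfig, path: str, clamp_unit: bool = False) -> "OWSAParam":
        """+/-10% bounds around the configured base value; probabilities and
        utilities are clamped to [0, 1]."""
        base = float(get_param(cfg, path))
        lo, hi = base * 0.9, base * 1.1
        if clamp_unit:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        return cls(path, base, lo, hi)


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icur_at_low: float
    icur_at_high: float
    dominance_at_low: str = "none"
    dominance_at_high: str = "none"

    @property
    def span(self) -> float:
        return abs(self.icur_at_high - self.icur_at_low)


_UNIT_INTERVAL_PATHS = [
    "response.p_resp_wk24_dup",
    "response.p_resp_wk24_bsc",
    "response.p_resp_wk52_given_wk24_dup",
    "response.p_resp_wk52_given_wk24_bsc",
    "sustained.annual_p_sustain",
    "surgery_access.p_ineligible",
    "surgery_access.annual_p_surgery",
    "surgery_access.p_postop_to_uncontrolled",
    "tree_utilities.u_baseline",
    "tree_utilities.u_wk12_24_dup",
    "tree_utilities.u_wk12_24_bsc",
    "tree_utilities.u_wk24plus_responder",
    "tree_utilities.u_wk24plus_nonresponder",
    "markov_utilities.u_controlled",
    "markov_utilities.u_inadequate",
    "markov_utilities.u_surgery",
    "markov_utilities.u_postop_controlled",
    "markov_utilities.u_postop_uncontrolled",
]

_COST_PATHS = [
    "tree_costs.therapy_responder_h1",
    "tree_costs.therapy_responder_h2",
    "tree_costs.medical_responder_h1",
    "tree_costs.medical_responder_h2",
    "tree_costs.therapy_nonresponder_h1",
    "tree_costs.therapy_nonresponder_h2",
    "tree_costs.medical_nonresponder_h1",
    "tree_costs.medical_nonresponder_h2",
    "markov_state_costs.controlled",
    "markov_state_costs.inadequate",
    "markov_state_costs.postop_controlled",
    "markov_state_costs.postop_uncontrolled",
    "surgery_costs.ct_scan",
    "surgery_costs.procedure",
    "surgery_costs.annual_followup",
    "drug.price_per_administration",
]

# structural settings belong in OWSA but are excluded from the PSA
_STRUCTURAL_OWSA_PATHS = [
    "econ.discount_rate_costs",
    "econ.discount_rate_effects",
    "surgery_access.max_surgery_age",
]


def default_owsa_params(cfg: ModelConfig) -> list[OWSAParam]:
    """+/-10% bounds on every substantive probability, utility, cost, AE rate
    and the structural settings (no 95% CIs are published)."""
    out = [OWSAParam.pm10(cfg, p, clamp_unit=True) for p in _UNIT_INTERVAL_PATHS]
    out += [OWSAParam.pm10(cfg, p) for p in _COST_PATHS + _STRUCTURAL_OWSA_PATHS]
    for i, item in enumerate(cfg.ae_items):
        for leaf in ("rate_dup", "rate_bsc", "unit_cost"):
            if getattr(item, leaf) > 0:
                out.append(OWSAParam.pm10(cfg, f"ae_items[{i}].{leaf}"))
    return out


def _icur_value(result: CEAResult) -> float:
    """Ratio value for tornado plotting, defined in every quadrant (dominant
    outcomes keep the raw ratio but are flagged via the dominance field)."""
    if result.delta_qaly == 0.0:
        return float("nan")
    return result.delta_cost / result.delta_qaly


def owsa(cfg: ModelConfig, params: Optional[Iterable[OWSAParam]] = None) -> list[TornadoEntry]:
    """Re-run the full model with each parameter at its low and high bound,
    restoring the base configuration between runs; entries come back sorted
    by ICUR span, widest first."""
    from .model import evaluate_config

    if params is None:
        params = default_owsa_params(cfg)
    entries = []
    for p in params:
        get_param(cfg, p.path)  # raises KeyError naming a bad path
        results = {}
        doms = {}
        for bound_name, value in (("low", p.low), ("high", p.high)):
            trial = cfg.copy()
            set_param(trial, p.path, value)
            _, _, inc = evaluate_config(trial)
            results[bound_name] = _icur_value(inc)
            doms[bound_name] = inc.dominance
        entries.append(
            TornadoEntry(
                parameter=p.path,
                low=p.low,
                high=p.high,
                icur_at_low=results["low"],
                icur_at_high=results["high"],
                dominance_at_low=doms["low"],
                dominance_at_high=doms["high"],
            )
        )
    entries.sort(key=lambda e: (np.nan_to_num(e.span, nan=-1.0)), reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icur_low": [e.icur_at_low for e in entries],
            "icur_high": [e.icur_at_high for e in entries],
            "span": [e.span for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

FAMILY_GAMMA = "gamma"
FAMILY_BETA = "beta"
FAMILY_NORMAL = "normal"


@dataclass
class PSADistributionSpec:
    """Moment-matched sampling distribution for one parameter.

    Families follow the standard convention: Gamma for costs and resource
    use, Beta for probabilities/proportions/adverse-event incidences, Normal
    (truncated to [0, 1]) for utilities.
    """

    path: str
    family: str
    mean: float
    se: float

    def __post_init__(self):
        if self.family not in (FAMILY_GAMMA, FAMILY_BETA, FAMILY_NORMAL):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if self.family == FAMILY_GAMMA and self.se > 0 and self.mean <= 0:
            raise ValueError(f"{self.path}: gamma requires a positive mean")
        if self.family == FAMILY_BETA and self.se > 0:
            if not 0.0 < self.mean < 1.0:
                raise ValueError(f"{self.path}: beta requires mean in (0, 1)")
            if self.se**2 >= self.mean * (1.0 - self.mean):
                raise ValueError(
                    f"{self.path}: infeasible beta moments (SE^2 >= mean(1-mean))"
                )

    def distribution(self):
        """The scipy frozen distribution this spec samples from (None when
        degenerate)."""
        if self.se == 0.0:
            return None
        if self.family == FAMILY_GAMMA:
            shape = (self.mean / self.se) ** 2
            scale = self.se**2 / self.mean
            return stats.gamma(a=shape, scale=scale)
        if self.family == FAMILY_BETA:
            nu = self.mean * (1.0 - self.mean) / self.se**2 - 1.0
            return stats.beta(a=self.mean * nu, b=(1.0 - self.mean) * nu)
        a = (0.0 - self.mean) / self.se
        b = (1.0 - self.mean) / self.se
        return stats.truncnorm(a, b, loc=self.mean, scale=self.se)


def sample_parameter(spec: PSADistributionSpec, rng: np.random.Generator, size=None):
    """Draw from the spec's distribution; SE = 0 returns the mean exactly."""
    if spec.se == 0.0:
        return spec.mean if size is None else np.full(size, spec.mean)
    return spec.distribution().rvs(size=size, random_state=rng)


def default_psa_specs(cfg: ModelConfig, se_fraction: float = 0.1) -> list[PSADistributionSpec]:
    """Distribution specs for every varied parameter, with SE defaulting to
    10% of the mean (no standard errors are published); degenerate means
    (0 or 1 for Beta, 0 for Gamma) get SE = 0 and are held fixed."""
    specs: list[PSADistributionSpec] = []

    def beta(path):
        m = float(get_param(cfg, path))
        se = se_fraction * m if 0.0 < m < 1.0 else 0.0
        specs.append(PSADistributionSpec(path, FAMILY_BETA, m, se))

    def gamma(path):
        m = float(get_param(cfg, path))
        se = se_fraction * m if m > 0 else 0.0
        specs.append(PSADistributionSpec(path, FAMILY_GAMMA, m, se))

    def normal(path):
        m = float(get_param(cfg, path))
        specs.append(PSADistributionSpec(path, FAMILY_NORMAL, m, se_fraction * m))

    for p in (
        "response.p_resp_wk24_dup",
        "response.p_resp_wk24_bsc",
        "response.p_resp_wk52_given_wk24_dup",
        "response.p_resp_wk52_given_wk24_bsc",
        "sustained.annual_p_sustain",
        "surgery_access.p_ineligible",
        "surgery_access.annual_p_surgery",
        "surgery_access.p_postop_to_uncontrolled",
        "surgery_access.p_surgery_to_postop_controlled",
    ):
        beta(p)
    for p in _UNIT_INTERVAL_PATHS:
        if p.startswith(("tree_utilities", "markov_utilities")):
            normal(p)
    for p in _COST_PATHS:
        gamma(p)
    for i, item in enumerate(cfg.ae_items):
        beta(f"ae_items[{i}].rate_dup")
        beta(f"ae_items[{i}].rate_bsc")
        gamma(f"ae_items[{i}].unit_cost")
    return specs


@dataclass
class PSAResult:
    """Paired (delta cost, delta QALY) draws with the sampled parameter sets."""

    seed: int
    n: int
    param_names: list[str]
    samples: np.ndarray  # (n, n_params)
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    base: CEAResult
    _ceac_cache: dict = field(default_factory=dict, repr=False)

    def ce_plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.param_names)


def psa(
    cfg: ModelConfig,
    n: int = 1000,
    seed: int = 0,
    specs: Optional[list[PSADistributionSpec]] = None,
) -> PSAResult:
    """Jointly re-sample all varied parameters n times and re-run the full
    model per draw.  A single seeded generator drives all sampling, so the
    same seed reproduces the result bit for bit."""
    from .model import evaluate_config

    if n < 1:
        raise ValueError("n must be at least 1")
    if specs is None:
        specs = default_psa_specs(cfg)
    for s in specs:
        get_param(cfg, s.path)  # fail fast on bad paths before sampling
    rng = np.random.default_rng(seed)
    samples = np.column_stack(
        [np.asarray(sample_parameter(s, rng, size=n), dtype=float) for s in specs]
    )
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        trial = cfg.copy()
        for j, s in enumerate(specs):
            set_param(trial, s.path, float(samples[i, j]))
        _, _, inc = evaluate_config(trial)
        dc[i] = inc.delta_cost
        dq[i] = inc.delta_qaly
    _, _, base = evaluate_config(cfg)
    return PSAResult(
        seed=seed,
        n=n,
        param_names=[s.path for s in specs],
        samples=samples,
        delta_cost=dc,
        delta_qaly=dq,
        base=base,
    )


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each threshold, the
    fraction of draws with non-negative incremental net monetary benefit."""
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    nmb = wtp[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp, "probability_cost_effective": prob})


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------


def scenario_societal(cfg: ModelConfig) -> ModelConfig:
    """Switch to the societal perspective: productivity losses (workdays lost
    x 8 h x EUR 29.80/h per state-year) are added to the cost side.  All
    other parameters are untouched."""
    if not cfg.indirect.workdays_lost_per_year_by_state:
        raise ValueError(
            "societal scenario requires workdays-lost-per-year inputs per health state"
        )
    out = cfg.copy()
    out.econ.perspective = PERSPECTIVE_SOCIETAL
    return out


def scenario_compliance(cfg: ModelConfig, rate: float = 0.9695) -> ModelConfig:
    """Reduced-compliance scenario: drug acquisition scales by the compliance
    rate; efficacy (and hence QALYs) is deliberately untouched."""
    if not 0.0 < rate <= 1.0:
        raise ValueError(f"compliance rate must lie in (0, 1], got {rate}")
    out = cfg.copy()
    out.drug.compliance = rate
    return out
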