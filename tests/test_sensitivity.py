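"""Tornado analysis, PSA sampling, acceptability curve, scenarios."""

import numpy as np
import pytest

from crswnp_cea import evaluate_config
from crswnp_cea.params import PERSPECTIVE_SOCIETAL
from crswnp_cea.sensitivity import (
    OWSAParam,
    PSADistributionSpec,
    ceac,
    default_psa_specs,
    owsa,
    psa,
    sample_parameter,
    scenario_compliance,
    scenario_societal,
    tornado_frame,
)


class TestOWSA:
    def test_degenerate_bounds_give_zero_span(self, cfg):
        p = OWSAParam("markov_utilities.u_controlled", 0.913, 0.913, 0.913)
        [entry] = owsa(cfg, [p])
        assert entry.span == pytest.approx(0.0)

    def test_inert_parameter_has_zero_span(self, cfg):
        """male_fraction feeds no downstream computation, so its tornado bar
        collapses."""
        p = OWSAParam.pm10(cfg, "demographics.male_fraction", clamp_unit=True)
        [entry] = owsa(cfg, [p])
        assert entry.span == pytest.approx(0.0)

    def test_intervention_only_cost_moves_icur_up(self, cfg):
        p = OWSAParam.pm10(cfg, "drug.price_per_administration")
        [entry] = owsa(cfg, [p])
        assert entry.icur_at_high > entry.icur_at_low

    def test_base_config_restored_between_runs(self, cfg):
        before = cfg.to_dict()
        owsa(cfg, [OWSAParam.pm10(cfg, "markov_state_costs.inadequate")])
        assert cfg.to_dict() == before

    def test_unknown_path_named_in_error(self, cfg):
        with pytest.raises(KeyError, match="nonexistent"):
            owsa(cfg, [OWSAParam("markov_utilities.nonexistent", 1, 0.5, 1.5)])

    def test_entries_sorted_by_span(self, cfg):
        entries = owsa(
            cfg,
            [
                OWSAParam.pm10(cfg, "drug.price_per_administration"),
                OWSAParam("demographics.male_fraction", 0.604, 0.604, 0.604),
            ],
        )
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)
        assert set(tornado_frame(entries).columns) == {
            "parameter", "low", "high", "icur_low", "icur_high", "span"
        }


class TestSampleParameter:
    def test_gamma_moment_matching(self):
        # mean 100, SE 10 -> shape 100, scale 1
        spec = PSADistributionSpec("x", "gamma", 100.0, 10.0)
        dist = spec.distribution()
        assert dist.kwds["a"] == pytest.approx(100.0)
        assert dist.kwds["scale"] == pytest.approx(1.0)

    def test_beta_moment_matching(self):
        # mean 0.5, SE 0.1 -> alpha = beta = 12
        spec = PSADistributionSpec("x", "beta", 0.5, 0.1)
        dist = spec.distribution()
        assert dist.kwds["a"] == pytest.approx(12.0)
        assert dist.kwds["b"] == pytest.approx(12.0)

    def test_zero_se_is_degenerate(self):
        spec = PSADistributionSpec("x", "beta", 0.3, 0.0)
        rng = np.random.default_rng(0)
        assert sample_parameter(spec, rng) == 0.3

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            PSADistributionSpec("x", "beta", 0.5, 0.6)

    def test_normal_is_truncated_to_unit_interval(self):
        spec = PSADistributionSpec("u", "normal", 0.95, 0.2)
        rng = np.random.default_rng(1)
        draws = sample_parameter(spec, rng, size=2000)
        assert np.all((draws >= 0) & (draws <= 1))

    def test_default_specs_cover_probabilities_utilities_costs(self, cfg):
        specs = default_psa_specs(cfg)
        fams = {s.path: s.family for s in specs}
        assert fams["sustained.annual_p_sustain"] == "beta"
        assert fams["markov_utilities.u_controlled"] == "normal"
        assert fams["markov_state_costs.inadequate"] == "gamma"
        assert fams["ae_items[0].rate_dup"] == "beta"
        # structural settings are excluded from the PSA
        assert not any(s.path.startswith("econ.") for s in specs)


class TestPSA:
    def test_same_seed_bitwise_identical(self, cfg):
        a = psa(cfg, n=8, seed=123)
        b = psa(cfg, n=8, seed=123)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)

    def test_different_seeds_differ(self, cfg):
        a = psa(cfg, n=4, seed=1)
        b = psa(cfg, n=4, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_all_zero_se_reproduces_base_case(self, cfg):
        specs = [
            PSADistributionSpec(s.path, s.family, s.mean, 0.0)
            for s in default_psa_specs(cfg)
        ]
        res = psa(cfg, n=3, seed=0, specs=specs)
        _, _, base = evaluate_config(cfg)
        assert np.allclose(res.delta_cost, base.delta_cost)
        assert np.allclose(res.delta_qaly, base.delta_qaly)

    def test_ce_plane_frame_shape(self, cfg):
        res = psa(cfg, n=5, seed=0)
        df = res.ce_plane_frame()
        assert list(df.columns) == ["draw", "delta_cost", "delta_qaly"]
        assert len(df) == 5


@pytest.fixture(scope="module")
def psa_result(bundle):
    return psa(bundle.config.copy(), n=60, seed=7)


class TestCEAC:

    def test_curve_is_a_probability(self, psa_result):
        curve = ceac(psa_result, [0, 10_000, 32_500, 100_000])
        p = curve["probability_cost_effective"]
        assert ((p >= 0) & (p <= 1)).all()

    def test_lambda_zero_counts_cost_saving_draws(self, psa_result):
        curve = ceac(psa_result, [0.0])
        expected = float(np.mean(psa_result.delta_cost <= 0))
        assert curve["probability_cost_effective"].iloc[0] == pytest.approx(expected)

    def test_large_lambda_counts_qaly_gaining_draws(self, psa_result):
        curve = ceac(psa_result, [1e12])
        dq, dc = psa_result.delta_qaly, psa_result.delta_cost
        expected = float(np.mean((dq > 0) | ((dq == 0) & (dc <= 0))))
        assert curve["probability_cost_effective"].iloc[0] == pytest.approx(expected)

    def test_monotone_when_all_draws_gain_qalys(self, psa_result):
        """Restricting the cloud to QALY-gaining draws makes the curve a
        non-decreasing threshold-crossing function of lambda."""
        import dataclasses as _dc

        keep = psa_result.delta_qaly > 0
        restricted = _dc.replace(
            psa_result,
            n=int(keep.sum()),
            samples=psa_result.samples[keep],
            delta_cost=psa_result.delta_cost[keep],
            delta_qaly=psa_result.delta_qaly[keep],
        )
        assert restricted.n > 0
        curve = ceac(restricted, list(np.linspace(0, 2e5, 40)))
        assert (np.diff(curve["probability_cost_effective"]) >= 0).all()

    def test_empty_grid_rejected(self, psa_result):
        with pytest.raises(ValueError):
            ceac(psa_result, [])


class TestScenarios:
    def test_societal_flips_perspective_only(self, cfg):
        scen = scenario_societal(cfg)
        assert scen.econ.perspective == PERSPECTIVE_SOCIETAL
        d_base, d_scen = cfg.to_dict(), scen.to_dict()
        d_base["econ"]["perspective"] = d_scen["econ"]["perspective"]
        assert d_base == d_scen

    def test_societal_requires_workdays(self, cfg):
        cfg.indirect.workdays_lost_per_year_by_state = {}
        with pytest.raises(ValueError, match="workdays"):
            scenario_societal(cfg)

    def test_zero_workdays_means_zero_indirect(self, cfg):
        cfg.indirect.workdays_lost_per_year_by_state = {
            k: 0.0 for k in cfg.indirect.workdays_lost_per_year_by_state
        }
        dup, bsc, _ = evaluate_config(scenario_societal(cfg))
        assert dup.costs.indirect == 0.0 and bsc.costs.indirect == 0.0

    def test_compliance_scales_drug_costs_exactly(self, cfg):
        dup_base, _, _ = evaluate_config(cfg)
        scen = scenario_compliance(cfg, 0.9695)
        dup_scen, _, _ = evaluate_config(scen)
        assert dup_scen.costs.drug_acquisition == pytest.approx(
            0.9695 * dup_base.costs.drug_acquisition
        )

    def test_full_compliance_is_identity(self, cfg):
        base = evaluate_config(cfg)
        scen = evaluate_config(scenario_compliance(cfg, 1.0))
        assert scen[2].delta_cost == pytest.approx(base[2].delta_cost)
        assert scen[2].delta_qaly == pytest.approx(base[2].delta_qaly)

    def test_compliance_leaves_qalys_untouched(self, cfg):
        base = evaluate_config(cfg)
        scen = evaluate_config(scenario_compliance(cfg, 0.9695))
        assert scen[0].qalys == pytest.approx(base[0].qalys)
        assert scen[1].qalys == pytest.approx(base[1].qalys)

    def test_out_of_range_rate_rejected(self, cfg):
        for bad in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                scenario_compliance(cfg, bad)
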