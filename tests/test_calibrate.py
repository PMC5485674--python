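"""Simulate-and-compare least squares: objectives and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import beanphen as bp
from beanphen.errors import ObjectiveError

from conftest import PLANTING, centered_params, genotype_with, make_constant_weather


@pytest.fixture(scope="module")
def small_world(params):
    """15 RILs on 2 synthetic sites with zero-noise observations."""
    sites = bp.gen_sites(bp.five_site_specs(seed=21)[:2], seed=21)
    pop = bp.gen_ril_markers(bp.SyntheticPopulationSpec(n_genotypes=15, seed=22))
    obs = bp.gen_observations(pop, sites, params, seed=23)
    return sites, pop, obs


class TestObjectives:
    def test_zero_at_generating_parameters(self, params, small_world):
        sites, pop, obs = small_world
        assert bp.ssq_flowering(params.rf, obs, pop, sites, params) == pytest.approx(
            0.0, abs=1e-18
        )
        assert bp.ssq_nodes(params.nar, obs, pop, sites, params) == pytest.approx(
            0.0, abs=1e-18
        )
        assert bp.ssq_final_nodes(
            params.msnodmax, obs, pop, sites, params
        ) == pytest.approx(0.0, abs=1e-18)

    def test_flowering_ssq_arithmetic(self, params, small_world):
        sites, pop, obs = small_world
        fl = obs[obs["obs_kind"] == "flowering_day_after_emergence"].copy()
        shifted = fl.head(2).copy()
        shifted.loc[shifted.index[0], "value"] += 2.0  # errors +2 and -2:
        shifted.loc[shifted.index[1], "value"] -= 2.0  # no cancellation
        assert bp.ssq_flowering(
            params.rf, shifted, pop, sites, params
        ) == pytest.approx(8.0, abs=1e-9)

    def test_flowering_ssq_matches_brute_force(self, params, small_world):
        """The objective equals a plain double loop over pairs, computed
        through the scalar (non-batch) engine."""
        sites, pop, obs = small_world
        rf = params.rf.with_params({"mu": 0.031})  # off-truth point
        expected = 0.0
        fl = obs[obs["obs_kind"] == "flowering_day_after_emergence"]
        by_site = {cfg.site_id: (cfg, w) for cfg, w in sites}
        shifted = params.replacing(rf)
        for row in fl.itertuples(index=False):
            cfg, weather = by_site[row.site_id]
            res = bp.simulate_genotype_site(
                pop.genotype(row.genotype_id), cfg, weather, shifted
            )
            sim = (
                res.anthesis_dae_frac
                if res.anthesis_dae_frac is not None
                else cfg.end_dap - cfg.emergence_dap
            )
            expected += (sim - row.value) ** 2
        actual = bp.ssq_flowering(rf, fl, pop, sites, params)
        assert actual == pytest.approx(expected, rel=1e-9)

    def test_node_ssq_single_observation(self, params):
        """Constant-environment check: simulated 2.52 nodes on day 10 vs an
        observed 2.0 gives (2.52 - 2.0)^2 = 0.2704."""
        oracle = centered_params(params, 21.35, 18.31, 12.7)
        weather = make_constant_weather(21.35, 18.31, 12.7, n_days=91)
        site = bp.SiteConfig("CONST", PLANTING, emergence_dap=0, end_dap=60)
        geno = genotype_with({"JC28": -1.0}, "g1")
        obs = pd.DataFrame(
            [["g1", "CONST", "node_count", 10, 2.0]],
            columns=["genotype_id", "site_id", "obs_kind", "obs_day", "value"],
        )
        ssq = bp.ssq_nodes(oracle.nar, obs, [geno], [(site, weather)], oracle)
        assert ssq == pytest.approx(0.2704, abs=1e-9)

    def test_final_node_ssq_at_means(self, params):
        """Ceiling 12.37 at the centering means vs observed 11.37 -> 1.0."""
        oracle = centered_params(params, 21.85, 18.74, 12.81)
        weather = make_constant_weather(21.85, 18.74, 12.81, n_days=91)
        site = bp.SiteConfig("CONST", PLANTING, emergence_dap=0, end_dap=60)
        geno = genotype_with({"JC28": -1.0}, "g1")
        obs = pd.DataFrame(
            [["g1", "CONST", "final_node_count", 40, 11.37]],
            columns=["genotype_id", "site_id", "obs_kind", "obs_day", "value"],
        )
        ssq = bp.ssq_final_nodes(
            oracle.msnodmax, obs, [geno], [(site, weather)], oracle
        )
        assert ssq == pytest.approx(1.0, abs=1e-9)

    def test_observation_before_emergence_excluded(self, params, caplog):
        oracle = centered_params(params, 21.35, 18.31, 12.7)
        weather = make_constant_weather(21.35, 18.31, 12.7, n_days=91)
        site = bp.SiteConfig("CONST", PLANTING, emergence_dap=7, end_dap=60)
        geno = genotype_with({"JC28": -1.0}, "g1")
        obs = pd.DataFrame(
            [
                ["g1", "CONST", "node_count", 3, 1.0],  # before emergence
                ["g1", "CONST", "node_count", 17, 2.52],
            ],
            columns=["genotype_id", "site_id", "obs_kind", "obs_day", "value"],
        )
        with caplog.at_level("WARNING"):
            ssq = bp.ssq_nodes(oracle.nar, obs, [geno], [(site, weather)], oracle)
        assert "excluded" in caplog.text
        assert ssq == pytest.approx(0.0, abs=1e-18)

    def test_empty_objective_raises(self, params, small_world):
        sites, pop, _ = small_world
        empty = pd.DataFrame(
            columns=["genotype_id", "site_id", "obs_kind", "obs_day", "value"]
        )
        with pytest.raises(ObjectiveError):
            bp.ssq_flowering(params.rf, empty, pop, sites, params)


class TestFitModule:
    def test_zero_free_parameters_degenerate(self, params, small_world):
        sites, pop, obs = small_world
        spec = bp.FitSpec(trait="NAR", free_parameters=[])
        fit = bp.fit_module(spec, obs, pop, sites, base_params=params)
        assert fit.converged
        assert fit.estimates == {}
        assert fit.ssq == pytest.approx(0.0, abs=1e-18)

    def test_zero_noise_recovery_from_perturbed_start(self, params, small_world):
        sites, pop, obs = small_world
        truth = params.nar
        start = truth.with_params(
            {n: truth.get_param(n) * 1.2 for n in truth.param_names()}
        )
        fit = bp.fit_module(
            bp.FitSpec(trait="NAR", initial=start), obs, pop, sites, params
        )
        assert fit.converged
        for name in truth.param_names():
            assert fit.estimates[name] == pytest.approx(
                truth.get_param(name), abs=1e-6
            )

    def test_partial_fit_keeps_frozen_parameters(self, params, small_world):
        sites, pop, obs = small_world
        truth = params.nar
        start = truth.with_params({"mu": truth.mu * 1.3})
        spec = bp.FitSpec(trait="NAR", free_parameters=["mu"], initial=start)
        fit = bp.fit_module(spec, obs, pop, sites, params)
        assert fit.estimates["mu"] == pytest.approx(truth.mu, abs=1e-6)
        assert fit.parameters.env_terms == truth.env_terms

    def test_standard_errors_shrink_with_replication(self, params, small_world):
        """Replicating every observation k-fold shrinks reported standard
        errors by about 1/sqrt(k)."""
        sites, pop, _ = small_world
        rng_obs = bp.gen_observations(
            pop, sites, params, noise=bp.ObservationNoise(node_sd=0.5), seed=77
        )
        nodes = rng_obs[rng_obs["obs_kind"] == "node_count"]
        spec = bp.FitSpec(trait="NAR", free_parameters=["mu", "env:TMEAN"])
        fit1 = bp.fit_module(spec, nodes, pop, sites, params)
        rep4 = pd.concat([nodes] * 4, ignore_index=True)
        fit4 = bp.fit_module(spec, rep4, pop, sites, params)
        ratio = fit4.standard_errors["mu"] / fit1.standard_errors["mu"]
        assert ratio == pytest.approx(0.5, rel=0.15)
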