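"""Daily integration: flowering, node accumulation, ceiling, determinacy.

The constant-environment closed form is the main oracle here: with every
covariate pinned at the module means, the daily rates are constant, so
anthesis falls on the smallest integer n with n * RF >= 1 and the node
trajectory is min(NAR * days-since-emergence, ceiling).
"""

import dataclasses
import datetime as dt
import math

import numpy as np
import pytest

import beanphen as bp
from beanphen.errors import DeterminacyError

from conftest import PLANTING, centered_params, genotype_with, make_constant_weather

SITE = bp.SiteConfig("CONST", PLANTING, emergence_dap=0, end_dap=60)


@pytest.fixture(scope="module")
def oracle_params(params):
    # all modules centered at one covariate point: rates are exactly the
    # module means under constant weather at that point
    return centered_params(params, 21.35, 18.31, 12.7)


@pytest.fixture(scope="module")
def oracle_weather():
    return make_constant_weather(21.35, 18.31, 12.7, n_days=91)


class TestDeterminacy:
    def test_jamapa_allele_is_indeterminate(self, indeterminate_genotype):
        assert bp.determinacy_of(indeterminate_genotype) == "indeterminate"

    def test_calima_allele_is_determinate(self, determinate_genotype):
        assert bp.determinacy_of(determinate_genotype) == "determinate"

    def test_missing_marker_without_tie_region_errors(self):
        geno = genotype_with({})  # all markers 0
        with pytest.raises(DeterminacyError):
            bp.determinacy_of(geno, tie_region=False)

    def test_tied_region_fallback(self):
        geno = genotype_with({"TF2": -1.0, "MSN2": -1.0, "NAR2": -1.0})
        assert bp.determinacy_of(geno) == "indeterminate"


class TestConstantEnvironmentOracle:
    def test_flowering_day_is_ceiling_of_reciprocal_rate(
        self, oracle_params, oracle_weather, indeterminate_genotype
    ):
        res = bp.simulate_genotype_site(
            indeterminate_genotype, SITE, oracle_weather, oracle_params
        )
        assert res.anthesis_dae == math.ceil(1 / 0.029) == 35
        assert res.anthesis_dae_frac == pytest.approx(1 / 0.029)
        assert res.tf_cum[1] == pytest.approx(0.029)

    def test_indeterminate_nodes_linear_to_ceiling(
        self, oracle_params, oracle_weather, indeterminate_genotype
    ):
        res = bp.simulate_genotype_site(
            indeterminate_genotype, SITE, oracle_weather, oracle_params
        )
        # linear phase: nodes(t) = 0.252 t, e.g. 2.52 nodes on day 10
        assert res.nodes_at(10) == pytest.approx(2.52)
        days = np.arange(0, 61)
        expected = np.minimum(0.252 * days, 12.37)
        assert np.allclose(res.nodes, expected)
        # ceiling 12.37 first reached on day 50 (12.37 / 0.252 = 49.08)
        assert res.nodes[49] < 12.37
        assert res.nodes[50] == pytest.approx(12.37)
        assert res.n_final == pytest.approx(12.37)

    def test_determinate_nodes_stop_at_anthesis(
        self, oracle_params, oracle_weather, determinate_genotype
    ):
        res = bp.simulate_genotype_site(
            determinate_genotype, SITE, oracle_weather, oracle_params
        )
        assert res.anthesis_dae == 35
        assert res.n_final == pytest.approx(35 * 0.252)
        # frozen thereafter
        assert np.all(res.nodes[35:] == res.nodes[35])

    def test_zero_rate_never_flowers(
        self, oracle_params, oracle_weather, indeterminate_genotype
    ):
        rf_zero = oracle_params.rf.with_params(
            {n: 0.0 for n in oracle_params.rf.param_names()}
        )
        params = oracle_params.replacing(rf_zero)
        res = bp.simulate_genotype_site(
            indeterminate_genotype, SITE, oracle_weather, params
        )
        assert res.never_flowered
        assert res.anthesis_dae is None

    def test_emergence_offset_bookkeeping(
        self, oracle_params, oracle_weather, indeterminate_genotype
    ):
        site = bp.SiteConfig("CONST", PLANTING, emergence_dap=7, end_dap=67)
        res = bp.simulate_genotype_site(
            indeterminate_genotype, site, oracle_weather, oracle_params
        )
        assert res.anthesis_dae == 35
        assert res.anthesis_dap == 42
        assert res.nodes_at(7) == 0.0  # initialized at emergence
        assert res.nodes_at(17) == pytest.approx(2.52)


@pytest.fixture(scope="module")
def population_runs(params):
    sites = bp.gen_sites(bp.five_site_specs(seed=42), seed=42)
    pop = bp.gen_ril_markers(bp.SyntheticPopulationSpec(n_genotypes=12, seed=5))
    return bp.simulate_population(pop, sites, params)


class TestTrajectoryInvariants:

    def test_monotone_development_and_nodes(self, population_runs):
        for res in population_runs:
            assert np.all(np.diff(res.tf_cum) >= -1e-12)
            assert np.all(np.diff(res.nodes) >= -1e-12)

    def test_nodes_respect_ceiling(self, population_runs):
        for res in population_runs:
            # never above the highest ceiling seen so far
            assert np.all(res.nodes <= np.maximum.accumulate(res.msnodmax) + 1e-9)

    def test_ceiling_frozen_after_anthesis(self, population_runs):
        for res in population_runs:
            if res.anthesis_dae is None:
                continue
            k = res.anthesis_dae  # index within emergence..end
            assert np.all(res.msnodmax[k:] == res.msnodmax[k])

    def test_determinacy_contract_on_variable_weather(
        self, params, determinate_genotype, indeterminate_genotype
    ):
        cfg, weather = bp.gen_sites(bp.five_site_specs(seed=42), seed=42)[0]
        det = bp.simulate_genotype_site(determinate_genotype, cfg, weather, params)
        ind = bp.simulate_genotype_site(indeterminate_genotype, cfg, weather, params)
        assert det.anthesis_dae is not None and ind.anthesis_dae is not None
        k = det.anthesis_dae
        assert np.all(det.nodes[k:] == det.nodes[k])
        # the indeterminate genotype keeps adding nodes after anthesis,
        # up to (never beyond) the frozen ceiling
        assert ind.nodes[-1] > ind.nodes[ind.anthesis_dae]
        assert ind.nodes[-1] <= ind.msnodmax[-1] + 1e-9

    def test_longer_days_never_hasten_flowering(self, params, indeterminate_genotype):
        # markers off: the DL main effect and TMEAN x DL at mean TMEAN both
        # slow development, so +1 h day length cannot advance anthesis
        base = make_constant_weather(21.35, 18.31, 12.7, n_days=121)
        longer = make_constant_weather(21.35, 18.31, 13.7, n_days=121)
        site = bp.SiteConfig("CONST", PLANTING, emergence_dap=0, end_dap=120)
        a1 = bp.simulate_genotype_site(
            indeterminate_genotype, site, base, params
        ).anthesis_dae
        a2 = bp.simulate_genotype_site(
            indeterminate_genotype, site, longer, params
        ).anthesis_dae
        assert a2 >= a1


class TestPopulation:
    def test_cardinality(self, params):
        sites = bp.gen_sites(bp.five_site_specs(seed=1)[:2], seed=1)
        pop = bp.gen_ril_markers(
            bp.SyntheticPopulationSpec(n_genotypes=2, include_parents=False, seed=2)
        )
        results = bp.simulate_population(pop, sites, params)
        assert len(results) == 4

    def test_order_independence(self, params):
        sites = bp.gen_sites(bp.five_site_specs(seed=1)[:1], seed=1)
        pop = bp.gen_ril_markers(bp.SyntheticPopulationSpec(n_genotypes=5, seed=2))
        fwd = bp.simulate_population(pop, sites, params)
        rev_frame = pop.frame.iloc[::-1]
        rev = bp.simulate_population(
            bp.MarkerTable(rev_frame), sites, params
        )
        by_id = {r.genotype_id: r for r in rev}
        for r in fwd:
            assert np.array_equal(r.nodes, by_id[r.genotype_id].nodes)
            assert r.anthesis_dae == by_id[r.genotype_id].anthesis_dae

    def test_msn2_calima_allele_lowers_final_nodes(self, params, oracle_weather):
        """Under identical weather, a genotype with the Calima haplotype at
        the chromosome-1 region (determinate, MSN2 = +1) finishes with no
        more main-stem nodes than its Jamapa counterpart."""
        calima_like = genotype_with(
            {"JC28": 1.0, "TF2": 1.0, "MSN2": 1.0, "NAR2": 1.0}, "cal"
        )
        jamapa_like = genotype_with(
            {"JC28": -1.0, "TF2": -1.0, "MSN2": -1.0, "NAR2": -1.0}, "jam"
        )
        det = bp.simulate_genotype_site(calima_like, SITE, oracle_weather, params)
        ind = bp.simulate_genotype_site(jamapa_like, SITE, oracle_weather, params)
        assert det.n_final <= ind.n_final


class TestBatchEquivalence:
    def test_batch_matches_scalar_engine(self, params):
        sites = bp.gen_sites(bp.five_site_specs(seed=9)[:3], seed=9)
        pop = bp.gen_ril_markers(bp.SyntheticPopulationSpec(n_genotypes=15, seed=3))
        genotypes = pop.genotypes()
        for cfg, weather in sites:
            batch = bp.simulate_site_batch(genotypes, cfg, weather, params)
            for i, geno in enumerate(genotypes):
                scalar = bp.simulate_genotype_site(geno, cfg, weather, params)
                assert np.allclose(batch.tf_cum[i], scalar.tf_cum, atol=1e-9)
                assert np.allclose(batch.nodes[i], scalar.nodes, atol=1e-9)
                assert np.allclose(batch.msnodmax[i], scalar.msnodmax, atol=1e-9)
                if scalar.anthesis_dae is None:
                    assert batch.anthesis_dae[i] == -1
                else:
                    assert batch.anthesis_dae[i] == scalar.anthesis_dae
                    assert batch.anthesis_dae_frac[i] == pytest.approx(
                        scalar.anthesis_dae_frac
                    )
                assert batch.n_final[i] == pytest.approx(scalar.n_final)
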