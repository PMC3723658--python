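"""Gibbs sampler: design assembly, conjugate correctness, recovery, chains."""

import numpy as np
import pandas as pd
import pytest

from nestlingqg.gibbs import (
    MCMCSettings,
    ModelSpec,
    PriorSpec,
    autocorrelation,
    build_design,
    run_gibbs,
)
from nestlingqg.simdata import SimConfig, TraitArchitecture, simulate_population
from nestlingqg.studies import conjugate_check


class TestBuildDesign:
    def test_univariate_response_covers_every_nestling(self, population):
        design = build_design(population, ModelSpec(response="hue"))
        assert len(design.y) == len(population)
        assert design.fixed_names[0] == "(Intercept)"
        assert "sex[male]" in design.fixed_names

    def test_bivariate_streams_partition_by_sex(self, population):
        spec = ModelSpec(response="hue", form="bivariate", fixed=("treatment", "year"))
        design = build_design(population, spec)
        n_male = (population["sex"] == "male").sum()
        mu_f = design.X[:, design.fixed_names.index("mu[female]")]
        mu_m = design.X[:, design.fixed_names.index("mu[male]")]
        assert mu_m.sum() == n_male
        assert mu_f.sum() == len(population) - n_male
        assert ((mu_f + mu_m) == 1).all()

    def test_single_level_factor_dropped_with_warning(self, population):
        one_year = population[population["year"] == population["year"].iloc[0]]
        with pytest.warns(UserWarning, match="single level"):
            design = build_design(one_year, ModelSpec(response="hue"))
        assert not any(n.startswith("year") for n in design.fixed_names)

    def test_unknown_sex_code_rejected(self, population):
        bad = population.copy()
        bad.loc[bad.index[0], "sex"] = "unknown"
        with pytest.raises(ValueError, match="sex code"):
            build_design(bad, ModelSpec(response="hue"))

    def test_rearing_outside_dyad_rejected(self, population):
        bad = population.copy()
        foreign = bad.loc[bad["dyad"] != bad["dyad"].iloc[0], "origin"].iloc[0]
        bad.loc[bad.index[0], "rearing"] = foreign
        with pytest.raises(ValueError, match="outside"):
            build_design(bad, ModelSpec(response="hue"))

    def test_bivariate_rejects_sex_as_fixed_effect(self):
        with pytest.raises(ValueError, match="sex"):
            ModelSpec(response="hue", form="bivariate", fixed=("treatment", "sex"))


class TestSampler:
    def test_fixed_effects_match_conjugate_closed_form(self):
        res = conjugate_check(seed=5, n_obs=300, n_draws=1500)
        assert res["max_abs_z"] < 3.0

    def test_origin_variance_recovery(self):
        # ~500 origin nests of ~10 nestlings, V_O = 4 (shared across sexes), V_Res = 1
        arch = TraitArchitecture(
            v_origin_m=4.0,
            v_origin_f=4.0,
            cov_mf=4.0,
            v_rearing_m=0.0,
            v_rearing_f=0.0,
            v_dyad_m=0.0,
            v_dyad_f=0.0,
            v_residual_m=1.0,
            v_residual_f=1.0,
        )
        cfg = SimConfig(n_dyads=250, mean_brood=10.0, traits={"t": arch}, seed=31)
        pop = simulate_population(cfg)
        settings = MCMCSettings(n_iterations=2000, burn_in=500, thinning=3, seed=7)
        samples = run_gibbs(build_design(pop, ModelSpec(response="t")), PriorSpec(), settings)
        chain = samples.draws["V_origin"]
        assert abs(chain.mean() - 4.0) < 3 * chain.std()

    def test_identical_seed_gives_bit_identical_chains(self, population):
        spec = ModelSpec(response="hue")
        settings = MCMCSettings(n_iterations=400, burn_in=100, thinning=2, seed=42)
        a = run_gibbs(build_design(population, spec), PriorSpec(), settings)
        b = run_gibbs(build_design(population, spec), PriorSpec(), settings)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_variance_draws_strictly_positive(self, uni_samples, bi_samples):
        for samples in (uni_samples, bi_samples):
            for col in samples.variance_columns:
                if col.startswith("V_"):
                    assert (samples.draws[col] > 0).all()

    def test_origin_block_positive_definite_every_draw(self, bi_samples):
        d = bi_samples.draws
        det = d["V_origin_M"] * d["V_origin_F"] - d["COV_origin_MF"] ** 2
        assert (det > 0).all()
        rmf = d["COV_origin_MF"] / np.sqrt(d["V_origin_M"] * d["V_origin_F"])
        assert (rmf.abs() < 1).all()

    def test_prior_dominates_without_data_signal(self):
        # huge degree of belief: posterior residual variance pinned to the prior scale
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "t": rng.normal(0.0, 1.0, 12),
                "sex": ["male", "female"] * 6,
                "treatment": ["control"] * 12,
                "year": ["2007"] * 12,
            }
        )
        spec = ModelSpec(response="t", fixed=(), random=())
        prior = PriorSpec(variance_scale=3.0, nu=1e6)
        settings = MCMCSettings(n_iterations=600, burn_in=100, thinning=1, seed=2)
        samples = run_gibbs(build_design(table, spec), prior, settings)
        assert samples.draws["V_residual"].mean() == pytest.approx(3.0, rel=0.02)


class TestAutocorrelation:
    def test_lag_zero_is_one_and_iid_decays(self):
        rng = np.random.default_rng(12)
        acf = autocorrelation(rng.standard_normal(20000), max_lag=3)
        assert acf[0] == 1.0
        assert abs(acf[1]) < 0.03

    def test_ar1_process_recovered(self):
        rng = np.random.default_rng(8)
        n, phi = 50000, 0.5
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.standard_normal()
        acf = autocorrelation(x, max_lag=2)
        assert acf[1] == pytest.approx(phi, abs=0.03)

    def test_constant_chain_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            acf = autocorrelation(np.ones(100), max_lag=5)
        assert np.isnan(acf).all()

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.arange(5.0), max_lag=10)
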