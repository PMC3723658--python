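"""Synthetic cross-fostered population generator."""

import numpy as np
import pandas as pd
import pytest

from nestlingqg.simdata import (
    SimConfig,
    TraitArchitecture,
    apply_epp,
    assign_treatment,
    cross_foster,
    default_traits,
    read_nestlings_csv,
    simulate_population,
    write_nestlings_csv,
)


def _flat_arch(**over):
    base = dict(
        v_origin_m=0.0,
        v_origin_f=0.0,
        cov_mf=0.0,
        v_rearing_m=0.0,
        v_rearing_f=0.0,
        v_dyad_m=0.0,
        v_dyad_f=0.0,
        v_residual_m=0.0,
        v_residual_f=0.0,
    )
    base.update(over)
    return TraitArchitecture(**base)


def _two_nest_population(brood_a, brood_b, dyad="d0", nests=("nA", "nB")):
    rows = []
    for nest, brood in zip(nests, (brood_a, brood_b)):
        for c in range(brood):
            rows.append(
                {
                    "nestling_id": f"{nest}_c{c}",
                    "origin": nest,
                    "rearing": nest,
                    "dyad": dyad,
                    "sex": "male" if c % 2 else "female",
                    "year": "2007",
                    "treatment": "control",
                }
            )
    return pd.DataFrame(rows)


class TestSimulatePopulation:
    def test_25_dyads_give_50_analysis_nests(self):
        pop = simulate_population(SimConfig(n_dyads=25, seed=4))
        assert pop["origin"].nunique() == 50
        assert pop["rearing"].nunique() == 50
        assert pop["dyad"].nunique() == 25

    def test_zero_variance_population_is_pure_intercept(self):
        arch = _flat_arch(intercept=7.5)
        pop = simulate_population(SimConfig(n_dyads=4, traits={"t": arch}, seed=0))
        np.testing.assert_allclose(pop["t"], 7.5)

    def test_male_origin_variance_matches_configured_value(self):
        arch = _flat_arch(v_origin_m=1.0, v_origin_f=1.0, v_residual_m=0.01, v_residual_f=0.01)
        cfg = SimConfig(n_dyads=2000, mean_brood=4.0, traits={"t": arch}, seed=9)
        pop = simulate_population(cfg)
        males = pop[pop["sex"] == "male"]
        per_nest = males.groupby("origin")["_t_origin"].first()
        assert per_nest.var() == pytest.approx(1.0, abs=0.08)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_dyads=5, seed=13)
        pd.testing.assert_frame_equal(simulate_population(cfg), simulate_population(cfg))

    def test_total_variance_decomposes(self):
        arch = _flat_arch(
            v_origin_m=1.0,
            v_origin_f=1.0,
            cov_mf=0.3,
            v_rearing_m=0.5,
            v_rearing_f=0.5,
            v_dyad_m=0.7,
            v_dyad_f=0.7,
            v_residual_m=2.0,
            v_residual_f=2.0,
        )
        cfg = SimConfig(n_dyads=1500, mean_brood=6.0, traits={"t": arch}, seed=21)
        pop = simulate_population(cfg)
        assert pop["t"].var() == pytest.approx(1.0 + 0.5 + 0.7 + 2.0, rel=0.06)

    def test_perfect_cross_sex_covariance_ranks_identically(self):
        arch = _flat_arch(v_origin_m=2.0, v_origin_f=2.0, cov_mf=2.0)
        cfg = SimConfig(n_dyads=100, traits={"t": arch}, seed=5)
        pop = simulate_population(cfg)
        by_nest = pop.groupby(["origin", "sex"])["_t_origin"].first().unstack()
        both = by_nest.dropna()
        rho = both["male"].corr(both["female"], method="spearman")
        assert rho == pytest.approx(1.0)

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError, match="cov_mf"):
            TraitArchitecture(v_origin_m=1.0, v_origin_f=1.0, cov_mf=1.5)


class TestCrossFoster:
    def test_half_brood_swapped(self):
        pop = _two_nest_population(8, 8)
        out = cross_foster(pop, seed=0)
        moved = out[out["origin"] != out["rearing"]]
        assert len(moved[moved["origin"] == "nA"]) == 4
        assert len(moved[moved["origin"] == "nB"]) == 4

    def test_single_chick_brood_never_moves(self):
        pop = _two_nest_population(1, 1)
        out = cross_foster(pop, seed=0)
        assert (out["origin"] == out["rearing"]).all()

    def test_swap_is_an_involution(self):
        pop = _two_nest_population(7, 8)
        once = cross_foster(pop, seed=3)
        twice = cross_foster(once, seed=3)
        pd.testing.assert_series_equal(twice["rearing"], pop["rearing"])

    def test_only_rearing_labels_move(self):
        arch = _flat_arch(v_residual_m=1.0, v_residual_f=1.0)
        pop = simulate_population(SimConfig(n_dyads=6, traits={"t": arch}, seed=2))
        refostered = cross_foster(pop, seed=99)
        pd.testing.assert_series_equal(refostered["origin"], pop["origin"])
        pd.testing.assert_series_equal(refostered["t"], pop["t"])

    def test_unpaired_dyad_rejected(self):
        pop = _two_nest_population(4, 4)
        with pytest.raises(ValueError, match="expected exactly 2"):
            cross_foster(pop[pop["origin"] == "nA"], seed=0)

    def test_unbalanced_broods_warned(self):
        pop = _two_nest_population(3, 8)
        with pytest.warns(UserWarning, match="differ by more than 1"):
            cross_foster(pop, seed=0)


class TestAssignTreatment:
    def test_one_enlarged_nest_per_dyad(self):
        pop = simulate_population(SimConfig(n_dyads=25, seed=8))
        out = assign_treatment(pop, seed=1)
        per_nest = out.groupby("rearing")["treatment"].first()
        assert (per_nest == "enlarged").sum() == 25
        assert (per_nest == "control").sum() == 25
        per_dyad = out.groupby("dyad").apply(
            lambda s: s.loc[s["treatment"] == "enlarged", "rearing"].nunique(),
            include_groups=False,
        )
        assert (per_dyad == 1).all()

    def test_deterministic(self):
        pop = _two_nest_population(4, 4)
        pd.testing.assert_frame_equal(
            assign_treatment(pop, seed=5), assign_treatment(pop, seed=5)
        )

    def test_each_nest_enlarged_about_half_the_time(self):
        pop = _two_nest_population(4, 4)
        hits = 0
        n = 400
        for seed in range(n):
            out = assign_treatment(pop, seed=seed)
            hits += (out.loc[out["rearing"] == "nA", "treatment"] == "enlarged").iloc[0]
        assert 0.4 < hits / n < 0.6


class TestApplyEpp:
    def _cfg(self, **arch_over):
        arch = _flat_arch(v_origin_m=1.0, v_origin_f=1.0, cov_mf=1.0, **arch_over)
        return SimConfig(n_dyads=400, mean_brood=6.0, traits={"t": arch}, seed=17)

    def test_rate_zero_is_identity(self):
        cfg = self._cfg()
        pop = simulate_population(cfg)
        pd.testing.assert_frame_equal(apply_epp(pop, 0.0, cfg, seed=1), pop)

    def test_contaminated_fraction_matches_rate(self):
        cfg = self._cfg()
        pop = simulate_population(cfg)
        out = apply_epp(pop, 0.08, cfg, seed=2)
        frac = (out["_t_origin"] != pop["_t_origin"]).mean()
        assert frac == pytest.approx(0.08, abs=0.02)

    def test_full_contamination_destroys_sib_resemblance(self):
        from nestlingqg.colour import repeatability

        cfg = self._cfg()
        pop = simulate_population(cfg)
        males = pop[pop["sex"] == "male"]
        keep = males.groupby("origin").filter(lambda s: len(s) >= 2)
        icc_before = repeatability(keep["_t_origin"], keep["origin"]).icc
        out = apply_epp(pop, 1.0, cfg, seed=3)
        males_after = out.loc[keep.index]
        icc_after = repeatability(males_after["_t_origin"], males_after["origin"]).icc
        assert icc_before == pytest.approx(1.0)
        assert icc_after < 0.1


class TestConfigAndIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(n_dyads=7, epp_rate=0.08, seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg

    def test_csv_round_trip_drops_private_columns(self, tmp_path):
        pop = simulate_population(SimConfig(n_dyads=3, seed=6))
        path = tmp_path / "pop.csv"
        write_nestlings_csv(pop, path)
        back = read_nestlings_csv(path)
        assert not any(c.startswith("_") for c in back.columns)
        assert set(default_traits()) <= set(back.columns)
        assert len(back) == len(pop)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_dyads=0)
        with pytest.raises(ValueError):
            SimConfig(epp_rate=1.5)
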