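"""Growth optimization, profiles, drain FVA and chemostat sweeps on toys.

Every quantitative expectation is cross-checked against exhaustive vertex
enumeration of the reduced route LP (the toy oracle), an independent solution
path from the cobra/GLPK models under test.
"""

import numpy as np
import pytest

from acidfba import (TOYEC1, build_acidfba, build_xi, make_toy_ecgem,
                     make_uniform_variant, mass_closure_gap)
from acidfba.amino_acids import AA_CODES
from acidfba.simulate import (AminoAcidProfile, Condition,
                              aa_profile_at_optimum, chemostat_sweep,
                              compare_modes, drain_fva, maximize_growth,
                              min_pool_at_growth)
from acidfba.toys import min_pool_oracle, toy_oracle

A, G = AA_CODES.index("A"), AA_CODES.index("G")


def oracle_profile(spec, routes):
    """Drain masses implied by route fluxes: a = xi^T e with e_k = v_k/kcat_k."""
    mass = np.zeros(20)
    for enz, v in zip(spec.enzymes, routes):
        e_k = v / enz.kcat
        from acidfba.amino_acids import count_residues, _RESIDUE_MASS_VECTOR
        mass += e_k * count_residues(enz.sequence) * _RESIDUE_MASS_VECTOR / 1000
    return mass


class TestMaximizeGrowth:
    def test_matches_vertex_enumeration(self, toyec1_acid):
        oracle = toy_oracle(TOYEC1)
        sol = maximize_growth(toyec1_acid)
        assert sol.objective == pytest.approx(oracle.objective, rel=1e-8)
        assert sol.objective == pytest.approx(6.476, abs=5e-4)

    def test_zero_pool_means_zero_growth(self):
        ec, proteins = make_toy_ecgem(TOYEC1.with_(pool_bound=0.0))
        acid = build_acidfba(ec, build_xi(proteins))
        assert maximize_growth(acid).objective == pytest.approx(0.0, abs=1e-9)

    def test_huge_pool_leaves_uptake_limited_optimum(self):
        spec = TOYEC1.with_(pool_bound=1.0e4)
        ec, proteins = make_toy_ecgem(spec)
        acid = build_acidfba(ec, build_xi(proteins))
        assert maximize_growth(acid).objective == pytest.approx(
            toy_oracle(spec).objective, rel=1e-8)
        assert maximize_growth(acid).objective == pytest.approx(10.0, rel=1e-8)

    def test_monotone_in_pool_bound(self):
        previous = -1.0
        for bound in (0.0, 0.002, 0.005, 0.01, 0.05, 1.0):
            ec, proteins = make_toy_ecgem(TOYEC1.with_(pool_bound=bound))
            acid = build_acidfba(ec, build_xi(proteins))
            growth = maximize_growth(acid).objective
            assert growth >= previous - 1e-9
            assert growth == pytest.approx(
                toy_oracle(TOYEC1.with_(pool_bound=bound)).objective, rel=1e-8,
                abs=1e-12)
            previous = growth


class TestProfileAtOptimum:
    def test_masses_match_oracle_vertex(self, toyec1_acid):
        oracle = toy_oracle(TOYEC1)
        sol, profile = aa_profile_at_optimum(toyec1_acid)
        expected = oracle_profile(TOYEC1, oracle.solution)
        np.testing.assert_allclose(profile.mass, expected, rtol=1e-6,
                                   atol=1e-12)
        assert profile.mass[A] == pytest.approx(0.00839, abs=5e-6)
        assert profile.mass[G] == pytest.approx(0.00161, abs=5e-6)
        # the whole pool is spent at the pool-limited optimum
        assert profile.total == pytest.approx(0.01, rel=1e-6)

    def test_fractions_normalized(self, toyec1_acid):
        _, profile = aa_profile_at_optimum(toyec1_acid)
        assert profile.fraction.sum() == pytest.approx(1.0, rel=1e-9)
        assert profile.fraction[A] == pytest.approx(0.839, abs=1e-3)

    def test_zero_growth_needs_no_proteome(self, toyec1_acid):
        _, profile = aa_profile_at_optimum(toyec1_acid, opt_fraction=0.0)
        assert profile.total == pytest.approx(0.0, abs=1e-9)

    def test_mass_closure(self, toyec1_acid):
        sol, _ = aa_profile_at_optimum(toyec1_acid, 0.99)
        assert mass_closure_gap(toyec1_acid, sol.fluxes) <= 1e-9


class TestMinPoolAtGrowth:
    @pytest.mark.parametrize("mu", [1.0, 3.0, 5.0, 6.0])
    def test_matches_oracle(self, toyec1_acid, mu):
        sol = min_pool_at_growth(toyec1_acid, mu)
        assert sol.ok
        assert sol.objective == pytest.approx(
            min_pool_oracle(TOYEC1, mu).objective, rel=1e-8)
        assert mass_closure_gap(toyec1_acid, sol.fluxes) <= 1e-9

    def test_cheapest_route_at_low_growth(self, toyec1_acid):
        # E2 costs 2 x 0.228208/1000 g per unit biomass
        sol = min_pool_at_growth(toyec1_acid, 3.0)
        assert sol.objective == pytest.approx(2 * 3.0 * 0.228208 / 1000,
                                              rel=1e-9)

    def test_pool_binds_at_maximum_growth(self, toyec1_acid):
        z_star = toy_oracle(TOYEC1).objective
        sol = min_pool_at_growth(toyec1_acid, z_star)
        assert sol.objective == pytest.approx(0.01, rel=1e-6)

    def test_above_maximum_is_infeasible(self, toyec1_acid):
        z_star = toy_oracle(TOYEC1).objective
        sol = min_pool_at_growth(toyec1_acid, 1.1 * z_star)
        assert not sol.ok
        assert sol.status == "infeasible"


class TestDrainFVA:
    def test_point_solution_inside_every_range(self, toyec1_acid):
        ranges = drain_fva(toyec1_acid, 0.99)
        _, profile = aa_profile_at_optimum(toyec1_acid, 0.99)
        for i, code in enumerate(AA_CODES):
            assert ranges.loc[code, "minimum"] - 1e-9 <= profile.mass[i]
            assert profile.mass[i] <= ranges.loc[code, "maximum"] + 1e-9

    def test_absent_amino_acids_are_pinned_to_zero(self, toyec1_acid):
        ranges = drain_fva(toyec1_acid, 0.99)
        for code in set(AA_CODES) - {"A", "G"}:
            assert ranges.loc[code, "minimum"] == pytest.approx(0.0, abs=1e-12)
            assert ranges.loc[code, "maximum"] == pytest.approx(0.0, abs=1e-12)
            assert np.isnan(ranges.loc[code, "rel_variability"])

    def test_uniform_variant_collapses_variability(self, enzyme_limited_acid):
        acid, _ = enzyme_limited_acid
        uni = make_uniform_variant(acid, np.full(20, 0.05))
        ranges = drain_fva(uni, 0.99)
        rel = ranges["rel_variability"].to_numpy()
        assert np.all(np.isfinite(rel))
        # all drains share one variability, set purely by the 1% slack
        assert rel.max() - rel.min() <= 1e-6
        assert 0.005 <= rel.mean() <= 0.02
        assert rel.mean() == pytest.approx(0.01 / 0.995, rel=1e-6)


class TestChemostatSweep:
    def test_profiles_shift_once_uptake_saturates(self, toyec1_acid):
        z_star = toy_oracle(TOYEC1).objective
        grid = [1.0, 3.0, 5.0, 6.0, z_star]
        curve = chemostat_sweep(toyec1_acid, grid, lambda mu: 0.01)
        assert curve.feasible.all()
        fractions = curve.fractions
        # below the uptake limit the cheap Gly-only enzyme carries everything
        for mu in (1.0, 3.0, 5.0):
            assert fractions.loc[mu, "G"] == pytest.approx(1.0, rel=1e-6)
        # beyond it the Ala-rich enzyme must contribute
        assert fractions.loc[6.0, "A"] > 0.1
        np.testing.assert_allclose(
            curve.pool_use[:-1],
            [min_pool_oracle(TOYEC1, mu).objective for mu in grid[:-1]],
            rtol=1e-6)

    def test_critical_rate_is_where_pool_binds(self, toyec1_acid):
        z_star = toy_oracle(TOYEC1).objective
        curve = chemostat_sweep(toyec1_acid, [3.0, 5.0, z_star],
                                lambda mu: 0.01)
        assert curve.critical_mu == pytest.approx(z_star, rel=1e-9)

    def test_infeasible_points_skipped(self, toyec1_acid):
        z_star = toy_oracle(TOYEC1).objective
        curve = chemostat_sweep(toyec1_acid, [3.0, 2 * z_star],
                                lambda mu: 0.01)
        assert list(curve.feasible) == [True, False]
        assert np.isnan(curve.pool_use[1])

    def test_condition_file_equivalent_to_plain_sweep(self, toyec1_acid,
                                                      tmp_path):
        cond_path = tmp_path / "empty.yaml"
        cond_path.write_text("{}\n")
        cond = Condition.from_yaml(cond_path)
        a = chemostat_sweep(toyec1_acid, [2.0, 4.0], lambda mu: 0.01)
        b = chemostat_sweep(toyec1_acid, [2.0, 4.0], lambda mu: 0.01,
                            condition=cond)
        np.testing.assert_allclose(a.pool_use, b.pool_use, rtol=1e-12)


class TestCompareModes:
    def test_identical_setups_have_zero_deviation(self, toyec1_acid):
        setup = Condition(name="same")
        frame = compare_modes(toyec1_acid, setup, setup)
        observed = frame["deviation"].dropna()
        np.testing.assert_allclose(observed.to_numpy(), 0.0, atol=1e-9)

    def test_single_route_modes_use_sentinels(self, toyec1_acid):
        only_e1 = Condition(name="E1", blocked=["R_E2"])
        only_e2 = Condition(name="E2", blocked=["R_E1"])
        frame = compare_modes(toyec1_acid, only_e1, only_e2)
        assert frame.loc["G", "deviation"] == pytest.approx(1.0)
        assert np.isnan(frame.loc["A", "deviation"])  # reference lacks Ala
        assert frame["deviation"].median() == pytest.approx(0.0)

    def test_pool_binding_vs_slack_modes_differ(self, toyec1_acid):
        batch = Condition(name="batch")          # pool binds at optimum
        slack = Condition(name="slow", growth_rate=3.0)  # pure cheap route
        frame = compare_modes(toyec1_acid, batch, slack)
        # slow growth uses only the Gly enzyme; batch growth mixes in Ala
        assert frame.loc["G", "fraction_b"] == pytest.approx(1.0, rel=1e-6)
        assert frame.loc["G", "deviation"] > 0.5


class TestAminoAcidProfile:
    def test_fraction_of_zero_profile_is_zero(self):
        profile = AminoAcidProfile(np.zeros(20))
        assert profile.fraction.sum() == 0.0

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            AminoAcidProfile(np.zeros(19))
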