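"""Species-distribution loading, hard profile coupling and the QP fit."""

import numpy as np
import pandas as pd
import pytest

from acidfba import TOYEC1
from acidfba.amino_acids import AA_CODES, RESIDUE_MASSES
from acidfba.simulate import aa_profile_at_optimum, maximize_growth
from acidfba.species import (SpeciesDistribution, constrain_profile,
                             constrained_max_growth, growth_fraction_scan,
                             load_distribution, min_euclidean_fit,
                             profile_difference)
from acidfba.toys import toy_oracle

A, G = AA_CODES.index("A"), AA_CODES.index("G")


def unit_dist(code, name="pure"):
    vec = np.zeros(20)
    vec[AA_CODES.index(code)] = 1.0
    return SpeciesDistribution(name, vec)


def table(values, header="fraction"):
    return pd.DataFrame({"code": list(AA_CODES)[:len(values)],
                         header: values}).rename(columns={"code": "aa"})


class TestLoadDistribution:
    def test_uniform_fractions(self):
        dist = load_distribution(table([0.05] * 20), species="uni")
        np.testing.assert_allclose(dist.fractions, 0.05)

    def test_missing_tryptophan_named(self):
        frame = table([0.05] * 20)
        frame = frame[frame["aa"] != "W"]
        with pytest.raises(ValueError, match="tryptophan"):
            load_distribution(frame)

    def test_negative_value_rejected(self):
        values = [0.05] * 20
        values[3] = -0.01
        with pytest.raises(ValueError, match="non-negative"):
            load_distribution(table(values))

    def test_coefficients_converted_by_residue_mass(self):
        # biomass coefficients (mmol gDW^-1): 2 of Ala, 1 of Gly, rest 0
        values = [0.0] * 20
        values[A], values[G] = 2.0, 1.0
        dist = load_distribution(table(values, header="mmol_gDW"))
        expected_a = 2 * RESIDUE_MASSES["A"]
        expected_g = 1 * RESIDUE_MASSES["G"]
        total = expected_a + expected_g
        assert dist.fractions[A] == pytest.approx(expected_a / total)
        assert dist.fractions[G] == pytest.approx(expected_g / total)

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "uni.tsv"
        table([0.05] * 20).to_csv(path, sep="\t", index=False)
        dist = load_distribution(path)
        assert dist.species == "uni"
        np.testing.assert_allclose(dist.fractions, 0.05)

    def test_unnormalized_input_renormalized(self):
        dist = SpeciesDistribution("off", np.full(20, 0.045))
        assert dist.fractions.sum() == pytest.approx(1.0)


class TestConstrainProfile:
    def test_pure_glycine_forces_cheap_enzyme_only(self, toyec1_acid):
        # only the Gly-only enzyme may be expressed: optimum = uptake-limited
        # single-route growth
        sol = constrained_max_growth(toyec1_acid, unit_dist("G"))
        assert sol.objective == pytest.approx(5.0, rel=1e-8)

    def test_pure_tryptophan_cannot_grow(self, toyec1_acid):
        # no enzyme contains Trp: any growth would violate the coupling
        sol = constrained_max_growth(toyec1_acid, unit_dist("W"))
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_own_optimal_distribution_keeps_optimum(self, toyec1_acid):
        _, profile = aa_profile_at_optimum(toyec1_acid)
        own = SpeciesDistribution("own", profile.fraction)
        sol = constrained_max_growth(toyec1_acid, own)
        assert sol.objective == pytest.approx(
            maximize_growth(toyec1_acid).objective, rel=1e-8)

    def test_original_model_untouched(self, toyec1_acid):
        constrain_profile(toyec1_acid, unit_dist("G"))
        assert "aa_couple_G" not in toyec1_acid.model.constraints


class TestMinEuclideanFit:
    def test_zero_distance_when_profile_attainable(self, toyec1_acid):
        fit = min_euclidean_fit(toyec1_acid, unit_dist("G"), 0.5, 5.0)
        assert fit.ok
        assert fit.distance <= 1e-7
        assert fit.profile.fraction[G] == pytest.approx(1.0, abs=1e-6)

    def test_positive_distance_beyond_single_route_limit(self, toyec1_acid):
        fit = min_euclidean_fit(toyec1_acid, unit_dist("G"), 1.2, 5.0)
        assert fit.ok
        assert fit.distance > 1e-4
        assert fit.profile.fraction[A] > 0.1  # Ala-rich enzyme forced in

    def test_infeasible_growth_reported(self, toyec1_acid):
        z_star = toy_oracle(TOYEC1).objective
        fit = min_euclidean_fit(toyec1_acid, unit_dist("G"), 1.5,
                                z_star)
        assert not fit.ok
        assert fit.status == "infeasible"

    def test_qp_beats_hand_constructed_profiles(self, toyec1_acid):
        # dense sweep over feasible route splits at fixed growth: the QP
        # objective must undercut every hand-built candidate
        dist = unit_dist("G")
        mu = 5.5
        fit = min_euclidean_fit(toyec1_acid, dist, mu / 5.0, 5.0)
        e1, e2 = TOYEC1.enzymes
        best_hand = np.inf
        for v1 in np.linspace(0.0, 10.0, 2001):
            v2 = (mu - e1.yield_coeff * v1) / e2.yield_coeff
            if v2 < 0 or v1 + v2 > 10.0:
                continue
            pool = e1.pool_cost * v1 + e2.pool_cost * v2
            if pool > 0.01:
                continue
            a = np.zeros(20)
            a[A] = v1 / e1.kcat * e1.mw / 1000.0
            a[G] = v2 / e2.kcat * e2.mw / 1000.0
            best_hand = min(best_hand,
                            np.sum((a - dist.fractions * a.sum()) ** 2))
        assert fit.distance ** 2 <= best_hand + 1e-12


class TestProfileDifference:
    def test_identical_profiles_are_zero(self):
        dist = unit_dist("G")
        diffs = profile_difference(dist.fractions, dist)
        assert diffs.fillna(0.0).abs().max() == 0.0

    def test_two_amino_acid_arithmetic(self):
        p = np.zeros(20)
        p[A], p[G] = 0.5, 0.5
        q = np.zeros(20)
        q[A], q[G] = 0.6, 0.4
        diffs = profile_difference(q, SpeciesDistribution("p", p))
        assert diffs["A"] == pytest.approx(0.2)
        assert diffs["G"] == pytest.approx(0.2)

    def test_zero_reference_gives_sentinel(self):
        q = np.zeros(20)
        q[A] = 1.0
        diffs = profile_difference(q, unit_dist("G"))
        assert np.isnan(diffs["A"])


class TestGrowthFractionScan:
    def test_own_behaviour_zero_below_one_rising_above(self, toyec1_acid):
        # reference state: growth hard-coupled to pure Gly (the cheap route's
        # composition); feasible up to 1.0, then the Ala enzyme must mix in
        dist = unit_dist("G")
        frame = growth_fraction_scan(toyec1_acid, dist,
                                     [0.5, 0.9, 1.0, 1.1, 1.25])
        assert frame.attrs["reference_growth"] == pytest.approx(5.0, rel=1e-8)
        by_frac = frame.groupby("growth_fraction")["distance"].first()
        assert by_frac[0.5] <= 1e-7
        assert by_frac[1.0] <= 1e-6
        assert by_frac[1.1] > 1e-4
        assert by_frac[1.25] > by_frac[1.1]

    def test_single_fraction_single_block(self, toyec1_acid):
        frame = growth_fraction_scan(toyec1_acid, unit_dist("G"), [0.1])
        assert set(frame["growth_fraction"]) == {0.1}
        assert len(frame) == 20

    def test_fraction_beyond_maximum_flagged(self, toyec1_acid):
        frame = growth_fraction_scan(toyec1_acid, unit_dist("G"),
                                     [0.5, 2.0])
        flags = frame.groupby("growth_fraction")["feasible"].first()
        assert bool(flags[0.5]) is True
        assert bool(flags[2.0]) is False

    def test_distance_monotone_once_pool_binds(self, toyec1_acid):
        frame = growth_fraction_scan(toyec1_acid, unit_dist("G"),
                                     [1.0, 1.05, 1.1, 1.15, 1.2, 1.25])
        distances = frame.groupby("growth_fraction")["distance"].first()
        assert (np.diff(distances.to_numpy()) >= -1e-8).all()
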