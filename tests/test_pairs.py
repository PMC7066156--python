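import numpy as np
import pandas as pd
import pytest

from quantherit.pairs import (
    build_fullsib_pairs,
    build_midparent_pairs,
    build_op_pairs,
    build_spouse_pairs,
    weighted_correlation,
)


class TestOffspringParent:
    def test_both_parents_give_two_half_weight_pairs(self, family_values):
        adjusted, ped = family_values
        ps = build_op_pairs(adjusted, ped)
        a1 = ps.pairs[ps.pairs["y_id"] == "A1"]
        assert len(a1) == 2
        assert (a1["weight"] == 0.5).all()
        assert set(a1["x_id"]) == {"FA", "MA"}

    def test_single_parent_gives_one_full_weight_pair(self, family_values):
        adjusted, ped = family_values
        ps = build_op_pairs(adjusted, ped)
        b1 = ps.pairs[ps.pairs["y_id"] == "B1"]
        assert len(b1) == 1
        assert b1["weight"].iloc[0] == 1.0
        assert b1["x_id"].iloc[0] == "MB"

    def test_total_weight_equals_offspring_with_measured_parent(self, family_values):
        adjusted, ped = family_values
        ps = build_op_pairs(adjusted, ped)
        assert ps.total_weight == pytest.approx(6.0)  # A1 A2 B1 C1 C2 C3
        assert ps.df == 6 - 2

    def test_offspring_without_measured_parent_excluded(self, family_values):
        adjusted, ped = family_values
        adjusted = adjusted[~adjusted["individual_id"].isin(["MB"])]
        ps = build_op_pairs(adjusted, ped)
        assert "B1" not in set(ps.pairs["y_id"])


class TestMidparent:
    def test_midparent_is_parental_mean(self, family_values):
        adjusted, ped = family_values
        ps = build_midparent_pairs(adjusted, ped)
        a = ps.pairs[ps.pairs["y_id"] == "A1"]
        assert a["x"].iloc[0] == pytest.approx(1.5)  # (1.0 + 2.0) / 2

    def test_single_parent_family_contributes_no_pair(self, family_values):
        adjusted, ped = family_values
        ps = build_midparent_pairs(adjusted, ped)
        assert "B1" not in set(ps.pairs["y_id"])
        assert (ps.pairs["weight"] == 1.0).all()


class TestFullSib:
    def test_sibship_counts_and_weights(self, family_values):
        adjusted, ped = family_values
        ps = build_fullsib_pairs(adjusted, ped)
        c = ps.pairs[ps.pairs["family_id"].str.contains("FC")]
        assert len(c) == 6  # k=3 -> k(k-1) ordered pairs
        assert np.allclose(c["weight"], 0.5)  # 1/(k-1)
        a = ps.pairs[ps.pairs["family_id"].str.contains("FA")]
        assert len(a) == 2 and (a["weight"] == 1.0).all()
        assert ps.df == (2 - 1) + (3 - 1)

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_enumeration_matches_k_times_k_minus_1(self, k):
        ids = [f"S{i}" for i in range(k)]
        ped = pd.DataFrame(
            [("P", "", "", "M", "g"), ("Q", "", "", "F", "g")]
            + [(s, "P", "Q", "M", "g") for s in ids],
            columns=["individual_id", "father_id", "mother_id", "sex", "cohort"],
        )
        adjusted = pd.DataFrame(
            {"individual_id": ids, "value": np.arange(k, dtype=float)}
        )
        ps = build_fullsib_pairs(adjusted, ped)
        assert len(ps) == k * (k - 1)
        per_sib = ps.pairs.groupby("y_id")["weight"].sum()
        np.testing.assert_allclose(per_sib, 1.0)  # each sib's y-weight sums to 1

    def test_flat_weight_mode(self, family_values):
        adjusted, ped = family_values
        ps = build_fullsib_pairs(adjusted, ped, flat_weights=True)
        assert (ps.pairs["weight"] == 1.0).all()

    def test_half_sibs_excluded(self):
        ped = pd.DataFrame(
            [("P", "", "", "M", "g"), ("Q", "", "", "F", "g"), ("R", "", "", "F", "g"),
             ("S1", "P", "Q", "M", "g"), ("S2", "P", "R", "M", "g"),
             ("S3", "P", "Q", "F", "g")],
            columns=["individual_id", "father_id", "mother_id", "sex", "cohort"],
        )
        adjusted = pd.DataFrame(
            {"individual_id": ["S1", "S2", "S3"], "value": [1.0, 2.0, 3.0]}
        )
        ps = build_fullsib_pairs(adjusted, ped)
        assert set(ps.pairs["y_id"]) == {"S1", "S3"}


class TestSpouse:
    def test_one_pair_per_couple_regardless_of_children(self, family_values):
        adjusted, ped = family_values
        ps = build_spouse_pairs(adjusted, ped)
        # fam A and fam C have both parents measured; fam B only the mother
        assert len(ps) == 2

    def test_unmarried_individual_contributes_nothing(self, family_values):
        adjusted, ped = family_values
        extra = pd.concat(
            [adjusted, pd.DataFrame({"individual_id": ["LONER"], "value": [9.9]})],
            ignore_index=True,
        )
        ped2 = pd.concat(
            [ped, pd.DataFrame([("LONER", "", "", "M", "g")], columns=ped.columns)],
            ignore_index=True,
        )
        assert len(build_spouse_pairs(extra, ped2)) == 2


class TestWeightedCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert weighted_correlation((x, 2 * x + 1, None)) == pytest.approx(1.0)
        assert weighted_correlation((x, -x, None)) == pytest.approx(-1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            weighted_correlation(([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], None))

    def test_monte_carlo_recovery(self, rng):
        rho = 0.31
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=100_000)
        est = weighted_correlation((z[:, 0], z[:, 1], None))
        assert est == pytest.approx(rho, abs=0.01)

    def test_frequency_weights_match_replication(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        w = rng.integers(1, 4, size=30).astype(float)
        xr = np.repeat(x, w.astype(int))
        yr = np.repeat(y, w.astype(int))
        assert weighted_correlation((x, y, w)) == pytest.approx(
            weighted_correlation((xr, yr, None)), abs=1e-12
        )


def test_pair_sets_invariant_to_row_order(family_values, rng):
    adjusted, ped = family_values
    perm_a = adjusted.sample(frac=1.0, random_state=7).reset_index(drop=True)
    perm_p = ped.sample(frac=1.0, random_state=8).reset_index(drop=True)
    for builder in (build_op_pairs, build_midparent_pairs, build_fullsib_pairs,
                    build_spouse_pairs):
        base = builder(adjusted, ped).pairs
        perm = builder(perm_a, perm_p).pairs
        pd.testing.assert_frame_equal(base, perm)
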