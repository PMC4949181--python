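import itertools
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.datatypes import CtTable, DataValidationError, ReferenceSet
from refstab.stability import (
    collapse_replicates,
    combination_ct,
    enumerate_and_rank,
    genorm_m,
    mean_dct_sd,
    pairwise_dct_sd,
)


class TestCollapseReplicates:
    def test_replicates_average_arithmetically(self):
        entries = pd.DataFrame(
            [("g1", "s1", 1, 20.0), ("g1", "s1", 2, 20.4), ("g1", "s1", 3, 20.3),
             ("g2", "s1", 1, 25.0)],
            columns=["gene", "sample", "replicate", "ct"],
        )
        grid = collapse_replicates(CtTable(entries=entries))
        assert grid.loc["g1", "s1"] == pytest.approx(20.2333333, abs=1e-6)
        assert grid.loc["g2", "s1"] == 25.0  # single replicate: identity

    def test_fully_missing_well_is_nan(self):
        entries = pd.DataFrame(
            [("g1", "s1", 1, 20.0), ("g2", "s2", 1, 25.0)],
            columns=["gene", "sample", "replicate", "ct"],
        )
        grid = collapse_replicates(CtTable(entries=entries))
        assert np.isnan(grid.loc["g1", "s2"]) and np.isnan(grid.loc["g2", "s1"])


class TestCombinationCt:
    def test_singleton_is_identity(self, tiny_grid):
        pd.testing.assert_series_equal(
            combination_ct(tiny_grid, ReferenceSet(["A"])), tiny_grid.loc["A"],
            check_names=False,
        )

    def test_pair_is_arithmetic_mean(self, tiny_grid):
        got = combination_ct(tiny_grid, ["A", "B"])
        expected = (tiny_grid.loc["A"] + tiny_grid.loc["B"]) / 2
        pd.testing.assert_series_equal(got, expected)

    def test_missing_member_poisons_the_sample(self, tiny_grid):
        grid = tiny_grid.copy()
        grid.loc["B", "s3"] = np.nan
        assert np.isnan(combination_ct(grid, ["A", "B"])["s3"])
        assert not combination_ct(grid, ["A", "B"]).drop("s3").isna().any()

    def test_empty_set_rejected(self, tiny_grid):
        with pytest.raises(DataValidationError, match="empty"):
            combination_ct(tiny_grid, [])


class TestPairwiseDctSd:
    def test_identical_and_offset_profiles_give_zero(self, tiny_grid):
        a = tiny_grid.loc["A"]
        assert pairwise_dct_sd(a, a) == 0.0
        assert pairwise_dct_sd(a, a + 1.5) == pytest.approx(0.0, abs=1e-12)

    def test_hand_oracle(self):
        a = pd.Series([10.0, 11.0, 12.0], index=["s1", "s2", "s3"])
        b = pd.Series([10.0, 10.0, 10.0], index=["s1", "s2", "s3"])
        assert pairwise_dct_sd(a, b) == pytest.approx(1.0)  # SD of [0, 1, 2]

    def test_too_few_shared_samples_names_the_pair(self):
        a = pd.Series([10.0, 11.0, np.nan], index=["s1", "s2", "s3"])
        b = pd.Series([10.0, np.nan, 10.0], index=["s1", "s2", "s3"])
        with pytest.raises(DataValidationError, match="'A' vs 'B'"):
            pairwise_dct_sd(a, b, names=("A", "B"))


class TestMeanDctSd:
    def test_matches_two_pair_oracle(self, tiny_grid):
        got = mean_dct_sd(tiny_grid, ["A"], ["A", "B", "C"])
        sd_ab = statistics.stdev(tiny_grid.loc["A"] - tiny_grid.loc["B"])
        sd_ac = statistics.stdev(tiny_grid.loc["A"] - tiny_grid.loc["C"])
        assert got == pytest.approx((sd_ab + sd_ac) / 2, abs=1e-12)

    def test_shared_profile_up_to_offsets_scores_zero(self, tiny_grid):
        base = tiny_grid.loc["A"]
        grid = pd.DataFrame(
            {g: base + off for g, off in zip("ABCD", [0, 1.0, -2.5, 3.25])}
        ).T
        for size in (1, 2):
            for combo in itertools.combinations("ABCD", size):
                assert mean_dct_sd(grid, list(combo), list("ABCD")) == pytest.approx(0, abs=1e-12)

    def test_set_equal_to_candidates_has_no_partner(self, tiny_grid):
        with pytest.raises(DataValidationError, match="partner"):
            mean_dct_sd(tiny_grid, ["A", "B"], ["A", "B"])

    def test_per_sample_constant_shift_is_invisible(self, tiny_grid, rng):
        """Loading offsets hit every gene of a sample equally and cancel in ΔCt."""
        shift = rng.normal(0, 3, size=tiny_grid.shape[1])
        shifted = tiny_grid + shift
        for combo in (["A"], ["B", "C"], ["A", "C", "D"]):
            assert mean_dct_sd(shifted, combo, list("ABCD")) == pytest.approx(
                mean_dct_sd(tiny_grid, combo, list("ABCD")), abs=1e-10
            )


class TestEnumerateAndRank:
    @pytest.mark.parametrize(
        "n, max_size, expected",
        [(2, 1, 2), (4, 3, 14), (10, 4, 385)],  # 4+6+4 and 10+45+120+210
    )
    def test_set_counts(self, rng, n, max_size, expected):
        genes = [f"g{i}" for i in range(n)]
        grid = pd.DataFrame(rng.normal(22, 1, size=(n, 6)), index=genes,
                            columns=[f"s{j}" for j in range(6)])
        ranking = enumerate_and_rank(grid, genes, max_size=max_size)
        assert len(ranking.table) == expected
        # tie-averaging preserves the total of the ranks
        assert ranking.table["rank_in_total"].sum() == expected * (expected + 1) / 2

    def test_scores_match_independent_brute_force(self, rng):
        """Every subset score equals a from-scratch statistics.stdev recomputation."""
        genes = list("ABCDE")
        grid = pd.DataFrame(rng.normal(22, 1.5, size=(5, 8)), index=genes,
                            columns=[f"s{j}" for j in range(8)])
        ranking = enumerate_and_rank(grid, genes, max_size=4)
        scores = dict(zip(ranking.table["reference"], ranking.table["mean_sd"]))
        for k in range(1, 5):
            for combo in itertools.combinations(genes, k):
                pseudo = grid.loc[list(combo)].mean(axis=0)
                partners = [g for g in genes if g not in combo]
                expected = statistics.mean(
                    statistics.stdev(pseudo - grid.loc[p]) for p in partners
                )
                assert scores["/".join(combo)] == pytest.approx(expected, abs=1e-12)

    def test_ranks_are_tie_averaged_permutations(self, rng):
        genes = [f"g{i}" for i in range(6)]
        grid = pd.DataFrame(rng.normal(22, 1, size=(6, 6)), index=genes,
                            columns=[f"s{j}" for j in range(6)])
        t = enumerate_and_rank(grid, genes, max_size=3).table
        assert sorted(t["rank_in_total"]) == list(range(1, len(t) + 1))
        for _, grp in t.groupby("size"):
            assert np.all(np.diff(grp.sort_values("mean_sd")["rank_in_class"]) >= 0)

    def test_combinatorial_guard(self, rng):
        genes = [f"g{i}" for i in range(20)]
        grid = pd.DataFrame(rng.normal(22, 1, size=(20, 6)), index=genes,
                            columns=[f"s{j}" for j in range(6)])
        with pytest.raises(DataValidationError, match="guard"):
            enumerate_and_rank(grid, genes, max_size=19)

    def test_missing_wells_use_pairwise_complete_samples(self, rng):
        genes = list("ABCD")
        grid = pd.DataFrame(rng.normal(22, 1, size=(4, 8)), index=genes,
                            columns=[f"s{j}" for j in range(8)])
        grid.loc["B", "s0"] = np.nan
        ranking = enumerate_and_rank(grid, genes, max_size=2)
        # single-gene A vs partner B must use the 7 complete samples only
        d = (grid.loc["A"] - grid.loc["B"]).dropna()
        row = ranking.table[ranking.table["reference"] == "A"].iloc[0]
        sd_ab = float(np.std(d, ddof=1))
        sd_ac = float(np.std(grid.loc["A"] - grid.loc["C"], ddof=1))
        sd_ad = float(np.std(grid.loc["A"] - grid.loc["D"], ddof=1))
        assert row["mean_sd"] == pytest.approx((sd_ab + sd_ac + sd_ad) / 3, abs=1e-12)


class TestGenormM:
    def test_all_identical_profiles_give_zero_m(self):
        base = pd.Series(np.linspace(20, 24, 6), index=[f"s{j}" for j in range(6)])
        grid = pd.DataFrame({g: base + off for g, off in zip("ABC", [0, 1, 2])}).T
        assert genorm_m(grid, list("ABC")).max() == pytest.approx(0, abs=1e-12)

    def test_noisy_gene_has_largest_m(self, rng):
        base = pd.Series(np.linspace(20, 24, 8), index=[f"s{j}" for j in range(8)])
        grid = pd.DataFrame(
            {"A": base, "B": base + 1, "C": base + rng.normal(0, 2, size=8)}
        ).T
        m = genorm_m(grid, list("ABC"))
        assert m.idxmax() == "C"
        assert m["C"] > m["A"] and m["C"] > m["B"]

    def test_matches_pairwise_sd_oracle(self, rng):
        genes = list("ABCD")
        grid = pd.DataFrame(rng.normal(22, 1, size=(4, 10)), index=genes,
                            columns=[f"s{j}" for j in range(10)])
        m = genorm_m(grid, genes)
        for j in genes:
            sds = [
                statistics.stdev(grid.loc[k] - grid.loc[j]) for k in genes if k != j
            ]
            assert m[j] == pytest.approx(statistics.mean(sds), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 5))
    def test_loading_shift_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        genes = list("ABCDE")
        grid = pd.DataFrame(rng.normal(22, 1, size=(5, 7)), index=genes,
                            columns=[f"s{j}" for j in range(7)])
        shift = rng.normal(0, scale, size=7)
        m0 = genorm_m(grid, genes)
        m1 = genorm_m(grid + shift, genes)
        pd.testing.assert_series_equal(m0, m1, atol=1e-10)
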