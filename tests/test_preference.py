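"""Consensus matrices, probability-logo statistics, motif group tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from synstarr.designs import acgt_flank_design, window_from_key
from synstarr.preference import (
    consensus_matrix,
    motif_group_test,
    position_stats,
    rank_sum_test,
)


def flank_windows(rng, n, design):
    keys = ["".join(k) for k in
            rng.choice(list("ACGT"), size=(n, 6))]
    return [window_from_key(design, k) for k in keys]


class TestConsensus:
    def test_singleton_is_one_hot(self, flank_design):
        freq, consensus = consensus_matrix(["GGGACGTTAT"], flank_design)
        assert consensus == "GGGACGTTAT"
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)
        assert freq.loc[0, "G"] == 1.0 and freq.loc[9, "T"] == 1.0

    def test_two_sequences_average_with_iupac_tie(self, flank_design):
        freq, consensus = consensus_matrix(
            ["GGGACGTTAT", "CGGACGTTAT"], flank_design)
        assert freq.loc[0, "C"] == 0.5 and freq.loc[0, "G"] == 0.5
        assert consensus == "SGGACGTTAT"  # S = C or G

    def test_fixed_core_positions_are_one_hot(self, flank_design):
        rng = np.random.default_rng(0)
        freq, consensus = consensus_matrix(
            flank_windows(rng, 50, flank_design), flank_design)
        for pos, base in zip((3, 4, 5, 6), "ACGT"):
            assert freq.loc[pos, base] == 1.0
        assert consensus[3:7] == "ACGT"
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)

    def test_empty_subset_rejected(self, flank_design):
        with pytest.raises(ValueError):
            consensus_matrix([], flank_design)


def brute_force_ranksum_p(x, y, alternative):
    """Exhaustive permutation enumeration of the rank-sum distribution."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    obs = ranks[:len(x)].sum()
    n = len(pooled)
    hits = total = 0
    for idx in itertools.combinations(range(n), len(x)):
        stat = sum(ranks[i] for i in idx)
        total += 1
        if alternative == "greater" and stat >= obs - 1e-9:
            hits += 1
        elif alternative == "less" and stat <= obs + 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_matches_enumeration_for_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 9, size=2)
        # include ties with 50% chance: integer-valued data
        if seed % 2:
            x = rng.integers(0, 5, size=nx).astype(float)
            y = rng.integers(0, 5, size=ny).astype(float)
        else:
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
        p_g, p_l = rank_sum_test(x, y)
        assert p_g == pytest.approx(brute_force_ranksum_p(x, y, "greater"))
        assert p_l == pytest.approx(brute_force_ranksum_p(x, y, "less"))

    def test_asymptotic_path_close_to_scipy_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 1, size=30)
        y = rng.normal(0, 1, size=40)
        assert comb(70, 30) > 20_000  # forces the asymptotic branch
        p_g, _ = rank_sum_test(x, y)
        from scipy.stats import mannwhitneyu
        ref = mannwhitneyu(x, y, alternative="greater",
                           method="exact").pvalue
        assert p_g == pytest.approx(ref, rel=0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test(np.array([]), np.array([1.0]))


class TestPositionStats:
    def test_equal_activities_show_no_signal(self, flank_design):
        rng = np.random.default_rng(1)
        windows = flank_windows(rng, 60, flank_design)
        stats_df = position_stats(windows, np.zeros(len(windows)),
                                  flank_design)
        assert not stats_df["significant"].fillna(False).any()
        valid = stats_df.dropna(subset=["p_greater"])
        assert (valid["p_greater"] > 0.5).all()  # all-tie ranks

    def test_fixed_positions_carry_no_statistic(self, flank_design):
        rng = np.random.default_rng(2)
        windows = flank_windows(rng, 40, flank_design)
        stats_df = position_stats(windows, rng.normal(size=40), flank_design)
        assert set(stats_df["position"]) == {0, 1, 2, 7, 8, 9}

    def test_constructed_effect_detected_with_positive_sign(self, flank_design):
        # +2 activity for G at the first downstream flank position
        # (window offset 7), n=200, noise sd 0.5
        rng = np.random.default_rng(4)
        windows = flank_windows(rng, 200, flank_design)
        values = rng.normal(0, 0.5, size=200)
        values += 2.0 * np.array([w[7] == "G" for w in windows])
        stats_df = position_stats(windows, values, flank_design)
        cell = stats_df[(stats_df["position"] == 7)
                        & (stats_df["base"] == "G")].iloc[0]
        assert cell["significant"]
        assert cell["p_greater"] < 0.01
        assert cell["height"] > 2  # positive sign, -log10 p > 2

        # independent brute-force check: Monte Carlo permutation of the
        # rank-sum statistic for that cell
        from scipy.stats import rankdata
        mask = np.array([w[7] == "G" for w in windows])
        ranks = rankdata(values)
        obs = ranks[mask].sum()
        perm_rng = np.random.default_rng(5)
        perm = np.array([ranks[perm_rng.permutation(200)[:mask.sum()]].sum()
                         for _ in range(2000)])
        assert (perm >= obs).mean() < 0.01

    def test_invariant_under_monotone_transform(self, flank_design):
        rng = np.random.default_rng(6)
        windows = flank_windows(rng, 80, flank_design)
        values = rng.normal(size=80)
        a = position_stats(windows, values, flank_design)
        b = position_stats(windows, np.exp(values) + 7, flank_design)
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_calibration_near_nominal(self, flank_design):
        # under label permutation, one-sided p-values are uniform: about
        # 1% of (cell, direction) p-values fall below 0.01
        rng = np.random.default_rng(7)
        windows = flank_windows(rng, 200, flank_design)
        values = rng.normal(size=200)
        hits = total = 0
        for _ in range(100):
            perm = rng.permutation(values)
            s = position_stats(windows, perm, flank_design)
            ps = np.concatenate([s["p_greater"].dropna(),
                                 s["p_less"].dropna()])
            hits += (ps < 0.01).sum()
            total += len(ps)
        rate = hits / total
        assert 0.003 <= rate <= 0.02


class TestMotifGroups:
    def test_no_signal_gives_flat_medians(self, flank_design):
        rng = np.random.default_rng(8)
        windows = flank_windows(rng, 300, flank_design)
        res = motif_group_test(windows, np.zeros(300), flank_design)
        assert set(res["group"]) == {"other", "GGG", "GTG"}
        assert (res["median_diff_vs_other"].fillna(0) == 0).all()

    def test_shifted_group_detected(self, flank_design):
        rng = np.random.default_rng(9)
        windows = flank_windows(rng, 400, flank_design)
        values = rng.normal(0, 0.5, size=400)
        ggg = np.array([w[7:10] == "GGG" for w in windows])
        assert ggg.sum() >= 3
        values += 1.0 * ggg
        res = motif_group_test(windows, values, flank_design).set_index("group")
        assert res.loc["GGG", "median_diff_vs_other"] > 0.5
        assert res.loc["GGG", "p_vs_other"] < 0.01

    def test_upstream_region_selection(self, flank_design):
        windows = ["GGGACGTTAT", "CCCACGTGGG", "AAAACGTCCC"]
        res = motif_group_test(windows, [1.0, 2.0, 3.0], flank_design,
                               motifs=["GGG"], region="upstream")
        assert res.set_index("group").loc["GGG", "n"] == 1

    def test_missing_motif_group_is_an_error(self, flank_design):
        windows = ["GGGACGTTAT", "CCCACGTGGG"]
        with pytest.raises(ValueError, match="AAA"):
            motif_group_test(windows, [1.0, 2.0], flank_design,
                             motifs=["AAA"])
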