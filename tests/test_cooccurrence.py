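"""Median dichotomization, 2x2 chi-square testing, direction filtering,
and pair ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import semibulk as sb
from semibulk.cooccurrence import PresenceMatrix, all_pair_tests


def presence_from_bools(a, b):
    return PresenceMatrix(
        unit_ids=[f"u{i}" for i in range(len(a))],
        cell_types=["A", "B"],
        present=np.column_stack([a, b]).astype(bool),
        thresholds_used=np.array([0.5, 0.5]),
    )


def presence_from_table(n11, n10, n01, n00):
    a = [True] * (n11 + n10) + [False] * (n01 + n00)
    b = [True] * n11 + [False] * n10 + [True] * n01 + [False] * n00
    return presence_from_bools(a, b)


class TestDichotomize:
    def test_median_split(self):
        df = pd.DataFrame({"t": [0.1, 0.2, 0.3, 0.4]}, index=list("abcd"))
        pres = sb.dichotomize(df)
        assert list(pres.present[:, 0]) == [False, False, True, True]
        assert pres.thresholds_used[0] == pytest.approx(0.25)

    def test_ties_at_median_are_absent(self):
        df = pd.DataFrame({"t": [0.2, 0.2, 0.2, 0.5]})
        pres = sb.dichotomize(df)
        assert list(pres.present[:, 0]) == [False, False, False, True]

    def test_constant_column_all_absent(self):
        df = pd.DataFrame({"t": [0.3, 0.3, 0.3]})
        assert not sb.dichotomize(df).present.any()

    def test_accepts_composition_matrix(self, ref4):
        comp, _ = sb.simulate_compositions(ref4.cell_types, 50, seed=1)
        pres = sb.dichotomize(comp)
        assert pres.cell_types == ref4.cell_types
        # strict median split: at most half the units can be present
        assert pres.present.sum(axis=0).max() <= 25

    def test_too_few_units(self):
        with pytest.raises(ValueError, match="2 units"):
            sb.dichotomize(pd.DataFrame({"t": [0.1]}))


class TestPairTest:
    def test_hand_computed_table(self):
        # [[30,10],[10,30]]: chi2 = 80*(900-100)^2/40^4 = 20
        r = sb.pair_test(presence_from_table(30, 10, 10, 30), "A", "B")
        assert r.chi2_stat == pytest.approx(20.0, abs=1e-12)
        assert r.p_value == pytest.approx(7.744e-6, rel=1e-3)
        assert r.passed_direction_filter

    def test_matches_independent_oracle_on_random_tables(self):
        # closed-form statistic vs scipy's contingency test, both variants
        rng = np.random.default_rng(12)
        for _ in range(100):
            cells = rng.integers(1, 60, size=4)
            pres = presence_from_table(*cells)
            table = np.array([[cells[0], cells[1]], [cells[2], cells[3]]])
            for yates in (False, True):
                r = sb.pair_test(pres, "A", "B", continuity_correction=yates)
                chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
                assert r.chi2_stat == pytest.approx(chi2, abs=1e-9)
                assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_symmetry_in_pair_order(self):
        pres = presence_from_table(25, 5, 12, 18)
        r1 = sb.pair_test(pres, "A", "B")
        r2 = sb.pair_test(pres, "B", "A")
        assert r1.chi2_stat == r2.chi2_stat
        assert r1.p_value == r2.p_value

    def test_table_conserves_units(self):
        pres = presence_from_table(7, 3, 9, 11)
        r = sb.pair_test(pres, "A", "B")
        assert r.table2x2.sum() == 30

    def test_degenerate_margin_is_untestable(self):
        pres = presence_from_bools([True] * 10, [True] * 5 + [False] * 5)
        r = sb.pair_test(pres, "A", "B")
        assert r.untestable
        assert r.p_value == 1.0
        assert r.neg_log10_p == 0.0

    def test_identical_columns_reach_maximal_chi2(self):
        n = 40
        pres = presence_from_table(20, 0, 0, 20)
        r = sb.pair_test(pres, "A", "B")
        assert r.chi2_stat == pytest.approx(n)
        assert not r.untestable
        assert r.passed_direction_filter

    def test_type_i_error_is_nominal(self):
        # 500 independently generated pairs; rejection rate at alpha=0.05
        # within 3 binomial SEs of nominal (no continuity correction)
        rng = np.random.default_rng(99)
        n, alpha, reps = 1000, 0.05, 500
        rejections = 0
        for _ in range(reps):
            pres = sb.dichotomize(
                pd.DataFrame({"A": rng.random(n), "B": rng.random(n)})
            )
            if sb.pair_test(pres, "A", "B").p_value < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se

    def test_yates_is_conservative(self):
        rng = np.random.default_rng(7)
        n, reps = 200, 300
        rej = 0
        for _ in range(reps):
            pres = sb.dichotomize(
                pd.DataFrame({"A": rng.random(n), "B": rng.random(n)})
            )
            rej += sb.pair_test(pres, "A", "B", continuity_correction=True).p_value < 0.05
        assert rej / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_same_type_rejected(self):
        pres = presence_from_table(5, 5, 5, 5)
        with pytest.raises(ValueError, match="distinct"):
            sb.pair_test(pres, "A", "A")


class TestDirectionFilter:
    def test_negative_association_discarded(self):
        # P(A|B) = 10/40 = 0.25 < P(A) = 0.5
        r = sb.pair_test(presence_from_table(10, 30, 30, 10), "A", "B")
        assert r.conditional_ratio_a_given_b < r.marginal_ratio_a
        assert not sb.direction_filter(r)

    def test_identical_columns_pass(self):
        r = sb.pair_test(presence_from_table(15, 0, 0, 15), "A", "B")
        assert sb.direction_filter(r)

    def test_one_directional_variant(self):
        # forward direction favourable, backward unfavourable is impossible
        # for a 2x2 (positive dependence is symmetric), so check agreement
        r = sb.pair_test(presence_from_table(22, 8, 10, 20), "A", "B")
        assert sb.direction_filter(r) == sb.direction_filter(
            r, both_directions=False
        )

    def test_planted_negative_association_filtered_despite_small_p(self):
        rng = np.random.default_rng(3)
        n = 2000
        a = rng.random(n)
        b = np.where(a > np.median(a), rng.random(n) * 0.3, rng.random(n))
        pres = sb.dichotomize(pd.DataFrame({"A": a, "B": b}))
        r = sb.pair_test(pres, "A", "B")
        assert r.p_value < 1e-6
        assert not sb.direction_filter(r)


class TestRankPairs:
    def test_planted_pair_ranks_first(self):
        types = list("ABCDEF")
        spec = sb.ColocalizationSpec(pairs=(("A", "B", 0.9),))
        wins = 0
        for seed in range(25):
            comp, _ = sb.simulate_compositions(types, 2000, coloc=spec, seed=seed)
            ranked = sb.rank_pairs(all_pair_tests(sb.dichotomize(comp)), top_n=15)
            wins += {ranked.loc[0, "type_a"], ranked.loc[0, "type_b"]} == {"A", "B"}
        assert wins >= 24

    def test_null_has_no_systematic_winner(self):
        # independent columns: every pair is a genuine independence null
        rng = np.random.default_rng(55)
        types = list("ABCDEF")
        winners = []
        for _ in range(30):
            df = pd.DataFrame(rng.random((500, 6)), columns=types)
            ranked = sb.rank_pairs(all_pair_tests(sb.dichotomize(df)), top_n=15)
            if len(ranked):
                winners.append((ranked.loc[0, "type_a"], ranked.loc[0, "type_b"]))
        # no single pair dominates rank 1 under the null
        assert len(winners) >= 20
        _, counts = np.unique(winners, axis=0, return_counts=True)
        assert counts.max() <= len(winners) * 0.4

    def test_top_n_larger_than_pair_count(self):
        comp, _ = sb.simulate_compositions(list("ABC"), 200, seed=2)
        ranked = sb.rank_pairs(all_pair_tests(sb.dichotomize(comp)), top_n=50)
        assert len(ranked) <= 3

    def test_sorted_by_p_then_chi2(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((400, 5)), columns=list("ABCDE"))
        ranked = sb.rank_pairs(all_pair_tests(sb.dichotomize(df)), top_n=10)
        assert len(ranked) > 1
        p = ranked["p_value"].to_numpy(dtype=float)
        assert np.all(np.diff(p) >= 0)
        assert np.allclose(ranked["neg_log10_p"].to_numpy(dtype=float), -np.log10(p))

    def test_bh_column_monotone_in_p(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.random((600, 6)), columns=list("ABCDEF"))
        ranked = sb.rank_pairs(all_pair_tests(sb.dichotomize(df)), top_n=15)
        assert len(ranked) > 1
        assert np.all(np.diff(ranked["bh_q"]) >= -1e-12)
        assert np.all(ranked["bh_q"] >= ranked["p_value"] - 1e-12)
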