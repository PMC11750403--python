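"""Paralogue families against a transitive-closure oracle, and the
chi-square / rank-sum duplication tests against enumeration oracles."""

import itertools

import numpy as np
import pytest

from saconflict import (
    ParalogPair,
    ValidationError,
    build_paralog_families,
    paralog_count_tertile_tests,
    proportion_with_paralogs_test,
    wilcoxon_rank_sum,
)


def closure_oracle(edges, universe):
    """Brute-force transitive closure: repeatedly merge overlapping sets."""
    sets = [{g} for g in universe]
    for a, b in edges:
        merged = {a, b}
        rest = []
        for s in sets:
            if s & merged:
                merged |= s
            else:
                rest.append(s)
        sets = rest + [merged]
    return {frozenset(s) for s in sets}


class TestFamilies:
    def test_worked_example(self):
        pairs = [("A", "B", 3), ("B", "C", 1), ("D", "E", 0)]
        families, counts = build_paralog_families(pairs, "ABCDE")
        members = {f.members for f in families}
        assert members == {
            frozenset("ABC"), frozenset("D"), frozenset("E"),
        }
        assert counts == {"A": 1, "B": 2, "C": 1, "D": 0, "E": 0}

    def test_no_pairs_all_singletons(self):
        families, counts = build_paralog_families([], "ABC")
        assert all(len(f.members) == 1 for f in families)
        assert set(counts.values()) == {0}

    def test_min_score_monotonicity(self):
        rng = np.random.default_rng(20)
        universe = [f"G{i}" for i in range(10)]
        pairs = [
            (*sorted(rng.choice(universe, 2, replace=False)), int(rng.integers(1, 6)))
            for _ in range(12)
        ]
        pairs = list({(a, b): (a, b, s) for a, b, s in pairs}.values())
        prev_sizes = None
        prev_counts = None
        for ms in (1, 2, 3, 4, 5):
            fams, counts = build_paralog_families(pairs, universe, min_score=ms)
            if prev_counts is not None:
                assert all(counts[g] <= prev_counts[g] for g in universe)
                assert len(fams) >= prev_sizes
            prev_counts, prev_sizes = counts, len(fams)

    def test_matches_closure_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            universe = [f"G{i}" for i in range(n)]
            possible = list(itertools.combinations(universe, 2))
            k = int(rng.integers(0, min(len(possible), 15) + 1))
            chosen = [possible[i] for i in rng.choice(len(possible), k, replace=False)]
            pairs = [(a, b, int(rng.integers(1, 4))) for a, b in chosen]
            families, counts = build_paralog_families(pairs, universe)
            assert {f.members for f in families} == closure_oracle(chosen, universe)
            # partition conservation and count bound
            assert sum(len(f.members) for f in families) == n
            size_of = {g: len(f.members) for f in families for g in f.members}
            assert all(counts[g] <= size_of[g] - 1 for g in universe)

    def test_family_count_mode(self):
        pairs = [("A", "B", 1), ("B", "C", 1)]
        _, counts = build_paralog_families(pairs, "ABC", count_mode="family")
        assert counts == {"A": 2, "B": 2, "C": 2}

    def test_validation(self):
        with pytest.raises(ValidationError):
            ParalogPair("A", "A", 1)
        with pytest.raises(ValidationError):
            build_paralog_families([("A", "B", 1), ("B", "A", 2)], "AB")
        # identical duplicates are tolerated
        families, _ = build_paralog_families([("A", "B", 1), ("B", "A", 1)], "AB")
        assert len(families) == 1

    def test_pair_canonicalisation(self):
        p = ParalogPair("Z", "A", 5)
        assert (p.gene_a, p.gene_b) == ("A", "Z")


def chi2_2x2_longhand(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestProportionTest:
    def test_homogeneous_proportions_give_zero(self):
        res = proportion_with_paralogs_test({"high": (50, 50)}, 5000, 5000)
        assert res["high"].statistic == pytest.approx(0.0)

    def test_matches_longhand_formula(self):
        res = proportion_with_paralogs_test({"high": (27, 23)}, 5000, 5000)
        assert res["high"].statistic == pytest.approx(
            chi2_2x2_longhand(27, 23, 5000, 5000)
        )
        assert res["high"].df == 1

    def test_row_column_swap_invariance(self):
        a = proportion_with_paralogs_test({"t": (27, 23)}, 40, 60)["t"].statistic
        b = proportion_with_paralogs_test({"t": (27, 40)}, 23, 60)["t"].statistic
        assert a == pytest.approx(b)

    def test_three_tertiles_three_results(self):
        res = proportion_with_paralogs_test(
            {"low": (10, 20), "medium": (15, 15), "high": (20, 10)}, 100, 100
        )
        assert set(res) == {"low", "medium", "high"}

    def test_low_expected_flag(self):
        res = proportion_with_paralogs_test({"t": (1, 1)}, 1, 999)
        assert res["t"].extra["low_expected"]

    def test_background_contract(self):
        with pytest.raises(ValidationError):
            proportion_with_paralogs_test({"t": (1, 1)}, 0, 10)


def rank_sum_enumeration(x, y):
    """Exact two-sided p by enumerating all labelings (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    ws = [
        sum(c)
        for c in itertools.combinations(range(1, n + 1), len(x))
    ]
    mean_w = len(x) * (n + 1) / 2
    extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in ws)
    return w_obs, extreme / len(ws)


class TestWilcoxon:
    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_small_instance_matches_enumeration(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        w_oracle, p_oracle = rank_sum_enumeration(x, y)
        res = wilcoxon_rank_sum(x, y)
        assert res.statistic == pytest.approx(w_oracle)
        assert res.p_value == pytest.approx(p_oracle)
        assert "exact" in res.method

    def test_random_small_instances_match_enumeration(self):
        rng = np.random.default_rng(30)
        for _ in range(30):
            nx, ny = rng.integers(2, 6, size=2)
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = list(pooled[:nx]), list(pooled[nx:])
            w_oracle, p_oracle = rank_sum_enumeration(x, y)
            res = wilcoxon_rank_sum(x, y)
            assert res.statistic == pytest.approx(w_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(31)
        x, y = rng.normal(size=10), rng.normal(size=12)
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(x + 100.0, y + 100.0)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_ties_fall_back_to_midrank_normal(self):
        res = wilcoxon_rank_sum([1, 1, 2, 3], [2, 3, 3, 4])
        assert "asymptotic" in res.method
        assert 0 <= res.p_value <= 1


class TestCountTertileTests:
    def test_equal_distributions_not_significant(self):
        counts = {"low": [1, 2, 3] * 10, "medium": [1, 2, 3] * 10,
                  "high": [1, 2, 3] * 10}
        res = paralog_count_tertile_tests(counts)
        for r in res.values():
            assert r.p_value > 0.9

    def test_zero_exclusion_filter(self):
        counts = {"low": [0, 0, 2, 3], "medium": [1, 1, 1, 2], "high": [2, 2, 3, 4]}
        res = paralog_count_tertile_tests(counts, restrict_to_positive=True)
        low_medium = res[("low", "medium")]
        # low becomes {2,3} after exclusion
        assert low_medium.extra["n_x"] == 2

    def test_emptied_tertile_skipped(self):
        counts = {"low": [0, 0], "medium": [1, 2], "high": [2, 3]}
        res = paralog_count_tertile_tests(counts, restrict_to_positive=True)
        assert res[("low", "medium")] == "skipped"
        assert res[("high", "medium")] != "skipped"

    def test_built_in_effect_detected_with_power(self):
        """Elevated counts in medium/high tertiles are detected reliably."""
        rng = np.random.default_rng(32)
        detections = 0
        reps = 60
        for _ in range(reps):
            low = rng.poisson(1.2, 60) + 1
            medium = rng.poisson(2.4, 60) + 1
            high = rng.poisson(2.4, 60) + 1
            res = paralog_count_tertile_tests(
                {"low": list(low), "medium": list(medium), "high": list(high)},
                restrict_to_positive=True,
            )
            ok = (
                res[("low", "medium")].p_value < 0.05
                and res[("high", "low")].p_value < 0.05
            )
            detections += ok
        assert detections / reps >= 0.8
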