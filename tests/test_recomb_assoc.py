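"""Liftover, gene pooling, rate assignment, tertiles and the median-test
battery, checked against longhand and brute-force oracles."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saconflict import (
    DegenerateDataError,
    InsufficientDataError,
    LiftoverMap,
    RecombWindow,
    ValidationError,
    assign_recomb_rate,
    assign_tertiles,
    levenes_test,
    liftover,
    moods_median_test,
    pairwise_posthoc_median,
    pool_gene_sai,
    two_sample_median_z,
)


def make_map(rows):
    return LiftoverMap.from_tuples(rows)


class TestLiftover:
    def test_identity_block(self):
        lmap = make_map([("2L", 0, 10_000, "2L", 0, "+")])
        assert liftover("2L", 1000, lmap) == ("2L", 1000)

    def test_affine_shift(self):
        lmap = make_map([("2L", 0, 10_000, "2L", 500, "+")])
        assert liftover("2L", 1000, lmap) == ("2L", 1500)

    def test_position_outside_blocks_unmapped(self):
        lmap = make_map([("2L", 0, 10_000, "2L", 500, "+")])
        assert liftover("2L", 20_000, lmap) is None
        assert liftover("3R", 1000, lmap) is None

    def test_minus_strand_reverses_order(self):
        lmap = make_map([("2L", 0, 10, "2L", 100, "-")])
        # first source base maps to last target base
        assert liftover("2L", 1, lmap) == ("2L", 110)
        assert liftover("2L", 10, lmap) == ("2L", 101)

    def test_overlapping_source_blocks_rejected(self):
        with pytest.raises(ValidationError):
            make_map([("2L", 0, 100, "2L", 0, "+"), ("2L", 50, 150, "2L", 500, "+")])

    def test_round_trip_through_inverse(self):
        lmap = make_map(
            [("2L", 0, 1000, "2L", 5000, "+"), ("2L", 2000, 3000, "2L", 9000, "+")]
        )
        inv = lmap.invert()
        for pos in (1, 500, 1000, 2001, 3000):
            mapped = lmap.map_position("2L", pos)
            assert mapped is not None
            assert inv.map_position(*mapped) == ("2L", pos)

    def test_injective_on_mapped_region(self):
        lmap = make_map(
            [("2L", 0, 500, "2L", 900, "+"), ("2L", 500, 1000, "2L", 3000, "-")]
        )
        images = [lmap.map_position("2L", p) for p in range(1, 1001)]
        assert len(set(images)) == len(images)


class TestGenePooling:
    def make_snps(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "pos", "category", "sai"]
        )

    def test_singleton_and_mean(self):
        snps = self.make_snps(
            [
                ("g1", "2L", 100, "missense", -0.4),
                ("g2", "2L", 900, "missense", -0.2),
                ("g2", "2L", 950, "missense", -0.6),
            ]
        )
        out = {g.gene_id: g for g in pool_gene_sai(snps, category="missense")}
        assert out["g1"].mean_sai == pytest.approx(-0.4)
        assert out["g2"].mean_sai == pytest.approx(-0.4)
        assert out["g2"].n_snps == 2

    def test_category_filter_drops_gene_without_qualifying_snps(self):
        snps = self.make_snps(
            [
                ("g1", "2L", 100, "missense", -0.4),
                ("g2", "2L", 900, "regulatory", -0.2),
            ]
        )
        genes = [g.gene_id for g in pool_gene_sai(snps, category="missense")]
        assert genes == ["g1"]

    def test_locality(self):
        snps = self.make_snps(
            [
                ("g1", "2L", 100, "missense", -0.4),
                ("g2", "2L", 900, "missense", -0.8),
            ]
        )
        both = {g.gene_id: g.mean_sai for g in pool_gene_sai(snps)}
        only_g1 = {
            g.gene_id: g.mean_sai
            for g in pool_gene_sai(snps[snps["gene_id"] == "g1"])
        }
        assert both["g1"] == only_g1["g1"]


class TestRecombAssignment:
    def test_containment(self):
        windows = [RecombWindow("2L", 0, 1000, 2.5)]
        assert assign_recomb_rate("2L", 100, 200, windows) == pytest.approx(2.5)

    def test_length_weighted_mean(self):
        windows = [RecombWindow("2L", 0, 100, 1.0), RecombWindow("2L", 100, 200, 3.0)]
        assert assign_recomb_rate("2L", 50, 150, windows) == pytest.approx(2.0)

    def test_no_overlap_returns_missing(self):
        windows = [RecombWindow("2L", 0, 100, 1.0)]
        assert assign_recomb_rate("2L", 500, 600, windows) is None
        assert assign_recomb_rate("3R", 50, 60, windows) is None

    def test_invariant_to_window_splitting(self):
        whole = [RecombWindow("2L", 0, 300, 2.0), RecombWindow("2L", 300, 600, 5.0)]
        split = [
            RecombWindow("2L", 0, 150, 2.0),
            RecombWindow("2L", 150, 300, 2.0),
            RecombWindow("2L", 300, 450, 5.0),
            RecombWindow("2L", 450, 600, 5.0),
        ]
        for start, end in [(0, 600), (100, 500), (290, 310)]:
            assert assign_recomb_rate("2L", start, end, whole) == pytest.approx(
                assign_recomb_rate("2L", start, end, split)
            )

    def test_window_validation(self):
        with pytest.raises(ValidationError):
            RecombWindow("2L", 100, 100, 1.0)
        with pytest.raises(ValidationError):
            RecombWindow("2L", 0, 100, -1.0)


class TestTertiles:
    def test_one_per_tertile(self):
        assert assign_tertiles([-0.9, -0.5, -0.1]) == ["high", "medium", "low"]

    def test_exact_thirds(self):
        labels = assign_tertiles(list(np.linspace(-1, 0, 9)))
        from collections import Counter

        assert Counter(labels) == {"high": 3, "medium": 3, "low": 3}

    def test_remainder_goes_to_high_intensity(self):
        values = list(np.linspace(-1, 0, 10))
        labels = assign_tertiles(values)
        from collections import Counter

        counts = Counter(labels)
        assert counts == {"high": 4, "medium": 3, "low": 3}
        # the extra member is the 4th most negative value
        assert labels[3] == "high" and labels[4] == "medium"

    def test_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in range(3, 40):
            labels = assign_tertiles(rng.normal(size=n))
            from collections import Counter

            sizes = Counter(labels).values()
            assert max(sizes) - min(sizes) <= 1

    def test_permutation_invariance_with_ties(self):
        values = [-0.5, -0.5, -0.5, -0.2, -0.2, -0.9]
        ids = ["a", "b", "c", "d", "e", "f"]
        base = dict(zip(ids, assign_tertiles(values, ids)))
        rng = np.random.default_rng(1)
        for _ in range(5):
            perm = rng.permutation(len(ids))
            labels = assign_tertiles(
                [values[i] for i in perm], [ids[i] for i in perm]
            )
            assert {ids[i]: lab for i, lab in zip(perm, labels)} == base

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            assign_tertiles([-1.0, -0.5])


def brute_force_median_chi2(groups):
    """Independent longhand chi-square on the 2xk above/at-or-below table."""
    pooled = np.concatenate(groups)
    grand = np.median(pooled)
    table = np.array(
        [[np.sum(g > grand) for g in groups], [np.sum(g <= grand) for g in groups]],
        dtype=float,
    )
    expected = table.sum(1, keepdims=True) * table.sum(0, keepdims=True) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((table - expected) ** 2 / expected).sum()
    return chi2, table


class TestMoodsMedianTest:
    def test_identical_groups(self):
        res = moods_median_test([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_longhand(self):
        res = moods_median_test([[1, 2, 3, 4], [5, 6, 7, 8]])
        assert res.extra["grand_median"] == pytest.approx(4.5)
        assert res.extra["table"] == [[0.0, 4.0], [4.0, 0.0]]
        assert res.statistic == pytest.approx(8.0)
        assert res.df == 1

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            groups = [rng.normal(size=rng.integers(5, 30)) for _ in range(3)]
            ours = moods_median_test(groups)
            stat, p, med, tbl = stats.median_test(
                *groups, ties="below", correction=False
            )
            assert ours.statistic == pytest.approx(stat, rel=1e-10)
            assert ours.p_value == pytest.approx(p, rel=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=12) for _ in range(3)]
        base = moods_median_test(groups).statistic
        for f in (np.exp, np.arctan, lambda x: x**3):
            assert moods_median_test([f(g) for g in groups]).statistic == (
                pytest.approx(base)
            )

    def test_degenerate_pooled_sample(self):
        with pytest.raises(DegenerateDataError):
            moods_median_test([[1.0, 1.0], [1.0, 1.0]])

    def test_contract_violations(self):
        with pytest.raises(ValidationError):
            moods_median_test([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            moods_median_test([[1.0, 2.0], []])


class TestTwoSampleMedianZ:
    def test_identical_samples_give_zero(self):
        res = two_sample_median_z([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=9), rng.normal(1.0, 1.0, size=14)
        assert two_sample_median_z(a, b).statistic == pytest.approx(
            -two_sample_median_z(b, a).statistic
        )

    def test_small_instance_hypergeometric_longhand(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [5.0, 6.0, 7.0, 8.0]
        # N=8, m=4 above the grand median 4.5; a has 0 above.
        # E = 4*4/8 = 2; Var = 4*4*4*4 / (64*7) = 4/7
        res = two_sample_median_z(a, b)
        assert res.statistic == pytest.approx((0 - 2) / math.sqrt(4 / 7))

    def test_z_squared_equals_scaled_chi_square(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 10))
            b = rng.normal(size=rng.integers(3, 10))
            n = len(a) + len(b)
            chi2, _ = brute_force_median_chi2([a, b])
            z = two_sample_median_z(a, b).statistic
            assert z * z == pytest.approx(chi2 * (n - 1) / n, rel=1e-9)


class TestLevene:
    def test_duplicated_group_gives_zero_f(self):
        res = levenes_test([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_closed_form(self):
        # deviations from group means: {1,1} vs {5,5}; zero within-group
        # spread makes the longhand F infinite
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = levenes_test([[0.0, 2.0], [-5.0, 5.0]])
        z1, z2 = np.array([1.0, 1.0]), np.array([5.0, 5.0])
        grand = np.concatenate([z1, z2]).mean()
        between = 2 * ((z1.mean() - grand) ** 2 + (z2.mean() - grand) ** 2) / 1
        within = (np.sum((z1 - z1.mean()) ** 2) + np.sum((z2 - z2.mean()) ** 2)) / 2
        if within == 0:
            assert not np.isfinite(res.statistic) or res.statistic > 1e10
        else:
            assert res.statistic == pytest.approx(between / within)
        assert res.df == (1, 2)

    def test_brown_forsythe_option(self):
        rng = np.random.default_rng(14)
        groups = [rng.normal(size=20), rng.normal(0, 3, size=20)]
        classic = levenes_test(groups, center="mean")
        robust = levenes_test(groups, center="median")
        assert classic.method != robust.method
        assert robust.p_value < 0.05  # 9x variance ratio is detectable

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            levenes_test([[1.0], [1.0, 2.0]])


class TestPosthoc:
    def test_three_identical_groups_all_adjusted_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        results = pairwise_posthoc_median([g, g, g], ["low", "medium", "high"])
        assert len(results) == 3
        for r in results:
            assert r.extra["p_adjusted"] == pytest.approx(1.0)

    def test_single_shifted_group_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        c = rng.normal(3.0, 1.0, size=40)
        results = pairwise_posthoc_median([a, b, c], ["a", "b", "c"])
        by_pair = {r.extra["pair"]: r.extra["p_adjusted"] for r in results}
        assert by_pair[("a", "b")] == max(by_pair.values())
        assert min(by_pair[("a", "c")], by_pair[("b", "c")]) < by_pair[("a", "b")]

    def test_bonferroni_factor_is_pair_count(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(size=15) for _ in range(4)]
        results = pairwise_posthoc_median(groups)
        assert len(results) == len(list(itertools.combinations(range(4), 2)))
        for r in results:
            assert r.extra["p_adjusted"] == pytest.approx(
                min(1.0, r.p_value * len(results))
            )
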