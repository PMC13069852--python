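"""Gene-set statistics: Mann-Whitney against an exhaustive-enumeration
oracle, resampling-null correctness, constraint summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from markerauc import (
    ConstraintTable,
    GeneSet,
    compare_sets_mannwhitney,
    constraint_summary,
    cross_dataset_consistency,
    pairwise_compare,
    resample_null,
)


def exact_mwu_two_sided(a, b):
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating
    every assignment of the pooled ranks to group A (tie-free input)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    order = pooled.argsort()
    ranks = np.empty(pooled.size)
    ranks[order] = np.arange(1, pooled.size + 1)
    n_a = a.size
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = []
    for idx in combinations(range(pooled.size), n_a):
        r = sum(ranks[list(idx)])
        us.append(r - n_a * (n_a + 1) / 2)
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2 * min(cdf, sf))


class TestMannWhitney:
    def test_worked_example(self):
        """A=[0.9,0.8] vs B=[0.5,0.6]: U=4, exact two-sided p=1/3."""
        r = compare_sets_mannwhitney([0.9, 0.8], [0.5, 0.6])
        assert r.u_statistic == 4
        assert r.p_two_sided == pytest.approx(1 / 3)
        assert r.median_diff == pytest.approx(0.30)

    def test_identical_samples_give_p_one(self):
        values = [0.4, 0.4, 0.4]
        r = compare_sets_mannwhitney(values, values)
        assert r.p_two_sided == 1.0
        assert r.median_diff == 0.0

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            compare_sets_mannwhitney([], [1.0])

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """Tie-free samples with n_a = n_b <= 5: p equals exhaustive
        enumeration over all rank arrangements, exactly."""
        for n in (1, 2, 3, 4, 5):
            for _ in range(20):
                a = rng.normal(size=n)
                b = rng.normal(size=n)
                r = compare_sets_mannwhitney(a, b)
                assert r.p_two_sided == pytest.approx(exact_mwu_two_sided(a, b), abs=1e-12)

    def test_exact_p_matches_oracle_unbalanced(self, rng):
        for n_a, n_b in [(2, 5), (3, 6), (4, 3)]:
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            r = compare_sets_mannwhitney(a, b)
            assert r.p_two_sided == pytest.approx(exact_mwu_two_sided(a, b), abs=1e-12)

    def test_exact_and_normal_approximation_agree(self, rng):
        """Tie-free 8x8 samples: enumeration vs tie-corrected normal
        approximation with continuity correction, within 0.02."""
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            p_asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert p_asym == pytest.approx(exact_mwu_two_sided(a, b), abs=0.02)

    def test_shifted_large_samples_significant(self, rng):
        a = rng.uniform(0.4, 0.8, size=200)
        b = a + 0.2
        r = compare_sets_mannwhitney(b, a)
        assert r.p_two_sided < 0.01
        assert r.median_diff > 0

    def test_median_diff_antisymmetric(self, rng):
        a = rng.uniform(size=30)
        b = rng.uniform(size=20)
        ab = compare_sets_mannwhitney(a, b)
        ba = compare_sets_mannwhitney(b, a)
        assert ab.median_diff == pytest.approx(-ba.median_diff)
        assert ab.p_two_sided == pytest.approx(ba.p_two_sided)


class TestPairwiseCompare:
    def test_identical_sets_not_flagged(self):
        values = list(np.linspace(0.3, 0.9, 25))
        df = pairwise_compare({"a": values, "b": values})
        row = df[(df.set_a == "a") & (df.set_b == "b")].iloc[0]
        assert row.p_two_sided == pytest.approx(1.0)
        assert row.median_diff == 0.0
        assert row.stars == ""

    def test_only_shifted_pairs_flagged(self, rng):
        base = rng.uniform(0.4, 0.6, size=80)
        sets = {
            "null1": base + rng.normal(0, 0.01, 80),
            "null2": base + rng.normal(0, 0.01, 80),
            "shifted": base + 0.25,
        }
        df = pairwise_compare(sets)
        flagged = {
            frozenset((r.set_a, r.set_b)) for r in df.itertuples() if r.p_two_sided < 0.01
        }
        assert frozenset(("shifted", "null1")) in flagged
        assert frozenset(("shifted", "null2")) in flagged
        assert frozenset(("null1", "null2")) not in flagged

    def test_bh_controls_flags_under_null(self, rng):
        """All sets drawn from one distribution: few BH-flagged pairs."""
        n_flagged, n_pairs = 0, 0
        for _ in range(60):
            sets = {f"s{i}": rng.uniform(size=40) for i in range(4)}
            df = pairwise_compare(sets, adjust="bh")
            upper = df.drop_duplicates(subset=["p_two_sided", "q_bh"])
            n_flagged += int((upper["q_bh"] < 0.05).sum())
            n_pairs += len(upper)
        assert n_flagged / n_pairs <= 0.05 + 0.02

    def test_single_set_is_error(self):
        with pytest.raises(ValueError):
            pairwise_compare({"only": [1.0, 2.0]})


class TestResampleNull:
    def test_observed_below_all_nulls_gives_p_one(self):
        universe = np.linspace(0.5, 1.0, 50)
        r = resample_null([0.0, 0.0], universe, B=99, seed=1)
        assert r.p_empirical == 1.0

    def test_observed_above_all_nulls_gives_add_one_floor(self):
        universe = np.linspace(0.0, 0.5, 50)
        r = resample_null([0.9, 0.95], universe, B=999, seed=1)
        assert r.p_empirical == pytest.approx(1 / 1000)

    def test_exhaustive_mode_matches_enumeration(self):
        universe = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        target = [0.7, 0.9]
        r = resample_null(target, universe, set_size=2, exhaustive=True)
        medians = [np.median(universe[list(c)]) for c in combinations(range(5), 2)]
        expected = (1 + sum(m >= np.median(target) for m in medians)) / (len(medians) + 1)
        assert r.B == 10
        assert r.p_empirical == pytest.approx(expected)

    def test_reproducible_given_seed(self):
        universe = np.random.default_rng(3).uniform(size=200)
        r1 = resample_null(universe[:20], universe, B=199, seed=5)
        r2 = resample_null(universe[:20], universe, B=199, seed=5)
        assert np.array_equal(r1.null_stats, r2.null_stats)
        assert r1.p_empirical == r2.p_empirical

    def test_p_never_zero(self, rng):
        universe = rng.uniform(size=100)
        for seed in range(5):
            r = resample_null(universe[:10] + 10, universe, B=49, seed=seed)
            assert r.p_empirical > 0

    def test_set_larger_than_universe_is_error(self):
        with pytest.raises(ValueError):
            resample_null([1, 2, 3], [1, 2], B=9)


class TestConstraintSummary:
    def _table(self, mapping):
        return ConstraintTable(loeuf=pd.Series(mapping))

    def test_median_and_fraction(self):
        t = self._table({"A": 0.3, "B": 0.7, "C": 0.5})
        s = constraint_summary(GeneSet("x", frozenset("ABC")), t)
        assert s.median_loeuf == pytest.approx(0.5)
        assert s.fraction_above_threshold == pytest.approx(1 / 3)

    def test_all_below_threshold(self):
        t = self._table({"A": 0.1, "B": 0.2})
        s = constraint_summary(GeneSet("x", frozenset("AB")), t)
        assert s.fraction_above_threshold == 0.0

    def test_unmatched_genes_reported(self):
        t = self._table({"A": 0.5})
        s = constraint_summary(GeneSet("x", frozenset({"A", "MISSING"})), t)
        assert s.n_matched == 1 and s.n_unmatched == 1

    def test_zero_matched_is_error(self):
        t = self._table({"A": 0.5})
        with pytest.raises(ValueError):
            constraint_summary(GeneSet("x", frozenset({"Z"})), t)


class TestCrossDataset:
    def test_identical_distributions_give_p_one(self):
        v = list(np.linspace(0.2, 0.9, 30))
        out = cross_dataset_consistency({"s": (v, v)})
        assert out["s"].p_two_sided == pytest.approx(1.0, abs=1e-6)

    def test_shifted_dataset_flagged(self, rng):
        v = rng.uniform(0.3, 0.7, size=100)
        out = cross_dataset_consistency({"s": (v, v + 0.2)})
        assert out["s"].p_two_sided < 0.01

    def test_same_generator_rarely_significant(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            out = cross_dataset_consistency(
                {"s": (r.uniform(size=60), r.uniform(size=60))}
            )
            hits += out["s"].p_two_sided < 0.05
        assert hits / 20 <= 0.10

    def test_missing_dataset_is_error(self):
        with pytest.raises(ValueError):
            cross_dataset_consistency({"s": ([1.0], [])})
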