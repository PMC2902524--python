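import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regged.ddd import PooledCounts, ddd_enrichment, pool_libraries
from regged.io import LibraryCounts
from regged.simulate import simulate_library_counts


def hypergeom_tail_oracle(a: int, b: int, n_a: int, n_b: int) -> float:
    """Exhaustive hypergeometric tail sum P(X >= a) computed from binomial
    coefficients only; independent of scipy."""
    total, drawn = n_a + n_b, a + b
    den = math.comb(total, drawn)
    num = sum(
        math.comb(n_a, k) * math.comb(n_b, drawn - k) for k in range(a, min(drawn, n_a) + 1)
    )
    return num / den


def _pooled(a, b, n_a, n_b, cluster="CL1"):
    table = pd.DataFrame({"pool_a": [a], "pool_b": [b]}, index=[cluster])
    return PooledCounts(table=table, total_a=n_a, total_b=n_b)


class TestPooling:
    def test_pooled_counts_sum_libraries(self):
        counts = LibraryCounts(
            counts=pd.DataFrame({"l1": [3, 1], "l2": [4, 0], "l3": [2, 5]}, index=["c1", "c2"])
        )
        pooled = pool_libraries(counts, ["l1", "l2"], ["l3"])
        assert pooled.table.loc["c1", "pool_a"] == 7
        assert pooled.total_a == 8 and pooled.total_b == 7

    def test_totals_conserve_library_sizes(self, rng):
        df = pd.DataFrame(rng.integers(0, 20, size=(30, 4)),
                          index=[f"c{i}" for i in range(30)], columns=list("abcd"))
        counts = LibraryCounts(counts=df)
        pooled = pool_libraries(counts, ["a", "b"], ["c", "d"])
        assert pooled.total_a + pooled.total_b == int(df.to_numpy().sum())
        expected = df[["a", "b"]].sum(axis=1)  # brute-force summation
        pd.testing.assert_series_equal(pooled.table["pool_a"], expected, check_names=False)

    @pytest.mark.parametrize("a, b", [(["l1"], ["l1"]), ([], ["l1"]), (["l1"], ["nope"])])
    def test_invalid_pools_rejected(self, a, b):
        counts = LibraryCounts(counts=pd.DataFrame({"l1": [1], "l2": [1]}, index=["c1"]))
        with pytest.raises(ValueError):
            pool_libraries(counts, a, b)


class TestFisherPValues:
    def test_identical_frequencies_not_flagged(self):
        result = ddd_enrichment(_pooled(10, 10, 100, 100))
        assert result["pvalue"].iloc[0] > 0.5
        assert not result["enriched"].iloc[0]

    def test_reference_table_matches_exhaustive_oracle(self):
        result = ddd_enrichment(_pooled(10, 1, 100, 1000))
        assert result["pvalue"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(10, 1, 100, 1000), rel=1e-12
        )

    def test_agrees_with_oracle_on_all_small_tables(self):
        # every 2x2 table with pool totals <= 12 each, plus a random sample
        # of larger tables with combined total <= 500
        tables = [
            (a, b, n_a, n_b)
            for n_a in range(1, 13)
            for n_b in range(1, 13)
            for a in range(n_a + 1)
            for b in range(n_b + 1)
            if a + b > 0
        ]
        rng = np.random.default_rng(99)
        for _ in range(300):
            n_a = int(rng.integers(1, 400))
            n_b = int(rng.integers(1, 500 - n_a + 1))
            a = int(rng.integers(0, n_a + 1))
            b = int(rng.integers(0, n_b + 1))
            if a + b > 0:
                tables.append((a, b, n_a, n_b))
        # implementation runs vectorised per pool-total pair
        for (n_a, n_b) in {(t[2], t[3]) for t in tables}:
            subset = [t for t in tables if t[2] == n_a and t[3] == n_b]
            table = pd.DataFrame(
                {"pool_a": [t[0] for t in subset], "pool_b": [t[1] for t in subset]},
                index=[f"c{i}" for i in range(len(subset))],
            )
            result = ddd_enrichment(PooledCounts(table=table, total_a=n_a, total_b=n_b))
            result = result.sort_index(key=lambda idx: idx.str.slice(1).astype(int))
            for (a, b, *_), p in zip(subset, result["pvalue"]):
                assert p == pytest.approx(hypergeom_tail_oracle(a, b, n_a, n_b), rel=1e-9)

    def test_cross_check_against_fisher_exact(self):
        for a, b, n_a, n_b in [(5, 2, 50, 80), (0, 7, 30, 60), (12, 12, 40, 40)]:
            result = ddd_enrichment(_pooled(a, b, n_a, n_b))
            expected = stats.fisher_exact(
                [[a, n_a - a], [b, n_b - b]], alternative="greater"
            )[1]
            assert result["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)


class TestEnrichmentCalls:
    def test_swapping_pools_and_direction_is_identity(self, rng):
        table = pd.DataFrame(
            {"pool_a": rng.integers(0, 30, 50), "pool_b": rng.integers(0, 30, 50)},
            index=[f"c{i}" for i in range(50)],
        )
        table = table[(table.sum(axis=1) > 0)]
        pooled = PooledCounts(table=table, total_a=2000, total_b=3000)
        swapped = PooledCounts(
            table=table.rename(columns={"pool_a": "pool_b", "pool_b": "pool_a"}),
            total_a=3000, total_b=2000,
        )
        flagged_a = set(ddd_enrichment(pooled).query("enriched").index)
        flagged_b = set(ddd_enrichment(swapped, direction="B-enriched").query("enriched").index)
        assert flagged_a == flagged_b

    def test_flagged_set_monotone_in_alpha(self, rng):
        table = pd.DataFrame(
            {"pool_a": rng.integers(0, 40, 80), "pool_b": rng.integers(0, 40, 80)},
            index=[f"c{i}" for i in range(80)],
        )
        table = table[table.sum(axis=1) > 0]
        pooled = PooledCounts(table=table, total_a=1500, total_b=1500)
        previous = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            flagged = set(ddd_enrichment(pooled, alpha=alpha).query("enriched").index)
            if previous is not None:
                assert flagged <= previous
            previous = flagged

    def test_zero_count_ratio_uses_half_count_substitution(self):
        result = ddd_enrichment(_pooled(10, 0, 100, 1000))
        assert result["ratio"].iloc[0] == pytest.approx((10 / 100) / (0.5 / 1000))
        # p-value must use the true zero count
        assert result["pvalue"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(10, 0, 100, 1000), rel=1e-12
        )

    def test_absent_clusters_skipped(self):
        table = pd.DataFrame({"pool_a": [5, 0], "pool_b": [3, 0]}, index=["c1", "c2"])
        result = ddd_enrichment(PooledCounts(table=table, total_a=100, total_b=100))
        assert list(result.index) == ["c1"]

    def test_simulated_truth_recovered(self):
        # 10-fold enriched clusters, pools 5000 vs 25000: all true positives
        # found, false positives within the alpha budget over 50 seeds
        n_null, alpha = 190, 0.05
        false_rates = []
        for seed in range(50):
            counts, enriched = simulate_library_counts(
                200, {"a1": 5000, "b1": 25000}, ["a1"],
                n_enriched_clusters=10, enrichment_ratio=10.0, seed=seed,
            )
            pooled = pool_libraries(counts, ["a1"], ["b1"])
            result = ddd_enrichment(pooled, alpha=alpha)
            flagged = set(result.query("enriched").index)
            assert set(enriched) <= flagged
            false_rates.append(len(flagged - set(enriched)) / n_null)
        se = math.sqrt(alpha * (1 - alpha) / (n_null * 50))
        assert np.mean(false_rates) <= alpha + 3 * se

    def test_bh_correction_never_flags_more(self, rng):
        table = pd.DataFrame(
            {"pool_a": rng.integers(0, 25, 60), "pool_b": rng.integers(0, 25, 60)},
            index=[f"c{i}" for i in range(60)],
        )
        table = table[table.sum(axis=1) > 0]
        pooled = PooledCounts(table=table, total_a=800, total_b=900)
        plain = set(ddd_enrichment(pooled).query("enriched").index)
        corrected = set(ddd_enrichment(pooled, bh_correction=True).query("enriched").index)
        assert corrected <= plain
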