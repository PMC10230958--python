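"""Relative distance plasticity index: enumeration, bounds, invariances,
variants, and genotype comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rootplast.plasticity import (
    compare_genotypes,
    mean_rdpi_contrast,
    pooled_distance_set,
    rdpi,
    rdpi_variants,
    relative_distances,
    RDPIResult,
)
from rootplast.trait_data import LONG_COLUMNS, PhenotypeTable
from conftest import plot_table
from _oracles import rdpi_bruteforce


def table_from_env_values(values_by_env, genotype="g"):
    rows = []
    for env, vals in values_by_env.items():
        for i, v in enumerate(vals):
            rows.append((genotype, env, i + 1, v))
    return plot_table(rows)


class TestRelativeDistances:
    def test_enumerated_cross_pairs(self):
        t = table_from_env_values({0: [2.0, 4.0], 15: [6.0, 8.0]})
        ds = relative_distances(t, "g", "T", 0, 15)
        assert sorted(np.round(ds.distances, 10)) == sorted(
            np.round([0.5, 0.6, 0.2, 1 / 3], 10)
        )
        assert ds.n == 4

    def test_identical_environments_give_zero(self):
        t = table_from_env_values({0: [5.0, 5.0], 15: [5.0, 5.0]})
        ds = relative_distances(t, "g", "T", 0, 15)
        assert np.all(ds.distances == 0.0)

    def test_single_zero_gives_maximal_distance(self):
        t = table_from_env_values({0: [0.0], 15: [3.0]})
        ds = relative_distances(t, "g", "T", 0, 15)
        assert ds.distances.tolist() == [1.0]

    def test_double_zero_pairs_dropped_and_counted(self):
        t = table_from_env_values({0: [0.0, 1.0], 15: [0.0]})
        ds = relative_distances(t, "g", "T", 0, 15)
        assert ds.n == 1 and ds.n_dropped == 1

    def test_negative_values_rejected(self):
        t = table_from_env_values({0: [-1.0], 15: [2.0]})
        with pytest.raises(ValueError, match="negative"):
            relative_distances(t, "g", "T", 0, 15)

    def test_same_environment_rejected(self):
        t = table_from_env_values({0: [1.0]})
        with pytest.raises(ValueError, match="differ"):
            relative_distances(t, "g", "T", 0, 0)

    def test_missing_environment_rejected(self):
        t = table_from_env_values({0: [1.0], 15: [2.0]})
        with pytest.raises(ValueError, match="no observations"):
            relative_distances(t, "g", "T", 0, 30)


class TestRdpi:
    def test_enumerated_mean(self):
        t = table_from_env_values({0: [2.0, 4.0], 15: [6.0, 8.0]})
        r = rdpi(relative_distances(t, "g", "T", 0, 15))
        assert r.rdpi == pytest.approx((0.5 + 0.6 + 0.2 + 1 / 3) / 4)
        assert r.rdpi == pytest.approx(0.4083, abs=5e-5)

    def test_single_pair(self):
        t = table_from_env_values({0: [1.0], 15: [3.0]})
        assert rdpi(relative_distances(t, "g", "T", 0, 15)).rdpi == 0.5

    def test_all_equal_gives_zero(self):
        t = table_from_env_values({0: [2.0] * 3, 15: [2.0] * 3, 30: [2.0] * 3})
        results = rdpi_variants(t, "g", "T", baseline=0)
        assert all(r.rdpi == 0.0 for r in results)

    @given(st.integers(0, 10_000))
    def test_bounds_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = {
            0: rng.uniform(0, 10, size=rng.integers(1, 5)).tolist(),
            15: rng.uniform(0, 10, size=rng.integers(1, 5)).tolist(),
            30: rng.uniform(0, 10, size=rng.integers(1, 5)).tolist(),
        }
        t = table_from_env_values(vals)
        r = rdpi_variants(t, "g", "T", baseline=0)
        for res in r:
            assert 0.0 <= res.rdpi <= 1.0
        c = float(rng.uniform(0.1, 20.0))
        t2 = table_from_env_values({k: [c * v for v in vs] for k, vs in vals.items()})
        r2 = rdpi_variants(t2, "g", "T", baseline=0)
        for a, b in zip(r, r2):
            assert a.rdpi == pytest.approx(b.rdpi, rel=1e-12)

    def test_total_is_pair_count_weighted_mean_of_pairwise_variants(self):
        rng = np.random.default_rng(12)
        levels = [0, 15, 30, 45]
        vals = {lv: rng.uniform(1, 9, size=3).tolist() for lv in levels}
        t = table_from_env_values(vals)
        sets = [
            relative_distances(t, "g", "T", a, b)
            for i, a in enumerate(levels)
            for b in levels[i + 1 :]
        ]
        total = rdpi(pooled_distance_set(sets))
        weighted = sum(rdpi(s).rdpi * s.n for s in sets) / sum(s.n for s in sets)
        assert total.rdpi == pytest.approx(weighted, rel=1e-12)
        assert total.n_pairs == sum(s.n for s in sets)


class TestRdpiVariants:
    def test_six_level_design_combinatorics(self):
        rng = np.random.default_rng(13)
        levels = [0, 15, 30, 45, 60, 75]
        t = table_from_env_values({lv: rng.uniform(1, 5, size=2).tolist() for lv in levels})
        results = rdpi_variants(t, "g", "T", baseline=0)
        by_variant = {r.variant: r for r in results}
        assert set(by_variant) == {"Total", "P15", "P30", "P45", "P60", "P75"}
        # 15 unordered level pairs x 2x2 observation pairs feed the total
        assert by_variant["Total"].n_pairs == 15 * 4
        assert all(by_variant[f"P{k}"].n_pairs == 4 for k in (15, 30, 45, 60, 75))

    def test_step_response_isolates_the_responding_contrast(self):
        vals = {lv: [2.0, 2.0] for lv in (0, 15, 30, 45, 60)}
        vals[75] = [6.0, 6.0]
        t = table_from_env_values(vals)
        by_variant = {r.variant: r for r in rdpi_variants(t, "g", "T", baseline=0)}
        assert by_variant["P15"].rdpi == 0.0
        assert by_variant["P75"].rdpi == pytest.approx(0.5)
        assert by_variant["P75"].rdpi > by_variant["P15"].rdpi

    def test_flat_noisy_norm_gives_similar_small_variants(self):
        rng = np.random.default_rng(14)
        t = table_from_env_values(
            {lv: (10 + 0.1 * rng.standard_normal(6)).tolist() for lv in (0, 15, 30, 45, 60, 75)}
        )
        results = rdpi_variants(t, "g", "T", baseline=0)
        vals = np.array([r.rdpi for r in results])
        assert vals.max() < 0.02
        assert vals.max() - vals.min() < 0.01

    def test_missing_baseline_rejected(self):
        t = table_from_env_values({15: [1.0], 30: [2.0]})
        with pytest.raises(ValueError, match="baseline"):
            rdpi_variants(t, "g", "T", baseline=0)

    def test_noise_free_spread_increase_never_decreases_rdpi(self):
        """Stretching a deterministic reaction norm about its mean cannot
        reduce the plasticity index."""
        base = np.array([4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        levels = [0, 15, 30, 45, 60, 75]
        prev = -1.0
        for scale in (0.5, 1.0, 1.5, 2.0):
            norm = base.mean() + scale * (base - base.mean())
            t = table_from_env_values({lv: [v] for lv, v in zip(levels, norm)})
            r = next(x for x in rdpi_variants(t, "g", "T", baseline=0) if x.variant == "Total")
            assert r.rdpi >= prev - 1e-12
            prev = r.rdpi


class TestGenotypeComparison:
    def test_identical_distance_sets(self):
        t = table_from_env_values({0: [1.0, 2.0], 15: [3.0, 4.0]})
        d1 = relative_distances(t, "g", "T", 0, 15)
        res = compare_genotypes(d1, d1)
        assert res["difference"] == 0.0 and res["p_value"] == 1.0

    def test_too_few_distances_rejected(self):
        t = table_from_env_values({0: [1.0], 15: [3.0]})
        d = relative_distances(t, "g", "T", 0, 15)
        with pytest.raises(ValueError, match=">= 2"):
            compare_genotypes(d, d)


class TestMeanRdpiContrast:
    def _results(self, genotype, values):
        return [
            RDPIResult(genotype, trait, "Total", v, 0.01, 10)
            for trait, v in values.items()
        ]

    def test_identical_result_sets(self):
        vals = {"A": 0.2, "B": 0.3, "C": 0.25}
        res = mean_rdpi_contrast(self._results("g1", vals), self._results("g2", vals))
        assert res["pct_difference"] == 0.0 and res["p_value"] == 1.0

    def test_uniform_inflation(self):
        vals = {f"T{i}": 0.1 + 0.02 * i for i in range(10)}
        inflated = {k: 1.25 * v for k, v in vals.items()}
        res = mean_rdpi_contrast(self._results("g1", vals), self._results("g2", inflated))
        assert res["pct_difference"] == pytest.approx(25.0, rel=1e-10)
        assert res["p_value"] < 1e-4

    def test_trait_mismatch_listed(self):
        with pytest.raises(ValueError, match="B"):
            mean_rdpi_contrast(
                self._results("g1", {"A": 0.1, "B": 0.2}), self._results("g2", {"A": 0.1})
            )


class TestBruteforceAgreement:
    def test_random_small_tables_match_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            levels = sorted(rng.choice([0, 15, 30, 45, 60, 75], size=rng.integers(2, 5), replace=False))
            vals = {
                int(lv): rng.uniform(0, 10, size=rng.integers(1, 4)).tolist() for lv in levels
            }
            t = table_from_env_values(vals)
            pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
            sets = [relative_distances(t, "g", "T", a, b) for a, b in pairs]
            got = rdpi(pooled_distance_set(sets))
            want, n = rdpi_bruteforce(vals, pairs)
            assert got.rdpi == pytest.approx(want, rel=1e-12)
            assert got.n_pairs == n
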