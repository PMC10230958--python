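"""Descriptive statistics, screening filters, factorial ANOVA, correlations."""

import numpy as np
import pandas as pd
import pytest

from rootplast import (
    DesignSpec,
    DoseResponse,
    SimParams,
    anova_factorial,
    band_count,
    correlation_matrix,
    cov_filter,
    cov_from_summary,
    genotype_filter,
    simulate_trial,
    summarize,
)
from conftest import plot_table
from _oracles import anova_bruteforce


class TestSummarize:
    def test_exact_small_sample_arithmetic(self):
        t = plot_table([("g", 0, i, v) for i, v in enumerate((10, 20, 30))])
        s = summarize(t, "T")
        assert (s.mean, s.sd, s.cov_pct) == (20.0, 10.0, 50.0)
        assert s.range == 20.0

    def test_constant_vector(self):
        t = plot_table([("g", 0, i, 7.0) for i in range(4)])
        s = summarize(t, "T")
        assert s.sd == 0.0 and s.cov_pct == 0.0

    def test_published_cov_arithmetic(self):
        assert round(cov_from_summary(mean=24059, sd=11438), 1) == 47.5

    def test_nonpositive_mean_flags_cov_undefined(self):
        t = plot_table([("g", 0, 1, -1.0), ("g", 0, 2, 1.0)])
        s = summarize(t, "T")
        assert not s.cov_defined
        with pytest.raises(ValueError, match="undefined"):
            cov_from_summary(0.0, 1.0)


class TestCovFilter:
    def test_published_threshold_eliminates_thirteen(self, fixture_table):
        kept, eliminated = cov_filter(fixture_table, 30.0)
        assert len(eliminated) == 13
        assert len(kept) + len(eliminated) == 51

    def test_boundary_value_is_kept(self):
        rows = pd.DataFrame({"cov_pct": [30.0, 29.999]})
        kept, eliminated = cov_filter(rows, 30.0)
        assert kept["cov_pct"].tolist() == [30.0]
        assert eliminated["cov_pct"].tolist() == [29.999]

    def test_empty_input(self):
        kept, eliminated = cov_filter(pd.DataFrame({"cov_pct": []}), 30.0)
        assert len(kept) == 0 and len(eliminated) == 0

    def test_partition_is_exact_and_order_preserving(self, fixture_table):
        kept, eliminated = cov_filter(fixture_table, 30.0)
        merged = pd.concat([kept, eliminated]).sort_index()
        pd.testing.assert_frame_equal(merged, fixture_table)


class TestBandCount:
    def test_published_bands(self, fixture_table):
        assert band_count(fixture_table, 30, 59) == 33
        assert band_count(fixture_table, 0, np.inf) == 51
        assert band_count(fixture_table, 200, 299) == 0

    def test_invalid_band_rejected(self, fixture_table):
        with pytest.raises(ValueError):
            band_count(fixture_table, 60, 30)


class TestAnova:
    def test_pure_genotype_shift_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, shift in (("red", 0.0), ("white", 5.0)):
            for p in (0, 15):
                for blk in (1, 2):
                    for plot in (1, 2, 3):
                        rows.append((g, p, 1, blk, plot, 10 + shift + rng.normal(0, 1e-3)))
        res = anova_factorial(plot_table(rows), "T")
        assert res["genotype"]["p"] < 1e-10
        assert res["p_rate"]["p"] > 0.05  # null effect: p is uniform

    def test_matches_bruteforce_partition(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in ("a", "b"):
            for p in (0, 30):
                for run in (1, 2):
                    for blk in (1, 2):
                        for plot in (1, 2):
                            rows.append((g, p, run, blk, plot, rng.normal(10, 2)))
        t = plot_table(rows)
        res = anova_factorial(t, "T")
        oracle = anova_bruteforce(t.data)
        assert res["genotype"]["F"] == pytest.approx(oracle["F_geno"], rel=1e-10)
        assert res["p_rate"]["F"] == pytest.approx(oracle["F_p"], rel=1e-10)
        assert res["gxp"]["F"] == pytest.approx(oracle["F_gxp"], rel=1e-10)
        for k, v in oracle["ss"].items():
            assert res["ss"][k] == pytest.approx(v, rel=1e-10)

    def test_matches_statsmodels_on_simulated_trial(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        t = simulate_trial(
            DesignSpec(), SimParams(mu=20.0, sigma2={"g": 2.0, "gp": 1.0, "eps": 1.0}), ["TRL"], seed=3
        ).aggregate("plot")
        res = anova_factorial(t, "TRL")
        df = t.data.copy()
        df["blk"] = df["run"].astype(str) + "-" + df["block"].astype(str)
        fit = smf.ols("value ~ C(blk) + C(genotype) * C(p_rate)", data=df).fit()
        tab = anova_lm(fit, typ=1)
        assert res["genotype"]["F"] == pytest.approx(tab.loc["C(genotype)", "F"], rel=1e-8)
        assert res["p_rate"]["F"] == pytest.approx(tab.loc["C(p_rate)", "F"], rel=1e-8)
        assert res["gxp"]["F"] == pytest.approx(tab.loc["C(genotype):C(p_rate)", "F"], rel=1e-8)

    def test_ss_partition_sums_to_total(self):
        t = simulate_trial(
            DesignSpec(), SimParams(mu=5.0, sigma2={"g": 1.0, "p": 1.0, "eps": 1.0}), ["TRL"], seed=4
        )
        res = anova_factorial(t.aggregate("plot"), "TRL")
        parts = sum(res["ss"][k] for k in ("blocks", "genotype", "p_rate", "gxp", "residual"))
        assert parts == pytest.approx(res["ss"]["total"], rel=1e-8)

    def test_unbalanced_table_rejected(self):
        rows = [("a", 0, 1, 1.0), ("a", 15, 1, 2.0), ("a", 15, 2, 3.0), ("b", 0, 1, 2.0), ("b", 15, 1, 1.0)]
        with pytest.raises(ValueError, match="unbalanced"):
            anova_factorial(plot_table(rows), "T")

    def test_power_monotone_in_effect_size(self):
        """Genotype-shift detection rate never decreases across 3 effect sizes."""
        d = DesignSpec()
        rates = []
        for delta in (0.0, 0.5, 1.0):
            rng = np.random.default_rng(17)
            dose = {"G1": DoseResponse(0.0, 0.0, 1.0), "G2": DoseResponse(delta, 0.0, 1.0)}
            rej = 0
            n = 40
            for _ in range(n):
                t = simulate_trial(
                    d, SimParams(mu=10.0, sigma2={"eps": 1.0}, dose_response=dose), ["TRL"], seed=rng
                ).aggregate("plot")
                rej += anova_factorial(t, "TRL")["genotype"]["p"] < 0.05
            rates.append(rej / n)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9


class TestGenotypeFilter:
    def test_strict_boundary(self):
        reports = pd.DataFrame({"trait": ["a", "b"], "p_geno": [0.04, 0.05]}).set_index("trait")
        kept, eliminated = genotype_filter(reports, alpha=0.05)
        assert list(kept.index) == ["a"]
        assert list(eliminated.index) == ["b"]

    def test_missing_p_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            genotype_filter({"t": {"genotype": {}}})

    def test_null_simulation_keeps_about_alpha_fraction(self):
        traits = [f"T{i}" for i in range(100)]
        t = simulate_trial(DesignSpec(), SimParams(mu=10.0, sigma2={"eps": 1.0}), traits, seed=21)
        plot = t.aggregate("plot")
        reports = {tr: anova_factorial(plot, tr) for tr in traits}
        kept, _ = genotype_filter(reports, alpha=0.05)
        assert 0 <= len(kept) <= 12  # ~5 expected of 100 under the null


def _multi_trait_table(trait_values: dict):
    """Plot-level table with several traits over one shared plot grid."""
    from rootplast.trait_data import PhenotypeTable

    frames = []
    for name, vals in trait_values.items():
        f = plot_table([("g", 0, i + 1, v) for i, v in enumerate(vals)]).data
        f["trait"] = name
        frames.append(f)
    return PhenotypeTable(pd.concat(frames, ignore_index=True), level="plot")


class TestCorrelations:
    def test_affine_invariance_and_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        r, p = correlation_matrix(
            _multi_trait_table({"X": x, "Y": 2 * x + 1, "Z": -x, "W": rng.normal(size=8)})
        )
        assert r.loc["X", "X"] == 1.0
        assert r.loc["X", "Y"] == pytest.approx(1.0)
        assert r.loc["X", "Z"] == pytest.approx(-1.0)
        assert np.allclose(r, r.T, equal_nan=True)

    def test_five_point_hand_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r, _ = correlation_matrix(_multi_trait_table({"T": x, "U": y}))
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r.loc["T", "U"] == pytest.approx(manual, rel=1e-12)

    def test_zero_variance_trait_flagged_nan(self):
        r, p = correlation_matrix(
            _multi_trait_table({"T": [1.0, 2.0, 3.0], "C": [5.0, 5.0, 5.0]})
        )
        assert np.isnan(r.loc["T", "C"]) and np.isnan(p.loc["T", "C"])
        assert r.loc["C", "C"] == 1.0
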