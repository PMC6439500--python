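"""Diversity panel: heterozygosity, rarefaction, private alleles, HWE, LD,
g2, and the diversity-vs-history analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from introtrace.data import MISSING, GenotypeDataset
from introtrace.diversity import (
    diversity_report,
    g2_inbreeding_test,
    heterozygosity_summary,
    hwe_exact_test,
    multilocus_ld_test,
    population_diversity_comparison,
    population_means,
    private_allele_count,
    rarefied_allelic_richness,
    render_diversity_table,
    retention_ratio,
    steps_regression,
)
from introtrace.history import ImportationEvent, ImportationHistory
from introtrace.reference import reported_diversity
from introtrace.simulate import SimulationConfig, apply_founder_event, sample_dataset, simulate_base_population
from .conftest import hw_dataset, hw_genotypes


def single_pop(calls: np.ndarray, loci=None) -> GenotypeDataset:
    n, L, _ = calls.shape
    return GenotypeDataset(
        [f"i{k}" for k in range(n)], ["P"] * n,
        loci or [f"L{j+1}" for j in range(L)], calls,
    )


class TestHeterozygosity:
    def test_closed_form_small_sample(self):
        # AA:1, AB:2, BB:1 -> H_O=0.5, H_E=(8/7)*0.5, F_IS=0.125
        calls = np.array([[[101, 101]], [[101, 102]], [[101, 102]], [[102, 102]]])
        df = heterozygosity_summary(single_pop(calls))
        row = df.iloc[0]
        assert row["H_O"] == pytest.approx(0.5)
        assert row["H_E"] == pytest.approx(8 / 7 * 0.5)
        assert row["F_IS"] == pytest.approx(1 - 0.5 / (8 / 7 * 0.5))
        assert row["F_IS"] == pytest.approx(0.125)

    def test_all_heterozygotes_negative_fis(self):
        calls = np.tile(np.array([[[101, 102]]]), (8, 1, 1))
        df = heterozygosity_summary(single_pop(calls))
        assert df.iloc[0]["H_O"] == 1.0
        assert df.iloc[0]["F_IS"] < 0

    def test_random_mating_fis_near_zero(self):
        """Mean F_IS over replicates of a large random-mating population is
        within 0.02 of zero."""
        fis = []
        for rep in range(50):
            ds = hw_dataset({"P": 500}, {"P": [np.full(4, 0.25)] * 4},
                            seed=200 + rep)
            df = heterozygosity_summary(ds)
            fis.append(population_means(df, ["F_IS"]).iloc[0, 0])
        assert abs(np.mean(fis)) < 0.02

    def test_monomorphic_fis_undefined(self):
        calls = np.tile(np.array([[[101, 101]]]), (5, 1, 1))
        df = heterozygosity_summary(single_pop(calls))
        assert np.isnan(df.iloc[0]["F_IS"])


class TestRarefaction:
    def test_monomorphic_is_one(self):
        calls = np.tile(np.array([[[101, 101]]]), (6, 1, 1))
        df, _ = rarefied_allelic_richness(single_pop(calls), g=4)
        assert df.iloc[0]["A_R"] == pytest.approx(1.0)

    def test_counts_9_1_matches_enumeration(self):
        # N=10 copies {9, 1}, g=2: brute-force over all C(10,2) subsamples
        copies = [101] * 9 + [102]
        expected = np.mean(
            [len(set(pair)) for pair in itertools.combinations(copies, 2)]
        )
        assert expected == pytest.approx(1.2)
        calls = np.array([[[101, 101]]] * 4 + [[[101, 102]]])  # 9 x 101, 1 x 102
        df, _ = rarefied_allelic_richness(single_pop(calls), g=2)
        assert df.iloc[0]["A_R"] == pytest.approx(expected, abs=1e-12)

    def test_matches_monte_carlo_oracle(self):
        """A_R equals the mean allele count over 100,000 random g-subsamples
        to within 0.01."""
        rng = np.random.default_rng(3)
        calls = hw_genotypes(10, [np.array([0.4, 0.3, 0.2, 0.1])], rng)
        ds = single_pop(calls)
        g = 6
        df, _ = rarefied_allelic_richness(ds, g=g)
        copies = calls[:, 0, :].ravel()
        draws = rng.random((100_000, copies.size)).argsort(axis=1)[:, :g]
        sampled = copies[draws]
        mc = np.mean([len(np.unique(row)) for row in sampled])
        assert df.iloc[0]["A_R"] == pytest.approx(mc, abs=0.01)

    def test_full_sample_equals_raw_allele_count(self):
        rng = np.random.default_rng(4)
        calls = hw_genotypes(8, [np.array([0.5, 0.3, 0.2])], rng)
        ds = single_pop(calls)
        df, _ = rarefied_allelic_richness(ds, g=16)
        assert df.iloc[0]["A_R"] == pytest.approx(len(np.unique(calls)))

    def test_g_too_large_names_limiting_cell(self):
        calls = np.array([[[101, 102]], [[101, 101]]])
        with pytest.raises(ValueError, match="L1"):
            rarefied_allelic_richness(single_pop(calls), g=6)


class TestPrivateAlleles:
    def test_identical_allele_sets_zero(self):
        ds = hw_dataset(
            {"A": 30, "B": 30},
            {"A": [np.array([0.5, 0.5])] * 2, "B": [np.array([0.5, 0.5])] * 2},
            seed=0,
        )
        ap = private_allele_count(ds)
        assert (ap == 0).all()

    def test_unique_allele_counted_once(self):
        calls = np.array([[[101, 103]], [[101, 101]]])
        ds = GenotypeDataset(["x", "y"], ["A", "B"], ["L"], calls)
        ap = private_allele_count(ds)
        assert ap["A"] == 1 and ap["B"] == 0  # 103 private to A; 101 shared

    def test_single_population_error(self):
        calls = np.array([[[101, 101]]])
        with pytest.raises(ValueError):
            private_allele_count(single_pop(calls))

    def test_native_richer_than_bottlenecked_daughter(self):
        """The native population holds at least as many private alleles as
        a severely bottlenecked daughter in >= 90% of replicates."""
        wins = 0
        for rep in range(50):
            cfg = SimulationConfig(seed=400 + rep, effective_size=60,
                                   alleles_per_locus_init=8, n_loci=6)
            native = simulate_base_population(cfg, 20)
            rng = np.random.default_rng(rep)
            daughter = apply_founder_event(native, 2, rng)
            ds = sample_dataset({"NAT": native, "DAU": daughter},
                                {"NAT": 25, "DAU": 2}, rng)
            ap = private_allele_count(ds)
            wins += ap["NAT"] >= ap["DAU"]
        assert wins >= 45


class TestHWE:
    def test_hw_proportions_not_rejected(self):
        # perfect HW proportions at a biallelic locus, large n
        calls = np.concatenate(
            [
                np.tile([[101, 101]], (25, 1)),
                np.tile([[101, 102]], (50, 1)),
                np.tile([[102, 102]], (25, 1)),
            ]
        )[:, None, :]
        per_locus, _ = hwe_exact_test(single_pop(calls), n_shuffles=2000, seed=0)
        assert per_locus.iloc[0]["p_value"] > 0.5

    def test_all_homozygotes_rejected_and_matches_enumeration(self):
        """n=30, p=q=0.5, no heterozygotes: the Monte-Carlo p agrees with
        full enumeration of the biallelic conditional distribution."""
        calls = np.concatenate(
            [np.tile([[101, 101]], (15, 1)), np.tile([[102, 102]], (15, 1))]
        )[:, None, :]
        per_locus, _ = hwe_exact_test(single_pop(calls), n_shuffles=5000, seed=1)
        p_mc = per_locus.iloc[0]["p_value"]
        assert p_mc < 0.01
        # enumeration oracle: conditional P(n_AB = h | n_A = n_B = 30) over
        # even h; probability mass of configurations as or less likely
        n, nA = 30, 30
        def log_prob(h):
            nAA = (nA - h) // 2
            nBB = n - nAA - h
            from scipy.special import gammaln
            return (
                gammaln(n + 1) - gammaln(nAA + 1) - gammaln(h + 1) - gammaln(nBB + 1)
                + h * np.log(2) + 2 * gammaln(nA + 1) - gammaln(2 * n + 1)
            )
        hs = [h for h in range(0, 31, 2)]
        logs = np.array([log_prob(h) for h in hs])
        probs = np.exp(logs - logs.max())
        probs /= probs.sum()
        p_exact = probs[probs <= probs[0] + 1e-12].sum()  # observed h=0
        assert p_mc == pytest.approx(p_exact, abs=0.01)

    def test_monomorphic_flagged_p_one(self):
        calls = np.tile(np.array([[[101, 101]]]), (10, 1, 1))
        per_locus, combined = hwe_exact_test(single_pop(calls), n_shuffles=999, seed=0)
        assert per_locus.iloc[0]["monomorphic"]
        assert per_locus.iloc[0]["p_value"] == 1.0
        assert combined["P"] == 1.0

    def test_null_pvalues_uniform(self):
        """p-values over 200 random-mating replicate loci pass a KS
        uniformity check at alpha = 0.01."""
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(200):
            freqs = rng.dirichlet(np.ones(4) * 2)
            calls = hw_genotypes(30, [freqs], np.random.default_rng(500 + rep))
            per_locus, _ = hwe_exact_test(single_pop(calls), n_shuffles=999,
                                          seed=rep)
            ps.append(per_locus.iloc[0]["p_value"])
        d, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01


class TestLinkageDisequilibrium:
    def test_duplicated_locus_detected(self):
        rng = np.random.default_rng(2)
        calls1 = hw_genotypes(40, [np.array([0.5, 0.3, 0.2])], rng)
        calls = np.concatenate([calls1, calls1], axis=1)  # perfect association
        res = multilocus_ld_test(single_pop(calls), n_perm=199, seed=0)
        assert res.rbar_d > 0.9
        assert res.p_perm == pytest.approx(1 / 200)

    def test_independent_loci_rbar_near_zero(self):
        vals = []
        for rep in range(30):
            ds = hw_dataset({"P": 40}, {"P": [np.full(4, 0.25)] * 5},
                            seed=700 + rep)
            res = multilocus_ld_test(ds, n_perm=99, seed=rep)
            vals.append(res.rbar_d)
        assert abs(np.mean(vals)) < 0.02

    def test_seeded_reproducibility(self):
        ds = hw_dataset({"P": 30}, {"P": [np.full(3, 1 / 3)] * 4}, seed=8)
        r1 = multilocus_ld_test(ds, n_perm=99, seed=5)
        r2 = multilocus_ld_test(ds, n_perm=99, seed=5)
        assert (r1.rbar_d, r1.p_perm) == (r2.rbar_d, r2.p_perm)

    def test_too_few_polymorphic_loci(self):
        calls = np.tile(np.array([[[101, 101], [102, 102]]]), (10, 1, 1))
        with pytest.raises(ValueError):
            multilocus_ld_test(single_pop(calls), n_perm=99, seed=0)


def inbred_mixture_calls(
    n: int, n_selfed: int, freqs: list[np.ndarray], f_selfed: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mixture population: ``n_selfed`` individuals with inbreeding
    coefficient ``f_selfed``, the rest outbred (identity disequilibrium)."""
    L = len(freqs)
    calls = np.empty((n, L, 2), dtype=np.int64)
    for i in range(n):
        f = f_selfed if i < n_selfed else 0.0
        for j, p in enumerate(freqs):
            a = rng.choice(len(p), p=p) + 101
            if rng.random() < f:
                calls[i, j] = (a, a)  # autozygous
            else:
                calls[i, j] = (a, rng.choice(len(p), p=p) + 101)
    return calls


class TestG2:
    def test_no_heterozygosity_variance_gives_zero(self):
        calls = np.tile(np.array([[[101, 102], [103, 104]]]), (10, 1, 1))
        res = g2_inbreeding_test(single_pop(calls), n_perm=100, seed=0)
        assert res.loc["P", "g2"] == pytest.approx(0.0)
        assert res.loc["P", "P_g2"] == 1.0

    def test_type_i_error_calibrated(self):
        """Under random mating the g2 permutation test rejects at ~5%
        (within +-3 points over 200 replicates)."""
        rejections = 0
        for rep in range(200):
            ds = hw_dataset({"P": 30}, {"P": [np.full(6, 1 / 6)] * 6},
                            seed=900 + rep)
            res = g2_inbreeding_test(ds, n_perm=200, seed=rep)
            rejections += res.loc["P", "P_g2"] <= 0.05
        rate = rejections / 200
        assert abs(rate - 0.05) <= 0.03

    def test_power_against_partial_selfing(self):
        """A 30% strongly selfed / 70% outbred mixture is detected
        (P_g2 <= 0.05) in >= 80% of replicates."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(3000 + rep)
            calls = inbred_mixture_calls(
                50, 15, [np.full(8, 0.125)] * 8, f_selfed=0.5, rng=rng
            )
            res = g2_inbreeding_test(single_pop(calls), n_perm=200, seed=rep)
            hits += res.loc["P", "P_g2"] <= 0.05
        assert hits >= 40


class TestDiversityReport:
    def test_three_population_structure(self):
        freqs = [np.full(4, 0.25)] * 4
        ds = hw_dataset({"A": 20, "B": 20, "C": 20},
                        {p: freqs for p in "ABC"}, seed=1)
        table, meta = diversity_report(ds, n_perm=100, n_shuffles=999, seed=0)
        assert list(table.index) == ["A", "B", "C"]
        assert list(table.columns) == [
            "A_R", "A_p", "H_E", "H_O", "F_IS", "P_HWE", "g2", "P_g2"
        ]
        assert meta["g"] == 40

    def test_monomorphic_dataset_degenerate_rows(self):
        calls = np.tile(np.array([[[101, 101], [102, 102]]]), (12, 1, 1))
        ds = GenotypeDataset(
            [f"i{k}" for k in range(12)], ["A"] * 6 + ["B"] * 6,
            ["L1", "L2"], calls,
        )
        table, _ = diversity_report(ds, n_perm=100, n_shuffles=999, seed=0)
        assert (table["H_E"] == 0).all() and (table["H_O"] == 0).all()
        assert (table["A_R"] == 1).all()

    def test_rendering_marks_significance(self):
        table = pd.DataFrame(
            {
                "A_R": [2.5], "A_p": [1], "H_E": [0.5], "H_O": [0.4],
                "F_IS": [0.2], "P_HWE": [0.01], "g2": [0.11], "P_g2": [0.04],
            },
            index=["X"],
        )
        out = render_diversity_table(table)
        assert out.loc["X", "P_HWE"] == "**0.01**"
        assert out.loc["X", "P_g2"] == "**0.04**"


class TestRetentionRatio:
    def test_identity_is_100(self):
        table = pd.DataFrame({"A_R": [3.0, 3.0]}, index=["X", "Y"])
        assert retention_ratio(table, "X", "X") == (100.0, 100)

    def test_published_florida_vs_uruguay_ratios(self):
        """Allelic-richness retention Florida/Uruguay: 86% for
        N. eichhorniae (4.43/5.16) and 85% for N. bruchi (2.63/3.11)."""
        eich = reported_diversity("eichhorniae")
        _, pct = retention_ratio(eich, "USA: Florida", "Uruguay")
        assert pct == 86
        bruchi = reported_diversity("bruchi")
        _, pct = retention_ratio(bruchi, "USA: Florida", "Uruguay")
        assert pct == 85


class TestStepsRegression:
    def history(self):
        return ImportationHistory(
            [
                ImportationEvent("NATIVE", f"P{k}", 1970 + k, 10)
                for k in range(1, 8)
            ]
        )

    def test_constant_response_flat(self):
        h = ImportationHistory(
            [
                ImportationEvent("NATIVE", "A", 1970, 10),
                ImportationEvent("A", "B", 1975, 10),
                ImportationEvent("B", "C", 1980, 10),
            ]
        )
        table = pd.DataFrame({"A_R": [2.0, 2.0, 2.0, 2.0]},
                             index=["NATIVE", "A", "B", "C"])
        res = steps_regression(table, h)
        assert res.slope == 0 and res.F_statistic == 0

    def test_perfect_fit(self):
        h = ImportationHistory(
            [
                ImportationEvent("NATIVE", "A", 1970, 10),
                ImportationEvent("A", "B", 1975, 10),
                ImportationEvent("B", "C", 1980, 10),
            ]
        )
        table = pd.DataFrame({"A_R": [0.0, 1.0, 2.0, 3.0]},
                             index=["NATIVE", "A", "B", "C"])
        res = steps_regression(table, h)
        assert res.slope == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_seven_populations_match_independent_fit(self):
        """F = (SSR/1)/(SSE/5) agrees with scipy.stats.linregress."""
        h = ImportationHistory(
            [
                ImportationEvent("NATIVE", "P1", 1970, 10),
                ImportationEvent("P1", "P2", 1971, 10),
                ImportationEvent("P2", "P3", 1972, 10),
                ImportationEvent("P3", "P4", 1973, 10),
                ImportationEvent("P4", "P5", 1974, 10),
                ImportationEvent("P5", "P6", 1975, 10),
            ]
        )
        rng = np.random.default_rng(5)
        y = 3.0 - 0.1 * np.arange(7) + rng.normal(0, 0.3, 7)
        table = pd.DataFrame({"A_R": y},
                             index=["NATIVE"] + [f"P{k}" for k in range(1, 7)])
        res = steps_regression(table, h)
        lr = stats.linregress(np.arange(7), y)
        assert res.slope == pytest.approx(lr.slope)
        assert res.df_den == 5
        assert res.p_value == pytest.approx(lr.pvalue, rel=1e-9)
        assert res.F_statistic == pytest.approx(lr.rvalue**2 / (1 - lr.rvalue**2) * 5)

    def test_too_few_points(self):
        h = ImportationHistory([ImportationEvent("NATIVE", "A", 1970, 10)])
        table = pd.DataFrame({"A_R": [2.0, 2.0]}, index=["NATIVE", "A"])
        with pytest.raises(ValueError):
            steps_regression(table, h)


class TestPopulationComparison:
    def test_null_calibration_label_split(self):
        """Random label splits of one panmictic sample give a roughly
        uniform p distribution."""
        ps = []
        for rep in range(60):
            ds = hw_dataset({"P": 60}, {"P": [np.full(4, 0.25)] * 6},
                            seed=1500 + rep)
            labels = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
            split = GenotypeDataset(ds.individuals, labels, ds.loci, ds.calls)
            res = population_diversity_comparison(split, "H_E", n_perm=99, seed=rep)
            ps.append(res.p_global)
        assert 0.35 < np.mean(ps) < 0.65
        assert np.mean(np.array(ps) <= 0.05) < 0.15

    def test_power_against_bottleneck(self):
        """One population founded by 2 individuals stands out (global
        p <= 0.05) in >= 80% of replicates."""
        from introtrace.simulate import evolve

        hits = 0
        for rep in range(50):
            cfg = SimulationConfig(seed=1700 + rep, effective_size=60,
                                   alleles_per_locus_init=8, n_loci=8)
            base = simulate_base_population(cfg, 20)
            rng = np.random.default_rng(rep)
            bott = evolve(apply_founder_event(base, 2, rng), cfg, 3, rng)
            ds = sample_dataset(
                {"A": base, "B": base, "C": bott}, 20, rng
            )
            res = population_diversity_comparison(ds, "A_R", n_perm=99, seed=rep)
            hits += res.p_global <= 0.05
        assert hits >= 40

    def test_seeded_reproducibility(self):
        ds = hw_dataset(
            {"A": 15, "B": 15},
            {"A": [np.full(4, 0.25)] * 4, "B": [np.array([0.7, 0.1, 0.1, 0.1])] * 4},
            seed=2,
        )
        r1 = population_diversity_comparison(ds, "A_R", n_perm=99, seed=3)
        r2 = population_diversity_comparison(ds, "A_R", n_perm=99, seed=3)
        assert r1.p_global == r2.p_global
        pd.testing.assert_frame_equal(r1.pairwise, r2.pairwise)

    def test_pairwise_bh_adjustment_bounds(self):
        ds = hw_dataset(
            {"A": 15, "B": 15, "C": 15},
            {p: [np.full(4, 0.25)] * 4 for p in "ABC"},
            seed=9,
        )
        res = population_diversity_comparison(ds, "H_E", n_perm=99, seed=0)
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p_raw"] - 1e-12).all()
        assert (res.pairwise["p_adjusted"] <= 1.0).all()
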