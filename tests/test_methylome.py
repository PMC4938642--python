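"""Bisulfite methylome calling: nonconversion, binomial test, BH, levels, DMRs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromaquant import (
    CytosineReport,
    Interval,
    MethylomeConfig,
    SimConfig,
    bh_adjust,
    call_sites,
    count_methylated,
    estimate_nonconversion,
    find_dmrs,
    shared_site_distribution,
    simulate_bisulfite,
    simulate_genome,
    weighted_level,
)

from conftest import make_genome


def report(rows):
    """rows: (contig, pos, strand, m, n)"""
    return CytosineReport(pd.DataFrame(rows, columns=["contig", "pos", "strand", "m", "n"]))


class TestNonconversion:
    def test_pooled_hand_example(self, toy_genome):
        rep = report([("mito", 10, "+", 2, 400), ("mito", 20, "+", 3, 600), ("chr1", 5, "+", 9, 10)])
        assert estimate_nonconversion(rep, toy_genome) == pytest.approx(0.005)

    def test_perfect_conversion(self, toy_genome):
        rep = report([("mito", 10, "+", 0, 100), ("mito", 20, "-", 0, 50)])
        assert estimate_nonconversion(rep, toy_genome) == 0.0

    def test_no_mito_sites_is_error(self, toy_genome):
        rep = report([("chr1", 5, "+", 1, 10)])
        with pytest.raises(ValueError, match="mito"):
            estimate_nonconversion(rep, toy_genome)

    def test_zero_mito_coverage_is_error(self, toy_genome):
        rep = report([("mito", 5, "+", 0, 0)])
        with pytest.raises(ValueError, match="mito"):
            estimate_nonconversion(rep, toy_genome)


class TestBH:
    def test_step_up_by_hand(self):
        # p = {0.01, 0.02, 0.03, 0.04}, T=4: q(k) = min_{j>=k} p(j)*4/j = 0.04 for all
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_empty_and_single(self):
        assert bh_adjust(np.array([])).size == 0
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    @pytest.mark.parametrize("size", [1, 2, 7, 100, 1000])
    def test_matches_reference_implementation(self, size):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(size)
        p = rng.random(size) ** 2
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_matches_reference_with_ties(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.5, 0.001, 0.001, 1.0, 0.2, 0.2])
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestCallSites:
    def test_low_coverage_excluded_from_family(self, toy_genome):
        rep = report([("chr1", 1, "+", 2, 2), ("chr1", 2, "+", 0, 10)])
        calls = call_sites(rep, 0.005, MethylomeConfig(min_coverage=3))
        assert calls.loc[0, "status"] == "insufficient_coverage"
        assert np.isnan(calls.loc[0, "p_value"])
        # the tested family has size 1, so the covered site's q == its p
        assert calls.loc[1, "q_value"] == calls.loc[1, "p_value"]

    def test_zero_m_is_never_methylated(self):
        rep = report([("chr1", i, "+", 0, 20) for i in range(10)])
        calls = call_sites(rep, 0.005)
        assert (calls["p_value"] == 1.0).all()
        assert (calls["status"] == "unmethylated").all()

    def test_closed_form_saturated_site(self):
        # m = n = 10 at r = 0.005: p = 0.005^10
        rep = report([("chr1", 1, "+", 10, 10)])
        calls = call_sites(rep, 0.005)
        assert calls.loc[0, "p_value"] == pytest.approx(0.005**10, rel=1e-9)
        assert calls.loc[0, "status"] == "methylated"

    def test_one_sided_tail_matches_scipy_definition(self):
        rep = report([("chr1", 1, "+", 3, 20)])
        calls = call_sites(rep, 0.01)
        assert calls.loc[0, "p_value"] == pytest.approx(stats.binom.sf(2, 20, 0.01))

    def test_degenerate_nonconversion_rejected(self):
        rep = report([("chr1", 1, "+", 1, 10)])
        with pytest.raises(ValueError):
            call_sites(rep, 1.0)

    def test_type_one_error_controlled_on_null(self):
        # fully unmethylated genomes: called fraction stays below alpha
        cfg = SimConfig(seed=0, n_nuclear_contigs=1, contig_length_bp=50_000,
                        mito_length_bp=10_000, n_genes=0, n_domains=0,
                        background_meth_freq=0.0, nonconversion_rate=0.005,
                        chip_n_fragments=1, mnase_n_fragments=1)
        genome, _, _ = simulate_genome(cfg)
        fractions = []
        for rep_seed in range(20):
            rep = simulate_bisulfite(genome, [], cfg, seed=1000 + rep_seed)
            calls = call_sites(rep, 0.005)
            tested = (calls["status"] != "insufficient_coverage").sum()
            fractions.append(count_methylated(calls) / tested)
        assert max(fractions) <= 0.05
        assert np.mean(fractions) < 0.01


class TestCounting:
    def test_empty_and_uncovered(self):
        assert count_methylated(pd.DataFrame(columns=["status"])) == 0
        rep = report([("chr1", 1, "+", 1, 1)])
        calls = call_sites(rep, 0.005, MethylomeConfig(min_coverage=3))
        assert count_methylated(calls) == 0

    def test_monotone_in_m(self):
        rng = np.random.default_rng(4)
        n = rng.integers(3, 30, size=200)
        m = rng.binomial(n, 0.2)
        base = report([("chr1", i, "+", int(mi), int(ni)) for i, (mi, ni) in enumerate(zip(m, n))])
        bumped = report(
            [("chr1", i, "+", int(min(mi + 1, ni)), int(ni))
             for i, (mi, ni) in enumerate(zip(m, n))]
        )
        assert count_methylated(call_sites(bumped, 0.01)) >= count_methylated(call_sites(base, 0.01))
        region = Interval("chr1", 0, 200)
        assert weighted_level(bumped, region) >= weighted_level(base, region)


class TestWeightedLevel:
    def test_hand_pooled(self):
        rep = report([("chr1", 1, "+", 3, 10), ("chr1", 2, "+", 7, 10)])
        assert weighted_level(rep, Interval("chr1", 0, 10), min_coverage=3) == 50.0

    def test_saturated(self):
        rep = report([("chr1", i, "+", 5, 5) for i in range(4)])
        assert weighted_level(rep, Interval("chr1", 0, 10)) == 100.0

    def test_no_qualifying_site_is_nan(self):
        rep = report([("chr1", 1, "+", 1, 2)])
        assert np.isnan(weighted_level(rep, Interval("chr1", 0, 10), min_coverage=3))
        assert np.isnan(weighted_level(rep, Interval("chr1", 100, 200), min_coverage=1))

    def test_equals_coverage_weighted_site_mean(self):
        rng = np.random.default_rng(8)
        n = rng.integers(3, 40, size=100)
        m = rng.binomial(n, rng.random(100))
        rep = report([("chr1", i, "+", int(mi), int(ni)) for i, (mi, ni) in enumerate(zip(m, n))])
        got = weighted_level(rep, Interval("chr1", 0, 100), min_coverage=3)
        oracle = 100.0 * np.sum(n * (m / n)) / np.sum(n)
        assert got == pytest.approx(oracle)


class TestSharedSites:
    def _calls(self, levels, n=20):
        rows = [("chr1", i, "+", int(round(l * n)), n) for i, l in enumerate(levels)]
        return call_sites(report(rows), 0.005)

    def test_identical_inputs_identical_distribution(self):
        calls = self._calls([0.5, 0.8, 1.0, 0.6])
        table = shared_site_distribution(calls, calls)
        np.testing.assert_allclose(table["percent_a"], table["percent_b"])
        assert table["percent_a"].sum() == pytest.approx(100.0)

    def test_fully_methylated_mass_in_top_bin(self):
        calls = self._calls([1.0, 1.0, 1.0])
        table = shared_site_distribution(calls, calls)
        assert table["percent_a"].iloc[-1] == pytest.approx(100.0)
        assert table["percent_a"].iloc[:-1].sum() == 0.0

    def test_no_shared_sites_warns_empty(self):
        high = self._calls([0.9, 0.9])
        rows = [("chr1", i + 50, "+", 18, 20) for i in range(2)]
        other = call_sites(report(rows), 0.005)
        with pytest.warns(UserWarning, match="no shared"):
            table = shared_site_distribution(high, other)
        assert (table[["percent_a", "percent_b"]].to_numpy() == 0).all()

    def test_higher_frequency_dominates(self):
        rng = np.random.default_rng(12)
        n = 20
        la = rng.binomial(n, 0.45, size=2000) / n
        lb = rng.binomial(n, 0.60, size=2000) / n
        a = self._calls(la)
        b = self._calls(lb)
        table = shared_site_distribution(a, b)
        cdf_a = table["percent_a"].cumsum().to_numpy()
        cdf_b = table["percent_b"].cumsum().to_numpy()
        assert (cdf_b <= cdf_a + 1e-9).all()
        assert (cdf_b < cdf_a - 1e-9).any()


class TestDMR:
    def _paired_reports(self, genome, domain, fa, fb, cov=20, seed=0):
        cfg = SimConfig(seed=seed, n_nuclear_contigs=1, contig_length_bp=genome.lengths["chr1"],
                        mito_length_bp=genome.lengths["mito"], n_genes=0, n_domains=0,
                        bs_mean_coverage=cov, nonconversion_rate=0.005,
                        chip_n_fragments=1, mnase_n_fragments=1)
        ra = simulate_bisulfite(genome, [domain], cfg, seed=seed + 1, domain_meth_freq=fa)
        rb = simulate_bisulfite(genome, [domain], cfg, seed=seed + 2, domain_meth_freq=fb)
        return ra, rb

    def test_self_comparison_no_dmrs(self, toy_genome):
        dom = Interval("chr1", 2000, 6000)
        ra, _ = self._paired_reports(toy_genome, dom, 0.5, 0.5)
        assert find_dmrs(ra, ra, toy_genome) == []

    def test_planted_domain_recovered(self):
        genome = make_genome(chr1_len=100_000, mito_len=5_000, seed=21)
        dom = Interval("chr1", 40_000, 50_000)
        ra, rb = self._paired_reports(genome, dom, 0.30, 0.90, seed=33)
        dmrs = find_dmrs(ra, rb, genome)
        assert len(dmrs) == 1
        (d,) = dmrs
        assert d.label == "gain_in_b"
        assert abs(d.start - dom.start) <= 1000
        assert abs(d.end - dom.end) <= 1000

    def test_small_difference_gated_by_min_diff(self):
        genome = make_genome(chr1_len=50_000, mito_len=5_000, seed=22)
        dom = Interval("chr1", 10_000, 20_000)
        # 40% vs 45% at very high coverage: significant but below the 20-point gate
        ra, rb = self._paired_reports(genome, dom, 0.40, 0.45, cov=200, seed=44)
        assert find_dmrs(ra, rb, genome) == []
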