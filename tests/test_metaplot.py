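"""Anchored aggregation: quintiles, gene metaplots, heatmaps, domain profiles."""

import numpy as np
import pandas as pd
import pytest

from chromaquant import (
    BasewiseSignal,
    Contig,
    CytosineReport,
    Gene,
    Genome,
    Interval,
    assign_quintiles,
    domain_metaplot,
    gene_metaplot,
    heatmap_matrix,
    weighted_level,
)
from chromaquant.metaplot import per_gene_matrix

from conftest import make_genome


def flat_signal(genome, value=1.0):
    return BasewiseSignal({c.name: np.full(c.length, value) for c in genome.contigs})


class TestQuintiles:
    def _genes(self, rpkms):
        return [Gene(f"g{i:02d}", "chr1", "+", i * 100, i * 100 + 50, r)
                for i, r in enumerate(rpkms)]

    def test_ten_genes_descending(self):
        grouping = assign_quintiles(self._genes([10, 9, 8, 7, 6, 5, 4, 3, 2, 1]))
        assert grouping.genes_in(1) == ["g00", "g01"]
        assert grouping.genes_in(5) == ["g08", "g09"]
        assert grouping.boundaries[0] == (10, 9)
        assert grouping.boundaries[4] == (2, 1)

    def test_all_zero_ties_broken_by_gene_id(self):
        grouping = assign_quintiles(self._genes([0.0] * 10))
        assert grouping.genes_in(1) == ["g00", "g01"]
        assert grouping.genes_in(5) == ["g08", "g09"]

    def test_seven_genes_remainder_to_early_groups(self):
        grouping = assign_quintiles(self._genes([7, 6, 5, 4, 3, 2, 1]))
        sizes = [len(grouping.genes_in(q)) for q in range(1, 6)]
        assert sizes == [2, 2, 1, 1, 1]

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="5 genes"):
            assign_quintiles(self._genes([1, 2, 3]))


class TestGeneMetaplot:
    def test_constant_field_is_flat(self, toy_genome):
        genes = [
            Gene("a", "chr1", "+", 3000, 4000, 2.0),
            Gene("b", "chr1", "-", 6000, 7000, 1.0),
        ]
        prof = gene_metaplot(flat_signal(toy_genome), genes, flank_bp=1000, bin_bp=10)
        np.testing.assert_allclose(prof.values, 1.0)
        assert prof.n_regions == 2

    def test_unit_impulse_plus_strand(self, toy_genome):
        sig = flat_signal(toy_genome, 0.0)
        gene = Gene("a", "chr1", "+", 3000, 4000)
        sig["chr1"][3025] = 1.0  # TSS + 25
        prof = gene_metaplot(sig, [gene], flank_bp=1000, bin_bp=10)
        hit = prof.values[prof.bin_offsets == 20]
        assert hit[0] == pytest.approx(0.1)  # impulse averaged over a 10 bp bin
        assert prof.values.sum() == pytest.approx(0.1)

    def test_unit_impulse_minus_strand_mirrored(self, toy_genome):
        sig = flat_signal(toy_genome, 0.0)
        gene = Gene("a", "chr1", "-", 3000, 4000)  # TSS at 3999
        sig["chr1"][3999 - 25] = 1.0
        prof = gene_metaplot(sig, [gene], flank_bp=1000, bin_bp=10)
        hit = prof.values[prof.bin_offsets == 20]
        assert hit[0] == pytest.approx(0.1)

    def test_empty_gene_list_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="empty"):
            gene_metaplot(flat_signal(toy_genome), [], flank_bp=100, bin_bp=10)
        with pytest.raises(ValueError, match="bin_bp"):
            gene_metaplot(flat_signal(toy_genome), [Gene("a", "chr1", "+", 0, 10)],
                          flank_bp=100, bin_bp=0)

    def test_matches_brute_force_oracle(self):
        # explicit per-gene, per-base loop on random signal; both strands,
        # anchors near contig edges to exercise truncation
        genome = make_genome(chr1_len=2000, mito_len=1000, seed=3)
        rng = np.random.default_rng(17)
        sig = BasewiseSignal({"chr1": rng.random(2000), "mito": rng.random(1000)})
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 1900))
            end = start + int(rng.integers(20, 100))
            genes.append(Gene(f"g{i}", "chr1", "+" if rng.integers(2) else "-",
                              start, min(end, 2000), float(rng.random())))
        flank, bin_bp = 200, 10
        for anchor in ("tss", "tts"):
            offsets, mat = per_gene_matrix(sig, genes, anchor, flank, bin_bp)
            for gi, g in enumerate(genes):
                a = g.tss if anchor == "tss" else g.tts
                for bi, off in enumerate(offsets):
                    vals = []
                    for o in range(off, off + bin_bp):
                        pos = a + o if g.strand == "+" else a - o
                        if 0 <= pos < 2000:
                            vals.append(sig["chr1"][pos])
                    expected = np.mean(vals) if vals else np.nan
                    if np.isnan(expected):
                        assert np.isnan(mat[gi, bi])
                    else:
                        assert mat[gi, bi] == pytest.approx(expected)

    def test_quintile_profiles_recombine_to_overall(self, toy_genome):
        rng = np.random.default_rng(5)
        sig = BasewiseSignal(
            {c.name: rng.random(c.length) for c in toy_genome.contigs}
        )
        genes = [Gene(f"g{i}", "chr1", "+" if i % 2 else "-", 1500 + i * 600,
                      1900 + i * 600, float(i)) for i in range(10)]
        grouping = assign_quintiles(genes)
        grouped = gene_metaplot(sig, genes, flank_bp=200, bin_bp=10, grouping=grouping)
        overall = gene_metaplot(sig, genes, flank_bp=200, bin_bp=10)
        weighted = sum(p.values * p.n_regions for p in grouped.values()) / sum(
            p.n_regions for p in grouped.values()
        )
        np.testing.assert_allclose(weighted, overall.values)

    def test_orientation_consistency(self):
        # flipping every strand and mirroring the signal leaves profiles unchanged
        L = 4000
        genome = Genome((Contig("chr1", L),), mito_name="chr1")
        rng = np.random.default_rng(23)
        arr = rng.random(L)
        sig = BasewiseSignal({"chr1": arr})
        sig_mirror = BasewiseSignal({"chr1": arr[::-1].copy()})
        genes = [Gene("a", "chr1", "+", 1000, 1400, 2.0), Gene("b", "chr1", "-", 2200, 2600, 1.0)]
        flipped = [
            Gene(g.gene_id, "chr1", "-" if g.strand == "+" else "+", L - g.end, L - g.start, g.rpkm)
            for g in genes
        ]
        p1 = gene_metaplot(sig, genes, flank_bp=300, bin_bp=10)
        p2 = gene_metaplot(sig_mirror, flipped, flank_bp=300, bin_bp=10)
        np.testing.assert_allclose(p1.values, p2.values)


class TestHeatmap:
    def test_rows_ordered_by_expression(self, toy_genome):
        genes = [
            Gene("g1", "chr1", "+", 1000, 1400, 5.0),
            Gene("g2", "chr1", "+", 3000, 3400, 1.0),
            Gene("g3", "chr1", "+", 5000, 5400, 9.0),
        ]
        _, labels, _ = heatmap_matrix(flat_signal(toy_genome), genes, flank_bp=100, bin_bp=10)
        assert labels == ["g3", "g1", "g2"]

    def test_column_means_equal_metaplot(self, toy_genome):
        rng = np.random.default_rng(2)
        sig = BasewiseSignal({c.name: rng.random(c.length) for c in toy_genome.contigs})
        genes = [Gene(f"g{i}", "chr1", "+", 1000 + 700 * i, 1500 + 700 * i, float(i))
                 for i in range(6)]
        mat, _, offsets = heatmap_matrix(sig, genes, flank_bp=200, bin_bp=10)
        prof = gene_metaplot(sig, genes, flank_bp=200, bin_bp=10)
        np.testing.assert_allclose(np.nanmean(mat, axis=0), prof.values)
        np.testing.assert_array_equal(offsets, prof.bin_offsets)

    def test_constant_signal_constant_matrix(self, toy_genome):
        genes = [Gene("g1", "chr1", "+", 2000, 2500, 1.0)]
        mat, _, _ = heatmap_matrix(flat_signal(toy_genome, 3.0), genes, flank_bp=100, bin_bp=10)
        np.testing.assert_allclose(mat, 3.0)


class TestDomainMetaplot:
    def _report(self, rows):
        return CytosineReport(pd.DataFrame(rows, columns=["contig", "pos", "strand", "m", "n"]))

    def test_saturated_report_all_bins_100(self):
        rows = [("chr1", p, "+", 8, 8) for p in range(0, 5000, 7)]
        prof = domain_metaplot(self._report(rows), [Interval("chr1", 1500, 3500)])
        covered = ~np.isnan(prof.values)
        assert covered.any()
        np.testing.assert_allclose(prof.values[covered], 100.0)
        assert prof.values.size == 60

    def test_profile_axis_layout(self):
        rows = [("chr1", p, "+", 0, 10) for p in range(0, 4000, 5)]
        prof = domain_metaplot(self._report(rows), [Interval("chr1", 1500, 2500)])
        assert prof.bin_offsets[0] == -20 and prof.bin_offsets[-1] == 39

    def test_short_domain_skipped_with_warning(self):
        rows = [("chr1", p, "+", 1, 10) for p in range(0, 200, 3)]
        with pytest.warns(UserWarning, match="skipped"):
            prof = domain_metaplot(self._report(rows), [
                Interval("chr1", 10, 20),  # shorter than 20 bp body bins
                Interval("chr1", 50, 150),
            ])
        assert prof.n_regions == 1

    def test_pooling_matches_weighted_level(self):
        # coverage-weighted mean of body bins == weighted_level over all bodies
        rng = np.random.default_rng(31)
        rows = []
        for p in range(0, 8000, 3):
            n = int(rng.integers(3, 30))
            rows.append(("chr1", p, "+", int(rng.binomial(n, 0.4)), n))
        rep = self._report(rows)
        domains = [Interval("chr1", 1000, 2000), Interval("chr1", 4000, 6500)]
        prof = domain_metaplot(rep, domains, min_coverage=3)
        body = prof.values[20:40]
        # recompute pooled n per body bin to weight the bin values
        total_m = sum(
            weighted_level(rep, d, 3) / 100.0 * rep.in_region(d)["n"].sum() for d in domains
        )
        total_n = sum(rep.in_region(d)["n"].sum() for d in domains)
        pooled = 100.0 * total_m / total_n
        # body-bin pooled counts reproduce the same overall level
        w = []
        for d in domains:
            sub = rep.in_region(d)
            w.append(sub["n"].sum())
        # direct check: weighted mean of bin values using per-bin pooled coverage
        m_bins = np.zeros(20)
        n_bins = np.zeros(20)
        for d in domains:
            sub = rep.in_region(d)
            b = (sub["pos"].to_numpy() - d.start) * 20 // d.length
            np.add.at(m_bins, b, sub["m"].to_numpy())
            np.add.at(n_bins, b, sub["n"].to_numpy())
        np.testing.assert_allclose(body, 100.0 * m_bins / n_bins)
        assert np.sum(body * n_bins) / np.sum(n_bins) == pytest.approx(pooled)

    def test_empty_domains_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            domain_metaplot(self._report([("chr1", 1, "+", 0, 5)]), [])
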