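"""Seven-category annotation, genomic background fractions, and the
log-space binomial enrichment test."""

import numpy as np
import pytest

import oxichip as ox
from oxichip.annotation import CATEGORIES


def brute_force_category(genes, scheme, chrom, position):
    """Independent per-position rule: direct membership checks, first
    category in scheme order wins."""
    hits = set()
    for g in genes:
        if g.chrom != chrom:
            continue
        up, down = scheme.promoter_upstream, scheme.tts_downstream
        if g.strand == "+":
            promoter = g.tx_start - up <= position < g.tx_start
            tts = g.tx_end <= position < g.tx_end + down
        else:
            promoter = g.tx_end <= position < g.tx_end + up
            tts = g.tx_start - down <= position < g.tx_start
        if promoter:
            hits.add("promoter")
        if tts:
            hits.add("tts")
        exonic = any(s <= position < e for s, e in g.exons)
        inside = g.tx_start <= position < g.tx_end
        if exonic:
            if not g.is_coding:
                hits.add("exon")
            elif g.cds_start <= position < g.cds_end:
                hits.add("exon")
            elif position < g.cds_start:
                hits.add("utr5" if g.strand == "+" else "utr3")
            else:
                hits.add("utr3" if g.strand == "+" else "utr5")
        elif inside:
            hits.add("intron")
    for cat in CATEGORIES:
        if cat in hits:
            return cat
    return "intergenic"


class TestAnnotatePosition:
    def test_promoter_upstream_of_plus_tss(self, plus_gene):
        scheme = ox.CategoryScheme()
        assert ox.annotate_position([plus_gene], scheme, "chrT", 1500) == "promoter"
        assert ox.annotate_position([plus_gene], scheme, "chrT", 999) == "intergenic"

    def test_tts_downstream_of_plus_end(self, plus_gene):
        assert ox.annotate_position([plus_gene], ox.CategoryScheme(), "chrT", 5010) == "tts"

    def test_minus_strand_promoter_is_genomically_downstream(self, minus_gene):
        scheme = ox.CategoryScheme()
        assert ox.annotate_position([minus_gene], scheme, "chrT", 8500) == "promoter"
        assert ox.annotate_position([minus_gene], scheme, "chrT", 5500) == "tts"

    def test_utr_exon_intron_partition_of_plus_gene(self, plus_gene):
        scheme = ox.CategoryScheme()
        # exon 1 spans [2000,3000): [2000,2100) is 5' UTR, rest CDS
        assert ox.annotate_position([plus_gene], scheme, "chrT", 2050) == "utr5"
        assert ox.annotate_position([plus_gene], scheme, "chrT", 2500) == "exon"
        assert ox.annotate_position([plus_gene], scheme, "chrT", 3500) == "intron"
        assert ox.annotate_position([plus_gene], scheme, "chrT", 4950) == "utr3"

    def test_gene_free_chromosome_is_intergenic(self):
        assert ox.annotate_position([], ox.CategoryScheme(), "chrEmpty", 10) == "intergenic"

    def test_gene_order_never_changes_assignment(self, plus_gene, minus_gene, single_run):
        scheme = ox.CategoryScheme()
        genes = single_run.genes
        rng = np.random.default_rng(0)
        positions = rng.integers(0, single_run.genome.length("chr1"), 200)
        forward = ox.Annotator(genes, scheme)
        backward = ox.Annotator(genes[::-1], scheme)
        for pos in positions:
            assert forward.annotate("chr1", int(pos)) == backward.annotate("chr1", int(pos))

    def test_agrees_with_brute_force_rule(self, single_run):
        scheme = ox.CategoryScheme()
        genes = single_run.genes
        annot = ox.Annotator(genes, scheme)
        rng = np.random.default_rng(1)
        for pos in rng.integers(0, single_run.genome.length("chr1"), 300):
            assert annot.annotate("chr1", int(pos)) == brute_force_category(
                genes, scheme, "chr1", int(pos)
            )

    def test_unknown_chromosome_rejected_when_genome_given(self, toy_genome, plus_gene):
        with pytest.raises(KeyError):
            ox.annotate_position([plus_gene], ox.CategoryScheme(), "chrZ", 10, toy_genome)


class TestProfiles:
    def test_fractions_sum_to_one(self, single_run):
        profiles = ox.category_profile(single_run.results.sites, single_run.genes)
        for prof in profiles.values():
            assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_identical_sites_give_indicator(self, plus_gene):
        sites = [ox.Peak("chrT", 1400, 1600) for _ in range(5)]  # centers at 1500
        prof = ox.category_profile(sites, [plus_gene])
        assert prof.fractions["promoter"] == 1.0

    def test_empty_site_list_rejected(self, plus_gene):
        with pytest.raises(ValueError, match="empty"):
            ox.category_profile([], [plus_gene])


class TestBackgroundFractions:
    def test_no_genes_all_intergenic(self, toy_genome):
        prof = ox.genomic_background_fractions([], toy_genome)
        assert prof.fractions["intergenic"] == 1.0

    def test_single_gene_promoter_area(self, toy_genome, plus_gene):
        prof = ox.genomic_background_fractions([plus_gene], toy_genome)
        assert prof.fractions["promoter"] == pytest.approx(1000 / 10_000)
        assert prof.fractions["tts"] == pytest.approx(1000 / 10_000)

    def test_partition_of_genome(self, single_run):
        prof = ox.genomic_background_fractions(single_run.genes, single_run.genome)
        assert sum(prof.counts.values()) == single_run.genome.total_length
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_base_painting_matches_positional_rule(self, toy_genome, plus_gene, minus_gene):
        genes = [plus_gene, minus_gene]
        scheme = ox.CategoryScheme()
        prof = ox.genomic_background_fractions(genes, toy_genome, scheme)
        expected = {c: 0 for c in CATEGORIES}
        for pos in range(toy_genome.length("chrT")):
            expected[brute_force_category(genes, scheme, "chrT", pos)] += 1
        assert prof.counts == expected


class TestEnrichmentTest:
    def test_all_successes_closed_form(self):
        assert ox.enrichment_test(10, 10, 0.5) == pytest.approx(10 * np.log10(0.5))

    def test_zero_successes_full_tail(self):
        assert ox.enrichment_test(0, 10, 0.5) == 0.0

    def test_monotone_nonincreasing_in_k(self):
        values = [ox.enrichment_test(k, 100, 0.1) for k in range(101)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matches_scipy_where_no_underflow(self):
        from scipy import stats

        for k, n, p0 in [(5, 50, 0.1), (30, 100, 0.25), (1, 10, 0.01), (400, 500, 0.5)]:
            expected = stats.binom.sf(k - 1, n, p0)
            assert 10 ** ox.enrichment_test(k, n, p0) == pytest.approx(expected, rel=1e-9)

    def test_extreme_tail_does_not_underflow(self):
        assert ox.enrichment_test(5000, 20000, 0.01) < -3000

    @pytest.mark.parametrize("bad", [-0.1, 0.0, 1.0, 1.5])
    def test_background_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            ox.enrichment_test(5, 10, bad)


class TestFoldOverBackground:
    def test_printed_ratios(self):
        assert ox.fold_over_background(0.083, 0.01) == pytest.approx(8.3)
        assert ox.fold_over_background(0.18, 0.01) == pytest.approx(18.0)

    def test_identity(self):
        assert ox.fold_over_background(0.3, 0.3) == 1.0

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            ox.fold_over_background(0.1, 0.0)
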