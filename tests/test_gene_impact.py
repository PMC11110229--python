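"""Gene-region decomposition and per-gene NUPT burden accounting."""

import pytest

from nuptools.gene_impact import (
    classify_gene_hits,
    gene_regions,
    impact_summary,
    impact_table,
)
from nuptools.intervals import GenomicInterval
from nuptools.io import GeneModel, NuptRecord

CHROM_LEN = 10_000


def make_gene(gene_id="g1", start=1000, end=2000, strand="+", exons=None):
    if exons is None:
        exons = [GenomicInterval("c", start, end)]
    return GeneModel(gene_id=gene_id, chrom="c", start=start, end=end,
                     strand=strand, exons=exons)


def make_nupt(nid, s, e, cls="II"):
    return NuptRecord(
        nupt_id=nid,
        nuclear=GenomicInterval("c", s, e),
        plastid=GenomicInterval("pt", 0, e - s),
        pident=95.0,
        age_class=cls,
    )


class TestGeneRegions:
    def test_plus_strand_flanks(self):
        r = gene_regions(make_gene(), CHROM_LEN, flank_bp=1000)
        assert [(i.start, i.end) for i in r.promoter] == [(0, 1000)]
        assert [(i.start, i.end) for i in r.terminator] == [(2000, 3000)]

    def test_minus_strand_mirrored(self):
        r = gene_regions(make_gene(strand="-"), CHROM_LEN, flank_bp=1000)
        assert [(i.start, i.end) for i in r.promoter] == [(2000, 3000)]
        assert [(i.start, i.end) for i in r.terminator] == [(0, 1000)]

    def test_truncated_at_chromosome_start(self):
        g = make_gene(start=200, end=800)
        r = gene_regions(g, CHROM_LEN, flank_bp=1000)
        assert [(i.start, i.end) for i in r.promoter] == [(0, 200)]
        assert r.promoter_truncated

    def test_fully_truncated_flank_is_empty_and_flagged(self):
        g = make_gene(start=0, end=500, exons=[GenomicInterval("c", 0, 500)])
        r = gene_regions(g, CHROM_LEN, flank_bp=1000)
        assert r.promoter == [] and r.promoter_truncated

    def test_cds_anchoring(self):
        """Flanks anchor at the CDS ends when CDS coordinates are known."""
        g = make_gene(start=1000, end=2000)
        g.cds_start, g.cds_end = 1100, 1900
        r = gene_regions(g, CHROM_LEN, flank_bp=100)
        assert [(i.start, i.end) for i in r.promoter] == [(1000, 1100)]
        assert [(i.start, i.end) for i in r.terminator] == [(1900, 2000)]

    def test_unstranded_gene_rejected(self):
        g = make_gene()
        g.strand = "."
        with pytest.raises(ValueError, match="unstranded"):
            gene_regions(g, CHROM_LEN)


class TestClassify:
    def two_exon_gene(self):
        return make_gene(
            exons=[GenomicInterval("c", 1000, 1400), GenomicInterval("c", 1700, 2000)]
        )

    def test_boundary_spanning_nupt_hits_both_regions(self):
        gene = self.two_exon_gene()
        recs = classify_gene_hits(
            [make_nupt("n1", 1300, 1500)], [gene], {"c": CHROM_LEN}
        )
        assert recs[0].regions_hit == {"exon", "intron"}

    def test_promoter_only(self):
        recs = classify_gene_hits(
            [make_nupt("n1", 100, 300)], [self.two_exon_gene()], {"c": CHROM_LEN}
        )
        assert recs[0].regions_hit == {"promoter"}

    def test_full_coverage_single_exon(self):
        gene = make_gene()
        recs = classify_gene_hits(
            [make_nupt("n1", 900, 2100)], [gene], {"c": CHROM_LEN}
        )
        assert recs[0].fully_covered and recs[0].single_exon_all_plastid

    def test_full_coverage_matches_per_base_oracle(self, rng):
        gene = self.two_exon_gene()
        for _ in range(30):
            edges = sorted(rng.integers(500, 2500, size=4))
            nupts = [make_nupt("a", edges[0], max(edges[1], edges[0] + 1)),
                     make_nupt("b", edges[2], max(edges[3], edges[2] + 1))]
            recs = classify_gene_hits(nupts, [gene], {"c": CHROM_LEN})
            covered = set()
            for n in nupts:
                covered.update(range(n.nuclear.start, n.nuclear.end))
            oracle = set(range(gene.start, gene.end)) <= covered
            got = recs[0].fully_covered if recs else False
            assert got == oracle

    def test_unaffected_gene_not_reported(self):
        recs = classify_gene_hits(
            [make_nupt("n1", 5000, 5100)], [self.two_exon_gene()], {"c": CHROM_LEN}
        )
        assert recs == []

    def test_order_invariance(self, rng):
        gene_a = make_gene("ga", 1000, 2000)
        gene_b = make_gene("gb", 5000, 6000)
        nupts = [make_nupt(f"n{i}", int(s), int(s) + 200, cls)
                 for i, (s, cls) in enumerate(
                     zip(rng.integers(0, 7000, 20), ["I", "II"] * 10))]
        fwd = impact_table(classify_gene_hits(nupts, [gene_a, gene_b], {"c": CHROM_LEN}))
        rev = impact_table(
            classify_gene_hits(nupts[::-1], [gene_b, gene_a], {"c": CHROM_LEN})
        )
        fwd = fwd.sort_values("gene_id").reset_index(drop=True)
        rev = rev.sort_values("gene_id").reset_index(drop=True)
        assert fwd.drop(columns="nupt_ids").equals(rev.drop(columns="nupt_ids"))
        assert all(
            sorted(a.split(",")) == sorted(b.split(","))
            for a, b in zip(fwd["nupt_ids"], rev["nupt_ids"])
        )


class TestSummary:
    def test_exclusivity_partition_sums_to_total(self):
        genes = [make_gene(f"g{i}", 1000 + 3000 * i, 2000 + 3000 * i)
                 for i in range(3)]
        nupts = [
            make_nupt("n1", 1100, 1200, "I"),
            make_nupt("n2", 4100, 4200, "II"),
            make_nupt("n3", 7100, 7200, "I"),
            make_nupt("n4", 7300, 7400, "unclassified"),
        ]
        recs = classify_gene_hits(nupts, genes, {"c": CHROM_LEN})
        summ = impact_summary(recs)
        assert sum(summ["class_exclusivity"].values()) == summ["total_affected_genes"] == 3
        assert summ["class_exclusivity"] == {"I-only": 1, "II-only": 1, "mixed": 1}

    def test_max_nupts_per_gene(self):
        gene = make_gene()
        nupts = [make_nupt(f"n{i}", 1000 + i * 50, 1040 + i * 50) for i in range(10)]
        recs = classify_gene_hits(nupts, [gene], {"c": CHROM_LEN})
        assert impact_summary(recs)["max_nupts_per_gene"] == 10

    def test_empty(self):
        summ = impact_summary([])
        assert summ["total_affected_genes"] == 0
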