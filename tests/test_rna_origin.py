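"""Best-hit origin calls, donor coordinate transfer, and the tRNA census."""

import pytest

from nuptools.intervals import GenomicInterval
from nuptools.io import AlignmentRow, FeatureSet, NuptRecord
from nuptools.rna_origin import (
    census_from_counts,
    classify_origin,
    map_donor,
    transfer_to_plastid,
    trna_census,
    OriginCall,
)


def hit(qid, sid, bits, ev=1e-10):
    return AlignmentRow(
        qseqid=qid, sseqid=sid, pident=95.0, length=75, mismatch=3, gapopen=0,
        qstart=1, qend=75, sstart=1, send=75, evalue=ev, bitscore=bits,
    )


COMP = {"s_mito": "mitochondrial", "s_plastid": "plastid", "a_pl": "plastid",
        "b_mt": "mitochondrial"}


class TestClassifyOrigin:
    def test_best_bitscore_wins(self):
        calls = classify_origin(
            [hit("q", "s_mito", 90.0), hit("q", "s_plastid", 80.0)], COMP
        )
        assert calls["q"].compartment == "mitochondrial"

    def test_no_passing_hit_unclassified(self):
        calls = classify_origin([hit("q", "s_mito", 90.0, ev=0.5)], COMP)
        assert calls["q"].compartment == "unclassified"

    def test_tie_breaks_lexicographic(self):
        calls = classify_origin(
            [hit("q", "b_mt", 90.0), hit("q", "a_pl", 90.0)], COMP
        )
        assert calls["q"].subject_id == "a_pl"
        assert calls["q"].compartment == "plastid"

    def test_order_invariance(self):
        rows = [hit("q", "s_mito", 85.0), hit("q", "s_plastid", 92.0),
                hit("q", "a_pl", 70.0)]
        fwd = classify_origin(rows, COMP)["q"]
        rev = classify_origin(rows[::-1], COMP)["q"]
        assert fwd == rev

    def test_missing_subject_rejected(self):
        with pytest.raises(KeyError, match="compartment map"):
            classify_origin([hit("q", "mystery", 90.0)], COMP)


def make_nupt(q_start, q_end, s_start, s_end, strand):
    return NuptRecord(
        nupt_id="n1",
        nuclear=GenomicInterval("chr1", q_start, q_end),
        plastid=GenomicInterval("pt", s_start, s_end, strand),
        pident=97.0,
    )


class TestTransfer:
    def test_forward_offset(self):
        nupt = make_nupt(0, 100, 500, 600, "+")
        got = transfer_to_plastid(GenomicInterval("chr1", 10, 20), nupt)
        assert (got.start, got.end) == (510, 520)

    def test_reverse_strand_mirrors(self):
        """Nuclear (10,20) inside query (0,100) mapped through a reversed
        subject span (100,200) lands on plastid (180,190)."""
        nupt = make_nupt(0, 100, 100, 200, "-")
        got = transfer_to_plastid(GenomicInterval("chr1", 10, 20), nupt)
        assert (got.start, got.end) == (180, 190)

    def test_round_trip(self, rng):
        """Transferring through a planted equal-length alignment and back
        recovers the original interval exactly on both strands."""
        for strand in "+-":
            nupt = make_nupt(1000, 1400, 2000, 2400, strand)
            for _ in range(20):
                s = int(rng.integers(1000, 1390))
                e = int(rng.integers(s + 1, 1401))
                donor = transfer_to_plastid(GenomicInterval("chr1", s, e), nupt)
                assert nupt.plastid.start <= donor.start < donor.end <= nupt.plastid.end
                back = NuptRecord(
                    nupt_id="inv",
                    nuclear=GenomicInterval("pt", nupt.plastid.start, nupt.plastid.end),
                    plastid=GenomicInterval("chr1", nupt.nuclear.start,
                                            nupt.nuclear.end, strand),
                    pident=97.0,
                )
                again = transfer_to_plastid(donor, back)
                assert (again.start, again.end) == (s, e)

    def test_zero_length_transfer_rejected(self):
        nupt = make_nupt(0, 100, 500, 600, "+")
        with pytest.raises(ValueError, match="zero-length"):
            transfer_to_plastid(GenomicInterval("chr1", 200, 300), nupt)


class TestMapDonor:
    def plastid_features(self):
        fs = FeatureSet("tRNA_plastid")
        fs.add(GenomicInterval("pt", 520, 590), gene_id="pt_trna_1")
        return {"tRNA_plastid": fs}

    def test_same_category_donor(self):
        nupt = make_nupt(0, 100, 500, 600, "+")
        m = map_donor(GenomicInterval("chr1", 20, 90), "g1", "tRNA_plastid",
                      nupt, self.plastid_features())
        assert m.same_category and m.donor_gene_ids == ["pt_trna_1"]

    def test_no_donor_feature(self):
        nupt = make_nupt(0, 100, 500, 600, "+")
        m = map_donor(GenomicInterval("chr1", 0, 15), "g1", "tRNA_plastid",
                      nupt, self.plastid_features())
        assert m.donor_gene_ids == [] and not m.same_category


class TestCensus:
    def test_counts_sum(self):
        census = census_from_counts(611, 913, 59)
        assert census.total == 1583

    def test_plastid_origin_percentage(self):
        """912 plastid + 48 resident mitochondrial + 112 resident nuclear
        over 1583 genes = 67.72% of plastid origin."""
        census = census_from_counts(
            611, 913, 59,
            n_mito_resident=48, n_nuclear_resident=112, n_plastid_origin=912,
        )
        assert census.total == 1583
        assert census.plastid_origin_count == 1072
        assert census.plastid_origin_percentage == pytest.approx(67.72)

    def test_single_compartment_extremes(self):
        all_plastid = census_from_counts(0, 10, 0)
        assert all_plastid.plastid_origin_percentage == 100.0
        none = census_from_counts(10, 0, 0)
        assert none.plastid_origin_percentage == 0.0

    def test_from_calls_with_residence(self):
        calls = [
            OriginCall("g1", "plastid"),
            OriginCall("g2", "mitochondrial"),
            OriginCall("g3", "nuclear"),
            OriginCall("g4", "nuclear"),
        ]
        census = trna_census(calls, {"g2": True, "g3": True, "g4": False})
        assert census.total == 4
        assert census.plastid_origin_count == 3  # plastid + resident mito + resident nuc

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trna_census([])
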