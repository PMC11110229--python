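"""Partitioning, the bp-proportional null, and the Yates-corrected test,
checked against per-base labeling oracles and hand-evaluated formulas."""

import numpy as np
import pytest
from scipy.stats import chi2

from nuptools.enrichment import (
    NuptEnrichment,
    enrichment_scan,
    expected_overlap,
    partition_genome,
    yates_chisq,
)
from nuptools.intervals import GenomicInterval, total_bp


def iv(s, e, c="c"):
    return GenomicInterval(c, s, e)


class TestPartition:
    def test_single_category_residual(self):
        part = partition_genome({"TE": [iv(0, 300)]}, {"c": 1000})
        assert part.sizes["TE"] == 300
        assert part.sizes["other_DNA"] == 700
        assert part.genome_size == 1000

    def test_priority_resolves_shared_bases(self):
        """100 shared bases go to the earlier category only; sizes tile."""
        part = partition_genome(
            {"structural_gene": [iv(0, 200)], "TE": [iv(100, 400)]}, {"c": 1000}
        )
        assert part.sizes["structural_gene"] == 200
        assert part.sizes["TE"] == 200  # lost (100,200) to structural_gene
        assert sum(part.sizes.values()) == 1000

    def test_empty_features_all_residual(self):
        part = partition_genome({}, {"c": 500})
        assert part.sizes["other_DNA"] == 500

    def test_feature_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            partition_genome({"TE": [iv(0, 2000)]}, {"c": 1000})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="priority"):
            partition_genome({"mystery": [iv(0, 10)]}, {"c": 100})

    def test_matches_per_base_labeling_oracle(self, rng):
        """Each base belongs to exactly the first priority category
        covering it, on random small genomes."""
        cats = ["structural_gene", "TE", "other_repeat"]
        for _ in range(30):
            length = int(rng.integers(500, 2000))
            fsets = {
                c: [
                    iv(int(s), int(min(s + l, length)))
                    for s, l in zip(
                        rng.integers(0, length - 1, 5), rng.integers(1, 200, 5)
                    )
                ]
                for c in cats
            }
            part = partition_genome(fsets, {"c": length})
            label = np.full(length, "other_DNA", dtype=object)
            for c in reversed(cats):  # earlier categories overwrite later
                for f in fsets[c]:
                    label[f.start : f.end] = c
            for c in cats + ["other_DNA"]:
                assert part.sizes[c] == int((label == c).sum())


class TestExpected:
    def test_proportional(self):
        part = partition_genome({"TE": [iv(0, 300)]}, {"c": 1000})
        exp = expected_overlap(100, part)
        assert exp["TE"] == pytest.approx(30.0)
        assert sum(exp.values()) == pytest.approx(100.0)

    def test_whole_genome_category(self):
        part = partition_genome({"TE": [iv(0, 1000)]}, {"c": 1000})
        assert expected_overlap(42, part)["TE"] == pytest.approx(42.0)

    def test_three_way_sums_to_total(self):
        part = partition_genome(
            {"structural_gene": [iv(0, 200)], "TE": [iv(200, 700)]}, {"c": 1000}
        )
        assert sum(expected_overlap(333, part).values()) == pytest.approx(333.0)


class TestYates:
    def test_no_deviation(self):
        stat, p = yates_chisq(20, 20, 100)
        assert stat == 0 and p == 1.0

    def test_hand_evaluated_example(self):
        """O=30, E=20, T=100: chi2 = 9.5^2/20 + 9.5^2/80 = 5.640625."""
        stat, p = yates_chisq(30, 20, 100)
        assert stat == pytest.approx(5.640625, abs=1e-12)
        assert p == pytest.approx(chi2.sf(5.640625, 1), abs=1e-12)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_clamped_below_half_base(self):
        stat, _ = yates_chisq(20.4, 20.0, 100)
        assert stat == 0.0

    @pytest.mark.parametrize("O,E,T", [(5, 0, 10), (5, 10, 10), (5, 5, 0)])
    def test_undefined_configurations(self, O, E, T):
        with pytest.raises(ValueError):
            yates_chisq(O, E, T)


class TestScan:
    def test_conservation(self, rng):
        """Observed and expected bp each sum to T when the partition tiles
        the genome."""
        part = partition_genome(
            {"structural_gene": [iv(0, 2000)], "TE": [iv(3000, 6000)]}, {"c": 10_000}
        )
        nupts = [
            iv(int(s), int(s) + 50) for s in rng.integers(0, 9_900, size=40)
        ]
        res = NuptEnrichment({"all": nupts}, part).fit().table
        T = total_bp(nupts)
        assert res["observed_bp"].sum() == T
        assert res["expected_bp"].sum() == pytest.approx(T)

    def test_planted_bias_flagged(self, rng):
        """NUPT bases concentrated 5x into one category are flagged
        enriched; unweighted categories come out depleted or ns."""
        part = partition_genome(
            {
                "TE": [iv(i * 1000, i * 1000 + 400) for i in range(5)],
                "other_repeat": [iv(i * 1000 + 500, i * 1000 + 900) for i in range(5)],
            },
            {"c": 10_000},
        )
        # place many 1-bp NUPTs, 5x density inside TE spans
        nupts = []
        for s in rng.integers(0, 400, size=1000):
            block = int(rng.integers(0, 5))
            nupts.append(iv(block * 1000 + int(s), block * 1000 + int(s) + 1))
        for s in rng.integers(0, 10_000 - 1, size=1000):
            nupts.append(iv(int(s), int(s) + 1))
        table = enrichment_scan({"all": nupts}, part)
        row = table.set_index("category")
        assert row.loc["TE", "direction"] == "enriched"
        assert row.loc["other_repeat", "direction"] != "enriched"

    def test_saturated_nupt_set_all_ns(self):
        """A NUPT set equal to the whole genome gives O=E everywhere."""
        part = partition_genome(
            {"TE": [iv(0, 300)], "other_repeat": [iv(400, 600)]}, {"c": 1000}
        )
        table = enrichment_scan({"all": [iv(0, 1000)]}, part)
        assert (table["direction"] == "ns").all()
        occupied = table[table["expected_bp"] > 0]
        assert np.allclose(occupied["log10_ratio"], 0.0)

    def test_empty_nupt_set_rejected(self):
        part = partition_genome({"TE": [iv(0, 300)]}, {"c": 1000})
        with pytest.raises(ValueError, match="empty NUPT set"):
            NuptEnrichment({"all": []}, part).fit()

    def test_log_ratio_zero_when_balanced(self):
        part = partition_genome({"TE": [iv(0, 500)]}, {"c": 1000})
        table = enrichment_scan({"all": [iv(200, 300), iv(700, 800)]}, part)
        te = table.set_index("category").loc["TE"]
        assert te["observed_bp"] == 100 and te["expected_bp"] == pytest.approx(100.0)
        assert te["log10_ratio"] == pytest.approx(0.0)
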