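"""Observed-vs-expected base-pair overlap enrichment of NUPTs by feature.

A genomic feature category that occupies more of the genome is expected to
intersect more NUPT bases purely by chance. The null model here is
bp-proportional: if a NUPT track contains T bases in total and category f
occupies S_f of the G genome bases, the expected overlap is

    E_f = T * S_f / G.

The genome is first partitioned so every base belongs to exactly one
category (a configurable priority order resolves overlaps; leftover bases
form the residual "other_DNA" category), which makes observed and expected
overlaps each sum to T. Each category is then tested with a two-cell
Pearson chi-squared test with Yates' continuity correction (deviation
clamped at zero), df = 1:

    chi2 = (max(|O-E| - 0.5, 0))^2 / E  +  (max(|O'-E'| - 0.5, 0))^2 / E'

with O' = T - O, E' = T - E the bases outside the category.

A separate non-exclusive mode reports per-category overlaps against the
raw (unpartitioned) feature sets, where a NUPT base may count toward
several categories; no test is run in that mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .intervals import GenomicInterval, intersect_bp, merge_intervals, subtract, total_bp
from .io import CATEGORIES, OTHER_DNA

#: Default priority order for resolving bases claimed by several categories.
DEFAULT_PRIORITY: tuple[str, ...] = CATEGORIES

DIRECTION_ENRICHED = "enriched"
DIRECTION_DEPLETED = "depleted"
DIRECTION_NS = "ns"


@dataclass
class PartitionTable:
    """Disjoint category partition of a genome.

    ``intervals[cat]`` are merged, pairwise-disjoint spans; sizes plus the
    residual ``other_DNA`` tile the genome exactly.
    """

    intervals: dict[str, list[GenomicInterval]]
    genome_size: int

    @property
    def sizes(self) -> dict[str, int]:
        return {c: sum(iv.length for iv in ivs) for c, ivs in self.intervals.items()}

    @property
    def categories(self) -> list[str]:
        return list(self.intervals)

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if sum(self.sizes.values()) != self.genome_size:
            raise ValueError("partition does not tile the genome")


def partition_genome(
    feature_sets: Mapping[str, Sequence[GenomicInterval]],
    genome_lengths: Mapping[str, int],
    priority_order: Sequence[str] = DEFAULT_PRIORITY,
) -> PartitionTable:
    """Assign every genome base to exactly one feature category.

    A base covered by several categories goes to the first category in
    ``priority_order`` that covers it; bases covered by none fall into the
    residual ``other_DNA`` category.

    Raises
    ------
    ValueError
        If a supplied category is missing from ``priority_order``, or a
        feature extends beyond its chromosome end.
    """
    supplied = {c for c, ivs in feature_sets.items() if len(ivs) > 0}
    missing = supplied - set(priority_order)
    if missing:
        raise ValueError(f"categories missing from priority order: {sorted(missing)}")
    for cat, ivs in feature_sets.items():
        for iv in ivs:
            if iv.chrom not in genome_lengths:
                raise ValueError(f"unknown chromosome {iv.chrom!r} in {cat}")
            if iv.end > genome_lengths[iv.chrom]:
                raise ValueError(
                    f"{cat} feature ({iv.start}, {iv.end}) beyond {iv.chrom} end"
                )
    genome_size = sum(genome_lengths.values())
    claimed: list[GenomicInterval] = []
    out: dict[str, list[GenomicInterval]] = {}
    for cat in priority_order:
        ivs = list(feature_sets.get(cat, ()))
        own = subtract(ivs, claimed) if claimed else merge_intervals(ivs)
        out[cat] = own
        claimed = merge_intervals(claimed + own)
    whole = [GenomicInterval(c, 0, n) for c, n in genome_lengths.items() if n > 0]
    out[OTHER_DNA] = subtract(whole, claimed)
    return PartitionTable(intervals=out, genome_size=genome_size)


def expected_overlap(total_nupt_bp: int, partition: PartitionTable) -> dict[str, float]:
    """Expected bp overlap per category under the bp-proportional null:
    E_f = T * S_f / G. The values sum to T exactly (up to float round-off)."""
    if total_nupt_bp < 0:
        raise ValueError("total NUPT bp must be >= 0")
    G = partition.genome_size
    if G == 0:
        raise ValueError("genome size is zero")
    return {c: total_nupt_bp * s / G for c, s in partition.sizes.items()}


def yates_chisq(observed: float, expected: float, total: float) -> tuple[float, float]:
    """Two-cell Pearson chi-squared with Yates' continuity correction.

    Cells are (inside category: O vs E) and (outside: T-O vs T-E); the
    0.5 continuity correction is clamped at zero so deviations below half
    a base give a statistic of exactly 0. Returns (chi2, upper-tail p at
    df=1).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed <= total:
        raise ValueError("observed must lie in [0, total]")
    if not 0 < expected < total:
        raise ValueError("undefined test: expected must lie strictly in (0, total)")
    dev = max(abs(observed - expected) - 0.5, 0.0)
    stat = dev**2 / expected + dev**2 / (total - expected)
    return stat, float(chi2_dist.sf(stat, df=1))


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected overlap of one NUPT class with one category."""

    nupt_class: str
    category: str
    observed_bp: int
    expected_bp: float
    total_bp: int
    log10_ratio: float
    chi2: float
    p: float
    direction: str


class NuptEnrichment:
    """Model: NUPT interval sets (optionally per age class) against a
    genome partition, tested with the bp-proportional null.

    Parameters
    ----------
    nupt_sets_by_class : mapping
        Class label -> NUPT intervals. NUPT intervals are merged per class
        before counting so nested alignments do not double-count bases.
    partition : PartitionTable
    alpha : float
        Significance level for the enriched/depleted call (default 0.05).
    """

    def __init__(
        self,
        nupt_sets_by_class: Mapping[str, Sequence[GenomicInterval]],
        partition: PartitionTable,
        alpha: float = 0.05,
    ):
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.nupt_sets = {c: merge_intervals(ivs) for c, ivs in nupt_sets_by_class.items()}
        self.partition = partition
        self.alpha = alpha

    def fit(self) -> "NuptEnrichmentResults":
        rows = []
        for cls, nupts in self.nupt_sets.items():
            T = sum(iv.length for iv in nupts)
            if T == 0:
                raise ValueError(f"empty NUPT set for class {cls!r}")
            exp = expected_overlap(T, self.partition)
            for cat, cat_ivs in self.partition.intervals.items():
                O = intersect_bp(nupts, cat_ivs)
                E = exp[cat]
                if E <= 0 or E >= T:
                    # category empty (or the whole genome): test undefined
                    rows.append(
                        EnrichmentResult(cls, cat, O, E, T, np.nan, np.nan, np.nan,
                                         DIRECTION_NS)
                    )
                    continue
                stat, p = yates_chisq(O, E, T)
                with np.errstate(divide="ignore"):
                    lr = float(np.log10(O / E)) if O > 0 else -np.inf
                if p < self.alpha and O > E:
                    direction = DIRECTION_ENRICHED
                elif p < self.alpha and O < E:
                    direction = DIRECTION_DEPLETED
                else:
                    direction = DIRECTION_NS
                rows.append(EnrichmentResult(cls, cat, O, E, T, lr, stat, p, direction))
        return NuptEnrichmentResults(self, rows)


@dataclass
class NuptEnrichmentResults:
    model: NuptEnrichment
    results: list[EnrichmentResult]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class": r.nupt_class,
                    "category": r.category,
                    "observed_bp": r.observed_bp,
                    "expected_bp": r.expected_bp,
                    "log10_ratio": r.log10_ratio,
                    "chi2": r.chi2,
                    "p": r.p,
                    "direction": r.direction,
                }
                for r in self.results
            ]
        )

    def summary(self) -> str:
        df = self.table
        lines = [
            "NUPT overlap enrichment (bp-proportional null, Yates chi-squared)",
            f"alpha = {self.model.alpha}, genome = {self.model.partition.genome_size} bp",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def enrichment_scan(
    nupt_sets_by_class: Mapping[str, Sequence[GenomicInterval]],
    partition: PartitionTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Functional wrapper: one enrichment row per (NUPT class x category)."""
    return NuptEnrichment(nupt_sets_by_class, partition, alpha=alpha).fit().table


def overlap_table(
    nupt_intervals: Sequence[GenomicInterval],
    feature_sets: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Non-exclusive per-category overlap accounting.

    Overlap bp of the merged NUPT union with each raw (unpartitioned)
    feature set; a NUPT base inside two categories counts toward both, so
    no statistical test is attached.
    """
    nupts = merge_intervals(nupt_intervals)
    rows = []
    for cat, ivs in feature_sets.items():
        rows.append(
            {
                "category": cat,
                "feature_bp": total_bp(ivs),
                "overlap_bp": intersect_bp(nupts, ivs),
            }
        )
    return pd.DataFrame(rows)
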