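"""Origin classification of tRNA genes and donor mapping of NUPT RNA genes.

tRNA genes in a nuclear genome may be native (nuclear), or copies of
mitochondrial or plastid tRNAs delivered by organellar DNA insertions.
Origin is called by a best-hit rule against a reference tRNA set whose
subjects carry compartment labels: among hits passing the E-value cutoff
(default 1e-2), the hit with the highest bit score wins; ties break on the
smaller E-value, then the lexicographically smallest subject id. A query
with no passing hit is "unclassified".

NUPT-resident RNA genes are mapped back to their donor region in the
plastid genome through the NUPT alignment: the overlapped sub-interval of
the nuclear gene is transferred linearly (strand-aware, proportionally if
query and subject spans differ in length, since tabular alignments carry
no gap structure) into plastid coordinates, and plastid annotation
features overlapping the transferred span are reported as donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, STRAND_REVERSE
from .io import AlignmentRow, FeatureSet, NuptRecord

COMPARTMENTS = ("nuclear", "mitochondrial", "plastid")
UNCLASSIFIED = "unclassified"

DEFAULT_EVALUE_CUTOFF = 1e-2


@dataclass(frozen=True)
class OriginCall:
    """Best-hit compartment call for one query gene."""

    gene_id: str
    compartment: str
    subject_id: str | None = None
    bitscore: float | None = None
    evalue: float | None = None


def classify_origin(
    hit_rows: Sequence[AlignmentRow],
    subject_compartment_map: Mapping[str, str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> dict[str, OriginCall]:
    """Call a compartment of origin for every query in ``hit_rows``.

    Returns one OriginCall per distinct query id. Queries whose hits all
    fail the cutoff are called "unclassified". A winning subject missing
    from the compartment map is an error.
    """
    by_query: dict[str, list[AlignmentRow]] = {}
    for row in hit_rows:
        by_query.setdefault(row.qseqid, []).append(row)
    calls: dict[str, OriginCall] = {}
    for qid, rows in by_query.items():
        passing = [r for r in rows if r.evalue <= evalue_cutoff]
        if not passing:
            calls[qid] = OriginCall(qid, UNCLASSIFIED)
            continue
        # max bit score; ties -> smaller e-value -> lexicographic subject id
        best = min(passing, key=lambda r: (-r.bitscore, r.evalue, r.sseqid))
        if best.sseqid not in subject_compartment_map:
            raise KeyError(f"subject {best.sseqid!r} missing from compartment map")
        calls[qid] = OriginCall(
            qid,
            subject_compartment_map[best.sseqid],
            subject_id=best.sseqid,
            bitscore=best.bitscore,
            evalue=best.evalue,
        )
    return calls


@dataclass
class DonorMapping:
    """A nuclear RNA gene mapped to its donor span in the plastid genome."""

    gene_id: str
    gene_category: str
    nupt_id: str
    donor_interval: GenomicInterval
    donor_gene_ids: list[str]
    donor_categories: list[str]
    same_category: bool


def transfer_to_plastid(
    nuclear_sub: GenomicInterval, nupt: NuptRecord
) -> GenomicInterval:
    """Linearly transfer a nuclear sub-interval of a NUPT into plastid
    coordinates through the NUPT's query<->subject span (strand-aware,
    proportional when span lengths differ)."""
    q, s = nupt.nuclear, nupt.plastid
    lo = max(nuclear_sub.start, q.start)
    hi = min(nuclear_sub.end, q.end)
    if hi <= lo:
        raise ValueError("zero-length transfer: sub-interval outside the NUPT span")
    scale = s.length / q.length
    off_lo = (lo - q.start) * scale
    off_hi = (hi - q.start) * scale
    if s.strand == STRAND_REVERSE:
        p_lo = s.end - off_hi
        p_hi = s.end - off_lo
    else:
        p_lo = s.start + off_lo
        p_hi = s.start + off_hi
    start, end = int(round(p_lo)), int(round(p_hi))
    if end <= start:
        end = start + 1
    return GenomicInterval(s.chrom, start, end, s.strand)


def map_donor(
    gene_interval: GenomicInterval,
    gene_id: str,
    gene_category: str,
    nupt: NuptRecord,
    plastid_features: Mapping[str, FeatureSet],
) -> DonorMapping:
    """Map one NUPT-resident RNA gene to its plastid donor annotation.

    The gene must overlap the NUPT's nuclear span. ``same_category`` is
    true when any donor feature shares the gene's taxonomy category.
    """
    donor = transfer_to_plastid(gene_interval, nupt)
    donor_ids: list[str] = []
    donor_cats: list[str] = []
    for cat, fs in plastid_features.items():
        for iv, attrs in zip(fs.intervals, fs.attributes or [{}] * len(fs.intervals)):
            if donor.chrom == iv.chrom and donor.start < iv.end and iv.start < donor.end:
                donor_ids.append(attrs.get("gene_id", f"{cat}:{iv.start}-{iv.end}"))
                donor_cats.append(cat)
    return DonorMapping(
        gene_id=gene_id,
        gene_category=gene_category,
        nupt_id=nupt.nupt_id,
        donor_interval=donor,
        donor_gene_ids=donor_ids,
        donor_categories=donor_cats,
        same_category=gene_category in donor_cats,
    )


@dataclass
class TrnaCensus:
    """Compartment counts of nuclear tRNA genes and the plastid-origin
    percentage, decomposed the way the headline figure is assembled:
    plastid-compartment genes, plus mitochondrial- and nuclear-compartment
    genes that reside inside NUPTs."""

    counts: dict[str, int]
    n_plastid_compartment: int
    n_mito_resident: int
    n_nuclear_resident: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def plastid_origin_count(self) -> int:
        return self.n_plastid_compartment + self.n_mito_resident + self.n_nuclear_resident

    @property
    def plastid_origin_percentage(self) -> float:
        """Percentage of nuclear-genome tRNA genes of plastid origin,
        rounded to two decimals."""
        return round(100.0 * self.plastid_origin_count / self.total, 2)


def trna_census(
    origin_calls: Mapping[str, OriginCall] | Iterable[OriginCall],
    resident_in_nupt: Mapping[str, bool] | None = None,
) -> TrnaCensus:
    """Tally origin calls per compartment and derive the plastid-origin
    fraction.

    ``resident_in_nupt`` flags genes whose span lies in a NUPT; it feeds
    the mitochondrial/nuclear-compartment terms of the plastid-origin
    numerator. When omitted, only plastid-compartment genes count.
    """
    calls = list(origin_calls.values()) if isinstance(origin_calls, Mapping) else list(origin_calls)
    if not calls:
        raise ValueError("empty origin-call set")
    resident_in_nupt = resident_in_nupt or {}
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.compartment] = counts.get(c.compartment, 0) + 1
    return TrnaCensus(
        counts=counts,
        n_plastid_compartment=counts.get("plastid", 0),
        n_mito_resident=sum(
            1 for c in calls
            if c.compartment == "mitochondrial" and resident_in_nupt.get(c.gene_id, False)
        ),
        n_nuclear_resident=sum(
            1 for c in calls
            if c.compartment == "nuclear" and resident_in_nupt.get(c.gene_id, False)
        ),
    )


def census_from_counts(
    n_nuclear: int, n_plastid: int, n_mitochondrial: int,
    n_mito_resident: int = 0, n_nuclear_resident: int = 0,
    n_plastid_origin: int | None = None,
) -> TrnaCensus:
    """Build a census directly from published-style compartment counts.

    ``n_plastid_origin`` overrides the plastid term of the plastid-origin
    numerator when it differs from the plastid-compartment count (a gene
    annotated as plastid tRNA need not map to an identically annotated
    donor); it defaults to ``n_plastid``.
    """
    if min(n_nuclear, n_plastid, n_mitochondrial) < 0:
        raise ValueError("counts must be non-negative")
    return TrnaCensus(
        counts={
            "nuclear": n_nuclear,
            "plastid": n_plastid,
            "mitochondrial": n_mitochondrial,
        },
        n_plastid_compartment=(
            n_plastid if n_plastid_origin is None else n_plastid_origin
        ),
        n_mito_resident=n_mito_resident,
        n_nuclear_resident=n_nuclear_resident,
    )


def donor_summary(mappings: Sequence[DonorMapping]) -> pd.DataFrame:
    """Per-category counts of donor mappings that kept or changed their
    annotation category between plastid and nucleus."""
    rows: dict[str, dict[str, int]] = {}
    for m in mappings:
        d = rows.setdefault(m.gene_category, {"same": 0, "different": 0})
        d["same" if m.same_category else "different"] += 1
    return pd.DataFrame(
        [
            {"category": cat, "same_category": d["same"], "different_category": d["different"]}
            for cat, d in sorted(rows.items())
        ]
    )
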