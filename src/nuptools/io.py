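"""Readers and writers for FASTA, GFF3, and tabular alignment files.

GFF3 is 1-based closed; the tabular alignment dialect (12-column
``outfmt 6``: qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore) is 1-based inclusive with possibly reversed
subject coordinates. Everything is converted to the package-internal
0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    GenomicInterval,
    STRAND_FORWARD,
    STRAND_NONE,
    STRAND_REVERSE,
    merge_intervals,
    subtract,
)

# The feature-category taxonomy: twelve named categories plus the residual
# "other_DNA" bucket for uncategorized sequence.
CATEGORIES: tuple[str, ...] = (
    "structural_gene",
    "TE",
    "other_repeat",
    "rRNA_eukaryotic",
    "rRNA_prokaryotic",
    "tRNA_nuclear",
    "tRNA_mitochondrial",
    "tRNA_plastid",
    "self_splicing_intron",
    "regulatory_RNA",
    "spliceosomal_RNA",
    "other_RNA",
)
OTHER_DNA = "other_DNA"

RNA_CATEGORIES: tuple[str, ...] = CATEGORIES[3:]

_IUPAC_NT = set("ACGTURYSWKMBDHVN")


@dataclass
class FeatureSet:
    """A labeled collection of intervals belonging to one feature category."""

    category: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    attributes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.attributes and len(self.attributes) != len(self.intervals):
            raise ValueError("attributes must parallel intervals")

    def add(self, interval: GenomicInterval, **attrs) -> None:
        self.intervals.append(interval)
        self.attributes.append(attrs)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class AlignmentRow:
    """One row of the 12-column tabular alignment dialect.

    Coordinates are stored as read (1-based inclusive; subject may be
    reversed). ``query_interval``/``subject_interval`` expose the
    forward-normalized half-open spans, with the subject strand inferred
    from the coordinate order.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"percent identity {self.pident} outside [0, 100]")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")

    @property
    def subject_strand(self) -> str:
        return STRAND_FORWARD if self.sstart <= self.send else STRAND_REVERSE

    @property
    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(self.qseqid, self.qstart - 1, self.qend, STRAND_FORWARD)

    @property
    def subject_interval(self) -> GenomicInterval:
        lo, hi = sorted((self.sstart, self.send))
        return GenomicInterval(self.sseqid, lo - 1, hi, self.subject_strand)


@dataclass
class NuptRecord:
    """One nuclear plastid DNA insertion: a nuclear-vs-plastid alignment row
    with its nuclear span, plastid donor span, percent identity and
    (once assigned) age class."""

    nupt_id: str
    nuclear: GenomicInterval
    plastid: GenomicInterval
    pident: float
    age_class: str | None = None  # "I", "II", "unclassified" or None


@dataclass
class GeneModel:
    """A structural (protein-coding) gene with exon/intron structure.

    Introns are derived (gene span minus merged exons), never stored.
    Promoter/terminator flanks are computed strand-aware from the CDS ends
    when CDS coordinates are known, else from the gene span ends.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.gene_id}")
        self.exons = merge_intervals(self.exons)
        for ex in self.exons:
            if ex.start < self.start or ex.end > self.end:
                raise ValueError(f"exon outside gene span for {self.gene_id}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> list[GenomicInterval]:
        if not self.exons:
            return []
        return subtract([self.span], self.exons)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a nucleotide FASTA into an ordered mapping id -> sequence.

    Raises
    ------
    ValueError
        On duplicate record ids, an empty file, or characters outside the
        IUPAC nucleotide alphabet.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise ValueError(
                f"non-IUPAC nucleotide characters {sorted(bad)} in record {rec.id!r}"
            )
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: Mapping[str, str], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def sequence_lengths(records: Mapping[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in records.items()}


# GFF3 feature types / category attribute values accepted for each taxonomy
# category. Structural genes use the canonical gene/mRNA/exon/CDS hierarchy.
_CATEGORY_TYPES = {c: c for c in CATEGORIES if c != "structural_gene"}


@dataclass
class Gff3Content:
    """Parsed GFF3: category feature sets, structural gene models, and
    counts of records skipped on the defined error paths."""

    features: dict[str, FeatureSet]
    genes: list[GeneModel]
    n_orphans: int = 0


def read_gff3(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int] | None = None
) -> Gff3Content:
    """Parse a GFF3 into feature sets and structural gene models.

    Structural genes require a gene/mRNA/exon hierarchy (CDS optional).
    Non-gene features are assigned to a taxonomy category from either the
    feature type or a ``category`` attribute. Exons whose Parent cannot be
    resolved are counted and excluded with a warning. GFF3 1-based closed
    coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: dict[str, FeatureSet] = {c: FeatureSet(c) for c in CATEGORIES}
    genes: list[GeneModel] = []
    n_orphans = 0

    def _check_bounds(f) -> None:
        if chrom_lengths is not None:
            if f.seqid not in chrom_lengths:
                raise ValueError(f"chromosome {f.seqid!r} absent from FASTA index")
            if f.end > chrom_lengths[f.seqid]:
                raise ValueError(
                    f"feature {f.id} extends beyond chromosome {f.seqid} end"
                )

    for f in db.all_features():
        ftype = f.featuretype
        if ftype == "gene":
            _check_bounds(f)
            exons = []
            cds_lo: int | None = None
            cds_hi: int | None = None
            for child in db.children(f.id):
                if child.featuretype == "exon":
                    exons.append(
                        GenomicInterval(child.seqid, child.start - 1, child.end)
                    )
                elif child.featuretype == "CDS":
                    lo, hi = child.start - 1, child.end
                    cds_lo = lo if cds_lo is None else min(cds_lo, lo)
                    cds_hi = hi if cds_hi is None else max(cds_hi, hi)
            gene = GeneModel(
                gene_id=f.id,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in "+-" else STRAND_NONE,
                exons=exons,
                cds_start=cds_lo,
                cds_end=cds_hi,
            )
            genes.append(gene)
            features["structural_gene"].add(
                GenomicInterval(f.seqid, f.start - 1, f.end, gene.strand),
                gene_id=f.id,
            )
        elif ftype in ("mRNA", "CDS"):
            continue  # folded into their parent gene
        elif ftype == "exon":
            parents = list(db.parents(f.id))
            if not parents:
                n_orphans += 1
                warnings.warn(f"orphan exon {f.id} excluded", stacklevel=2)
            continue
        else:
            cat = _CATEGORY_TYPES.get(ftype) or _CATEGORY_TYPES.get(
                f.attributes.get("category", [""])[0]
            )
            if cat is None:
                continue  # unrecognised feature type: not part of the taxonomy
            _check_bounds(f)
            features[cat].add(
                GenomicInterval(
                    f.seqid,
                    f.start - 1,
                    f.end,
                    f.strand if f.strand in "+-" else STRAND_NONE,
                ),
                gene_id=f.id,
            )
    return Gff3Content(features=features, genes=genes, n_orphans=n_orphans)


def write_gff3(path: str | os.PathLike, rows: Iterable[tuple]) -> None:
    """Write GFF3 rows given as (chrom, source, type, interval, attrs dict).

    Internal half-open coordinates are converted back to 1-based closed.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, iv, attrs in rows:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_s}\n"
            )


_ALN_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore"
).split()


def read_alignment_tab(path: str | os.PathLike) -> list[AlignmentRow]:
    """Read a 12-column tabular alignment file into AlignmentRow records.

    No filtering is applied; every row is retained. An empty file yields an
    empty list. Raises on a wrong column count or unparsable numerics.
    """
    rows: list[AlignmentRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    AlignmentRow(
                        qseqid=parts[0],
                        sseqid=parts[1],
                        pident=float(parts[2]),
                        length=int(parts[3]),
                        mismatch=int(parts[4]),
                        gapopen=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    return rows


def write_alignment_tab(path: str | os.PathLike, rows: Iterable[AlignmentRow]) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.qseqid}\t{r.sseqid}\t{r.pident:.2f}\t{r.length}\t{r.mismatch}\t"
                f"{r.gapopen}\t{r.qstart}\t{r.qend}\t{r.sstart}\t{r.send}\t"
                f"{r.evalue:.2e}\t{r.bitscore:.1f}\n"
            )


def nupt_records(rows: Sequence[AlignmentRow]) -> list[NuptRecord]:
    """Turn alignment rows (query = nuclear, subject = plastid) into
    NuptRecords. Each row is one NUPT; ids are ``nupt{i:05d}`` in file order."""
    out = []
    for i, r in enumerate(rows):
        out.append(
            NuptRecord(
                nupt_id=f"nupt{i:05d}",
                nuclear=r.query_interval,
                plastid=r.subject_interval,
                pident=r.pident,
            )
        )
    return out


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
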