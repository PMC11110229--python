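"""Synthetic genomes with planted plastid-DNA insertions and ground truth.

The generator emulates the data a NUPT characterization run consumes:

* a plastid genome carrying tRNA / rRNA / self-splicing-intron /
  regulatory-RNA gene annotation and a compartment-labeled reference tRNA
  set;
* a nuclear genome (several chromosomes) with structural genes
  (exon/intron), TEs, repeats and RNA genes, into which NUPTs from two
  insertion episodes are planted: each NUPT copies a plastid segment,
  mutates it by substitutions only to a drawn target identity (episode I
  ~ Normal(82, 3^2), episode II ~ Normal(97, 1.5^2), truncated to
  [60, 100]), and overwrites nuclear bases at a location sampled in
  proportion to per-category placement weights over the genome partition
  (insertions never shift annotated coordinates);
* the matching truth alignment table (12-column tabular dialect), a
  tRNA-vs-reference hit table, a genes x tissues TPM matrix with planted
  silent / uniform / tissue-specific genes, and term annotations with one
  planted enriched term;
* a truth ledger (JSON) sufficient to score every downstream module.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, STRAND_FORWARD, STRAND_REVERSE, merge_intervals
from .io import (
    AlignmentRow,
    CATEGORIES,
    FeatureSet,
    GeneModel,
    OTHER_DNA,
    write_alignment_tab,
    write_fasta,
    write_gff3,
    write_tsv,
)
from .enrichment import partition_genome

_BASES = np.array(list("ACGT"))

TISSUES = ("flower", "leaf", "root", "seed", "stem")

#: taxonomy category -> compartment of the corresponding reference tRNAs
_TRNA_COMPARTMENT = {
    "tRNA_nuclear": "nuclear",
    "tRNA_mitochondrial": "mitochondrial",
    "tRNA_plastid": "plastid",
}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    The defaults define the conditions every property check runs under:
    two insertion episodes with well-separated identity regimes, placement
    biased into the RNA-gene categories and away from structural genes
    (echoing the retention pattern the analysis is built to detect), five
    tissues, and one functional term planted at a 5x relative frequency.
    """

    seed: int = 0
    # plastid donor genome
    plastid_length: int = 150_000
    plastid_gene_counts: dict = field(
        default_factory=lambda: {
            "tRNA_plastid": 30,
            "tRNA_mitochondrial": 3,
            "tRNA_nuclear": 2,
            "rRNA_prokaryotic": 4,
            "rRNA_eukaryotic": 2,
            "self_splicing_intron": 12,
            "regulatory_RNA": 1,
        }
    )
    # nuclear genome
    n_chromosomes: int = 3
    chromosome_length: int = 500_000
    n_structural_genes: int = 150
    n_te: int = 350
    n_other_repeat: int = 80
    n_nuclear_trna: int = 60
    n_rrna_eukaryotic: int = 30
    n_spliceosomal: int = 15
    n_other_rna: int = 15
    # NUPT planting
    n_episode_I: int = 200
    n_episode_II: int = 800
    identity_mean_I: float = 82.0
    identity_sd_I: float = 3.0
    identity_mean_II: float = 97.0
    identity_sd_II: float = 1.5
    identity_bounds: tuple = (60.0, 100.0)
    fragment_length_range: tuple = (100, 1200)
    placement_weights: dict = field(
        default_factory=lambda: {
            "structural_gene": 0.2,
            "rRNA_prokaryotic": 5.0,
            "tRNA_plastid": 5.0,
            "self_splicing_intron": 5.0,
            "regulatory_RNA": 5.0,
        }
    )
    # expression
    tissues: tuple = TISSUES
    frac_silent: float = 0.2
    frac_uniform: float = 0.5
    noise_sd_frac: float = 0.10
    # term annotation
    n_terms: int = 30
    planted_term_factor: float = 5.0
    base_term_prob: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.identity_bounds
        for m in (self.identity_mean_I, self.identity_mean_II):
            if not 50.0 < m <= 100.0:
                raise ValueError("identity means must lie in (50, 100]")
        if any(w < 0 for w in self.placement_weights.values()):
            raise ValueError("placement weights must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutate_to_identity(
    sequence: str, target_identity: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute bases so the expected identity equals ``target_identity``.

    Each base is substituted independently with probability
    1 - target/100, the replacement drawn uniformly from the three
    alternative bases (substitution-only: no indels, so the mutated
    sequence keeps its length). Returns (mutated sequence, substitution
    count).
    """
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target identity must lie in (0, 100]")
    p = 1.0 - target_identity / 100.0
    if p == 0.0:
        return sequence, 0
    arr = np.array(list(sequence))
    mask = rng.random(arr.size) < p
    idx = np.flatnonzero(mask)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr), int(idx.size)


def _layout_genes(
    total_length: int,
    sizes: list[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Place features of the given sizes non-overlapping along a sequence,
    separated by Dirichlet-distributed gaps (uniform spread in expectation)."""
    need = sum(sizes)
    if need >= total_length:
        raise ValueError(f"layout overflow: {need} feature bp on {total_length} bp")
    slack = total_length - need
    gaps = rng.dirichlet(np.ones(len(sizes) + 1)) * slack
    spans = []
    cursor = 0.0
    for size, gap in zip(sizes, gaps[:-1]):
        cursor += gap
        start = int(round(cursor))
        spans.append((start, start + size))
        cursor = start + size
    return spans


@dataclass
class PlastidBundle:
    sequence: str
    chrom: str
    features: dict[str, FeatureSet]
    trna_reference: dict[str, str]  # subject_id -> compartment


def generate_plastid(config: SimConfig, rng: np.random.Generator) -> PlastidBundle:
    """Generate the plastid donor genome, its RNA-gene annotation, and the
    compartment-labeled reference tRNA set."""
    _GENE_SIZES = {
        "tRNA_plastid": (70, 90),
        "tRNA_mitochondrial": (70, 90),
        "tRNA_nuclear": (70, 90),
        "rRNA_prokaryotic": (700, 1500),
        "rRNA_eukaryotic": (800, 1600),
        "self_splicing_intron": (300, 700),
        "regulatory_RNA": (150, 250),
    }
    seq = random_sequence(config.plastid_length, rng)
    queue: list[tuple[str, int]] = []
    for cat, count in config.plastid_gene_counts.items():
        lo, hi = _GENE_SIZES.get(cat, (100, 300))
        for _ in range(count):
            queue.append((cat, int(rng.integers(lo, hi + 1))))
    order = rng.permutation(len(queue))
    queue = [queue[i] for i in order]
    spans = _layout_genes(config.plastid_length, [s for _, s in queue], rng)
    features = {c: FeatureSet(c) for c in CATEGORIES}
    counters: dict[str, int] = {}
    trna_reference: dict[str, str] = {}
    chrom = "plastid"
    for (cat, _), (s, e) in zip(queue, spans):
        counters[cat] = counters.get(cat, 0) + 1
        gid = f"pt_{cat}_{counters[cat]:03d}"
        strand = STRAND_FORWARD if rng.random() < 0.5 else STRAND_REVERSE
        features[cat].add(GenomicInterval(chrom, s, e, strand), gene_id=gid)
        if cat in _TRNA_COMPARTMENT:
            trna_reference[f"ref_{gid}"] = _TRNA_COMPARTMENT[cat]
    # extra off-genome reference tRNAs so decoy hits have subjects
    for i in range(5):
        trna_reference[f"ref_nuc_extra_{i:02d}"] = "nuclear"
    for i in range(3):
        trna_reference[f"ref_mt_extra_{i:02d}"] = "mitochondrial"
    return PlastidBundle(seq, chrom, features, trna_reference)


@dataclass
class PlantedNupt:
    """Truth record of one planted insertion."""

    nupt_id: str
    chrom: str
    start: int
    end: int
    src_start: int
    src_end: int
    strand: str
    episode: str  # "I" or "II"
    target_identity: float
    realized_identity: float
    n_substitutions: int
    target_category: str


@dataclass
class NuclearBundle:
    sequences: dict[str, str]
    features: dict[str, FeatureSet]
    genes: list[GeneModel]
    nupts: list[PlantedNupt]
    alignment_rows: list[AlignmentRow]
    trna_hits: list[AlignmentRow]
    truth: dict


def _sample_position(
    category_intervals: list[GenomicInterval], cum: np.ndarray, rng: np.random.Generator
) -> tuple[str, int]:
    """Uniformly sample one base of a merged category track."""
    total = int(cum[-1])
    offset = int(rng.integers(0, total))
    i = int(np.searchsorted(cum, offset, side="right"))
    iv = category_intervals[i]
    prev = int(cum[i - 1]) if i > 0 else 0
    return iv.chrom, iv.start + (offset - prev)


def generate_nuclear(
    plastid: PlastidBundle, config: SimConfig, rng: np.random.Generator
) -> NuclearBundle:
    """Generate the nuclear genome with planted two-episode NUPTs.

    Background features (structural genes, TEs, repeats, RNA genes) are
    laid out first; NUPTs then overwrite bases at positions sampled in
    proportion to per-category placement weights over the partition, so
    annotated coordinates never shift. Plastid genes fully inside a
    NUPT's source span are projected into nuclear coordinates and added
    to the annotation as NUPT-derived RNA genes.
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sequences = {
        c: list(random_sequence(config.chromosome_length, rng)) for c in chroms
    }
    chrom_lengths = {c: config.chromosome_length for c in chroms}
    features = {c: FeatureSet(c) for c in CATEGORIES}
    genes: list[GeneModel] = []

    # ---- background feature queue, round-robin across chromosomes ----
    def plan_structural(i: int) -> tuple[str, dict]:
        n_exons = int(rng.integers(1, 9))
        exon_lens = rng.integers(120, 400, size=n_exons)
        intron_lens = rng.integers(150, 500, size=max(n_exons - 1, 0))
        return "structural_gene", {
            "gene_id": f"gene{i:05d}",
            "exon_lens": exon_lens.tolist(),
            "intron_lens": intron_lens.tolist(),
            "size": int(exon_lens.sum() + intron_lens.sum()),
        }

    queue: list[tuple[str, dict]] = [
        plan_structural(i) for i in range(config.n_structural_genes)
    ]
    simple = [
        ("TE", config.n_te, (300, 2500)),
        ("other_repeat", config.n_other_repeat, (150, 600)),
        ("tRNA_nuclear", config.n_nuclear_trna, (70, 90)),
        ("rRNA_eukaryotic", config.n_rrna_eukaryotic, (1000, 3000)),
        ("spliceosomal_RNA", config.n_spliceosomal, (100, 200)),
        ("other_RNA", config.n_other_rna, (100, 400)),
    ]
    counters: dict[str, int] = {}
    for cat, count, (lo, hi) in simple:
        for _ in range(count):
            counters[cat] = counters.get(cat, 0) + 1
            queue.append(
                (cat, {"gene_id": f"n_{cat}_{counters[cat]:04d}",
                       "size": int(rng.integers(lo, hi + 1))})
            )
    order = rng.permutation(len(queue))
    queue = [queue[i] for i in order]
    per_chrom: dict[str, list[tuple[str, dict]]] = {c: [] for c in chroms}
    for i, item in enumerate(queue):
        per_chrom[chroms[i % len(chroms)]].append(item)

    for chrom in chroms:
        items = per_chrom[chrom]
        spans = _layout_genes(
            chrom_lengths[chrom], [d["size"] for _, d in items], rng
        )
        for (cat, d), (s, e) in zip(items, spans):
            strand = STRAND_FORWARD if rng.random() < 0.5 else STRAND_REVERSE
            if cat == "structural_gene":
                exons = []
                cursor = s
                for j, ex_len in enumerate(d["exon_lens"]):
                    exons.append(GenomicInterval(chrom, cursor, cursor + ex_len))
                    cursor += ex_len
                    if j < len(d["intron_lens"]):
                        cursor += d["intron_lens"][j]
                genes.append(
                    GeneModel(
                        gene_id=d["gene_id"], chrom=chrom, start=s, end=e,
                        strand=strand, exons=exons,
                    )
                )
                features[cat].add(GenomicInterval(chrom, s, e, strand),
                                  gene_id=d["gene_id"])
            else:
                features[cat].add(GenomicInterval(chrom, s, e, strand),
                                  gene_id=d["gene_id"])

    # ---- partition for placement sampling ----
    partition = partition_genome(
        {c: fs.intervals for c, fs in features.items()}, chrom_lengths
    )
    sizes = partition.sizes
    cats = [c for c in partition.categories if sizes[c] > 0]
    weights = np.array(
        [config.placement_weights.get(c, 1.0) * sizes[c] for c in cats], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("no positive placement weight")
    probs = weights / weights.sum()
    cum_by_cat = {
        c: np.cumsum([iv.length for iv in partition.intervals[c]]) for c in cats
    }

    # ---- plant NUPTs ----
    episodes = [("I", config.n_episode_I, config.identity_mean_I, config.identity_sd_I),
                ("II", config.n_episode_II, config.identity_mean_II, config.identity_sd_II)]
    total_planned = sum(n for _, n, _, _ in episodes)
    frag_lo, frag_hi = config.fragment_length_range
    mean_frag = (frag_lo + frag_hi) / 2
    if total_planned * mean_frag >= 0.5 * sum(chrom_lengths.values()):
        raise ValueError("planted NUPT bp would exceed half the nuclear genome")
    lo_id, hi_id = config.identity_bounds
    nupts: list[PlantedNupt] = []
    rows: list[AlignmentRow] = []
    k = 0
    for episode, n, mu, sd in episodes:
        for _ in range(n):
            L = int(rng.integers(frag_lo, frag_hi + 1))
            target = float(np.clip(rng.normal(mu, sd), lo_id, hi_id))
            src = int(rng.integers(0, config.plastid_length - L))
            ci = int(rng.choice(len(cats), p=probs))
            chrom, pos = _sample_position(
                partition.intervals[cats[ci]], cum_by_cat[cats[ci]], rng
            )
            L_real = min(L, chrom_lengths[chrom] - pos)
            if L_real < 30:  # too close to the chromosome end; resample cheaply
                pos = max(0, pos - L)
                L_real = min(L, chrom_lengths[chrom] - pos)
            fragment = plastid.sequence[src : src + L_real]
            mutated, n_sub = mutate_to_identity(fragment, target, rng)
            strand = STRAND_FORWARD if rng.random() < 0.5 else STRAND_REVERSE
            inserted = mutated if strand == STRAND_FORWARD else revcomp(mutated)
            sequences[chrom][pos : pos + L_real] = list(inserted)
            realized = 100.0 * (1.0 - n_sub / L_real)
            nupt_id = f"nupt{k:05d}"
            k += 1
            nupts.append(
                PlantedNupt(
                    nupt_id=nupt_id, chrom=chrom, start=pos, end=pos + L_real,
                    src_start=src, src_end=src + L_real, strand=strand,
                    episode=episode, target_identity=target,
                    realized_identity=realized, n_substitutions=n_sub,
                    target_category=cats[ci],
                )
            )
            if strand == STRAND_FORWARD:
                sstart, send = src + 1, src + L_real
            else:
                sstart, send = src + L_real, src + 1
            rows.append(
                AlignmentRow(
                    qseqid=chrom, sseqid=plastid.chrom,
                    pident=round(realized, 2), length=L_real,
                    mismatch=n_sub, gapopen=0,
                    qstart=pos + 1, qend=pos + L_real,
                    sstart=sstart, send=send,
                    evalue=1e-30, bitscore=round(1.9 * L_real, 1),
                )
            )

    # ---- project plastid genes inside NUPT source spans into the nucleus ----
    derived_counter = 0
    derived_genes: list[tuple[str, str, str]] = []  # (gene_id, category, nupt_id)
    for nupt in nupts:
        for cat, fs in plastid.features.items():
            for iv, attrs in zip(fs.intervals, fs.attributes):
                # project the carried part of the gene (>= 30 bp of overlap)
                lo = max(iv.start, nupt.src_start)
                hi = min(iv.end, nupt.src_end)
                if hi - lo >= 30:
                    if nupt.strand == STRAND_FORWARD:
                        g_start = nupt.start + (lo - nupt.src_start)
                        g_end = nupt.start + (hi - nupt.src_start)
                    else:
                        g_start = nupt.start + (nupt.src_end - hi)
                        g_end = nupt.start + (nupt.src_end - lo)
                    derived_counter += 1
                    gid = f"n_{attrs['gene_id']}_{derived_counter:04d}"
                    features[cat].add(
                        GenomicInterval(nupt.chrom, g_start, g_end, nupt.strand),
                        gene_id=gid,
                        donor_gene=attrs["gene_id"],
                        nupt_id=nupt.nupt_id,
                    )
                    derived_genes.append((gid, cat, nupt.nupt_id))

    # ---- tRNA best-hit rows against the compartment-labeled reference ----
    trna_hits: list[AlignmentRow] = []
    decoy_pool = sorted(plastid.trna_reference)

    def _hit(qid: str, sid: str, bits: float, ev: float) -> AlignmentRow:
        return AlignmentRow(
            qseqid=qid, sseqid=sid, pident=round(float(rng.uniform(80, 100)), 2),
            length=75, mismatch=int(rng.integers(0, 10)), gapopen=0,
            qstart=1, qend=75, sstart=1, send=75, evalue=ev, bitscore=bits,
        )

    for cat in ("tRNA_nuclear", "tRNA_mitochondrial", "tRNA_plastid"):
        fs = features[cat]
        for attrs in fs.attributes:
            qid = attrs["gene_id"]
            donor = attrs.get("donor_gene")
            if donor is not None and f"ref_{donor}" in plastid.trna_reference:
                true_subject = f"ref_{donor}"
            else:
                pool = [s for s, comp in plastid.trna_reference.items()
                        if comp == _TRNA_COMPARTMENT[cat]]
                true_subject = pool[int(rng.integers(0, len(pool)))]
            trna_hits.append(_hit(qid, true_subject, 140.0, 1e-20))
            for _ in range(int(rng.integers(0, 3))):
                decoy = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
                trna_hits.append(
                    _hit(qid, decoy, float(rng.uniform(60, 120)), 1e-5)
                )

    truth = {
        "config": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.name not in ("plastid_gene_counts", "placement_weights")
        },
        "placement_weights": dict(config.placement_weights),
        "nupts": [dataclasses.asdict(n) for n in nupts],
        "episode_counts": {"I": config.n_episode_I, "II": config.n_episode_II},
        "derived_rna_genes": [
            {"gene_id": g, "category": c, "nupt_id": n} for g, c, n in derived_genes
        ],
        "chrom_lengths": chrom_lengths,
    }
    return NuclearBundle(
        sequences={c: "".join(s) for c, s in sequences.items()},
        features=features,
        genes=genes,
        nupts=nupts,
        alignment_rows=rows,
        trna_hits=trna_hits,
        truth=truth,
    )


def generate_expression(
    gene_ids: list[str], config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Genes x tissues TPM matrix with planted specificity classes.

    Three classes: silent (all zeros), uniform (equal tissue means with
    multiplicative noise, Tau near 0), and specific (one dominant tissue,
    Tau near 1). Noise sd is ``noise_sd_frac`` of the mean.
    """
    n_tissues = len(config.tissues)
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    labels: dict[str, str] = {}
    data = np.zeros((len(gene_ids), n_tissues))
    for i, gid in enumerate(gene_ids):
        u = rng.random()
        if u < config.frac_silent:
            labels[gid] = "silent"
        elif u < config.frac_silent + config.frac_uniform:
            labels[gid] = "uniform"
            mean = rng.uniform(5, 50)
            vals = rng.normal(mean, config.noise_sd_frac * mean, size=n_tissues)
            data[i] = np.clip(vals, 0, None)
        else:
            labels[gid] = "specific"
            mean = rng.uniform(10, 80)
            dom = int(rng.integers(0, n_tissues))
            vals = np.abs(rng.normal(0.0, config.noise_sd_frac * mean * 0.1, size=n_tissues))
            vals[dom] = max(rng.normal(mean, config.noise_sd_frac * mean), 1.0)
            data[i] = vals
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"),
                      columns=list(config.tissues)).round(3)
    return df, labels


def generate_terms(
    background_ids: list[str],
    special_set: set[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, str]:
    """Term annotations with one term planted at ``planted_term_factor``
    times its background frequency inside ``special_set``."""
    vocab = [f"TERM:{i:04d}" for i in range(config.n_terms)]
    planted = vocab[0]
    rows = []
    for gid in background_ids:
        p0 = config.base_term_prob
        p_planted = min(p0 * config.planted_term_factor, 0.95) if gid in special_set else p0
        if rng.random() < p_planted:
            rows.append({"gene_id": gid, "term_id": planted, "namespace": "GO"})
        for term in vocab[1:]:
            if rng.random() < p0:
                rows.append({"gene_id": gid, "term_id": term, "namespace": "GO"})
    return pd.DataFrame(rows), planted


def _gff_rows(features: dict[str, FeatureSet], genes: list[GeneModel], source: str):
    rows = []
    for gene in genes:
        rows.append((gene.chrom, source, "gene", gene.span, {"ID": gene.gene_id}))
        mrna_id = f"{gene.gene_id}.t1"
        rows.append(
            (gene.chrom, source, "mRNA",
             GenomicInterval(gene.chrom, gene.start, gene.end, gene.strand),
             {"ID": mrna_id, "Parent": gene.gene_id})
        )
        for j, ex in enumerate(gene.exons, 1):
            rows.append(
                (gene.chrom, source, "exon",
                 GenomicInterval(gene.chrom, ex.start, ex.end, gene.strand),
                 {"ID": f"{mrna_id}.exon{j}", "Parent": mrna_id})
            )
    for cat, fs in features.items():
        if cat == "structural_gene":
            continue
        for iv, attrs in zip(fs.intervals, fs.attributes):
            rows.append((iv.chrom, source, cat, iv, {"ID": attrs["gene_id"]}))
    return rows


def simulate(config: SimConfig, outdir: str | os.PathLike) -> dict[str, Path]:
    """Generate a complete synthetic input bundle under ``outdir``.

    Writes plastid/nuclear FASTA + GFF3, the truth alignment TSV, the
    tRNA hit TSV, the compartment map, the TPM matrix, term annotations
    and the truth ledger. Returns a name -> path mapping. Byte-identical
    for a fixed config (including seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    plastid = generate_plastid(config, rng)
    nuclear = generate_nuclear(plastid, config, rng)

    gene_ids = [g.gene_id for g in nuclear.genes]
    rna_ids = [
        attrs["gene_id"]
        for cat, fs in nuclear.features.items()
        if cat not in ("structural_gene", "TE", "other_repeat")
        for attrs in fs.attributes
    ]
    expr, expr_labels = generate_expression(gene_ids + rna_ids, config, rng)

    # genes overlapped by any NUPT get the planted term enrichment
    nupt_union = merge_intervals(
        [GenomicInterval(n.chrom, n.start, n.end) for n in nuclear.nupts]
    )
    special = set()
    for g in nuclear.genes:
        if any(g.span.overlaps(iv) for iv in nupt_union):
            special.add(g.gene_id)
    terms, planted_term = generate_terms(gene_ids, special, config, rng)

    paths = {
        "plastid_fasta": outdir / "plastid.fasta",
        "plastid_gff3": outdir / "plastid.gff3",
        "nuclear_fasta": outdir / "nuclear.fasta",
        "nuclear_gff3": outdir / "nuclear.gff3",
        "alignment": outdir / "alignments.tsv",
        "trna_hits": outdir / "trna_hits.tsv",
        "compartment_map": outdir / "compartment_map.tsv",
        "expression": outdir / "expression.tsv",
        "terms": outdir / "terms.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(paths["plastid_fasta"], {plastid.chrom: plastid.sequence})
    write_gff3(paths["plastid_gff3"], _gff_rows(plastid.features, [], "sim"))
    write_fasta(paths["nuclear_fasta"], nuclear.sequences)
    write_gff3(paths["nuclear_gff3"], _gff_rows(nuclear.features, nuclear.genes, "sim"))
    write_alignment_tab(paths["alignment"], nuclear.alignment_rows)
    write_alignment_tab(paths["trna_hits"], nuclear.trna_hits)
    write_tsv(
        pd.DataFrame(
            sorted(plastid.trna_reference.items()),
            columns=["subject_id", "compartment"],
        ),
        paths["compartment_map"],
    )
    expr.reset_index().to_csv(paths["expression"], sep="\t", index=False)
    write_tsv(terms, paths["terms"])

    truth = dict(nuclear.truth)
    truth["expression_labels"] = expr_labels
    truth["planted_term"] = planted_term
    truth["nupt_overlapped_genes"] = sorted(special)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
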