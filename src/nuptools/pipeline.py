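"""End-to-end orchestration of the NUPT characterization stages.

``run_all`` wires the stages together on one input bundle: age
classification of NUPTs, overlap enrichment against the genome partition,
structural-gene impact accounting, tRNA origin and donor mapping, and the
expression layer. Each stage is also callable on its own (the CLI exposes
one subcommand per stage). All report files are TSV with header rows; a
manifest records parameters and input checksums so a run is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agemix import LABEL_UNCLASSIFIED, fit_identity_mixture
from .enrichment import DEFAULT_PRIORITY, NuptEnrichment, partition_genome
from .expression import (
    fisher_fraction_test,
    flag_expressed,
    tau_table,
    term_enrichment,
    wilcoxon_rank_test,
)
from .gene_impact import classify_gene_hits, impact_summary, impact_table
from .intervals import GenomicInterval, merge_intervals, windowed_density
from .io import (
    RNA_CATEGORIES,
    nupt_records,
    read_alignment_tab,
    read_fasta,
    read_gff3,
    read_tsv,
    sequence_lengths,
    write_tsv,
)
from .rna_origin import classify_origin, donor_summary, map_donor, trna_census

logger = logging.getLogger("nuptools")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, parameters and output location for one pipeline run."""

    nuclear_fasta: Path
    nuclear_gff3: Path
    plastid_gff3: Path
    alignment: Path
    outdir: Path
    trna_hits: Path | None = None
    compartment_map: Path | None = None
    expression: Path | None = None
    terms: Path | None = None
    posterior_threshold: float = 0.95
    flank_bp: int = 1_000
    window_bp: int = 500_000
    alpha: float = 0.05
    expression_threshold: float = 0.0
    priority: tuple = DEFAULT_PRIORITY
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nuclear_fasta", "nuclear_gff3", "plastid_gff3", "alignment",
                     "trna_hits", "compartment_map", "expression", "terms"):
            value = getattr(self, name)
            if value is None:
                continue
            p = Path(value)
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} input missing: {p}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_classify(config: RunConfig) -> pd.DataFrame:
    """Fit the identity mixture and assign every NUPT an age class."""
    try:
        rows = read_alignment_tab(config.alignment)
        records = nupt_records(rows)
        fit = fit_identity_mixture(
            [r.pident for r in records], k=2, seed=config.seed
        )
        assignments = fit.assign(
            [r.pident for r in records], threshold=config.posterior_threshold
        )
        for rec, a in zip(records, assignments):
            rec.age_class = a.label
        df = pd.DataFrame(
            {
                "nupt_id": [r.nupt_id for r in records],
                "chrom": [r.nuclear.chrom for r in records],
                "start": [r.nuclear.start for r in records],
                "end": [r.nuclear.end for r in records],
                "pident": [r.pident for r in records],
                "gamma_I": [round(a.gamma_I, 6) for a in assignments],
                "gamma_II": [round(a.gamma_II, 6) for a in assignments],
                "label": [a.label for a in assignments],
            }
        )
        config.outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(df, config.outdir / "nupt_classes.tsv")
        fit_df = pd.DataFrame(
            {
                "component": ["I", "II"],
                "mean": np.round(fit.means, 6),
                "sd": np.round(fit.sds, 6),
                "weight": np.round(fit.weights, 6),
                "loglik": [round(fit.loglik, 6)] * 2,
                "n_iter": [fit.n_iter] * 2,
                "converged": [fit.converged] * 2,
            }
        )
        write_tsv(fit_df, config.outdir / "mixture_fit.tsv")
        return df
    except StageError:
        raise
    except Exception as err:
        raise StageError("classify", str(err)) from err


def _load_genome(config: RunConfig):
    lengths = sequence_lengths(read_fasta(config.nuclear_fasta))
    content = read_gff3(config.nuclear_gff3, chrom_lengths=lengths)
    return lengths, content


def _nupt_sets_by_class(classes: pd.DataFrame) -> dict[str, list[GenomicInterval]]:
    sets: dict[str, list[GenomicInterval]] = {"all": []}
    for _, row in classes.iterrows():
        iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        sets["all"].append(iv)
        sets.setdefault(row["label"], []).append(iv)
    return sets


def stage_enrich(config: RunConfig, classes: pd.DataFrame) -> pd.DataFrame:
    """Partition the genome and test per-class NUPT overlap enrichment."""
    try:
        lengths, content = _load_genome(config)
        partition = partition_genome(
            {c: fs.intervals for c, fs in content.features.items()},
            lengths,
            priority_order=config.priority,
        )
        sets = _nupt_sets_by_class(classes)
        results = NuptEnrichment(sets, partition, alpha=config.alpha).fit()
        write_tsv(results.table, config.outdir / "enrichment.tsv")
        dens = []
        for cls, ivs in sorted(sets.items()):
            d = windowed_density(ivs, config.window_bp, lengths)
            d.insert(0, "class", cls)
            dens.append(d)
        write_tsv(pd.concat(dens, ignore_index=True),
                  config.outdir / "windowed_density.tsv")
        return results.table
    except StageError:
        raise
    except Exception as err:
        raise StageError("enrich", str(err)) from err


def stage_impact(config: RunConfig, classes: pd.DataFrame) -> pd.DataFrame:
    """Classify structural-gene NUPT burden by region and age class."""
    try:
        lengths, content = _load_genome(config)
        rows = read_alignment_tab(config.alignment)
        records = nupt_records(rows)
        for rec, (_, row) in zip(records, classes.iterrows()):
            rec.age_class = row["label"]
        impacts = classify_gene_hits(
            records, content.genes, lengths, flank_bp=config.flank_bp
        )
        table = impact_table(impacts)
        write_tsv(table, config.outdir / "gene_impact.tsv")
        summary = impact_summary(impacts)
        srows = [("total_affected_genes", summary["total_affected_genes"]),
                 ("total_gene_nupt_pairs", summary["total_gene_nupt_pairs"])]
        srows += [(f"region_{k}", v) for k, v in summary["region_counts"].items()]
        srows += [(f"class_{k}", v) for k, v in sorted(summary["class_exclusivity"].items())]
        srows += [("fully_covered", summary["fully_covered"]),
                  ("single_exon_all_plastid", summary["single_exon_all_plastid"]),
                  ("max_nupts_per_gene", summary["max_nupts_per_gene"])]
        write_tsv(pd.DataFrame(srows, columns=["metric", "value"]),
                  config.outdir / "gene_impact_summary.tsv")
        return table
    except StageError:
        raise
    except Exception as err:
        raise StageError("impact", str(err)) from err


def stage_origin(config: RunConfig, classes: pd.DataFrame) -> pd.DataFrame:
    """tRNA origin calls, the plastid-origin census, and donor mapping of
    NUPT-resident RNA genes."""
    try:
        if config.trna_hits is None or config.compartment_map is None:
            raise FileNotFoundError("trna_hits and compartment_map inputs required")
        lengths, content = _load_genome(config)
        plastid = read_gff3(config.plastid_gff3)
        hits = read_alignment_tab(config.trna_hits)
        comp_df = read_tsv(config.compartment_map)
        comp_map = dict(zip(comp_df["subject_id"], comp_df["compartment"]))
        calls = classify_origin(hits, comp_map)

        rows = read_alignment_tab(config.alignment)
        records = nupt_records(rows)
        for rec, (_, row) in zip(records, classes.iterrows()):
            rec.age_class = row["label"]
        nupt_union = merge_intervals([r.nuclear for r in records])

        def resident(iv: GenomicInterval) -> bool:
            return any(
                m.chrom == iv.chrom and m.start <= iv.start and iv.end <= m.end
                for m in nupt_union
            )

        trna_cats = ("tRNA_nuclear", "tRNA_mitochondrial", "tRNA_plastid")
        residence = {}
        gene_iv = {}
        gene_cat = {}
        for cat in RNA_CATEGORIES:
            fs = content.features[cat]
            for iv, attrs in zip(fs.intervals, fs.attributes):
                gid = attrs["gene_id"]
                gene_iv[gid] = iv
                gene_cat[gid] = cat
                residence[gid] = resident(iv)

        call_df = pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "compartment": c.compartment,
                    "subject_id": c.subject_id or "",
                    "bitscore": c.bitscore if c.bitscore is not None else "",
                    "evalue": c.evalue if c.evalue is not None else "",
                    "resident_in_nupt": residence.get(c.gene_id, False),
                }
                for c in sorted(calls.values(), key=lambda c: c.gene_id)
            ]
        )
        write_tsv(call_df, config.outdir / "trna_origin.tsv")
        census = trna_census(calls, residence)
        crow = {f"n_{k}": v for k, v in sorted(census.counts.items())}
        crow.update(
            total=census.total,
            plastid_origin_count=census.plastid_origin_count,
            plastid_origin_percentage=census.plastid_origin_percentage,
        )
        write_tsv(pd.DataFrame([crow]), config.outdir / "trna_census.tsv")

        # donor mapping for every NUPT-resident RNA gene
        mappings = []
        for gid, iv in sorted(gene_iv.items()):
            for rec in records:
                if rec.nuclear.chrom == iv.chrom and rec.nuclear.start <= iv.start \
                        and iv.end <= rec.nuclear.end:
                    mappings.append(
                        map_donor(iv, gid, gene_cat[gid], rec, plastid.features)
                    )
                    break
        donor_df = pd.DataFrame(
            [
                {
                    "gene_id": m.gene_id,
                    "category": m.gene_category,
                    "nupt_id": m.nupt_id,
                    "donor_start": m.donor_interval.start,
                    "donor_end": m.donor_interval.end,
                    "donor_genes": ",".join(m.donor_gene_ids),
                    "donor_categories": ",".join(m.donor_categories),
                    "same_category": m.same_category,
                }
                for m in mappings
            ]
        )
        write_tsv(donor_df, config.outdir / "donor_mapping.tsv")
        write_tsv(donor_summary(mappings), config.outdir / "donor_summary.tsv")
        return call_df
    except StageError:
        raise
    except Exception as err:
        raise StageError("origin", str(err)) from err


def stage_express(config: RunConfig, impact: pd.DataFrame) -> pd.DataFrame:
    """Expressed flags, Tau, and the NUPT-vs-background comparisons."""
    try:
        if config.expression is None:
            raise FileNotFoundError("expression (TPM) input required")
        matrix = read_tsv(config.expression).set_index("gene_id")
        expressed = flag_expressed(matrix, threshold=config.expression_threshold)
        taus = tau_table(matrix).set_index("gene_id")
        per_gene = pd.DataFrame(
            {
                "gene_id": matrix.index,
                "expressed": expressed.values,
                "tau": taus["tau"].values,
                "tau_defined": taus["defined"].values,
            }
        )
        write_tsv(per_gene, config.outdir / "expression_per_gene.tsv")

        lengths, content = _load_genome(config)
        structural = [g.gene_id for g in content.genes if g.gene_id in matrix.index]
        nupt_genes = [g for g in impact["gene_id"] if g in matrix.index]
        tests = []
        if structural and nupt_genes:
            bg_expr = int(expressed.loc[structural].sum())
            grp_expr = int(expressed.loc[nupt_genes].sum())
            p = fisher_fraction_test(
                grp_expr, len(nupt_genes), bg_expr, len(structural)
            )
            tests.append(
                {"comparison": "expressed_fraction_nupt_vs_background",
                 "n_group": len(nupt_genes), "n_background": len(structural),
                 "statistic": grp_expr, "p": p}
            )
            non_nupt = [g for g in structural if g not in set(nupt_genes)]
            grp_vals = matrix.loc[[g for g in nupt_genes if expressed.loc[g]]]
            bg_vals = matrix.loc[[g for g in non_nupt if expressed.loc[g]]]
            if len(grp_vals) and len(bg_vals):
                u, p = wilcoxon_rank_test(
                    grp_vals.max(axis=1).to_numpy(), bg_vals.max(axis=1).to_numpy()
                )
                tests.append(
                    {"comparison": "tpm_nupt_vs_background",
                     "n_group": len(grp_vals), "n_background": len(bg_vals),
                     "statistic": u, "p": p}
                )
                gt = taus.loc[grp_vals.index]
                bt = taus.loc[bg_vals.index]
                gt = gt[gt["defined"]]["tau"].to_numpy()
                bt = bt[bt["defined"]]["tau"].to_numpy()
                if gt.size and bt.size:
                    u, p = wilcoxon_rank_test(gt, bt)
                    tests.append(
                        {"comparison": "tau_nupt_vs_background",
                         "n_group": gt.size, "n_background": bt.size,
                         "statistic": u, "p": p}
                    )
        write_tsv(pd.DataFrame(tests), config.outdir / "expression_tests.tsv")

        if config.terms is not None and structural and nupt_genes:
            terms = read_tsv(config.terms)
            enr = term_enrichment(nupt_genes, structural, terms, alpha=config.alpha)
            write_tsv(enr, config.outdir / "term_enrichment.tsv")
        return per_gene
    except StageError:
        raise
    except Exception as err:
        raise StageError("express", str(err)) from err


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage in order and write the manifest.

    Deterministic given inputs and seed; any stage error aborts with a
    :class:`StageError` naming the failing stage.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    logger.info("classify: fitting identity mixture")
    classes = stage_classify(config)
    logger.info("enrich: overlap enrichment scan")
    stage_enrich(config, classes)
    logger.info("impact: structural-gene accounting")
    impact = stage_impact(config, classes)
    if config.trna_hits is not None and config.compartment_map is not None:
        logger.info("origin: tRNA origin and donor mapping")
        stage_origin(config, classes)
    if config.expression is not None:
        logger.info("express: expression statistics")
        stage_express(config, impact)

    inputs = {}
    for name in ("nuclear_fasta", "nuclear_gff3", "plastid_gff3", "alignment",
                 "trna_hits", "compartment_map", "expression", "terms"):
        p = getattr(config, name)
        if p is not None:
            inputs[name] = {"path": str(p), "sha256": _sha256(p)}
    manifest = {
        "nuptools_version": __version__,
        "parameters": {
            "posterior_threshold": config.posterior_threshold,
            "flank_bp": config.flank_bp,
            "window_bp": config.window_bp,
            "alpha": config.alpha,
            "expression_threshold": config.expression_threshold,
            "priority": list(config.priority),
            "seed": config.seed,
        },
        "inputs": inputs,
    }
    manifest_path = config.outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    reports = {p.name: p for p in sorted(config.outdir.glob("*.tsv"))}
    reports["manifest.json"] = manifest_path
    return reports
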