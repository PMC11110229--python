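# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `nuptools`, in the order a run executes them.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open `[start, end)`. GFF3 is
converted from 1-based closed on read and back on write; the 12-column
tabular alignment dialect is 1-based inclusive, and a subject span given in
descending order (a reverse-strand hit) is normalized to a forward interval
with a recorded `-` strand flag, so interval arithmetic always sees
`start < end`. Touching half-open intervals merge into one run: base-pair
accounting treats `(0,5)` and `(5,10)` as 10 contiguous bases. Overlap
counting ignores strand, and percent identity is always taken from the
alignment row as given, never recomputed from sequence — the analysis
consumes a precomputed alignment file, and re-deriving identity would
silently change the statistic being classified.

Each alignment row is treated as one NUPT. Whether overlapping rows should
be merged into single insertions is genuinely ambiguous in practice;
`merge_intervals` is exposed so a caller can collapse them, but no merging
happens implicitly, because per-row identities are what the age classifier
needs. Within each age class, NUPT intervals *are* merged before bp
counting so nested alignments cannot double-count bases.

## Age-class mixture

`IdentityMixture` fits a k-component (default 2) univariate Gaussian
mixture to percent identities by EM.

* Initialization is deterministic: component means at the evenly spaced
  inner quantiles of the data (25th/75th percentile for k = 2), equal
  weights, pooled standard deviation. With two well-separated identity
  regimes this starts each component on its own side of the valley and
  makes the fit a pure function of the data; a `seed` argument is accepted
  and recorded for provenance only.
* Convergence: relative log-likelihood change below 1e-8, at most 1000
  iterations; the per-iteration log-likelihood trace is kept on the results
  object so monotonicity is testable.
* A standard-deviation floor of 1e-3 identity units prevents a component
  collapsing onto a repeated value (EM degeneracy guard). Constant data and
  n < 10 are rejected outright.
* Components are reported sorted by ascending mean. The lower-mean
  component is labeled episode I and the higher-mean episode II, because
  sequence identity to the donor decays with insertion age — the older
  wave is the more diverged one. Assignment requires the posterior of the
  winning component to reach the threshold (default 0.95); everything else
  is "unclassified". At a threshold of exactly 1.0 no finite point with
  two positive densities can be assigned, which is the intended reading of
  a strict bound.

## Genome partition and overlap enrichment

`partition_genome` assigns every base to exactly one category. Overlaps
between categories are resolved by a priority order whose default follows
the category taxonomy's listing (structural gene first, then TEs, repeats,
the RNA-gene classes); uncovered bases form the residual `other_DNA`. The
partition is what makes the bookkeeping identities hold exactly:
Σ_f S_f = G, and both observed and expected overlap sum to the NUPT track
size T.

Expected overlap is bp-proportional, E_f = T·S_f/G: a category twice as
large is expected to absorb twice the NUPT bases by chance. Each category
is tested with a two-cell chi-squared statistic (inside the category,
O vs E; outside, T−O vs T−E) with Yates' continuity correction clamped at
zero, df = 1, so a deviation below half a base gives a statistic of
exactly 0. Calls are `enriched`/`depleted` at p < α (default 0.05), else
`ns`; empty categories get NaN statistics and `ns`.

Two caveats are deliberate. First, the test treats bases as independent
draws, which is exact for 1-bp fragments but optimistic for long fragments
whose bases are autocorrelated; the calibration suite therefore asserts
the false-positive rate only under uniform 1-bp placement, where it sits
near the nominal 3–5%. Second, a separate non-exclusive `overlap_table`
reports overlaps against the raw, unpartitioned feature sets — a base
inside two annotations counts toward both — for multi-membership
accounting; no test is attached in that mode because the margins no longer
tile.

## Gene impact

Structural genes are decomposed into merged exons, derived introns (gene
span minus exons, never stored independently), and strand-aware flanks of
1,000 bp by default: the promoter upstream of the translation start and
the terminator downstream of the stop. When the annotation carries CDS
rows the flanks anchor at the CDS ends; otherwise the gene ends stand in.
Flanks are truncated at chromosome edges and flagged (possibly empty).
Unstranded genes are rejected — the decomposition is direction-dependent.

A gene is "affected" on any ≥ 1 bp overlap between a NUPT and any region;
a NUPT spanning a boundary contributes to both regions, so region tallies
may exceed the distinct-gene total, which is reported separately. The
age-class exclusivity partition (I-only / II-only / unclassified-only /
mixed) always sums to the distinct-gene total. "Fully covered" means every
base of the gene span lies inside the NUPT union; a fully covered
single-exon gene is additionally flagged as candidate all-plastid.

## RNA-gene origin and donor mapping

Origin calls use a best-hit rule over alignment rows against a reference
tRNA set whose subjects carry compartment labels: hits must pass the
E-value cutoff (default 1e-2), the maximal bit score wins, and ties break
by smaller E-value then lexicographically smallest subject id, making the
call invariant to row order. A query with no passing hit is unclassified.

Donor mapping transfers the overlapped part of a nuclear RNA gene into
plastid coordinates linearly through the NUPT's query↔subject spans,
mirrored on reverse-strand alignments, and proportionally when the two
spans differ in length — tabular alignments carry no gap structure, so a
proportional map is the only information-preserving choice. On
substitution-only (equal-length) alignments the transfer is exact and
round-trips. The plastid-origin percentage of the tRNA census is assembled
from three terms: plastid-compartment genes, plus mitochondrial- and
nuclear-compartment genes that reside inside a NUPT — residence meaning
the gene span lies within the merged NUPT track.

## Expression layer

"Expressed" defaults to TPM > 0 in at least one tissue; the threshold is a
parameter since no universal cutoff exists, and the flag is monotone in it.
Tau is computed on raw TPM (it is scale-invariant, so within-gene
normalization is immaterial, and log transforms are left to display);
genes with zero maximum expression have no defined Tau and are excluded
from Tau comparisons. Fisher tests contrast a group against the background
minus the group, two-sided. The Wilcoxon rank-sum test is exact by full
enumeration of group relabelings of the pooled midranks for combined
sample sizes up to 12 (exact even under ties) and switches to the normal
approximation with tie correction and 0.5 continuity correction above
that. Term enrichment runs a two-sided Fisher test per term annotating the
background, with Bonferroni correction over the number of terms tested and
significance at adjusted p < 0.05. The log2(x+1) transform appears only in
report output, never in a statistic.

## Synthetic data

The generator's defaults are the study conditions every property check
runs under:

* Plastid donor: 150 kb, with 30 plastid-type tRNA genes, a few tRNAs
  labeled mitochondrial/nuclear, 4 prokaryotic and 2 eukaryotic rRNA
  genes, 12 self-splicing introns, and 1 regulatory RNA, laid out
  non-overlapping with Dirichlet-distributed gaps.
* Nuclear genome: 3 × 500 kb chromosomes; 150 structural genes with 1–8
  exons, 350 TEs, 80 other repeats, and background RNA genes.
* NUPTs: 200 episode-I insertions at identity ~ Normal(82, 3²) and 800
  episode-II at Normal(97, 1.5²), truncated to [60, 100] — an old/young
  separation convention, not a measured value; fragment lengths uniform
  100–1200 bp. Mutation is substitution-only at per-base probability
  1 − target/100, so realized identity concentrates binomially around the
  target and query/subject spans stay equal length (which keeps donor
  mapping exact). Insertions overwrite bases at positions sampled in
  proportion to per-category placement weights over the partition —
  default 0.2 on structural genes and 5 on the plastid-type RNA-gene
  categories — and never shift annotated coordinates, so truth coordinates
  stay valid without re-annotation.
* Plastid genes overlapping an insertion's source span by ≥ 30 bp are
  projected into the nucleus as NUPT-derived RNA genes; each nuclear tRNA
  gene gets a truth-consistent best-hit row (plus decoys) against the
  compartment-labeled reference.
* Expression: five tissues; 20% silent, 50% uniform, 30% single-tissue
  specific genes, noise sd 10% of the mean. Term annotation plants one
  term at 5× its 5% background frequency among NUPT-overlapped genes.

Everything is a deterministic function of the seed, down to file bytes.
Replicated checks (mixture recovery over 20 seeds, enrichment power over
20 genomes, the 200-replicate null calibration) run on a scaled-down
configuration — 2 × 200 kb chromosomes, 60 + 240 insertions — chosen so
the whole suite stays quick while the planted effects remain far above the
detection floor.

What the generator does **not** emulate: indels and rearrangements inside
insertions (so proportional donor mapping is exact here but approximate on
real alignments), insertion hotspots/clustering, TE superfamily structure,
GC/compositional bias, read-level expression noise, and alignment-detection
artifacts (the pipeline consumes the truth alignment directly). Passing
tests therefore validate the statistics and bookkeeping, not the upstream
alignment or annotation tools.

## Pipeline

`run_all` executes classify → enrich → impact → origin → express on one
input bundle, each stage also exposed as a CLI subcommand; any stage error
aborts with the failing stage named and exit status 1. Reports are TSV
with documented headers; the manifest records package version, parameters,
and sha256 checksums of all inputs, and contains no timestamps, so two
runs on identical inputs are byte-identical. Defaults: posterior threshold
0.95, flank 1,000 bp, density window 500,000 bp, α = 0.05, expression
threshold 0.

## Known limitations

* The chi-squared enrichment p-values on multi-bp fragments inherit the
  base-independence assumption; treat them as a ranking, and rely on the
  1-bp calibration for nominal error control.
* Donor mapping through length-mismatched alignments rounds to integer
  coordinates; sub-bp ambiguity is resolved toward the nearest base and a
  minimum 1 bp donor interval.
* The origin census depends entirely on the supplied reference compartment
  labels; no covariance-model or isotype evidence is consulted.
* GFF3 parsing expects a gene/mRNA/exon hierarchy for structural genes and
  taxonomy-named types (or a `category` attribute) for RNA/TE features;
  exotic dialects need pre-normalization.
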