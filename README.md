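# nuptools

Characterization of **nuclear plastid DNA sequences (NUPTs)** — stretches of
chloroplast genome copied into and fixed in a plant nuclear genome. Some
plant genomes (the orphan crop moringa being an extreme case) carry massive
loads of plastid DNA inserted in two waves, and the analytical questions are
always the same: how old is each insertion, where in the genome do
insertions survive, which genes do they hit and in which region, which
nuclear RNA genes are actually plastid-derived, and what happens to the
expression of the affected genes. `nuptools` implements that analysis as a
tested, reusable library plus CLI, together with a synthetic-genome
generator that plants every signal with known ground truth.

The package is aimed at comparative/plant genomicists who already have the
standard inputs: nuclear and plastid FASTA + GFF3, a 12-column tabular
nuclear-vs-plastid alignment file defining the NUPTs, a TPM expression
matrix over tissues, and gene→term annotation tables.

## The statistics at the core

**Age classes.** Percent identity of a NUPT to its plastid donor decays
with insertion age. A two-component Gaussian mixture

&nbsp;&nbsp;&nbsp;&nbsp;*f(x) = π₁ 𝒩(x; μ₁, σ₁²) + π₂ 𝒩(x; μ₂, σ₂²)*

is fitted to the identity values by EM (deterministic quantile
initialization, variance floor). The lower-mean component is episode I
(older), the higher-mean component episode II (younger); a NUPT is assigned
to an episode only when its posterior responsibility γ ≥ 0.95, else it is
*unclassified*.

**Overlap enrichment.** The genome is partitioned so every base belongs to
exactly one feature category (structural gene, TE, repeats, nine RNA-gene
classes, residual "other DNA"). Under the bp-proportional null, a NUPT
track of *T* total bases is expected to overlap category *f* by
*E_f = T·S_f/G*, where *S_f* is the category's partition size and *G* the
genome size. Each category is tested with a two-cell Pearson chi-squared
test with Yates' continuity correction (df = 1), and reported as
log₁₀(O/E) with an enriched/depleted/ns call.

**Gene impact.** Each structural gene is decomposed into a 1 kb promoter,
exons, derived introns, and a 1 kb terminator (strand-aware); genes are
tallied by region hit, by age-class exclusivity (I-only / II-only /
unclassified-only / mixed), and by full plastid coverage.

**RNA-gene origin.** tRNA genes are assigned a nuclear / mitochondrial /
plastid origin by the best hit (bit score, E ≤ 10⁻²) against a
compartment-labeled reference set, and every NUPT-resident RNA gene is
projected back through its alignment onto the plastid annotation to find
its donor gene.

**Expression.** Expressed flags, the Tau tissue-specificity index
τ = Σᵢ(1 − xᵢ/max x)/(N−1) ∈ [0, 1], Fisher exact tests on expressed
fractions, exact/asymptotic Wilcoxon rank tests on TPM and Tau, and
Bonferroni-corrected Fisher term enrichment.

## Worked example

Generate a synthetic dataset (two planted insertion episodes at identity
means 82 and 97, placement biased 5× into the plastid-type RNA-gene
categories and 0.2× into structural genes), then run the whole analysis:

```bash
nuptools simulate --seed 3 --out sim/
nuptools run-all \
    --nuclear-fasta sim/nuclear.fasta --nuclear-gff3 sim/nuclear.gff3 \
    --plastid-gff3 sim/plastid.gff3 --alignment sim/alignments.tsv \
    --trna-hits sim/trna_hits.tsv --compartment-map sim/compartment_map.tsv \
    --expression sim/expression.tsv --terms sim/terms.tsv --out run/
```

`run/mixture_fit.tsv` — the fitted age-class mixture recovers the planted
episodes:

```
component  mean       sd        weight    loglik        n_iter  converged
I          81.886712  3.291458  0.201179  -2563.982749  15      True
II         97.079177  1.662129  0.798821  -2563.982749  15      True
```

`run/enrichment.tsv` — observed vs expected bp overlap per category
(excerpt): the structural-gene partition is strongly depleted and the
plastid-type RNA-gene categories enriched, exactly as planted:

```
class  category              observed_bp  expected_bp    log10_ratio  direction
all    structural_gene       39946        117539.678208  -0.468711    depleted
all    tRNA_plastid          5209         1806.387438     0.459943    enriched
all    self_splicing_intron  8787         3047.173434     0.459943    enriched
```

`run/trna_census.tsv` — of the 227 tRNA genes annotated in this synthetic
nuclear genome, 142 have a plastid best hit and the plastid-origin
decomposition (plastid-compartment genes plus NUPT-resident mitochondrial-
and nuclear-compartment genes) reaches 84.14%.

The same results are available programmatically:

```python
from nuptools import IdentityMixture
fit = IdentityMixture(identities).fit()      # identities: array in [0, 100]
print(fit.summary())
labels = fit.assign(identities, threshold=0.95)
```

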