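# Methods

## The analysis model

The pipeline targets a two-color CpG-island tiling array read out against a
MeDIP (anti-5-methylcytosine immunoprecipitation) protocol, paired with a
one-color expression array, in a fully pooled design: all offspring of one
group and sex contribute to a single hybridized sample, so there is exactly
one intensity per probe, group and sex, and no replicate variance exists
anywhere in the data. Every statistic downstream of the scanner is therefore
a ratio, a threshold rule, or a set operation — not a variance-based test.
The only inferential statistic in the workflow is the hypergeometric
over-representation test applied to gene *sets*, where the randomness is the
sampling of genes, not of arrays.

Probe-level relative methylation in one group is the IP channel over the
input channel, `Cy5/Cy3`; this cancels probe-specific hybridization
efficiency and DNA input. The exposure effect at a probe is the ratio of
relative methylation between exposed and sham groups, so probe affinity and
per-gene baseline methylation cancel as well — what remains is the
multiplicative change in methylation plus noise. The same logic applies to
the one-color expression array with a single intensity per group.

### Thresholds

| parameter | default | meaning |
|---|---|---|
| `up_threshold` | 1.5 | fold at or above which a probe/gene is flagged increased/up |
| `down_threshold` | 0.67 | fold at or below which it is flagged decreased/down |
| `p_cutoff` | 0.05 | detection p-value bound (strict `<`) for keeping a probe |
| `min_ef` | 2.0 | enrichment-factor floor for extracting a category |
| `min_nf` | 5 | minimum flagged genes in a category |
| `max_p` | 0.05 | hypergeometric p bound (strict `<`) for extraction |

Both fold thresholds are inclusive (`>=`/`<=`). Note that 0.67 is the
conventional printed value, not exactly 1/1.5 ≈ 0.6667; the package keeps
0.67 as the default and leaves both ends configurable. The channel-swap
antisymmetry property (swapping groups maps fold to 1/fold and exchanges
the flags) holds exactly only with reciprocal thresholds (1.5, 1/1.5), and
the property tests use that pair.

### Gene-level aggregation

Probes map many-to-one onto genes through GenBank accessions. A gene is
flagged in a direction when **any** of its surviving probes is flagged that
way; a gene with probes flagged in both directions receives the call
`both` and contributes to both per-direction tallies. This any-probe rule is
the only aggregation consistent with genome-scale probe and gene counts of
this array family (an order of magnitude more flagged probes than flagged
genes), and no per-gene summary statistic is assumed. The per-gene
`extreme_fold` reported alongside the call is the fold ratio of the probe
with maximal |log fold|; the expression collapse uses the same max-|log|
representative rule, since published per-gene folds come without a stated
collapse rule and the most extreme probe is the only choice that preserves
the flag that triggered the gene.

### Integration classes

Gene-level methylation and expression calls are outer-joined on accession.
Each gene gets exactly one class; the coupled classes require coupling in
the repressive direction (`up_demethylated`: regulation up and methylation
call in {decreased, both}; `down_methylated`: regulation down and call in
{increased, both}). Genes flagged on one layer only — including genes with
no probes at all on the other array — fall into the single-layer classes.
Two rare conflict cases are resolved deterministically: an expression gene
flagged `both` acts in the direction of its max-|log| fold, and a
methylation-only gene called `both` is classed by the sign of its extreme
fold. Cross-sex overlaps compare gene symbols (the reporting identifier);
within-sex joins always use accessions.

### Over-representation

For flagged set margins (nf, n, Nf, N) the enrichment factor
`EF = (nf/n)/(Nf/N)` is evaluated in exact rational arithmetic, and the
p-value is the one-sided upper hypergeometric tail `P(X >= nf)` with
`X ~ Hypergeom(N, Nf, n)` (computed via `scipy.stats.hypergeom.sf(nf-1, ...)`;
an independent enumeration oracle verifies it exhaustively for all margins
with N ≤ 12 in the tests). Only enrichment is tested — the extraction filter
requires EF ≥ 2, which excludes the depletion tail by construction. The
default background N is the set of array genes carrying at least one
annotation in the tested vocabulary, because unannotated genes cannot
contribute to any category; `universe="array"` switches to all array genes.
Annotations are used as given, with no GO-graph or MeSH-tree propagation.
Raw p-values gate extraction; a Benjamini–Hochberg column (`p_bh`) is
emitted for reference and participates in `passes` only when requested,
since the extraction rule this pipeline reproduces uses raw p < 0.05.

## The synthetic-data generator

`synthgen` emulates the statistical structure the analysis assumes, at desk
scale: the default universe is 1,000 genes with 1–6 methylation probes per
island (~3,500 probes) and 1–2 expression probes per gene — a scaled-down
stand-in for a 15,342-island / ~88,000-probe CpG-island array and a ~60K
expression array. Genes cycle through all 21 mouse chromosome labels so
per-chromosome tallies are populated.

Signal model, per probe and group: the input channel is log-normal with
location `baseline_mu` (default log 1000 fluorescence units) and log-scale
`log_sigma_signal`; the IP channel is the input times a per-gene baseline
methylation level, times the planted effect in the exposed group, times an
independent log-normal factor. Baseline methylation is log-uniform on
[0.2, 5] so both gains and losses of methylation stay observable above the
background level (default 100 units). The expression array draws one shared
baseline per probe and multiplies in the planted effect and per-group noise.
Consequences used heavily by the tests: at `log_sigma_signal = 0` every
probe's fold ratio equals its gene's planted effect exactly, and the
probe-level log fold ratio has standard deviation `sqrt(2) * log_sigma_signal`
in the noisy case. Detection p-values land below 0.05 except with
probability `p_detect_fail` (default 0.02); above-background flags require
both channels of a group to exceed the background level.

Planted effects assign each gene, independently per sex, to one of five
classes — coupled-up (methylation 1/fold, expression fold), coupled-down
(the reverse), meth-only, expr-only, null — with default fractions
0.10 / 0.05 / 0.05 and effect fold 2.0. Each planted-enriched annotation
category owns a disjoint core of 12 genes that enter the coupled classes
with probability 0.9 in each sex; the annotation builder then forms an
enriched category as its core topped up with uniform draws, while null
categories are uniform samples of 10–40 genes. The core construction is
what makes planted categories recoverable in each sex separately even
though class assignment is otherwise sex-independent. Default scale: 50
categories, 5 enriched. With ~100 coupled genes flagged out of 1,000, an
enriched category contributes nf ≈ 10 of Nf ≤ 40, giving EF ≳ 2.5 and
p ≪ 0.05, while a null category passes all three filters only by chance
(≈ the raw 5% level, further reduced by the EF and nf conditions).

What the generator does **not** model: dye bias, spatial artifacts,
probe-sequence effects, litter/dam hierarchy, and any sequence-level
chemistry. Passing recovery tests therefore show the pipeline's logic is
correct under a clean multiplicative-noise model; they do not certify
performance on arrays with structured artifacts, which the upstream
normalization (outside this package's scope) is assumed to have removed.

## Numerical choices and degenerate inputs

- Intensities are floored at 1.0 fluorescence unit before any ratio, so
  background-subtracted near-zero signals cannot produce unbounded folds;
  the floor is configurable per call.
- Locus strings are 1-based inclusive `chrN:start-end`; the parser accepts
  both the typographic en-dash and the ASCII hyphen, the writer always emits
  the hyphen. CpG islands are treated as unstranded.
- All writers sort rows (probe id / gene / category id), and enrichment ties
  are broken by EF desc, p asc, then category id, so outputs are diffable.
- Empty filtered tables, genes absent from one array, categories with no
  annotated array gene, and n = 0 flagged genes are all defined cases (the
  last reports EF = NaN, p = 1 rather than failing).
- One pipeline seed fans out to stage seeds by fixed offsets (+0 universe,
  +1 effects, +2/+3 methylation arrays, +4/+5 expression arrays,
  +6 annotations), making whole runs reproducible from one integer.

## Problem sizes

The test suite and the acceptance script run the recovery analyses at 1,000
genes (≈3,500 methylation probes) and the structural property suites at
60–300 genes; the complete hypergeometric oracle sweep covers all 3,184
margin combinations with N ≤ 12 plus 10,000 random enrichment-factor
quadruples. These sizes exercise every code path at full fidelity; the
generator scales linearly if larger universes are wanted.

## Known limitations

- Fold-change-only flagging inherits the pooled design's inability to
  separate biological effect from pooling artifact; the package
  deliberately adds no mock variance.
- The detection p-value is treated as a per-probe detection statistic
  supplied in the input table; arrays whose "p-value" column is a
  differential statistic need reinterpretation upstream.
- The gene–MeSH correspondence format is this package's own three-column
  TSV dialect (GeneID, MeSH_ID, MeSH_term); the historical upstream resource
  is discontinued and its exact layout undocumented.
- Published enrichment tables print EF and p but not the underlying margins,
  so those p-values can be checked for filter consistency, not recomputed.
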