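# Methods

`methdiv` reimplements, as a tested pipeline over synthetic data, the core
computational chain of a whole-genome bisulphite methylome comparison
between two plant cultivars: per-cytosine methylation calling, binned
differential-methylation-region (DMR) detection, DMR–gene/TE association,
and integration with gene expression and small-RNA (smRNA) abundance.

## Methylation calling

Bisulphite treatment converts unmethylated cytosines to uracil (sequenced
as T); methylated cytosines resist conversion. At a cytosine covered by
`x = m + u` reads (`m` methylated calls, `u` unmethylated), the null
hypothesis "this site is unmethylated" predicts `m ~ Binomial(x, e)`, where
`e` is the non-conversion (error) rate. The caller reports the inclusive
upper tail `P(X >= m)` and calls a methylcytosine (mC) when `P <= 0.001`
and `x >= 5` (both thresholds inclusive; the tail is inclusive so that
`m = 0` gives `P = 1` and can never be called).

`e` is estimated as the read-weighted pooled ratio `sum(m) / sum(m + u)`
over a designated control contig that is biologically unmethylated (the
chloroplast in real plant data; a labelled `control` contig in the
synthetic cohort). Pooling reads rather than averaging per-site ratios is
robust at low per-site depth. The generator's default non-conversion rate
is 0.05%, a typical value for a well-converted plant library.

Sequence contexts follow the plant convention, read 5'→3' on the strand
carrying the cytosine: CG (next base G), CHG (base after next G), CHH
(neither; H = A, C or T). Cytosines within two bases of a chromosome end
are classified on the available bases (CHH when undecidable). CG sites on
opposite strands are kept separate (strand-resolved reporting); no
symmetric-CG pooling is performed.

The methylome summary reports, over called mCs: the context composition,
the mean per-site level (level = 100·m/x) per context, per-strand counts,
and the mC frequency with covered cytosines (depth >= 5) as denominator
(an `all cytosines` denominator is available via a flag — the choice of
denominator is not canonical in the field).

## DMR detection

The genome is tiled into non-overlapping 100-bp bins. Within a bin, only
cytosines covered by at least 5 reads **in both samples** contribute. Read
counts are pooled per sample (`level = 100·Σm/Σ(m+u)`), and the two
samples are compared by a two-sided Fisher exact test on
`[[m_A, u_A], [m_B, u_B]]`. P-values are corrected genome-wide in one
batch; Benjamini–Hochberg is the default, with a simplified SLIM-style
option that scales BH q-values by a Pounds–Cheng π₀ estimate (the
published sliding-linear-model procedure is under-determined from its
description, so this mode documents itself as a pragmatic variant).

A bin is a DMR when all three filters pass (inclusive): at least 3 mCs
(sites called mC in either sample — the union reading; a per-sample mode is
available), an absolute pooled-level difference of at least 20 percentage
points, and q <= 0.01. `diff = level_A − level_B`; positive diff = `hyper`
(test sample A more methylated than reference B). Using pooled counts for
both the Fisher table and the level difference keeps the test and the
filter internally consistent; a mean-of-site-levels mode exists for
comparison. Adjacent significant bins are reported as separate DMRs (no
merging), and q-values are computed over all tested bins, never
post-filter.

DMRs are associated with genes and TEs by the bin midpoint: `genic` when
the midpoint falls in the feature body, otherwise `flank_upstream` /
`flank_downstream` when within 2 kb of the strand-appropriate end
(genomic left/right for unstranded features, with a warning). A DMR may
associate with several features; each (DMR, feature) pair is one row.

## Expression and smRNA integration

A deliberately simple differential-expression filter replaces a full
RNA-seq DE pipeline (out of scope here): log2 fold change from replicate
means of log2(abundance + 0.01), a two-sided two-sample t-test on log2
abundances, and DEG status at >= 2-fold with P <= 0.05. Precomputed DE
tables can be supplied instead.

Genes are classed `hyper`/`hypo` by their associated DMRs (a gene touched
by both directions takes the direction of its largest-|diff| DMR; exact
ties are excluded). The coupling analyses are:

* log2fc distributions of each class against all (expressed) genes, with a
  two-tailed Wilcoxon rank-sum test — exact when the combined sample is
  <= 20 and tie-free, else a continuity-corrected normal approximation;
* directional enrichment (hyper-associated × downregulated, and
  hypo × up) as 2×2 Fisher tests with cross-product odds ratios, computed
  separately for genic and flanking placements;
* on/off classification: `on` at mean abundance >= 1.0, `off` below 0.1,
  with the dead zone [0.1, 1.0) excluded. The thresholds are this
  package's own operational definition (no canonical value exists) and
  are exposed as parameters;
* TE density per gene class: TEs overlapping the gene ± 2 kb, class means
  compared by a two-sided label-permutation test (10,000 shuffles, seeded).

smRNA loci (21–24 nt intervals with read abundance) are related to
methylation by (a) the fraction of mCs inside loci per context and the
fraction of loci containing >= 1 mC, and (b) density enrichment: smRNA
loci per kb of hyper-/hypo-class gene territory divided by loci per kb of
all-gene territory, with a Fisher test of locus counts against territory
sizes discretised to kb. The territory normalisation makes the identity
check exact: class = all genes gives fold 1.0.

## Profiles and density tracks

Metagene/meta-TE profiles aggregate item positions (mC calls by base,
smRNA loci by midpoint) over 1-kb flanks in 50-bp bins plus a
length-normalised body of 40 equal relative segments; minus-strand
features are mirrored so bin 0 is always 5'-most. Fraction-mode profiles
normalise each track to sum to 1 (per context by default); features
shorter than the body bin count are skipped and counted. Chromosome
density tracks count items per fixed window (100 kb default, last window
truncated) and are compared by Spearman rank correlation.

## The synthetic cohort

The generator emulates the statistical structure of a two-cultivar
methylome study at desk scale; its defaults are the package's fixed study
conditions:

* **Genome**: one 1-Mb chromosome (43% GC, random sequence) plus a 20-kb
  fully unmethylated control contig. 150 genes (0.8–2.2 kb) sit on the
  chromosome arms (outer 30% each side); 150 TEs (0.5–2 kb) are placed
  mostly (80%) in the central 40% "pericentromere", the rest interleaved
  with arm genes. This gene/TE anticorrelation is what makes mC density
  correlate positively with TE density and negatively with gene density,
  as in real plant chromosomes.
* **Methylome**: a methylated cytosine carries the context-typical level
  (CG 87.5%, CHG 67.5%, CHH 42% — midpoints of the ranges typical for
  rice); the per-context probability that a site is methylated at all
  (CG 0.18, CHG 0.14, CHH 0.029) was chosen once so that, with the 2.5×
  TE elevation below, the cohort reproduces field-typical mC context
  fractions (~44/27/29%) and an overall mC frequency of ~12% of covered
  cytosines. Inside TEs the methylated-site fraction is multiplied by 2.5
  (capped at 1), so TEs are hypermethylated in every context.
* **Planted DMRs**: 200 single-bin (100 bp) regions, half hyper / half
  hypo in A vs B, drawn 37.5% from gene bodies, 25% from TE bodies and
  the rest from intergenic space kept >= 2 kb from genes so the truth
  categories stay unambiguous. Every site in a planted region receives a
  context-anchored level pair (context level ∓ delta/2, shifted into
  [0,100] at fixed width delta = 40), high member to the hyper sample.
  Two properties follow: each region's realised mean A−B difference
  equals the planted delta exactly, and — because hyper and hypo regions
  are equinumerous — the per-context mean levels of either methylome stay
  unbiased, so level recovery and DMR recovery can be tested on the same
  cohort. A config flag (`offset_dmrs`) shifts regions by 50 nt to
  exercise bin-straddling effects.
* **Counts**: depth ~ Poisson(30); methylated reads ~ Binomial(depth,
  p_eff) with p_eff = level/100 + (1 − level/100)·0.0005 — the exact
  generative inverse of the caller, so a truly unmethylated site realises
  the caller's null exactly.
* **Expression**: per-gene baseline log2 abundance ~ Normal(5, 2) shared
  between samples; genes whose body/2-kb flank contains a planted hyper
  (hypo) DMR midpoint have sample-A log2 abundance shifted by −2 (+2);
  genes touched by both directions are left unshifted. Three replicates
  per sample with lognormal noise (log2 SD 0.25). Abundances are
  FPKM-like positive reals; no read-level RNA-seq simulation.
* **smRNA**: loci of 21–24 nt at 4 per kb (chosen to give stable density
  estimates at the 1-Mb scale), multiplied by 1.7 inside hyper-DMR genes
  and divided by 1.7 in hypo-DMR genes (sample A; sample B is uniform);
  per-locus abundance is geometric (>= 1).

All randomness flows from a single seed through spawned child generators,
so a config + seed pair yields byte-identical output files.

### What the generator does and does not emulate

It reproduces the *statistical couplings* the downstream analyses assume:
context-specific levels, TE hypermethylation, pericentromeric TE/mC
enrichment, planted between-sample DMRs, negative gene-body-methylation →
expression coupling, and smRNA excess at hypermethylated genes. It does
not emulate biological sequence realism (motifs, isochores), read-level
artefacts (M-bias, clonal reads — upstream of this pipeline's inputs),
spatial autocorrelation of methylation beyond the feature structure, or
replicate-level methylation variance (one pooled methylome per cultivar,
matching the pooled-library design of the kind of study emulated).
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted signal under realistic sampling noise — not
performance on real libraries.

## Numerical and design notes

* Internal coordinates are 1-based inclusive everywhere (CX/GFF3
  convention); BED's 0-based half-open coordinates are converted only at
  I/O boundaries.
* Binomial tails use the survival function (`sf(m−1)`); Fisher tests and
  rank-sum tests are exact-oracle-checked by enumeration at small sizes
  (all binomial instances with depth <= 12, all 2×2 tables with total
  <= 15, rank-sum samples with combined n <= 12) to a relative tolerance
  of 1e-12.
* Degenerate inputs: a zero-depth sample in a bin gives Fisher P = 1 with
  a warning; an empty feature class is reported absent rather than zero; a
  single-replicate DE comparison falls back to fold change with a warning.
* Zero-depth sites have undefined (NaN) level but still receive a call row
  (`is_mc = False`).
* The Wilcoxon "class vs all genes" comparison includes the class in the
  baseline, mirroring the boxplot-plus-rank-sum convention of the analyses
  this package emulates; this is slightly conservative.
* Problem sizes in tests and in `scripts/acceptance.py` (1-Mb cohort,
  100-replicate null calibrations, enumeration oracles at n <= 15) were
  chosen so the whole validation runs in minutes on one CPU.

## Known limitations

* The SLIM correction mode is a simplified π₀-scaled BH, not the published
  procedure.
* smRNA fold recovery is measured against the planted gene classes; with
  half the genes DMR-coupled, the all-gene baseline itself absorbs part of
  the planted enrichment, so the recovered fold is expected a few points
  below the planted multiplier (observed ~1.5 for a planted 1.7).
* The DEG caller is a t-test filter, not a count-model DE method; it
  exists to close the loop on synthetic data and to accept precomputed DE
  tables transparently.
* Bins are fixed tiles; no sliding windows or DMR merging.
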