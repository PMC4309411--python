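# Methods

This note records the models, estimators and numerical choices behind
`pericompart`, and what the synthetic-data generator does and does not
emulate.

## Compartment calling from a Marey-style map

The per-gene recombination rate is expressed in **cM per gene**, not cM/Mbp:
the rate of gene *i* is the genetic distance spanned by a centred window of
`W` genes (default 50) divided by `W`, with the window clamped at chromosome
ends.  Physical length enters only through the region-span rule.  Working in
gene units avoids artifacts from assembly gaps and highly uneven physical
gene density in repeat-rich genomes.

Raw genetic maps are made non-decreasing per chromosome by isotonic
clamping (`cM_i := max(cM_i, cM_{i-1})`) before rate computation; the number
of clamped genes is reported.  Small map inversions from mapping error would
otherwise generate negative rates.

LR regions are maximal runs of genes with rate ≤ (chromosome mean rate) /
`fold` (default 20; a gene exactly at the threshold is inside the run — a
deterministic tie rule).  Runs separated by fewer than `gap_genes` (default
`W/2 = 25`) above-threshold genes are merged before the span test, so short
high-rate blips cannot split a suppressed region.  Merged runs are retained
when their physical span exceeds `min_frac` (default 2%) of the chromosome
length (maximum mapped position unless a lengths file is supplied).  The
chromosome mean rate is total map length over gene *intervals* (n−1), so a
perfectly uniform map has windowed rate exactly equal to the mean.  The
window size and gap parameter are exposed as options rather than asserted as
canonical values; `W = 50` matches the rolling-average convention used
elsewhere in the package.

Because the window is centred, a called boundary sits systematically up to
`W/2` genes inside the true edge of a suppressed segment: the first gene
whose whole window lies inside the segment is `W/2` genes in.  Boundary
accuracy claims are therefore stated as "within `W/2` genes".

The LR region containing the centromere becomes **LR-PC**; other LR regions
are flanking LR; everything else is HR.  Two-class analyses use
LR = LR-PC ∪ LR-flank.

## Diversity estimation

Samples are inbred lines, each contributing one haplotype; a sample's
genotype at a site is the majority allele of its reads (ties to reference).
Sites pass the error filter when the minor allele has sample-level frequency
≥ 0.1 and ≥ 3 supporting reads in at least one sample.  Whether the MAF is
computed over samples or pooled reads is a genuine ambiguity; sample-level
is the default, `pooled_reads=True` the switch.

Per-site diversity is the unbiased heterozygosity
π̂ = n/(n−1)·(1 − Σ pᵢ²) over the n genotyped haplotypes (samples missing at
a site are excluded from its n; sites with n < 2 are dropped).  Gene-level
π divides the site sum by the number of covered positions — all reference
positions by default, since real read-depth masks are input-specific; the
parameter keeps the denominator explicit.

The protein-coding region is the longest ATG-initiated open reading frame on
the forward strand (inputs are oriented cDNAs), ties to the smaller start,
running to the first in-frame stop or the 3′ end truncated to a codon
boundary.  ORFs shorter than 30 codons are treated as noncoding — this
floor suppresses spurious micro-ORFs.  Synonymous and nonsynonymous site
counts are fractional (each codon position contributes the fraction of its
three changes that are synonymous), computed from the reference sequence
only: reference-anchored counts are deterministic, and sample-averaged
counts change results by well under 1% at these diversities.  A codon
carrying two SNPs classifies each SNP independently against the reference
codon.

**Compartment-level π<sub>a</sub>/π<sub>s</sub>** is reported as a pooled
ratio — (Σ π<sub>a</sub>·N)/(Σ N) over (Σ π<sub>s</sub>·S)/(Σ S) — rather
than a mean of per-gene ratios.  At π<sub>s</sub> ≈ 0.01 most genes segregate
no synonymous SNP, so the per-gene ratio is usually undefined, and its mean
conditional on π<sub>s</sub> > 0 is upward-biased.  The pooling weights are
the site counts, making the ratio an estimate of the underlying
per-site-rate ratio.

## Ka/Ks and the molecular clock

Ka/Ks uses the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction, K = −¾ ln(1 − 4p/3).  Substitution pathways between codons
differing at 2–3 positions are averaged over orderings; pathways through a
stop codon are excluded unless all of them pass through one.  Codons with
gaps, ambiguous bases or stops in either sequence are skipped.  p ≥ 0.75 is
saturation: the estimate is undefined and the pair flagged (downstream
trimming treats it like Ks > 3).  Codon-pair path counts are cached in a
lazily built 64×64 table.  A full maximum-likelihood counting model is out
of scope; at the Ks ≈ 1.3 scale relevant here, NG86 is adequate for the
threshold decisions the pipeline makes.

The clock rate is r = Ks/(2T): synonymous divergence accrues along both
lineages since duplication.  With Ks = 1.290 and T = 60 My this gives
1.075×10⁻⁸ substitutions/site/year; published per-site rates quoted for the
same quantities do not always follow from this formula, so the package
reports only what it computes.

## Ohnolog detection

The chain: all-vs-all nucleotide hits → drop self-hits, best HSP per
subject, best subject per query (ties by e-value then subject id) → filter
pairs too similar (bit > 8000, or 100% identity over > 200 bp) or too weak
(bit < 300 **and** alignment < 500 bp) to be WGD-derived → optional
reference-genome reordering within synteny blocks with a density filter
(genes whose anchor differs from the local window median by > 400 reference
genes are dropped) and running-median/MAD map-outlier removal (window 51,
5 MADs, with a MAD-0 guard) → dynamic-programming chaining → NG86 Ka/Ks →
trimming.

Chaining finds maximal chains strictly increasing in one chromosome's gene
index and strictly monotone (either direction; the inverted direction
captures segmental inversions) in the other, with index gaps ≤ `max_gap`
(default 25, the common default of collinearity tools) between consecutive
members.  Chains are harvested greedily best-first, each pair joining at
most one region; chains shorter than `min_pairs` (default 9) stop the
harvest.  An exhaustive chain-enumeration oracle verifies optimality on
small instances in the test suite.

Trimming removes, in order: pairs with Ks > 3 (or saturated Ks); every pair
containing a gene present in more than one pair (pair-level removal — both
pairs go, which is conservative and deterministic); pairs outside regions of
≥ `min_pairs` members; and the pairs of the weaker region wherever two
regions overlap in gene-index span (strength = pair count, ties to lower
mean Ks — the younger, cleaner region — then region id).  After trimming,
no gene occurs in two pairs (hard assertion).  Manual curation of X–Y
paralogy plots is replaced entirely by this algorithmic path; a
user-supplied whitelist can union extra pairs in.

## Local duplicates

Per query gene, the best non-self hit on its own chromosome; the pair is a
local (tandem) duplicate when the physical distance is ≤ 2% of the
chromosome length (at exactly 2% it is local — the removal rule is
"remote by more than 2%"), otherwise an intrachromosomal translocation.
The depletion table contrasts {locally duplicated genes} with {all mapped
genes} split HR vs LR — overlapping categories, which is the construction
that reproduces the published p-values; a disjoint duplicated-vs-not variant
is also provided.

## Expression

Specificity is the quotient mean/sd across conditions, exactly as defined by
the reproduced analysis, rather than τ or entropy measures; it is undefined
for constant genes, which are excluded (and counted), not imputed.  ANOVA is
run separately overall, per chromosome, and per condition; no log transform
is applied by default (a `log1p` switch exists).  For two groups the F
statistic equals the squared equal-variance t statistic; this identity is
asserted numerically in the tests.

## Statistical kernels

χ², Yates-corrected 2×2 χ² (correction term floored at zero), equal-variance
t and one-way F are computed from their closed-form definitions; p-values
come from closed-form distribution functions (`scipy.stats` sf), never
simulation, so report tables are exactly reproducible.  Report rounding: p
to 4 decimals, ratios to 2 decimals.

## The synthetic-data generator

All outputs are pure functions of the `SimConfig` seed: NumPy PCG64 streams
seeded with `(seed, stage-offset)` so adding a stage never perturbs earlier
ones.

* **Map**: uniform physical spacings (mean 25 kb); exponential per-gene cM
  increments, mean 0.2 cM/gene in flanks, 50-fold lower in a planted central
  segment containing 30% of genes.  The fold default exceeds the 20-fold
  calling threshold the way real pericentromeres do (>95% suppression).
* **Coding panel**: 14 haplotypes; cDNAs with scrubbed UTRs (no upstream
  ATG) and planted ORFs of 200–400 codons — a realistic mRNA scale chosen so
  the pooled compartment ratio has sampling error well inside the ±0.03
  recovery band at 2000 genes.  SNP counts are Poisson with mean
  target·sites/E[site π̂] under a minor-allele count uniform on 2..n/2, so
  the pooled estimators are unbiased for π<sub>s</sub> = 0.01 and
  π<sub>a</sub>/π<sub>s</sub> = 0.235 (LR) / 0.170 (HR).  Mutation placement
  uses the package's own effect classifier; this circularity is intentional
  (it is the estimator under test, and the classifier is verified against an
  independent genetic-code table).  Error decoys (singleton carrier, 2
  reads) fail both filters by construction.
* **WGD**: chromosomes paired consecutively; gene *i* of A pairs with gene
  *i* + 15%·n of B, so compartment classes mix at segment boundaries;
  survival is Bernoulli per class (defaults 0.30 / 0.15 / 0 for HR–HR /
  LR–HR / LR–LR).  Surviving pairs' CDSs are built from four-fold-degenerate
  codons with third-position differences at the uncorrected proportion for a
  lognormal Ks around 1.3 (clipped to [0.5, 2]) and first/second-position
  differences for Ka = 0.16·Ks — at this divergence pairwise identity lands
  near 70%, matching the scale of real WGD relics.  Decoys exercise every
  filter: saturated relics (Ks 3.5–5), transposed paralogs placed off the
  planted synteny diagonal (a decoy that landed on the diagonal would be
  syntenic, not transposed), near-identical long alignments, weak short
  hits, self-hits.  Bit scores come from a declared monotone formula
  2·L·f·(1 − 0.9(1−f)) with f the identity fraction — a stated convention,
  not a BLAST emulation — whose values land on the meaningful side of each
  published filter threshold for the lengths used.
* **Tandem & expression**: gene *i* duplicates with probability
  (rate)·(local cM/gene) — duplication proportional to recombination —
  with its map neighbour as partner; expression is i.i.d. lognormal across
  genes, tissues and compartments (a pure null for the ANOVA).

What the generator does **not** emulate: within-gene recombination or
coalescent correlation between sites, read-level sequencing noise beyond the
planted error decoys, expression correlation between tissues, assembly gaps,
or gene-density variation along chromosomes.  Passing recovery tests
therefore demonstrates correctness of the estimators and calling logic under
the stated generative assumptions, not robustness to every property of real
RNA-seq data.

## Problem sizes

Default study conditions: 2 chromosomes × 1000 genes, 14 haplotypes, 15
tissues.  Recovery properties are evaluated over 100 replicates (200 for the
expression null calibration); the chaining oracle uses 500 random instances
of ≤ 15 pairs.  These sizes give the binomial margins the acceptance
properties quote while keeping a full run of the suite to a few minutes.

## Known limitations

* The best-hit reduction keeps one subject per query; genuine multi-copy
  families are represented only by their strongest edge.
* Region overlap resolution is greedy; a globally optimal assignment could
  differ on pathological overlap structures.
* NG86 Ks has ~0.2 sd at 200 codons near Ks = 1.3; pairs near the Ks = 3
  ceiling can cross it by noise in either direction.
* The per-gene coverage default (all positions covered) overstates the π
  denominator when real coverage is partial; supply `covered_positions`
  where a mask is known.
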