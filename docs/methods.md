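# Methods

## Scope and model

`imescan` screens canonical hexamers (reverse-complement pairs counted as
one class; 2080 classes for k = 6) for the signature expected of an
intron-mediated-enhancement (IME) element in first introns: elevated
population-level conservation, enrichment relative to other introns, a
non-uniform position distribution within first introns, and a position
distribution that differs between first and other introns. Selected
candidates are validated through co-expression and allelic-variant effect
sizes, collapsed into IUPAC consensus motifs, and complemented by an
expression-level classifier built on first-intron features. Everything
operates on standard formats (FASTA, GFF3, VCF, BED, TSV matrices).

Coordinates are 0-based half-open internally (GFF3 converted on read).
Intron sequences and all positional statistics are taken in transcript
orientation, because IME semantics (distance from the TSS, 5′ bias) are
transcript-relative. "First intron" is resolved per gene: among all
transcripts, the rank-1 intron whose 5′ end lies closest to the gene TSS,
ties broken by longest transcript then transcript id. Distinct intervals
from alternative isoforms that tie on (gene, rank) receive disambiguated
identifiers. Introns shorter than 10 bp are discarded; k-mer windows
containing N, and the 3 bp at each intron end (splice sites), are never
counted.

## Variant handling

Only single-nucleotide records are used; multi-allelic sites are split and
a position counts once however many alternates pass. Thresholds are
haploid allele counts: by default a site needs a minor-allele count ≥ 50
and ≥ 500 called alleles, values appropriate for a cohort of ~1000+
inbred diploid accessions (~2000+ haploid calls per site). The pipeline
defaults for the synthetic cohort (200 accessions = 400 haploid alleles)
are proportionally equivalent: minor count ≥ 10 (2.5% minor-allele
fraction) and ≥ 300 called (75% call rate). Masking replaces SNP positions
with `*`, so any window touching a SNP drops out of the masked count; the
conservation rate of a k-mer is masked/unmasked count, compared with the
closed-form expectation C_r = (1 − density)^k under uniform SNP placement.

## Positional tests and their numerical behaviour

Relative position of an occurrence = (1-based first position within the
untrimmed intron) / intron length, binned into ten equal bins of (0, 1).
Entropy uses the natural logarithm (the base only rescales the statistic,
not the empirical p). The uniform null is simulated: 10,000 multinomial
draws with the same occurrence count, p = (1 + #{S_sim ≤ S_obs}) /
(1 + 10,000) (add-one; never exactly zero). The first-vs-other contrast is
an exact conditional homogeneity test of the 2×10 table: row-1 counts are
drawn from the multivariate hypergeometric distribution given the margins
and tables at most as probable as the observed one are counted; 2×2
collapses dispatch to the exact hypergeometric test. Because the exact
tests being approximated have unbounded p-value resolution while a
Monte-Carlo p is floored at 1/(n_sim + 1) — too coarse to survive FDR
adjustment across 2080 k-mers when few k-mers carry signal — both tests
use two-stage adaptive sampling: screen at the stated draw count, then
re-simulate any k-mer with p ≤ 0.02 at 200,000 draws. Both stages yield
unbiased Monte-Carlo p-values; refinement only sharpens resolution.
Benjamini–Hochberg adjustment is applied across k-mers per test family;
selection requires strict inequalities (ties fail) and both FDR q-values
< α = 0.05.

## Effect sizes and validation

Cohen's d uses the pooled-SD (Hedges-uncorrected) formula throughout;
two-sample tests are Welch's t. Co-expression validation compares the
pairwise Pearson correlation vector of the motif gene set with that of
each occurrence-matched control hexamer (first-intron count within ±10%,
inclusive integer bounds); the mean d over controls is thresholded at
+0.05. Pair vectors above 200,000 pairs are seeded uniform subsamples; the
orchestrated pipeline additionally caps the number of controls at a seeded
subsample of 50 for desk-scale runtime (the estimator is a mean over
controls; the cap only adds Monte-Carlo variance). The elements of a
correlation vector are not independent (each gene participates in many
pairs); the procedure is reproduced as defined, without correction.

Allelic validation: for each gene carrying the motif in its first intron,
accessions split into canonical (intact motif at every covered position)
vs variant (≥ 1 alternate allele anywhere in the footprint; accessions
missing at all covered sites dropped; minimum group size 2). d is signed
canonical-minus-variant. Genes whose alleles also carry additional intact
copies of the motif are still classified by the ≥ 1-mutation rule. Across
motifs, the positive-median-d counts of candidates vs the non-candidate
hexamer controls form a one-sided (greater) Fisher test, and the candidate
positive count a two-sided exact binomial at p₀ = 0.5 — sidedness chosen
to match the printed reference values of these tests. FDR is applied
across motifs within each test family of the summary table.

## Consensus motifs

Pairwise hexamer distance = min over orientation (reverse complement
collapsed) and shifts of ±2 bp of (mismatches in overlap + 0.6·|shift|)/6,
capped at 1. Average-linkage clustering is cut at 0.22 by default,
calibrated so that the shift-related families of a published 16-hexamer
candidate set are recovered (the A-R-ATCGA family and the CGAGA-core
family exactly; two single-hexamer motifs remain separate).
Per cluster, members are oriented and offset-aligned to the medoid;
columns supported by ≥ 2 member bases are emitted as the IUPAC code
covering all observed bases, weaker terminal columns are trimmed. A
reference manual grouping based on visual dendrogram inspection cannot be
reproduced exactly by any flat cut of this (or any) pairwise-distance
clustering; linkage heights are reported so users can regroup by hand.

## Pentamer log-odds scorer

Weights are log2 ratios of canonical pentamer relative frequencies in
TSS-proximal (first) vs distal (other) introns, with an additive
pseudocount of 1; a sequence scores the sum over its step-1 pentamer
windows. The scorer is trained on the corpus at hand — it is a
self-contained stand-in for external intron-scoring tools trained on
curated corpora, and reports state this substitution. On the default
synthetic corpus it separates planted from unplanted genes with AUC ≈ 0.95.

## Expression classifier

25 features per gene (first intron): length, distances from TSS and
translation start to the intron 5′ end, pentamer log-odds score, SNPs per
bp, differentially methylated positions overlapping the intron in the C
and CG contexts (position counts, the stated default; region counts are a
documented alternative reading), transposable-element count and conserved
non-coding positions (both length-normalized), an intron-retention flag
(1 iff the intron overlaps an exon of an alternative isoform), minimum
folding energy consumed from a pluggable per-intron table and divided by
(length + 40) for the 20 bp exon overhangs, base composition A/T/C/G on
the splice-site-trimmed sequence, and ten canonical dimer frequencies
(reverse-complement dimers combined, counts divided by intron length).
Computing folding thermodynamics is out of scope; the generator fabricates
plausibly scaled energies.

Labels: per-gene median expression, split at the median (ties low) or into
upper/lower quartiles (middle half unlabeled). The forest uses 6000 trees,
max depth 10, min split 5, min leaf 2, sqrt features; evaluation is
10-fold cross-validated ROC/AUC plus accuracy on a stratified 80/20
hold-out. One master seed fans out to split/CV/bootstrap sub-seeds,
recorded in the report. Permutation importance is the mean decrease in
held-out accuracy over 5 seeded permutations per feature. Shapley
attributions are computed exactly for the tree ensemble under the
interventional value function with a seeded background subsample
(defaults: 50 foreground × 25 background): per (foreground, background)
pair the decision-path intervals of each leaf partition features into
"must take the foreground value" / "must take the background value" /
free, giving closed-form Shapley weights; attributions sum to the
predicted probability minus the background mean exactly (float precision),
which the tests assert at 1e-6.

## Synthetic corpus: what it emulates, and what it does not

The generator emits five chromosomes of AT-rich sequence (GC 0.32), 500
genes (2–6 exons; first-intron lengths lognormal, mean ≈ 260 bp vs
≈ 160 bp for other introns; GT..AG boundaries; 35% of genes start their
CDS after the first intron so that intron lies in the 5′UTR; 15% of
eligible genes get an isoform retaining the first intron), a planted
hexamer (default TTTCGA, composition-compatible with the AT-rich
background so it has a natural background occurrence rate) written into
the first introns of 30% of genes, two copies per intron, at Beta(2, 5)
relative positions (5′-biased, clearly non-uniform); SNPs at 0.016 per
genic bp with the rate multiplied by 0.2 inside planted copies (purifying
selection on a functional element), a two-point allele-frequency spectrum
(60% common sites, MAF 0.10–0.45; the rest rare) over 200 inbred
homozygous accessions with 2% missingness; and expression on the log
scale: condition matrix value = baseline + 0.4·[motif gene] +
0.6·[motif gene]·f_c + N(0, 1) with a shared per-condition factor f_c, and
accession matrix value = baseline + 0.4·[motif gene] − 0.5·[accession
mutated in that gene's motif] + N(0, 1), so the planted per-gene allele
effect is exactly δ/σ = 0.5. Baselines are N(3, 1) plus a moderate
G-content term (coefficient 0.5 on the z-scored first-intron G fraction),
emulating the empirically observed informativeness of base composition
for expression level; 10% of non-motif genes are lowly expressed
(baseline N(−1, 0.5)) to exercise the expression filters. An
`ensure_motif_snp` option plants one common SNP inside a motif copy per
gene, used by the allelic-recovery scenario (δ/σ recovery needs motif-locus
variation in every tested gene).

Not emulated: linkage disequilibrium, population structure, realistic
splicing signals beyond GT..AG, genome repeat structure, expression
heteroscedasticity, and any correlation between the auxiliary interval
annotations (DMR/CNS/TE) and the planted truth — those intervals are
random, so the corresponding classifier features are genuine nulls.
Passing tests therefore demonstrate statistical correctness and
recoverability of planted structure, not performance on real genomes.

## Problem sizes and runtime choices

The default corpus (500 genes, 200 accessions, 300 conditions) keeps the
full discovery run at ~1 minute on one CPU. The allelic-recovery scenario
uses 120 genes × 200 accessions with guaranteed motif-locus SNPs (≥ 50
testable genes, ~100 accessions per allele group). Auxiliary classifier
checks that only need an AUC mean (permuted-label null at n = 2000,
median-vs-quartile comparison) run with 300 and 1000 trees respectively —
the forest size affects AUC variance, not its level — while the showcase
model, permutation importances and Shapley attributions use the full
6000-tree configuration.

## Known limitations

- The Monte-Carlo contrast test's refined resolution (minimum p ≈ 5e-6)
  bounds attainable FDR q-values at ≈ 0.01 when a single k-mer carries
  signal; corpora needing far smaller q require raising `refine_nsim`.
- Matched-control selection conditions on first-intron counts only; a
  control that is itself a shifted relative of the target is not excluded.
- The per-gene allele split treats any footprint mutation as "variant"
  regardless of allele frequency or position within the motif.
- IMEter-style scores are corpus-trained log-odds sums; absolute values
  are not comparable across corpora or to external tool scores.
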