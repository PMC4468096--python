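# Methods

## The assay being modeled

`tagnat` implements the analysis of a restriction-site-anchored digital gene
expression (DGE) assay. cDNA is cut with NlaIII (recognition site `CATG`);
an MmeI-containing adapter ligated at the cut releases a fragment carrying
exactly 17 bases downstream of the site, so every transcript is represented
by 21-base tags (`CATG` + 17) whose sequencing counts are a digital readout
of abundance. Because tags are strand-specific, tags matching the strand
*opposite* an annotated gene evidence a natural antisense transcript (NAT)
of that gene, and the same counting machinery quantifies both layers.

## Reference tag database

Every occurrence of `CATG` with at least 17 following bases, in the
gene-forward sequence and in its reverse complement, yields one reference
tag annotated with (gene, strand relation, site offsets). The tag universe
is gene space, not whole-genome space: statistics are reported against the
annotated gene set, and tags from unannotated regions fall into the
`unknown` category at mapping time. A tag string claimed by more than one
(gene, strand) pair is *ambiguous* and excluded from counting; repeats of
one tag within a single gene and strand stay unambiguous and their counts
are summed into that gene. Because `CATG` is its own reverse complement, a
tag can occur on both strands of one gene; such self-assignments count as
two pairs and are therefore ambiguous (the strand claim is unresolvable).
Windows containing `N` are skipped and counted in the statistics.

## Cleaning and mapping

Cleaning trims the 3' adapter (full-match anywhere, else the longest
adapter prefix at the read end), keeps the leading 21 bases as the tag,
drops empty and short (<21 nt) inserts, and — after counting — removes
singleton tags (count 1 in the whole library), which at multi-million-tag
depth are dominated by sequencing errors. An optional mean-quality floor
(off by default) applies to FASTQ input.

Mapping resolves each distinct clean tag in fixed order: an exact hit to
exactly one (gene, strand) is assigned; an exact hit shared by several
pairs is discarded as ambiguous; otherwise all 63 Hamming-1 neighbors are
looked up **among unambiguous reference tags only**, and the tag is
assigned iff the neighbor hits agree on a single (gene, strand) —
several pairs → ambiguous, none → unknown. Exact hits deliberately take
precedence over mismatch candidates so perfect evidence is never diluted.
The four categories (unique sense, unique antisense, ambiguous, unknown)
partition the clean total exactly; this conservation law is asserted on
every run.

Library saturation is estimated by nested subsampling without replacement
(a single random permutation of the tag multiset, prefix distinct counts),
which makes the curve non-decreasing by construction.

## Quantification and NAT profile

Expression is TPM — transcripts per million clean tags:
`count / total_clean × 1e6`, per sample and per strand layer. Summed over
genes and both layers the TPM of a sample is ≤ 1e6, with equality exactly
when no tag was ambiguous or unknown.

The NAT profile reports, per sample: genes with any antisense count (as a
percentage of the reference gene set), the sense:antisense ratios of total
tags, distinct tags and detected genes, and the Spearman correlation of
sense vs antisense TPM. The correlation is computed over genes detected on
*both* strands in that sample; including one-strand-only genes would tie a
third of the ranks at zero and the statistic would measure detection, not
co-expression. Ratios are real numbers; the report layer also prints a
nearest-integer `a:b` form.

## Differential expression: M/D noise dominance

For each transcript the signal is `M = log2((mean_S + k)/(mean_F + k))`
and `D = |mean_S − mean_F|`, where the condition summary is the arithmetic
mean of replicate TPM and `k` (default 0.5 TPM, configurable) is a
pseudo-abundance guarding the log against zeros. The empirical null pools
(|M|, D) over every within-condition replicate pair and over all
transcripts — a global pool, which is what makes the procedure usable with
3+3 replicates. The probability of differential expression is the fraction
of noise pairs the signal strictly dominates in both coordinates; ties
count against significance, so an all-zero transcript scores exactly 0.
The probability is a noise-dominance score, **not** an FDR q-value, even
though DGE reports often print it in a column labelled "q"; at the usual
threshold 0.8 the implied odds of signal over noise are 0.8/0.2 = 4.

Significance additionally requires |M| ≥ 1 (two-fold) and a TPM of at
least 1 in the lower-expressed condition (an expression floor; the
threshold is on TPM — the mean of the lower condition — as no
between-sample normalization beyond TPM is applied). Genes and NATs are
called by the identical procedure on their respective layers, each layer
with its own noise pool. A consequence of the global pool worth knowing:
a transcript's D must beat the absolute differences of *abundant* noisy
transcripts, so fold changes on weakly expressed transcripts saturate at
probabilities below the threshold — sensitivity is abundance-dependent.

The ΔΔCt helper (`2^−ΔΔCt`) mirrors the standard qRT-PCR validation
arithmetic and is pure bookkeeping.

## Enrichment

Term enrichment uses the upper hypergeometric tail
`P(X ≥ m) = 1 − Σ_{i<m} C(M,i)C(N−M,n−i)/C(N,n)` with N = annotated
background genes, n = annotated significant genes, M = background genes
with the term, m = significant genes with the term — computed with exact
integer arithmetic (`math.comb`), so no log-space approximation is needed.
The gene→term map is flat (taken as already propagated; no ontology DAG
traversal). Terms with m = 0 are not tested and do not consume
multiple-testing budget. Correction is Benjamini–Hochberg step-up
(monotonicity enforced, input order preserved), significant at adjusted
P ≤ 0.05.

## Synthetic study generator

The generator emulates the study design the pipeline targets: two groups
(S, super-fine; F, fine) of 3 replicates. Defaults mirror the protocol's
scale where stated — 5M tags per library, ~98% of genes carrying a usable
`CATG` site, ~33% of genes with antisense transcription, a 10:1
sense:antisense tag-mass ratio, and a sense–antisense log-scale rank
correlation of ~0.55 (achieved with a Gaussian copula; the Pearson
parameter is `2·sin(π·ρ_s/6)` so the *rank* correlation hits the target).

Sense abundances are log-normal across genes (σ = 1.5 natural log), a
dynamic range typical of tag libraries. Per-replicate biological noise is
log-normal jitter (σ = 0.2) on the expected abundance; counts are then
multinomial over all (gene, strand) categories, so sampling noise is
Poisson-like on top. DE is planted by shifting group S so that
`|log2((S+k)/(F+k))|` equals the requested effect exactly. Planting is
restricted to genes above the 60th abundance percentile: with a global
noise pool, the D statistic of a weakly expressed transcript cannot
dominate the noise of abundant transcripts, so "planted DE" is defined as
DE on detectably expressed genes — matching what the assay can validate.
Tag sites within a gene are drawn uniformly among its usable sites (a
weighting hook exists; real protocols enrich 3'-most sites, but uniform
keeps simulator and reference DB exactly consistent). Reads are
tag + constant 14-base adapter = 35 bases; the adapter is a configuration
constant, not a reconstruction of any vendor sequence. Per-base
substitution errors are optional; indels, PCR duplication bias and
quality-profile degradation are deliberately not modeled.

What passing tests on this generator show: the pipeline's bookkeeping,
mapping logic, statistics and calibration are correct under a faithful
null and under planted effects. What they cannot show: robustness to
vendor-specific artifacts (adapter variants, quality dropouts, PCR
duplicates) or to annotation errors in a real genome.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down studies chosen to keep the
statistical properties in their asymptotic regime while remaining quick:
2,000–4,000 genes and 1–2M tags/sample for calibration, recovery and
fidelity checks (full-protocol scale, 19k genes × 5M tags, runs through
the same code paths via the CLI defaults). Null calibration uses 2,000
transcripts with Poisson counts on log-normal means. Determinism:
one master seed; per-sample streams use documented offsets (sample *i* of
an experiment uses `seed + i`); all randomness flows through
`numpy.random.default_rng`.

Degenerate inputs: an empty gene list yields an empty reference DB (not an
error); a sample with zero antisense tags gets infinite ratio sentinels
with a warning rather than an exception; TPM with a zero denominator, a
noise pool with unreplicated groups, and inconsistent hypergeometric
counts raise errors.

## Known limitations

- Dominance probabilities are granular at 1/(6 × n_transcripts) with 3+3
  replicates and are not comparable across runs with different pools.
- The published study's exact probabilities are not bit-reproducible: they
  depend on its raw libraries and on smoothing details of its DE software
  that are not specified; this package reproduces the mechanism and the
  printed-table arithmetic, not those third-party internals.
- The published distinct-tag sense:antisense ratio "2:1" is inconsistent
  with its own printed counts (43,158 : 15,192 ≈ 2.8:1); computed ratios
  are reported as-is.
- Mapping is dictionary-based on tag space; there is no genome-coordinate
  (SAM/BAM) output and no suffix-array alignment — at 21 bp with ≤1
  mismatch, exact + neighborhood lookup is complete.
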