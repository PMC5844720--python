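# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the places where the design was genuinely open.

## The count model and the exact test

Digital expression counts (reads per feature per library) are compared with
the Audic–Claverie statistic. Conditional on x reads for a feature in
library 1 (total clean reads N1), the null distribution of the count y in
library 2 (total N2) is

    P(y | x) = (N2/N1)^y · (x+y)!/(x!·y!) · (1 + N2/N1)^-(x+y+1),

i.e. y ~ NegativeBinomial(x+1, N1/(N1+N2)) — the posterior predictive of a
shared Poisson rate under a flat prior. The pmf is evaluated in log space
(gammaln) and its normalisation Σ_y P(y|x) = 1 is verified to 1e-9 in the
tests for x up to 200 and library ratios up to 3.

P-values are inclusive tail sums. One-sided tails include the observed
count. The two-sided p doubles the smaller inclusive tail and caps at 1;
because an inclusive tail becomes a strict tail when the roles of the two
libraries are exchanged, the doubled minimum is computed in both
orientations and the larger value reported. This makes the statistic
exactly invariant to which library is called "1" at the price of a slightly
conservative p. Measured null behaviour (Poisson λ=50, equal libraries,
10,000 replicates): rejection rate ≈ 0.04 at α = 0.05.

Replicates are pooled (summed) within condition before testing: the
statistic is a two-library comparison, and pooling is the faithful way to
use it with n=3 per group. A per-matched-pair mode (most conservative
pairwise p) is available behind a flag. Fold changes are computed on
pooled, library-size-normalised means (counts per million); a pseudocount
(default 1) enters only when a mean is exactly zero. Multiplicity is
controlled with Benjamini–Hochberg; significance defaults are
|log2FC| ≥ 1 and adjusted p ≤ 0.05, both configurable. The adjusted-vs-raw
choice is exposed because small-RNA workflows often report raw p.

Caveat: the exact test assumes Poisson sampling. Overdispersed features
(biological replicates) make it anti-conservative on null features; in this
package the DE call is protected by the fold-change threshold, and the
empirical FDR on the synthetic study (NB dispersion 0.05) is ≈ 0.01. With
strongly dispersed real data a dispersion-aware test would be preferable.

## Quantification

Small-RNA TPM is 10⁶·C/L with no length term — miRNA tags are near-uniform
in length, so the length term would be a constant; the unit name is kept
for continuity with the field's usage. FPKM divides counts by exonic
kilobases and mapped millions (the library-size field); gene-level FPKM is
the exact sum over the gene's transcripts. Sequenced tags are assigned to a
known miRNA only when they match a precursor exactly (sense strand, no
mismatches) at a placement overlapping the annotated mature sequence by
≥ 16 nt; ties go to the largest overlap, then lexicographic miRNA id, one
assignment per tag, which makes the assignment independent of input order.

## lncRNA prediction cascade

Steps run strictly in order with short-circuiting, and every transcript
receives exactly one label:

1. class code ∈ {j, i, o, u, x} (consumed from the GTF, not computed);
2. length ≥ 200 nt (strict "shorter than" removal);
3. known-lncRNA matching — a blastn stand-in using shared 11-mer seeding
   and gapless diagonal alignment; known iff identity ≥ 0.95 over ≥ 0.90 of
   the shorter sequence. The thresholds are explicit package defaults (no
   published cutoff exists for this step) and are configurable;
4. coding potential — a CPC/TransDecoder stand-in: three forward reading
   frames are scanned for ATG-to-stop ORFs (codons counted through the stop,
   open-ended ORFs allowed at the 3' end); coding iff the longest ORF has
   ≥ 100 codons (the conventional TransDecoder minimum) or covers ≥ 50% of
   the transcript. Scanning is sense-strand only: assembled transcripts are
   stranded.

The gapless alignment is adequate for reference matching at fixture scale;
it will under-call "known" for reference pairs related through indels.

## Target prediction and the network

Seed matching: with the miRNA 5'→3', the seed is nt 2–8. Site patterns on
the target are the reverse complement of nt 2–7 (6mer), nt 2–8 (7mer-m8),
and either with a 3' A opposite position 1 (7mer-A1 / 8mer). Every
occurrence of the 6mer core yields exactly one site labelled with the most
specific class its flanks support, so classes are mutually exclusive per
occurrence. All matching is in DNA space (U→T at the boundary). The scanner
is verified against an exhaustive position-by-position oracle on 1,000
random kilobase targets × 20 miRNAs.

The intersect-two-predictors convention is realised predictor-agnostically:
a strict regime ({7mer-m8, 8mer}) and a lenient regime (all four classes)
act as two predictors whose per-miRNA target-gene sets are intersected
(union available). No free-energy or conservation scoring is attempted.

Cis targets are genes whose span lies within 10 kb (inclusive, nearest-end
gap) of a lncRNA on the same chromosome, any strand; overlap is distance 0.
Antisense targets are opposite-strand overlaps (≥ 1 base), annotated with
the longest contiguous perfectly complementary run between the sequences —
a deterministic hybridisation proxy standing in for a thermodynamic duplex
model; it is reported, not thresholded.

Network assembly restricts to differentially expressed features, adds a
miRNA–ceRNA edge per MRE-supported pair, and emits a triplet for every
miRNA with edges to both a lncRNA and an mRNA. The co-regulation filter
implements the sponge direction logic explicitly: lncRNA and mRNA
co-directional, opposite to the miRNA. A permissive mode (any non-ns
pattern) exists for exploration. Pairwise expression correlation across
samples is deliberately **not** used as a filter — with n=3 per group it
carries almost no information. Transcripts are kept as distinct nodes
(no gene collapsing), matching the transcript|gene labelling convention.

## Enrichment

Upper-tail hypergeometric p (inclusive of the observed overlap k) for each
term against a universe that defaults to all annotated genes; enrichment
factor (k/n)/(K/N); BH instead of π₀-estimating q-values — deterministic
and adequate at this scale. Ranking keeps terms with ≥ 4 selected genes,
sorts by enrichment factor (ties: p, then term id) and reports the top 20.

## The synthetic study

The generator's defaults are the emulated study conditions: 3 tumour vs 3
matched control samples; 500 mRNAs, 150 lncRNA candidates, 200 miRNAs; 10%
of each class differentially expressed with signed |log2FC| = 2 (half up,
half down); baseline mean 200 counts; negative-binomial dispersion 0.05
(variance = μ + 0.05μ², a typical bulk-RNA-seq overdispersion; Poisson at
dispersion 0). Counts are drawn per feature and sample; library sizes are
column sums.

Sponge modules: each DE lncRNA is paired round-robin with a DE miRNA of the
opposite direction and 1–3 unused DE mRNAs co-directional with the lncRNA;
`sites_per_true_pair` (default 2) perfect 8mer sites of the module miRNA
are implanted at recorded positions (within the 3'UTR for mRNAs). Every
implanted triplet therefore satisfies the co-regulation rule by
construction, and the implanted sites are the complete ground-truth site
set.

Decoy purity is guaranteed, not sampled for: transcript sequences are
generated base-by-base, rejecting any base that would complete the seed
6mer of any simulated miRNA (with bounded restarts and a hard failure when
the space is over-constrained). Whole-sequence rejection would be hopeless
here — with 200 miRNAs a random kilobase contains dozens of chance seed
matches. mRNAs embed an ATG + non-stop-codon + stop ORF of 110–200 codons
between clean UTRs; lncRNA candidates (400–1000 nt) are resampled until the
coding-potential rule calls them noncoding. After implantation each target
is re-scanned against every miRNA and the placement retried if any
unintended site appeared. Consequences: the seed scanner's fixture
precision is exactly measurable (no ambiguous chance sites), and the
sequence composition is mildly non-uniform (forbidden-word avoidance);
nothing downstream depends on composition.

What the generator does *not* emulate: splice isoforms (single-exon
transcripts only), batch effects, read-level simulation of long-RNA
libraries, length-dependent count means, and realistic genomic clustering.
Passing recovery tests therefore demonstrates correctness of the pipeline's
logic under its stated assumptions, not robustness to real-data artefacts.
A small raw small-RNA FASTQ with implanted contaminants (adapter-carrying,
high-N, low-quality reads) is emitted so the cleaning stage runs on real
input end-to-end.

Determinism: one root seed; per-stage generators are spawned with fixed
spawn keys; all output writers use fixed float formats; two runs with the
same configuration produce byte-identical trees (manifest checksums verify
this).

## Read cleaning

Rules in order, each read counted once under its first failing rule:
(a) 3' adapter — the read suffix matches a prefix of the adapter over
≥ 8 nt; removal by default, trimming behind a flag (the upstream protocol
treats adapter presence as a removal criterion for short tags);
(b) N fraction strictly > 5%; (c) fraction of bases at Phred ≤ 10 strictly
> 50%. Boundary cases sit exactly on the quoted thresholds: 5% N is
retained, half-low-quality is retained. Q20/Q30/GC are reported over clean
reads.

## Problem sizes used in the checks

The test suite and acceptance script use the default study scale
(850 features, 6 samples), 10,000-replicate null calibration, 5,000-sample
moment checks of the count model, and a 1,000 × 20 oracle comparison for
the scanner — sizes chosen so each check is statistically meaningful while
the whole suite stays quick on one CPU.
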