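# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and conventions

Internal coordinates are 0-based, half-open, everywhere; conversion happens
only at format boundaries (wiggle output is 1-based). The one deliberate
exception is the promoter window, which is the inclusive interval
`|pos − tss| ≤ flank` (default flank 1500 bp), matching the figure-caption
convention of TSS ± 1500 bp rather than BED arithmetic.

## Dual-context methylation model

A cytosine's context is a deterministic function of its two flanking bases
read 5'→3' on its own strand: GCH (G before, non-G after) carries the
exogenous GpC methyltransferase signal and reports accessibility; HCG
(non-G before, G after) carries endogenous CpG methylation; GCG matches
both patterns and is catalogued but excluded from either track, since the
enzymatic and endogenous signals cannot be separated there; HCH is
uninformative. Sites are catalogued on both strands and strands are kept
separate by default (GpC footprinting is strand-symmetric only at
palindromic sites); merging is left to the caller.

**Emission model.** The signal-level caller is a per-k-mer Gaussian naive
Bayes: for each k-mer (k = 6, target C at offset 2; both configurable) the
methylated and unmethylated signal distributions are fitted as independent
Gaussians from labeled training runs — PCR-amplified DNA is ground-truth
unmethylated, enzyme-treated PCR product ground-truth methylated. A site's
LLR is the sum over its events of Gaussian log-density differences.
K-mers with fewer than 20 events per label are omitted and reported;
zero-variance fits are floored at a configurable epsilon (default 1e-6)
with a warning. This is a deliberate simplification relative to a full
signal-space HMM: it preserves the learn-from-labeled-runs structure and
the per-site LLR interface while remaining analytically checkable
(closed-form expected LLRs, CLT bands on recovered means).

**Calling.** `call = methylated` iff `llr ≥ t`, `unmethylated` iff
`llr ≤ −t`, else ambiguous; the boundary is a definite call. The default
t = 2.0 (natural log) follows the common nanopore-caller convention; the
threshold is configurable since no single value is canonical.

**Contaminant filter.** Cell-free DNA that leaks into the library is fully
exposed to the GpC enzyme and appears as reads methylated at almost every
GC site. A read is dropped iff some window of exactly 80 consecutive
GC-context calls (GCH + GCG, ambiguous calls excluded from both numerator
and window membership) contains ≥ ceil(0.75·80) = 60 methylated calls.
Evaluating windows of exactly 80 makes the "at least 80 sites" rule
monotone and checkable: any longer qualifying stretch contains a
qualifying 80-window, and reads with fewer than 80 informative GC calls
are always kept. Whether ambiguous calls belonged in the original
denominator is unknowable from the rule's wording; they are excluded here
and the choice is documented rather than guessed.

**Aggregation and smoothing.** Per-site proportion is
`n_meth/(n_meth + n_unmeth)` over definite calls, reported only at ≥ 4-fold
definite coverage. Track smoothing uses a 5-site triangular kernel
(weights 1,2,3,2,1) renormalized over in-range neighbours at the edges, so
constants are fixed points and the output never leaves `[min x, max x]`.

## Insertion mapping

Reads are screened by local alignment (Biopython `PairwiseAligner`, local
mode, scores match/mismatch/gap-open/gap-extend = 2/−4/−4/−2, both
orientations; multiple non-overlapping hits recovered by masking the best
hit and realigning). A read is integration evidence only if it aligns
≥ 30 bp (inclusive) to both the shared vector backbone and a construct
insert. Host flanks — maximal read segments ≥ 50 bp not covered by any
construct alignment — are aligned to the host; the anchor is the host
coordinate of the junction side of the flank. Anchors are clustered by
single-linkage within 50 bp (long-read endpoint jitter; no canonical value
exists). A cluster is rejected as native when its centre overlaps the
insert gene's native locus *or* any supporting read's host-flank alignment
does — the inserts are cDNAs of host genes, so reads anchored in the native
gene are transcribed-from-genome lookalikes, not integration evidence.
Clusters with a single supporting read are rejected as singletons.
Integration orientation is recorded but not used for filtering.

## Differential expression

Size factors are median-of-ratios against the per-gene geometric-mean
pseudo-reference, computed over genes nonzero in every sample. The test
is an NB Wald test on normalized group means with pseudocount 0.5:
`log2FC = log2(m_B + ½) − log2(m_A + ½)`, delta-method standard error from
the NB variance `μ + αμ²`, two-sided normal p, Benjamini–Hochberg
adjustment over tested genes (all-zero genes are excluded and reported).

Dispersion is estimated by the method of moments on normalized counts
(pooled within-group variance), then, by default, replaced by a
mean-dispersion trend `α(μ) = a₀ + a₁/μ` fitted across genes by iterated
trimmed least squares. With triplicates, the raw per-gene moment estimate
has ~4 degrees of freedom, and plugging it into a normal Wald statistic
inflates the type-I error to ~0.11 at nominal 0.05; the trend pools
information across thousands of genes, making the plug-in variance
effectively known and restoring calibration (measured in the acceptance
suite) without per-gene empirical-Bayes shrinkage. `dispersion="genewise"`
keeps the raw estimates for callers who want them. No fold-change
shrinkage is applied anywhere, and exact replication of any particular
NB-GLM package's gene lists is explicitly not promised: the signature
rules downstream, not the test internals, are the defined computation.

**Signature rules.** The DE filter uses strict inequalities exactly as
worded: `baseMean > 50`, `FDR < 0.01`, `|log2FC| > 2`. "Top N" needs a
ranking key the wording does not supply; the default is padj ascending,
ties by |log2FC| descending, then gene id (configurable to rank by |log2FC|
first). The hepatocyte signature takes per-direction top-500 from each of
two primary-cell tables *then* intersects (the alternative order —
intersect first — is noted as open; this one is implemented). The
HCC-style signature caps the up direction at 500 and leaves the down
direction uncapped. The consensus rule admits a gene in a direction iff it
holds that direction in ≥ k of n studies (default 3 of 5); genes
qualifying in both directions are excluded and reported. Externally
published study lists enter through plain set/GMT inputs, since consensus
building must accept lists that were never recomputed.

## GSEA

The ranking metric is `−log10(p)·sign(log2FC)` on nominal p (whether
adjusted p was originally intended is unknowable; nominal is the default
and the column is configurable), with p = 0 clipped to the smallest
positive float and ties broken by gene id. The ES is the signed extremum
of the weighted KS running sum (hit increments `|metric|^w / Σ_hits`,
default w = 1; miss decrements `1/(N − N_hits)`). The null permutes gene
labels — with n = 3 per group, phenotype permutation admits only 10
distinct splits and is degenerate. NES, nominal p and FDR are sign-matched
per the original GSEA convention: a score is compared only against null
scores of its own sign, `NES = ES / mean|null ES same sign|`,
`p = (1 + #{|null| ≥ |ES|}) / (1 + n_same_sign)` floored at
`1/(n_perm + 1)`, and FDR compares |NES| against the pooled sign-matched
null NES distribution. A degenerate null (no same-sign permutations) is
floored and flagged rather than silently reported.

## Single-cell QC and cell cycle

Thresholds are class-specific and strict as worded ("fewer than" /
"greater than"), so boundary cells — exactly 4000 genes, exactly 6 % mito —
pass. iHep: min 50 000 mapped reads, min 4000 genes, max 6 % mitochondrial
UMI; HFL-CMT: min 2500 genes, max 10 % mito, no read threshold.
Mitochondrial genes are identified by a configurable identifier-prefix
list (default `MT-`/`mt-`), keeping the module annotation-agnostic. Genes
not detected in ≥ 5 cells are discarded; 500 cells per sample are
downsampled uniformly without replacement, seeded; normalization is
`ln(1 + 10⁴ · x / cell_total)`.

Phase scores average marker-gene expression per phase after z-scoring each
marker across cells. "Averaged normalized expression" is ambiguous between
raw and standardized means; the standardized form is the default so highly
expressed markers do not dominate the phase score, and a raw-mean mode is
available. Assignment is the argmax with ties broken by the fixed phase
order G1/S < S < G2/M < M < M/G1. Covariate regression of phase scores,
nUMI and mito fraction is out of scope (it is internal to external
toolkits). Relative expression divides each gene by its mean across cells;
zero-mean genes are excluded and reported, so per-gene output means are
identically 1.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its arguments and one explicit
`numpy` Generator seeded per call; truth tables accompany every dataset
and suffice to score the downstream stage.

* **Genome/methylome.** I.i.d. bases at a target GC fraction; promoters
  are 200 bp intervals on a jittered grid (midpoint = TSS). The width is
  chosen to mimic a nucleosome-depleted region: accessible stretches in
  real chromatin are far shorter than the contaminant filter's 80-GC-site
  window, and the synthetic genome must preserve that separation or an
  open promoter would masquerade as contamination. GCH/GCG sites are open
  (methylated) with probability 0.85 inside promoters and 0.15 outside;
  HCG sites are methylated with probability 0.7 — levels typical of
  footprinting experiments. Not emulated: sequence composition structure
  (CpG islands, repeats), nucleosome phasing, allele-specific states.
* **Call tables.** Reads are contiguous fixed-length intervals at a target
  mean depth; per-site LLRs are Normal(±effect, sd) around the true state
  (defaults effect 4, sd 1 — a moderately confident caller). Contaminant
  reads (default 5 %) have their GC-site states redrawn as
  Bernoulli(0.9), so both boundary-passing and boundary-failing windows
  occur and the filter's threshold, not just its happy path, is exercised;
  the 0.9 is a fixture parameter, not a claim about real cell-free DNA.
  Not emulated: raw squiggle, basecalling errors, mapping errors, adapter
  artifacts.
* **Bulk counts.** Gamma-Poisson (NB) with log-normal gene means (median
  ~200), gene-wise dispersions around 0.05, log-uniform size factors in
  [2^−½, 2^½], and a planted fraction of genes at ±log2FC = 3 — triplicate
  bulk RNA-seq conditions. Not emulated: gene-gene correlation, batch
  structure, GC/length bias.
* **Single-cell counts.** ~6000 background genes at Poisson mean 5 so
  healthy cells detect well over the 4000-gene threshold; phase markers
  4-fold overexpressed in the cell's true phase; planted low-quality cells
  are either thinned 50-fold (few genes, few reads) or given ~12 %
  mitochondrial UMI. Mapped reads are a fixed multiple of UMI total.
  Not emulated: dropout structure beyond Poisson sampling, doublets,
  ambient RNA, batch effects.
* **Insertion reads.** Chimeric reads are host-flank + backbone + insert +
  host-flank at planted loci (flanks jittered ±20 %); native-locus reads
  embed the insert at its native host position with no backbone;
  background reads are pure host. Not emulated: sequencing error on the
  reads, nested/partial integrations, multi-copy tandem insertions.

Because these omissions are exactly the nuisance processes real data adds,
passing tests demonstrate the *logic* of each stage — thresholds,
boundaries, set algebra, statistical calibration, recovery under the
stated noise model — not robustness to basecalling artifacts, alignment
ambiguity or biological covariance.

## Problem sizes

The shipped demo and the acceptance script run desk-scale instances chosen
as the package's own test conditions: 8–20 kb genomes, 12–20× read depth,
2–3 planted integration loci with 3–4 supporting reads, 1500–5000 genes at
3 vs 3, 400–500 cells. All headline checks (filter sensitivity/specificity,
type-I error, planted-effect recovery, phase recovery, insertion
precision/recall) are computed at these sizes by
`scripts/acceptance.py` and the acceptance tests.

## Known limitations

* The emission model ignores event-to-event dependence along a read and
  k-mer overlap; it is a per-site naive Bayes, not an HMM.
* The DE test has no empirical-Bayes dispersion moderation per gene and no
  LFC shrinkage; very-low-count genes rely on the trend fit.
* Local alignment is exact but quadratic; it is sized for desk-scale
  synthetic hosts (tens of kb), not genome-scale mapping.
* Native-locus rejection requires the construct's native interval to be
  annotated; un-annotated host paralogs of an insert would not be caught.
* The GSEA FDR follows the sign-matched pooled-null convention and is not
  a BH adjustment of the nominal p values.
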