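# Methods

## The mixture model

Every estimator in the package derives from one two-population mixture: a
sequenced sample contains a fraction ρ of neoplastic cells and 1−ρ of
diploid non-neoplastic cells. At a locus where tumor cells carry `c_t`
total copies of which `m` carry the allele of interest, the expected read
fraction of that allele is

    f = (ρ·m + k·(1−ρ)) / (ρ·c_t + 2·(1−ρ))

with `k` the non-neoplastic copy count of that allele (k = 1 for one of two
germline alleles, k = 0 for a somatic mutant allele). Read counts are
binomial around this expectation. Special cases:

- somatic clonal het SNV (m = 1, c_t = 2, k = 0): MAF = ρ/2;
- germline het SNP over a clonal hemizygous deletion (lost allele: m = 0,
  c_t = 1, k = 1): f = (1−ρ)/(2−ρ);
- over copy-neutral LOH (m = 0, c_t = 2, k = 1): f = (1−ρ)/2;
- male sex chromosome, somatic (m = 1, c_t = 1, k = 0):
  MAF = ρ/(ρ + 2(1−ρ)). The denominator keeps the 2(1−ρ) normal-cell
  term so that the filter's hemizygous CCF formula is its exact inverse;
  this is a deliberate internal-consistency choice rather than a claim
  about X-chromosome dosage in normal male tissue.

## Detection power and the callable footprint

Calling a somatic mutation needs the reference to reveal both germline
alleles (else a germline variant can be mistaken for somatic) and the tumor
to supply enough mutant reads. With alleles sampled Binomial(n, ½):

- P(both alleles ≥ 1 read | n = 6) = 1 − 2·(½)⁶ = 0.96875 — the basis of
  the 6× reference threshold;
- P(≥ 4 mutant reads | effective depth 8) = 163/256 ≈ 0.637 — the basis of
  the 8× effective-depth threshold, where effective depth is raw tumor
  depth × ρ. Non-integer effective depths are rounded half-to-even before
  the binomial computation (a deterministic convention; the quantity is
  otherwise undefined at non-integer n).

The per-sample callable footprint is by default the scalar minimum of the
reference footprint (bp with depth ≥ 6) and tumor footprint (bp with
effective depth ≥ 8) — an explicit, reproducible convention — with the
per-base intersection available via `intersection=True`. The intersection
is never larger; both are invariant to how the depth function is
partitioned into intervals. Effective depth uses a single sample-level ρ
with no local copy-number adjustment.

## Cellularity estimation

Four estimators, applied in the fixed priority order deletion-AI >
cnLOH-AI > modal-MAF > median-MAF. The allelic-imbalance estimators invert
the mixture formulas above using a pooled minor-allele fraction
f = Σᵢ min(aᵢ, bᵢ) / Σᵢ (aᵢ + bᵢ), which weights SNPs by depth; per-SNP
minima make the estimate insensitive to which haplotype carries the B
label. Estimates are clamped to [0, 1]. The priority order is a package
decision (AI methods make no assumption that somatic mutations are
heterozygous-diploid, so they outrank the MAF-doubling methods); all
applicable estimates are reported so disagreement stays visible.

The modal-MAF estimator takes 2× the peak of a Gaussian KDE (Silverman
bandwidth) evaluated on (0, 0.6]; zero-spread inputs short-circuit to the
common value (a KDE is singular there) and other KDE failures fall back to
a 0.01-width histogram. It requires ≥ 50 mutations (default); below that
the median method is the fallback. For males, the median method combines
2×median(autosomal MAF) and 1×median(sex-chromosome MAF) as a
mutation-count-weighted mean — the combiner is a package decision.

## Clonality filter

A variant is kept iff total reads ≥ 14 AND mutant reads ≥ 4 AND
CCF ≥ 0.40, where CCF = min(1, 2·MAF/ρ) (hemizygous male sex-chromosome
loci: min(1, MAF·(ρ + 2(1−ρ))/ρ)). The CCF model is deliberately
copy-number-unaware. The total-reads floor of 14 (≈ 6 reference + 8
effective tumor) is a configurable package default, not a published
constant. Every removal records all failed criteria; the filter is
idempotent and monotone in each threshold. Indels pass through the same
read-count/CCF rules. Germline het SNPs are selected from reference-tissue
calls at known polymorphic sites with VAF in the closed window
[0.40, 0.60] (boundaries inclusive, for bit-reproducibility).

## Burden, spectra, signatures, UV fraction

Burden = kept clonal mutations / callable footprint in Mb, which cancels
both depth differences (subclone detection at high coverage) and footprint
differences across studies. Spectra use the 96 strand-collapsed
trinucleotide classes ordered substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G; then 5' base A,C,G,T; then 3' base); purine-strand calls are
reverse-complemented.

Signature refitting solves min‖p − S·w‖₂, w ≥ 0, by NNLS on the
normalized spectrum p — the same objective as iterative per-signature
refitting tools, but deterministic and solved exactly. `prune_below`
(default 0; 0.06 mimics common refitting practice) zeroes small weights
and rescales survivors to preserve the attributed total;
unattributed = max(0, 1 − Σw), with Σw renormalized onto the simplex in
the rare case NNLS overshoots 1. The residual is reported.

The UV fraction counts C>T SNVs whose pyrimidine-strand 5' neighbor is C
or T (the mutated base is the 3' member of a dipyrimidine) plus CC>TT
dinucleotide events, over all SNV + dinucleotide events. A CC>TT event
counts once in numerator and denominator; indels are excluded from the
denominator — both are declared conventions where event weighting is
otherwise ambiguous.

## Focal copy-number selection

Amplification: log2 ratio strictly > 0.9, ≥ 20 probes, and pooled
allelic-imbalance evidence (exact two-sided binomial on min(A,B) of the
pooled per-segment het-SNP counts, needing ≥ 5 SNPs, at α = 0.01).
Deep deletion: log2 strictly < −1 and the probe support; the imbalance
requirement extends to deletions behind a flag. Strict inequalities are a
declared convention (configurable). Segments rescued by manual review
enter through an explicit allowlist that waives probe support and
imbalance but never amplitude; nothing is rescued automatically. Gene
annotation is ≥ 1 bp overlap with half-open interval semantics.

The imbalance test pools the A and B totals as labelled rather than
per-SNP minima: per-SNP minima have expectation below n/2 under the
balanced null, which would make the test anti-conservative. (The
cellularity estimators keep per-SNP-minor pooling because there f is a
point estimate of an asymmetric mixture fraction, not a null test
statistic.)

## Overlap statistics

Features (genes, pathway ORs, subtype indicators) altered in ≥ 16 samples
are tested pairwise with a two-sided Fisher's exact test under the
minimum-likelihood convention: the p-value sums hypergeometric
probabilities of all tables at the observed margins whose probability is ≤
the observed table's (relative slack 1e-12 for floating-point ties).
Benjamini–Hochberg q-values are computed across all performed tests.
Pathway-vs-member pairs are excluded as structurally dependent (pathway
rows are the OR of their members). The min-mutant constant 16 is honored
as configurable input, not re-derived. Hotspot matching requires identical
gene and protein change; primary matches need catalog q < 0.01, and with
`relax_secondary` any further hotspot in an anchored gene is reported with
its own q.

## The synthetic cohort generator

The generator emulates, per sample: negative-binomial per-window depth
(window 500 bp) whose mean is modulated by a smooth GC-like covariate
(exp(3·(gc − 0.45)), gc a fixed sinusoid) — reproducing the
coverage-variability failure mode the footprint machinery absorbs; planted
arm-level deletions and cnLOH (second half of a chromosome block),
focal amplifications (8 copies) over oncogene loci and focal homozygous
deletions over suppressor loci, with tumor coverage scaled by the local
dosage factor (ρ·c_t + 2(1−ρ))/2 and SEG log2 ratios equal to the log of
that factor plus N(0, 0.03) noise; germline het SNPs (density 1/2 kb) with
binomial counts at the mixture expectation, the B allele oriented on the
lost/minor haplotype within CN segments (phase-consistent, as a
BAF-segmented caller reports them); somatic SNVs with contexts drawn from
S·w (w ~ Dirichlet per subtype), positions uniform, counts
Poisson(burden × Mb), reported on a random strand; a subclonal fraction
(default 0.15) at CCF ~ U(0.05, 0.35) so the 40% filter has true
positives and negatives; CC>TT dinucleotides at a subtype rate; sex ~
Bernoulli(½) with hemizygous male X (no het SNPs, hemizygous MAFs).

Default study conditions: cellularity U(0.12, 0.99), matching the range
reported for real cSCC cohorts; five subtypes (xeroderma pigmentosum,
sporadic, azathioprine immunosuppressed, other immunosuppressed, RDEB)
with lognormal burden medians 60/25/45/10/3 mut/Mb (σ 0.4–0.5) — invented
magnitudes consistent with the qualitative subtype ordering, since no
distributional forms are published; signature mixtures concentrated on a
UV-like, XP-UV-like, azathioprine-like or APOBEC-like process per subtype;
CASP8 enrichment probability 0.7 for RDEB vs 0.15 elsewhere. Mean depth is
drawn U(30, 200) — a typical exome range chosen once; real multi-study
cohorts span wider extremes (means from ~12× to ~500×) but publish no
distribution to emulate. The K = 6 signature catalog is synthetic and
built deterministically in code (published catalogs are third-party data
and user-suppliable); its UV column is concentrated on dipyrimidine C>T so
UV-content arithmetic is exact.

What the generator does not emulate: alignment artifacts, mapping bias,
read-level errors, panel-of-normals effects, germline contamination of the
tumor's reference, subclonal copy number, or realistic genome annotation
(its genome is 5 synthetic chromosome blocks with 25 named gene loci).
Passing tests therefore demonstrate correctness of the estimators under
the stated sampling model, not robustness to artifacts the model omits.

## Pipeline and exclusion screen

Stages run per sample in dependency order; cellularity is estimated first
from het SNPs plus read-support-filtered MAFs (alt ≥ 4, total ≥ 14 — the
CCF rule cannot apply yet since it needs ρ). Samples that defeat a
required stage (no applicable estimator, zero callable footprint) are
quarantined with a logged reason; remaining samples are unaffected, and
re-running without a quarantined sample leaves the others' outputs
bit-identical. The advisory exclusion screen flags samples with < 20 kept
mutations whose MAFs sit below 0.10 (poor neoplastic sampling) or with
mean reference depth < 5× (germline/somatic separation unreliable); floors
are package defaults, and enforcement is opt-in. Germline-concordance
checks (sample swaps, tumor-in-normal contamination) are a documented gap:
they need genotype-level machinery outside this package's inputs.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale, chosen as the
package's documented study conditions: cellularity recovery on a purity
grid {0.2, 0.4, 0.6, 0.8, 0.95} × 20 seeds with 1000 het SNPs per region
and 300 clonal mutations at 60× (mean absolute error ≤ 0.05 per
estimator); signature recovery from 5000 multinomial draws × 20 seeds
(mean L1 ≤ 0.05); Fisher agreement with exact rational enumeration on all
2×2 tables up to n = 40 (≤ 1e-12); overlap type-I error from 1000
independence-null replicates at 88 samples (q < 0.05 rate ≤ 0.05); and an
end-to-end run of 20 samples over a 5 Mb territory at 60–150× and ρ ∈
(0.3, 0.95). Integration tolerances were fixed a priori from sampling-noise
scales at those sizes: cellularity MAE ≤ 0.05, burden median relative
error ≤ 0.20 against realized clonal density (samples with ≥ 20 clonal
mutations), signature-weight L1 ≤ 0.30 and UV-fraction error ≤ 0.10 on
samples with ≥ 50 kept mutations, and recall ≥ 0.9 for planted focal
events whose true amplitude clears the thresholds (|log2| ≥ 1 with
purity ≥ 0.4 for amplifications). Published cohort-level values (mean
callable fraction, pathway frequencies, cohort counts) require the
original controlled-access data and are intentionally not reproduced.
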