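# csccqc

Cohort-level quality control and driver-context analysis for cutaneous
squamous cell carcinoma (cSCC) sequencing cohorts.

cSCC has one of the highest mutation burdens of any cancer — mostly
UV-induced C>T changes at dipyrimidines — which makes cross-study cohorts
hard to compare: tumors differ wildly in neoplastic cell content
(cellularity), mean coverage, and coverage variability, and normal skin
contributes mutant keratinocyte clones that masquerade as tumor subclones.
`csccqc` implements the QC machinery that makes such cohorts comparable,
plus a synthetic-cohort generator with known ground truth so every stage is
testable without controlled-access patient data.

## What it computes

For a tumor/reference pair with cellularity ρ:

- **Detection power.** With reads sampling alleles as Binomial(n, ½), the
  probability that n reference reads see both germline alleles is
  1 − 2·(½)ⁿ (0.96875 at the 6× threshold); the probability that a clonal
  heterozygous mutation accrues ≥ 4 mutant reads at effective tumor depth
  d·ρ = 8 is 163/256 ≈ 0.637.
- **Callable footprint.** Bases with reference depth ≥ 6 and effective
  tumor depth ≥ 8; the per-sample footprint is the minimum of the two (the
  per-base intersection is available behind a flag). Mutation burden is
  clonal mutations per callable megabase.
- **Cellularity**, by four estimators in priority order: allelic imbalance
  of germline het SNPs over deletions (minor read fraction
  f = (1−ρ)/(2−ρ), so ρ = (1−2f)/(1−f)), over copy-neutral LOH
  (f = (1−ρ)/2, ρ = 1−2f), the modal somatic MAF doubled, and the median
  somatic MAF doubled (male sex-chromosome MAFs enter undoubled).
- **Clonality filter.** A variant is kept iff total reads ≥ 14, mutant
  reads ≥ 4, and cancer cell fraction CCF = 2·MAF/ρ ≥ 0.40 (hemizygous
  male sex-chromosome loci use CCF = MAF·(ρ + 2(1−ρ))/ρ). This removes
  subclones and unrelated field-clone keratinocytes.
- **Mutational signatures.** 96-context trinucleotide spectra
  (pyrimidine-strand convention) refit against a signature catalog by
  nonnegative least squares; plus the signature-free UV fraction: C>T at
  the 3' base of a dipyrimidine, or CC>TT, over all substitution events.
- **Focal copy number.** Amplifications need log2(T/R) > 0.9, ≥ 20 probes
  and allelic-imbalance corroboration (exact binomial, α = 0.01); deep
  deletions need log2 < −1 and the probe support.
- **Cohort statistics.** Hotspot-catalog matching (primary q < 0.01,
  secondary hotspots relaxed within anchored genes) and pairwise
  co-occurrence/exclusivity testing over a binary alteration matrix:
  features with ≥ 16 altered tumors, two-sided Fisher's exact test,
  Benjamini–Hochberg q-values.

## Worked example

```bash
python examples/02_cellularity.py
```

```
simulated tumor purity: 0.65
  deletion_AI  rho = 0.653  (n = 800)  <- selected
  cnLOH_AI     rho = 0.648  (n = 800)
  modal_MAF    rho = 0.636  (n = 300)
  median_MAF   rho = 0.646  (n = 300)
```

All four estimators recover the simulated purity of 0.65 within a few
points; the deletion allelic-imbalance method is selected because it makes
no diploid-heterozygosity assumption about somatic mutations. The other
examples cover the power model (`01`), signature refitting and UV fraction
(`03`), and a full 12-sample cohort run (`04`), which prints a per-sample
profile table (cellularity, callable fraction, burden, UV fraction) next to
the generator's ground truth, the focal CNA calls, and the top
co-occurrence/exclusivity pairs.

A thin CLI mirrors the stages
(`cscc-qc simulate|footprint|cellularity|filter|burden-signatures|cna|overlap|hotspots|run`).

## Scope

The package reimplements the post-calling analysis layer. Read alignment,
variant calling (Mutect2/Pindel/FreeBayes), CNV segmentation, and
driver-discovery statistics (MutSig, dN/dS and relatives) are out of scope:
the pipeline consumes their outputs as flat files (bedGraph coverage,
MAF-like variant TSV, het-SNP TSV, SEG-like segments) and emulates them in
simulation.
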