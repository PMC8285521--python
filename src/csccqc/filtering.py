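"""Clonality-aware somatic variant filtering and germline het-SNP selection.

Candidate somatic calls are kept only when (i) overall coverage at the site
is adequate, (ii) enough reads support the mutant allele, and (iii) the
variant is predicted to be present in at least 40% of tumor cells. The last
rule removes subclonal mutations and mutations from unrelated keratinocyte
clones that commingle with skin tumors — both inflate burden estimates and
confound driver discovery.

The cancer cell fraction (CCF) is derived from the mutant allele frequency
under a copy-number-unaware heterozygous-diploid model: an autosomal clonal
het mutation has expected MAF rho/2, so CCF = 2*MAF/rho. On male sex
chromosomes the locus is hemizygous: the expected clonal MAF is
rho / (rho + 2(1-rho)) and CCF = MAF * (rho + 2(1-rho)) / rho.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_COLUMNS",
    "cancer_cell_fraction",
    "filter_somatic_variants",
    "call_het_germline_snps",
]

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads",
    "trinucleotide_context", "variant_class", "gene", "effect", "is_sex_chrom",
]

DEFAULT_MIN_TOTAL_READS = 14  # ~ 6x reference + 8x effective tumor
DEFAULT_MIN_ALT_READS = 4
DEFAULT_MIN_CCF = 0.40


def cancer_cell_fraction(maf: float, rho: float, is_sex_chrom: bool = False,
                         sex: str = "female") -> float:
    """Fraction of tumor cells estimated to carry a variant, capped at 1."""
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"cellularity must be in (0, 1], got {rho}")
    if maf < 0:
        raise ValueError("maf must be non-negative")
    if is_sex_chrom and sex == "male":
        ccf = maf * (rho + 2.0 * (1.0 - rho)) / rho
    else:
        ccf = 2.0 * maf / rho
    return float(min(1.0, ccf))


def filter_somatic_variants(
    variants: pd.DataFrame,
    rho: float,
    sex: str = "female",
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_ccf: float = DEFAULT_MIN_CCF,
) -> pd.DataFrame:
    """Apply the three-rule somatic filter; annotate every decision.

    Returns a copy of ``variants`` (input order preserved) with added
    columns ``maf``, ``ccf``, ``kept`` and ``reasons`` (semicolon-joined
    failure labels from {low_coverage, few_alt_reads,
    subclonal_or_field_clone}; empty iff kept).
    """
    out = variants.copy()
    ref_reads = out["ref_reads"].to_numpy(dtype=float)
    alt_reads = out["alt_reads"].to_numpy(dtype=float)
    total = ref_reads + alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, alt_reads / np.where(total > 0, total, 1), 0.0)
    is_sex = out["is_sex_chrom"].to_numpy(dtype=bool) if "is_sex_chrom" in out else \
        np.zeros(len(out), dtype=bool)
    ccf = np.array([
        cancer_cell_fraction(m, rho, is_sex_chrom=s, sex=sex)
        for m, s in zip(maf, is_sex)
    ]) if len(out) else np.array([])

    reasons = []
    for i in range(len(out)):
        r = []
        if total[i] < min_total_reads:
            r.append("low_coverage")
        if alt_reads[i] < min_alt_reads:
            r.append("few_alt_reads")
        if ccf[i] < min_ccf:
            r.append("subclonal_or_field_clone")
        reasons.append(";".join(r))
    out["maf"] = maf
    out["ccf"] = ccf
    out["kept"] = [r == "" for r in reasons]
    out["reasons"] = reasons
    return out


def call_het_germline_snps(
    reference_variants: pd.DataFrame,
    known_sites: pd.DataFrame | set,
    vaf_window: tuple[float, float] = (0.40, 0.60),
) -> pd.DataFrame:
    """Select germline heterozygous SNPs from reference-tissue calls.

    Keeps variants at known polymorphic sites (e.g. 1000 Genomes) whose
    variant allele frequency lies inside the closed ``vaf_window``. Returns a
    het-SNP table (chrom, pos, a_reads, b_reads) with a_reads the reference
    allele count and b_reads the variant allele count.
    """
    lo, hi = vaf_window
    if isinstance(known_sites, pd.DataFrame):
        site_set = set(zip(known_sites["chrom"], known_sites["pos"]))
    else:
        site_set = set(known_sites)
    ref_reads = reference_variants["ref_reads"].to_numpy(dtype=float)
    alt_reads = reference_variants["alt_reads"].to_numpy(dtype=float)
    total = ref_reads + alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(total > 0, alt_reads / np.where(total > 0, total, 1), np.nan)
    in_window = (vaf >= lo) & (vaf <= hi)
    at_known = np.array([
        (c, p) in site_set
        for c, p in zip(reference_variants["chrom"], reference_variants["pos"])
    ]) if len(reference_variants) else np.array([], dtype=bool)
    kept = reference_variants.loc[in_window & at_known]
    return pd.DataFrame({
        "chrom": kept["chrom"].to_numpy(),
        "pos": kept["pos"].to_numpy(),
        "a_reads": kept["ref_reads"].to_numpy(),
        "b_reads": kept["alt_reads"].to_numpy(),
    })
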