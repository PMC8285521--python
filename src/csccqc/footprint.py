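"""Binomial detection power and callable-footprint computation.

Somatic mutation calling requires adequate coverage on both sides of a
tumor/reference pair. On the reference side, both germline alleles must be
sampled at least once so that a tumor-only variant can be recognized as
somatic rather than as an unseen germline allele. On the tumor side, only the
reads derived from neoplastic cells carry the mutant allele, so raw depth is
discounted by tumor cellularity ("effective tumor coverage") before asking
whether a heterozygous mutation could plausibly accumulate the minimum number
of supporting reads.

The callable footprint of a sample is the number of targeted bases at which
both conditions hold; mutation burdens are normalized against it so that
samples with very different depth profiles remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoverageProfile",
    "FootprintReport",
    "prob_both_alleles_sampled",
    "effective_coverage",
    "prob_detect_het",
    "callable_footprint",
]

#: Default minimum reference depth: both alleles sampled >=1x with p = 96.875%.
DEFAULT_MIN_REF_DEPTH = 6
#: Default minimum effective tumor depth: >=4 mutant reads at a clonal het
#: site more than half of the time (163/256).
DEFAULT_MIN_EFFECTIVE_DEPTH = 8

BEDGRAPH_COLUMNS = ["chrom", "start", "end", "depth"]


@dataclass
class CoverageProfile:
    """Per-interval sequencing depth over a bait territory.

    Intervals are 0-based half-open (bedGraph convention) and must be
    non-overlapping within a chromosome.
    """

    sample_id: str
    role: str  # "tumor" or "reference"
    intervals: pd.DataFrame  # columns: chrom, start, end, depth
    bait_territory_bp: int

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "reference"):
            raise ValueError(f"role must be 'tumor' or 'reference', got {self.role!r}")
        missing = [c for c in BEDGRAPH_COLUMNS if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"coverage intervals missing columns: {missing}")
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("coverage intervals must satisfy start < end")
        if len(iv) and (iv["depth"] < 0).any():
            raise ValueError("coverage depth must be non-negative")

    @property
    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def mean_depth(self) -> float:
        """Length-weighted mean depth over the covered intervals."""
        lengths = (self.intervals["end"] - self.intervals["start"]).to_numpy()
        if lengths.sum() == 0:
            return 0.0
        return float(np.average(self.intervals["depth"].to_numpy(), weights=lengths))


@dataclass
class FootprintReport:
    """Callable-footprint summary for one tumor/reference pair."""

    sample_id: str
    reference_footprint_bp: int
    tumor_footprint_bp: int
    sample_footprint_bp: int
    fraction_callable: float
    min_ref_depth: int = DEFAULT_MIN_REF_DEPTH
    min_effective_depth: int = DEFAULT_MIN_EFFECTIVE_DEPTH
    method: str = "scalar_min"
    cellularity: float = field(default=1.0)

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "reference_footprint_bp": self.reference_footprint_bp,
            "tumor_footprint_bp": self.tumor_footprint_bp,
            "sample_footprint_bp": self.sample_footprint_bp,
            "fraction_callable": self.fraction_callable,
            "min_ref_depth": self.min_ref_depth,
            "min_effective_depth": self.min_effective_depth,
            "method": self.method,
            "cellularity": self.cellularity,
        }


def prob_both_alleles_sampled(n_reads: int) -> float:
    """Probability that n reads over a heterozygous site sample both alleles.

    With alleles drawn independently and uniformly, the count of one allele is
    X ~ Binomial(n, 1/2) and both alleles are seen iff 1 <= X <= n-1, i.e.
    ``1 - 2 * 0.5**n``. At the default 6x reference threshold this is
    0.96875 (96.9%).
    """
    n = int(n_reads)
    if n < 1:
        raise ValueError("n_reads must be >= 1")
    return 1.0 - 2.0 * 0.5**n


def effective_coverage(total_depth: float, cellularity: float) -> float:
    """Sequencing depth attributable to tumor cells: depth x cellularity."""
    if not 0.0 < cellularity <= 1.0:
        raise ValueError(f"cellularity must be in (0, 1], got {cellularity}")
    if total_depth < 0:
        raise ValueError("total_depth must be non-negative")
    return total_depth * cellularity


def prob_detect_het(effective_depth: float, min_alt_reads: int = 4) -> float:
    """P(>= min_alt_reads mutant reads) at a clonal heterozygous site.

    Mutant reads X ~ Binomial(n, 1/2) with n the effective tumor depth
    (rounded half-to-even for non-integer values). At 8x effective depth and
    4 required reads this is 163/256 ~ 0.637, i.e. detection succeeds more
    than half of the time.
    """
    if min_alt_reads < 0:
        raise ValueError("min_alt_reads must be >= 0")
    if effective_depth < 0:
        raise ValueError("effective_depth must be non-negative")
    if min_alt_reads == 0:
        return 1.0
    n = int(round(effective_depth))  # banker's rounding: half-to-even
    if n < min_alt_reads:
        return 0.0
    return float(stats.binom.sf(min_alt_reads - 1, n, 0.5))


def _passing_intervals(profile: CoverageProfile, min_depth: float,
                       scale: float = 1.0) -> pd.DataFrame:
    """Intervals whose (scaled) depth meets the threshold."""
    iv = profile.intervals
    mask = iv["depth"].to_numpy() * scale >= min_depth
    return iv.loc[mask, ["chrom", "start", "end"]]


def _total_length(intervals: pd.DataFrame) -> int:
    if len(intervals) == 0:
        return 0
    return int((intervals["end"] - intervals["start"]).sum())


def _intersection_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total overlap (bp) between two sets of disjoint half-open intervals."""
    total = 0
    b_by_chrom = {c: g.sort_values("start") for c, g in b.groupby("chrom")}
    for chrom, ga in a.groupby("chrom"):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        a_start = ga["start"].to_numpy()
        a_end = ga["end"].to_numpy()
        b_start = gb["start"].to_numpy()
        b_end = gb["end"].to_numpy()
        i = j = 0
        while i < len(a_start) and j < len(b_start):
            lo = max(a_start[i], b_start[j])
            hi = min(a_end[i], b_end[j])
            if hi > lo:
                total += hi - lo
            if a_end[i] <= b_end[j]:
                i += 1
            else:
                j += 1
    return int(total)


def callable_footprint(
    reference: CoverageProfile,
    tumor: CoverageProfile,
    cellularity: float,
    min_ref_depth: int = DEFAULT_MIN_REF_DEPTH,
    min_effective_depth: int = DEFAULT_MIN_EFFECTIVE_DEPTH,
    intersection: bool = False,
) -> FootprintReport:
    """Callable footprint of a tumor/reference pair.

    The reference footprint counts bases with depth >= ``min_ref_depth``; the
    tumor footprint counts bases whose effective coverage
    (depth x cellularity) is >= ``min_effective_depth``. The sample footprint
    is by default the scalar minimum of the two footprints; with
    ``intersection=True`` it is instead the per-base intersection of the two
    passing regions (never larger than the scalar minimum).
    """
    if not 0.0 < cellularity <= 1.0:
        raise ValueError(f"cellularity must be in (0, 1], got {cellularity}")
    if reference.bait_territory_bp != tumor.bait_territory_bp:
        raise ValueError("tumor and reference profiles target different bait territories")
    territory = reference.bait_territory_bp
    if territory <= 0:
        raise ValueError("bait_territory_bp must be positive")

    ref_pass = _passing_intervals(reference, min_ref_depth)
    tum_pass = _passing_intervals(tumor, min_effective_depth, scale=cellularity)
    ref_fp = _total_length(ref_pass)
    tum_fp = _total_length(tum_pass)
    if intersection:
        sample_fp = _intersection_length(ref_pass, tum_pass)
        method = "intersection"
    else:
        sample_fp = min(ref_fp, tum_fp)
        method = "scalar_min"
    return FootprintReport(
        sample_id=tumor.sample_id,
        reference_footprint_bp=ref_fp,
        tumor_footprint_bp=tum_fp,
        sample_footprint_bp=sample_fp,
        fraction_callable=sample_fp / territory,
        min_ref_depth=min_ref_depth,
        min_effective_depth=min_effective_depth,
        method=method,
        cellularity=cellularity,
    )


def footprint_table(reports: Iterable[FootprintReport]) -> pd.DataFrame:
    """Collect per-sample reports into a TSV-ready table."""
    return pd.DataFrame([r.to_row() for r in reports])
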