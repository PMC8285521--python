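"""Sequencing power and the callable footprint of a tumor/reference pair.

Builds a small piecewise coverage track, asks how much of the territory is
statistically powered for somatic mutation calling at a given tumor purity,
and prints the analytic detection probabilities behind the thresholds.
"""

import pandas as pd

from csccqc import (
    CoverageProfile,
    callable_footprint,
    effective_coverage,
    prob_both_alleles_sampled,
    prob_detect_het,
)

print("P(both germline alleles seen | 6 reads)  =",
      f"{prob_both_alleles_sampled(6):.5f}",
      "-> a 6x reference covers both alleles 96.9% of the time")
print("effective tumor coverage, 100x at 8% purity =",
      effective_coverage(100, 0.08),
      "-> only 8 of every 100 reads come from tumor cells")
print("P(>=4 mutant reads | 8x effective depth) =",
      f"{prob_detect_het(8, 4):.4f}",
      "-> a clonal het mutation is callable more than half the time")

# A 1 Mb territory where the reference thins out at the end and the tumor
# starts shallow: only the middle 600 kb is callable on both sides.
territory = 1_000_000
ref = CoverageProfile("demo", "reference", pd.DataFrame(
    [("chr1", 0, 700_000, 30), ("chr1", 700_000, 1_000_000, 2)],
    columns=["chrom", "start", "end", "depth"]), territory)
tum = CoverageProfile("demo", "tumor", pd.DataFrame(
    [("chr1", 0, 100_000, 5), ("chr1", 100_000, 1_000_000, 40)],
    columns=["chrom", "start", "end", "depth"]), territory)

report = callable_footprint(ref, tum, cellularity=0.5)
print(f"\nscalar-minimum callable footprint: {report.sample_footprint_bp:,} bp "
      f"({100 * report.fraction_callable:.1f}% of target)")
report = callable_footprint(ref, tum, cellularity=0.5, intersection=True)
print(f"per-base intersection footprint:   {report.sample_footprint_bp:,} bp "
      "(never larger than the scalar minimum)")
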