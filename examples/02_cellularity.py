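"""Tumor-purity inference from allelic imbalance and somatic MAFs.

Simulates one tumor with known purity and shows all four estimators
recovering it: germline het SNPs over a deleted arm and a copy-neutral-LOH
arm, plus the modal and median somatic mutant-allele frequencies.
"""

import numpy as np
import pandas as pd

from csccqc import estimate_cellularity
from csccqc.simulate import simulate_clonal_read_counts, simulate_het_snp_counts

TRUE_RHO = 0.65
rng = np.random.default_rng(11)

het_snps = pd.concat([
    simulate_het_snp_counts(TRUE_RHO, "deletion", 800, 60, rng),
    simulate_het_snp_counts(TRUE_RHO, "cnLOH", 800, 60, rng),
], ignore_index=True)
alt, ref = simulate_clonal_read_counts(TRUE_RHO, 300, 60, rng)
mafs = alt / (alt + ref)

selected, estimates = estimate_cellularity(het_snps, mafs, sex="female")
print(f"simulated tumor purity: {TRUE_RHO}")
for est in estimates:
    mark = "  <- selected" if est.method == selected.method else ""
    print(f"  {est.method:12s} rho = {est.rho:.3f}  (n = {est.n_support}){mark}")
print("\nallelic-imbalance methods take priority: they do not assume somatic"
      "\nmutations are heterozygous in a diploid genome.")
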