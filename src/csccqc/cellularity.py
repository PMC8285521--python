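"""Tumor cellularity (purity) inference.

Four estimators, all based on the same two-population mixture: a fraction
rho of cells are neoplastic, the rest are diploid non-neoplastic cells.

* ``deletion_AI`` — allelic imbalance of germline het SNPs over clonally
  deleted regions. Tumor cells retain one copy, normal cells two, so the
  minor-allele read fraction is f = (1 - rho) / (2 - rho) and
  rho = (1 - 2f) / (1 - f).
* ``cnLOH_AI`` — het SNPs over copy-number-neutral LOH: tumor cells carry two
  copies of one allele, so f = (1 - rho) / 2 and rho = 1 - 2f.
* ``modal_MAF`` — the mode of the somatic mutant-allele-frequency histogram;
  a clonal heterozygous mutation has expected MAF rho/2, so rho = 2 x mode.
* ``median_MAF`` — fallback when mutations are too sparse for a stable mode:
  rho = 2 x median autosomal MAF; for males, sex-chromosome mutations are
  hemizygous and their median MAF enters without doubling.

f is pooled over SNPs as (sum of per-SNP minor counts) / (sum of reads),
which weights SNPs by depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellularityEstimate",
    "pooled_minor_fraction",
    "cellularity_from_deletion_ai",
    "cellularity_from_cnloh_ai",
    "cellularity_from_modal_maf",
    "cellularity_from_median_maf",
    "estimate_cellularity",
]

HET_SNP_COLUMNS = ["chrom", "pos", "a_reads", "b_reads", "region_label"]

#: Estimator priority when several are applicable. Allelic-imbalance methods
#: come first: they do not assume mutations are heterozygous-diploid.
METHOD_PRIORITY = ("deletion_AI", "cnLOH_AI", "modal_MAF", "median_MAF")


@dataclass
class CellularityEstimate:
    rho: float
    method: str
    n_support: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")


def _clamp(rho: float) -> float:
    return float(min(1.0, max(0.0, rho)))


def pooled_minor_fraction(a_reads: np.ndarray, b_reads: np.ndarray) -> float:
    """Depth-weighted minor-allele read fraction across het SNPs."""
    a = np.asarray(a_reads, dtype=float)
    b = np.asarray(b_reads, dtype=float)
    total = (a + b).sum()
    if total <= 0:
        raise ValueError("no reads in het SNP set")
    return float(np.minimum(a, b).sum() / total)


def _check_labels(snps: pd.DataFrame, expected: str) -> None:
    if len(snps) == 0:
        raise ValueError("empty het SNP set")
    labels = set(snps["region_label"].unique())
    if labels != {expected}:
        raise ValueError(f"expected only {expected!r} SNPs, got labels {sorted(labels)}")


def cellularity_from_deletion_ai(snps: pd.DataFrame) -> CellularityEstimate:
    """rho from allelic imbalance over hemizygous deletions.

    Reads from the lost allele can only come from non-neoplastic cells:
    f = (1 - rho)/(2 - rho), inverted as rho = (1 - 2f)/(1 - f).
    """
    _check_labels(snps, "deletion")
    f = pooled_minor_fraction(snps["a_reads"].to_numpy(), snps["b_reads"].to_numpy())
    if f >= 1.0:
        rho = 0.0
    else:
        rho = _clamp((1.0 - 2.0 * f) / (1.0 - f))
    return CellularityEstimate(rho=rho, method="deletion_AI", n_support=len(snps))


def cellularity_from_cnloh_ai(snps: pd.DataFrame) -> CellularityEstimate:
    """rho from allelic imbalance over copy-neutral LOH: rho = 1 - 2f."""
    _check_labels(snps, "cnLOH")
    f = pooled_minor_fraction(snps["a_reads"].to_numpy(), snps["b_reads"].to_numpy())
    rho = _clamp(1.0 - 2.0 * f)
    return CellularityEstimate(rho=rho, method="cnLOH_AI", n_support=len(snps))


def _modal_value(mafs: np.ndarray, bandwidth: str | float | None) -> float:
    """Mode of the MAF distribution on (0, 0.6]."""
    if np.ptp(mafs) < 1e-12:
        # Degenerate spread: the mode is the common value; KDE would be singular.
        return float(mafs[0])
    grid = np.linspace(0.001, 0.6, 600)
    try:
        kde = stats.gaussian_kde(mafs, bw_method=bandwidth or "silverman")
        density = kde(grid)
        return float(grid[int(np.argmax(density))])
    except np.linalg.LinAlgError:
        edges = np.arange(0.0, 0.6 + 0.01, 0.01)
        counts, _ = np.histogram(mafs, bins=edges)
        k = int(np.argmax(counts))
        return float((edges[k] + edges[k + 1]) / 2.0)


def cellularity_from_modal_maf(
    mafs: Sequence[float],
    bandwidth: str | float | None = None,
    min_mutations: int = 50,
) -> CellularityEstimate:
    """rho = 2 x modal somatic MAF (kernel-density peak on (0, 0.6])."""
    mafs = np.asarray(mafs, dtype=float)
    if len(mafs) < min_mutations:
        raise ValueError(
            f"modal MAF needs >= {min_mutations} mutations, got {len(mafs)}; "
            "fall back to the median method"
        )
    mode = _modal_value(mafs, bandwidth)
    return CellularityEstimate(rho=_clamp(2.0 * mode), method="modal_MAF",
                               n_support=len(mafs))


def cellularity_from_median_maf(
    mafs_autosomal: Sequence[float],
    mafs_sex: Sequence[float] | None = None,
    sex: str = "female",
) -> CellularityEstimate:
    """rho = 2 x median autosomal MAF; male sex-chromosome MAFs undoubled.

    For males the autosomal estimate (doubled) and the sex-chromosome
    estimate (hemizygous, not doubled) are combined as a mutation-count
    weighted mean.
    """
    auto = np.asarray(mafs_autosomal, dtype=float)
    sexm = np.asarray(mafs_sex if mafs_sex is not None else [], dtype=float)
    use_sex = sex == "male" and len(sexm) > 0
    if len(auto) == 0 and not use_sex:
        raise ValueError("no MAFs supplied")
    parts, weights = [], []
    if len(auto) > 0:
        parts.append(2.0 * float(np.median(auto)))
        weights.append(len(auto))
    if use_sex:
        parts.append(float(np.median(sexm)))
        weights.append(len(sexm))
    rho = float(np.average(parts, weights=weights))
    return CellularityEstimate(rho=_clamp(rho), method="median_MAF",
                               n_support=int(sum(weights)))


def estimate_cellularity(
    het_snps: pd.DataFrame | None,
    mafs_autosomal: Sequence[float] | None = None,
    mafs_sex: Sequence[float] | None = None,
    sex: str = "female",
    min_snps: int = 20,
    min_mutations_modal: int = 50,
    bandwidth: str | float | None = None,
) -> tuple[CellularityEstimate, list[CellularityEstimate]]:
    """Apply every applicable estimator; select by fixed priority.

    Returns the selected estimate and the full list of estimates (for QC
    output, so disagreement between methods stays visible).
    """
    estimates: dict[str, CellularityEstimate] = {}
    if het_snps is not None and len(het_snps) > 0:
        for label, fn in (("deletion", cellularity_from_deletion_ai),
                          ("cnLOH", cellularity_from_cnloh_ai)):
            sub = het_snps[het_snps["region_label"] == label]
            if len(sub) >= min_snps:
                est = fn(sub)
                estimates[est.method] = est
    auto = np.asarray(mafs_autosomal if mafs_autosomal is not None else [], dtype=float)
    sexm = np.asarray(mafs_sex if mafs_sex is not None else [], dtype=float)
    if len(auto) >= min_mutations_modal:
        est = cellularity_from_modal_maf(auto, bandwidth=bandwidth,
                                         min_mutations=min_mutations_modal)
        estimates[est.method] = est
    if len(auto) > 0 or (sex == "male" and len(sexm) > 0):
        est = cellularity_from_median_maf(auto, sexm, sex=sex)
        estimates[est.method] = est
    if not estimates:
        raise ValueError("no cellularity method applicable for this sample")
    for method in METHOD_PRIORITY:
        if method in estimates:
            return estimates[method], list(estimates.values())
    raise AssertionError("unreachable")
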