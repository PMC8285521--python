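"""Cohort-level statistics: hotspot annotation, Fisher/BH overlap analysis.

The mutational-overlap analysis asks whether alterations in pairs of
features (genes, pathways, tumor subtypes) co-occur or exclude each other
more than chance predicts. Features altered in fewer than ``min_mutant``
tumors are excluded up front; every retained unordered pair is tested with a
two-sided Fisher's exact test and the resulting p-values are converted to
q-values with the Benjamini-Hochberg step-up procedure.

Pathway rows of the alteration matrix are the OR of their member genes, so
pathway-vs-member pairs are structurally dependent and excluded from
testing. Tumor subtypes enter as binary indicator features, which lets
subtype-vs-gene enrichment (e.g. a subtype enriched for one gene's
mutations) reuse the same machinery.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "annotate_hotspots",
    "fisher_exact_2x2",
    "bh_fdr",
    "build_alteration_matrix",
    "overlap_analysis",
]

DEFAULT_MIN_MUTANT = 16
DEFAULT_Q_PRIMARY = 0.01

HOTSPOT_COLUMNS = ["gene", "protein_change", "q_value"]


def annotate_hotspots(
    variants: pd.DataFrame,
    hotspots: pd.DataFrame,
    q_primary: float = DEFAULT_Q_PRIMARY,
    relax_secondary: bool = False,
) -> pd.DataFrame:
    """Match variants against a hotspot catalog by gene and protein change.

    A primary match requires the catalog q-value to be below ``q_primary``.
    With ``relax_secondary``, any further hotspot in a gene that already has
    a primary match is also reported (its own q-value recorded), capturing
    secondary hotspots too weak to pass the primary threshold alone.
    Returns matched rows with ``match_type`` in {primary, secondary}.
    """
    if not {"gene", "protein_change"}.issubset(variants.columns):
        raise ValueError("variants need gene and protein_change columns")
    merged = variants.merge(hotspots[HOTSPOT_COLUMNS], on=["gene", "protein_change"],
                            how="inner")
    primary = merged[merged["q_value"] < q_primary].copy()
    primary["match_type"] = "primary"
    if not relax_secondary:
        return primary.reset_index(drop=True)
    anchored_genes = set(primary["gene"])
    secondary = merged[(merged["q_value"] >= q_primary)
                       & merged["gene"].isin(anchored_genes)].copy()
    secondary["match_type"] = "secondary"
    out = pd.concat([primary, secondary], ignore_index=True)
    return out.sort_values(["gene", "q_value"], kind="mergesort").reset_index(drop=True)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    With margins fixed, the count a follows a hypergeometric distribution;
    the two-sided p-value sums the probabilities of all tables whose
    probability does not exceed that of the observed table
    (minimum-likelihood convention, with 1e-12 relative slack for
    floating-point ties). An all-zero table has p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of m * p_(j) / j (capped at 1), where p_(1) <=
    ... <= p_(m) are the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_alteration_matrix(
    sample_alterations: pd.DataFrame,
    samples: list[str],
    pathways: dict[str, list[str]] | None = None,
    subtypes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Binary features x samples matrix from a long alteration table.

    ``sample_alterations`` has columns (sample_id, feature) listing altered
    genes per sample. Pathway rows are the OR of their member gene rows
    (members need not all be present as gene rows). Subtype indicator rows
    (one per subtype label) are appended when ``subtypes`` maps sample ->
    label.
    """
    genes = sorted(set(sample_alterations["feature"]))
    mat = pd.DataFrame(0, index=genes, columns=list(samples), dtype=int)
    for sid, feat in zip(sample_alterations["sample_id"],
                         sample_alterations["feature"]):
        if sid in mat.columns:
            mat.loc[feat, sid] = 1
    if pathways:
        for pw, members in pathways.items():
            present = [g for g in members if g in mat.index]
            row = mat.loc[present].max(axis=0) if present else \
                pd.Series(0, index=mat.columns)
            mat.loc[pw] = row.astype(int)
    if subtypes:
        for label in sorted(set(subtypes.values())):
            mat.loc[f"subtype:{label}"] = [
                int(subtypes.get(s) == label) for s in mat.columns
            ]
    return mat


def overlap_analysis(
    matrix: pd.DataFrame,
    min_mutant: int = DEFAULT_MIN_MUTANT,
    pathway_members: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Pairwise co-occurrence/exclusivity tests over an alteration matrix.

    Features altered in fewer than ``min_mutant`` samples are dropped;
    pathway-vs-member-gene pairs are excluded as structurally dependent. All
    remaining unordered pairs (in sorted feature order) are Fisher-tested and
    BH-corrected across the full set of performed tests. Output is sorted by
    (q, p, feature_a, feature_b).
    """
    if not matrix.isin([0, 1]).all().all():
        raise ValueError("alteration matrix must be binary")
    n_samples = matrix.shape[1]
    counts = matrix.sum(axis=1)
    retained = sorted(counts.index[counts >= min_mutant])
    excluded_pairs = set()
    if pathway_members:
        for pw, members in pathway_members.items():
            for g in members:
                excluded_pairs.add(frozenset((pw, g)))
    rows = []
    for fa, fb in combinations(retained, 2):
        if frozenset((fa, fb)) in excluded_pairs:
            continue
        va = matrix.loc[fa].to_numpy(dtype=bool)
        vb = matrix.loc[fb].to_numpy(dtype=bool)
        a = int((va & vb).sum())
        b = int((va & ~vb).sum())
        c = int((~va & vb).sum())
        d = int((~va & ~vb).sum())
        rows.append({
            "feature_a": fa, "feature_b": fb,
            "a": a, "b": b, "c": c, "d": d,
            "p": fisher_exact_2x2(a, b, c, d),
        })
    if len(rows) < 1:
        return pd.DataFrame(columns=["feature_a", "feature_b", "a", "b", "c",
                                     "d", "p", "q"])
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values(["q", "p", "feature_a", "feature_b"],
                          kind="mergesort").reset_index(drop=True)
    assert (out["a"] + out["b"] + out["c"] + out["d"] == n_samples).all()
    return out
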