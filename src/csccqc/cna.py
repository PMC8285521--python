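"""Focal somatic copy-number event selection and gene annotation.

Segmented copy-number calls are filtered to a short list of focal events by
amplitude (log2 tumor/reference ratio), probe support, and — for
amplifications — corroborating allelic imbalance at germline het SNPs inside
the segment, which guards against hybridization artifacts that shift the
ratio without any real dosage change. Deletions are exempt from the
imbalance requirement by default (a flag extends it). Manually rescued
segments (e.g. an extremely focal event with too few probes) can be supplied
through an explicit allowlist; they are never rescued automatically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "SEGMENT_COLUMNS",
    "allelic_imbalance_test",
    "select_focal_events",
    "annotate_genes",
]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "log2_ratio"]

DEFAULT_AMP_LOG2 = 0.9
DEFAULT_DEL_LOG2 = -1.0
DEFAULT_MIN_PROBES = 20
DEFAULT_AI_ALPHA = 0.01
DEFAULT_MIN_AI_SNPS = 5


def allelic_imbalance_test(snps: pd.DataFrame,
                           min_snps: int = DEFAULT_MIN_AI_SNPS) -> float | None:
    """Exact two-sided binomial test of allelic balance over a segment.

    A- and B-allele reads are pooled across the segment's het SNPs and the
    minor pooled total is tested against Binomial(n, 1/2). Returns the
    p-value, or None when fewer than ``min_snps`` SNPs are available (the
    segment then fails corroboration by default).
    """
    if snps is None or len(snps) < min_snps:
        return None
    a = int(snps["a_reads"].sum())
    b = int(snps["b_reads"].sum())
    n = a + b
    if n == 0:
        return None
    return float(stats.binomtest(min(a, b), n, 0.5, alternative="two-sided").pvalue)


def _snps_in_segment(het_snps: pd.DataFrame | None, chrom: str,
                     start: int, end: int) -> pd.DataFrame | None:
    if het_snps is None or len(het_snps) == 0:
        return None
    mask = (het_snps["chrom"] == chrom) & (het_snps["pos"] - 1 >= start) & \
        (het_snps["pos"] - 1 < end)  # pos is 1-based, segments half-open
    return het_snps.loc[mask]


def select_focal_events(
    segments: pd.DataFrame,
    het_snps: pd.DataFrame | None = None,
    amp_log2: float = DEFAULT_AMP_LOG2,
    del_log2: float = DEFAULT_DEL_LOG2,
    min_probes: int = DEFAULT_MIN_PROBES,
    ai_alpha: float = DEFAULT_AI_ALPHA,
    min_ai_snps: int = DEFAULT_MIN_AI_SNPS,
    require_ai_for_deletions: bool = False,
    allowlist: list[tuple] | None = None,
) -> pd.DataFrame:
    """Filter segments to focal amplifications and deep deletions.

    An amplification requires log2 strictly above ``amp_log2``, at least
    ``min_probes`` supporting probes, and an allelic-imbalance p-value below
    ``ai_alpha``. A deep deletion requires log2 strictly below ``del_log2``
    and the probe support (plus imbalance if ``require_ai_for_deletions``).
    ``allowlist`` entries are (sample_id, chrom, start, end) tuples exempted
    from the probe-support and imbalance requirements (amplitude still
    applies). Returns an events table with evidence columns.
    """
    allow = set(allowlist or [])
    rows = []
    for _, seg in segments.iterrows():
        key = (seg["sample_id"], seg["chrom"], int(seg["start"]), int(seg["end"]))
        allowed = key in allow
        log2 = float(seg["log2_ratio"])
        if log2 > amp_log2:
            event_type = "amplification"
        elif log2 < del_log2:
            event_type = "deep_deletion"
        else:
            continue
        if not allowed and int(seg["n_probes"]) < min_probes:
            continue
        seg_snps = _snps_in_segment(het_snps, seg["chrom"],
                                    int(seg["start"]), int(seg["end"]))
        ai_p = allelic_imbalance_test(seg_snps, min_snps=min_ai_snps)
        needs_ai = event_type == "amplification" or require_ai_for_deletions
        if needs_ai and not allowed:
            if ai_p is None or not ai_p < ai_alpha:
                continue
        rows.append({
            "sample_id": seg["sample_id"],
            "chrom": seg["chrom"],
            "start": int(seg["start"]),
            "end": int(seg["end"]),
            "n_probes": int(seg["n_probes"]),
            "log2_ratio": log2,
            "event_type": event_type,
            "allelic_imbalance_p": np.nan if ai_p is None else ai_p,
            "allowlisted": allowed,
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "start", "end", "n_probes", "log2_ratio",
        "event_type", "allelic_imbalance_p", "allowlisted",
    ])


def annotate_genes(events: pd.DataFrame, gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach overlapping genes (>= 1 bp, half-open semantics) to each event.

    ``gene_intervals`` is BED-like: chrom, start, end, name. Adds a ``genes``
    column (comma-joined, ordered by gene start).
    """
    for col in ("chrom", "start", "end", "name"):
        if col not in gene_intervals.columns:
            raise ValueError(f"gene intervals missing column {col!r}")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in gene_intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), n) for s, e, n in zip(grp["start"], grp["end"], grp["name"])
            if e > s
        )
    genes_col = []
    for _, ev in events.iterrows():
        tree = trees.get(ev["chrom"])
        if tree is None:
            genes_col.append("")
            continue
        hits = sorted(tree.overlap(int(ev["start"]), int(ev["end"])),
                      key=lambda iv: (iv.begin, iv.data))
        genes_col.append(",".join(iv.data for iv in hits))
    out = events.copy()
    out["genes"] = genes_col
    return out
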