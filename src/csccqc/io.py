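"""Readers and writers for the flat-file dialects used across the pipeline.

Everything is plain TSV/BED/bedGraph so cohorts are diffable and portable:

* coverage: 4-column bedGraph (chrom, start, end, depth), no header
* bait territory / gene intervals: BED (chrom, start, end[, name]), no header
* variants: headered TSV with the VariantCall columns
* het SNPs: headered TSV (chrom, pos, a_reads, b_reads, region_label)
* copy-number segments: headered SEG-like TSV
* signature matrix: headered TSV, first column the 96 context labels
* manifest: headered TSV (sample_id, subtype, sex, per-file paths)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .filtering import VARIANT_COLUMNS
from .cellularity import HET_SNP_COLUMNS
from .cna import SEGMENT_COLUMNS

__all__ = [
    "read_bedgraph", "write_bedgraph",
    "read_bed", "write_bed",
    "read_variants", "write_variants",
    "read_het_snps", "write_het_snps",
    "read_segments", "write_segments",
    "read_signature_matrix", "write_signature_matrix",
    "read_manifest", "write_manifest",
    "read_hotspots",
]

MANIFEST_FILE_COLUMNS = [
    "variants", "tumor_coverage", "reference_coverage", "het_snps", "segments",
]


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"],
                     dtype={"chrom": str})
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "depth"]].to_csv(path, sep="\t", header=False,
                                                  index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if df.shape[1] < 3:
        raise ValueError(f"malformed BED file {path}: fewer than 3 columns")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_variants(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, VARIANT_COLUMNS)
    df["gene"] = df["gene"].fillna("")
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_het_snps(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, HET_SNP_COLUMNS)


def write_het_snps(df: pd.DataFrame, path: str | Path) -> None:
    df[HET_SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, SEGMENT_COLUMNS)


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"{path}: signature matrix must have 96 rows, got {df.shape[0]}")
    return df


def write_signature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="context")


def read_manifest(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["sample_id", "subtype", "sex"])


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_hotspots(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["gene", "protein_change", "q_value"])
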