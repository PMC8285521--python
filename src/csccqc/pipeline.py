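"""End-to-end orchestration: cellularity -> footprint -> filter -> burden /
signatures -> focal CNA -> cohort overlap statistics.

Each sample runs independently; a sample whose inputs defeat a required
stage (no applicable cellularity method, zero callable footprint) is
quarantined with a logged reason rather than aborting the cohort, mirroring
how QC failures are excluded rather than patched. The exclusion screen adds
advisory flags for samples that look like poor neoplastic sampling (few
mutations, all near the detection limit) or have under-covered reference
tissue; enforcement is opt-in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as qio
from .cellularity import estimate_cellularity
from .cna import annotate_genes, select_focal_events
from .filtering import filter_somatic_variants
from .footprint import CoverageProfile, callable_footprint
from .signatures import build_spectrum, fit_signature_weights, mutation_burden, uv_fraction
from .stats import build_alteration_matrix, overlap_analysis

logger = logging.getLogger("csccqc")

__all__ = ["RunConfig", "run_pipeline", "exclusion_screen", "DEFAULT_PATHWAYS"]

#: Pathway groupings used for the alteration matrix; gene sets are editable
#: via the pathway config file.
DEFAULT_PATHWAYS: dict[str, list[str]] = {
    "NOTCH": ["NOTCH1", "NOTCH2", "EP300", "CREBBP"],
    "p53": ["TP53", "MDM2", "USP28"],
    "cell_cycle": ["CDKN2A", "CCND1"],
    "SWI_SNF": ["PBRM1", "ARID2", "EZH2"],
    "Hippo": ["FAT1", "AJUBA", "YAP1"],
    "stress": ["CASP8", "CHUK", "NFE2L2"],
    "MAPK_PI3K": ["HRAS", "KRAS", "PIK3CA", "PTEN", "MTOR", "RAP1B"],
}

NONSILENT_EFFECTS = ("missense", "nonsense", "frameshift", "splice")


@dataclass
class RunConfig:
    """Paths and thresholds for a full cohort run."""

    manifest: str
    baits: str
    out_dir: str
    signatures: str | None = None   # falls back to the synthetic catalog
    genes: str | None = None
    pathways: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PATHWAYS.items()})
    min_ref_depth: int = 6
    min_effective_depth: int = 8
    min_total_reads: int = 14
    min_alt_reads: int = 4
    min_ccf: float = 0.40
    amp_log2: float = 0.9
    del_log2: float = -1.0
    min_probes: int = 20
    ai_alpha: float = 0.01
    min_mutant: int = 16
    min_mutations_exclusion: int = 20
    modal_maf_floor: float = 0.10
    min_reference_mean_depth: float = 5.0
    enforce_exclusions: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def exclusion_screen(n_kept_mutations: int, modal_maf: float | None,
                     reference_mean_depth: float,
                     min_mutations: int = 20, modal_maf_floor: float = 0.10,
                     min_reference_mean_depth: float = 5.0) -> list[str]:
    """Advisory QC flags for one sample.

    ``poor_sampling``: few discernible mutations whose MAFs all sit near the
    detection limit (suggesting the neoplastic cells were barely sampled).
    ``low_reference_coverage``: mean reference depth below 5x, which makes
    somatic calls hard to distinguish from germline SNPs.
    """
    flags = []
    if n_kept_mutations < min_mutations and (modal_maf is None
                                             or modal_maf < modal_maf_floor):
        flags.append("poor_sampling")
    if reference_mean_depth < min_reference_mean_depth:
        flags.append("low_reference_coverage")
    return flags


def _maf_arrays(variants: pd.DataFrame, min_alt: int, min_total: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Read-support-prefiltered MAFs split into autosomal and sex-chromosome.

    Used for cellularity only; the CCF filter cannot run yet because it
    needs the cellularity this feeds.
    """
    total = variants["ref_reads"] + variants["alt_reads"]
    ok = (variants["alt_reads"] >= min_alt) & (total >= min_total)
    sub = variants.loc[ok]
    maf = sub["alt_reads"] / (sub["ref_reads"] + sub["alt_reads"])
    is_sex = sub["is_sex_chrom"].astype(bool)
    return maf[~is_sex].to_numpy(), maf[is_sex].to_numpy()


def _process_sample(row: pd.Series, cohort_dir: Path, baits_bp: int,
                    sigs: pd.DataFrame, config: RunConfig) -> dict:
    sid = row["sample_id"]
    variants = qio.read_variants(cohort_dir / row["variants"])
    tumor_cov = qio.read_bedgraph(cohort_dir / row["tumor_coverage"])
    ref_cov = qio.read_bedgraph(cohort_dir / row["reference_coverage"])
    het_snps = qio.read_het_snps(cohort_dir / row["het_snps"])
    segments = qio.read_segments(cohort_dir / row["segments"])

    mafs_auto, mafs_sex = _maf_arrays(variants, config.min_alt_reads,
                                      config.min_total_reads)
    est, all_estimates = estimate_cellularity(
        het_snps, mafs_auto, mafs_sex, sex=row["sex"])
    logger.info("%s cellularity %.3f via %s (%d estimates)", sid, est.rho,
                est.method, len(all_estimates))
    if est.rho <= 0:
        raise RuntimeError("estimated cellularity is zero")

    ref_profile = CoverageProfile(sid, "reference", ref_cov, baits_bp)
    tum_profile = CoverageProfile(sid, "tumor", tumor_cov, baits_bp)
    report = callable_footprint(ref_profile, tum_profile, est.rho,
                                config.min_ref_depth, config.min_effective_depth)
    logger.info("%s callable footprint %d bp (%.1f%%)", sid,
                report.sample_footprint_bp, 100 * report.fraction_callable)
    if report.sample_footprint_bp == 0:
        raise RuntimeError("zero callable footprint")

    decisions = filter_somatic_variants(
        variants, est.rho, sex=row["sex"],
        min_total_reads=config.min_total_reads,
        min_alt_reads=config.min_alt_reads, min_ccf=config.min_ccf)
    kept = decisions[decisions["kept"]]
    logger.info("%s variants kept %d / %d", sid, len(kept), len(decisions))

    burden = mutation_burden(len(kept), report.sample_footprint_bp)
    spectrum = build_spectrum(kept)
    if spectrum.sum() > 0:
        attribution = fit_signature_weights(spectrum, sigs)
        weights = attribution.weights
        unattributed = attribution.unattributed
    else:
        weights = pd.Series(0.0, index=sigs.columns)
        unattributed = 1.0
    uv = uv_fraction(kept)

    events = select_focal_events(
        segments, het_snps, amp_log2=config.amp_log2, del_log2=config.del_log2,
        min_probes=config.min_probes, ai_alpha=config.ai_alpha)

    kept_mafs = kept.loc[~kept["is_sex_chrom"].astype(bool), "maf"].to_numpy()
    modal_maf = float(np.median(kept_mafs)) if len(kept_mafs) else None
    flags = exclusion_screen(
        len(kept), modal_maf, ref_profile.mean_depth(),
        config.min_mutations_exclusion, config.modal_maf_floor,
        config.min_reference_mean_depth)

    profile = {
        "sample_id": sid, "subtype": row["subtype"], "sex": row["sex"],
        "cellularity": est.rho, "cellularity_method": est.method,
        "callable_footprint_bp": report.sample_footprint_bp,
        "fraction_callable": report.fraction_callable,
        "n_variants": len(decisions), "n_kept": len(kept),
        "burden_per_mb": burden, "uv_fraction": uv,
        "unattributed": unattributed,
        "reference_mean_depth": ref_profile.mean_depth(),
        "flags": ";".join(flags),
    }
    for name in sigs.columns:
        profile[f"w_{name}"] = float(weights[name])
    return {"profile": profile, "kept": kept, "events": events,
            "spectrum": spectrum}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over a cohort directory; write cohort outputs.

    Returns a dict with keys ``samples`` (per-sample profile table,
    quarantined samples flagged), ``overlap`` (pairwise Fisher/BH results),
    ``events`` (focal CNA calls, gene-annotated when a gene BED is given) and
    ``matrix`` (the binary alteration matrix).
    """
    cohort_dir = Path(config.manifest).parent
    manifest = qio.read_manifest(config.manifest)
    baits = qio.read_bed(config.baits)
    baits_bp = int((baits["end"] - baits["start"]).sum())
    if config.signatures:
        sigs = qio.read_signature_matrix(config.signatures)
    else:
        from .signatures import synthetic_signature_matrix
        sigs = synthetic_signature_matrix()

    profiles, quarantined = [], []
    kept_frames, event_frames = [], []
    for _, row in manifest.iterrows():
        try:
            result = _process_sample(row, cohort_dir, baits_bp, sigs, config)
        except (RuntimeError, ValueError) as exc:
            logger.warning("%s quarantined: %s", row["sample_id"], exc)
            quarantined.append({"sample_id": row["sample_id"],
                                "subtype": row["subtype"], "sex": row["sex"],
                                "quarantine_reason": str(exc)})
            continue
        profiles.append(result["profile"])
        if len(result["kept"]):
            kept_frames.append(result["kept"])
        if len(result["events"]):
            event_frames.append(result["events"])

    samples = pd.DataFrame(profiles)
    if config.enforce_exclusions:
        analyzed_ids = [p["sample_id"] for p in profiles if not p["flags"]]
    else:
        analyzed_ids = [p["sample_id"] for p in profiles]
    if quarantined:
        samples = pd.concat([samples, pd.DataFrame(quarantined)],
                            ignore_index=True)

    events = pd.concat(event_frames, ignore_index=True) if event_frames else \
        pd.DataFrame()
    if len(events) and config.genes:
        events = annotate_genes(events, qio.read_bed(config.genes))

    # cohort alteration matrix: non-silent kept mutations + focal-event genes
    alt_rows = []
    if kept_frames:
        kept_all = pd.concat(kept_frames, ignore_index=True)
        nonsilent = kept_all[(kept_all["gene"] != "")
                             & kept_all["effect"].isin(NONSILENT_EFFECTS)]
        for sid, gene in zip(nonsilent["sample_id"], nonsilent["gene"]):
            alt_rows.append({"sample_id": sid, "feature": gene})
    if len(events) and "genes" in events.columns:
        for sid, genes_str in zip(events["sample_id"], events["genes"]):
            for gene in filter(None, str(genes_str).split(",")):
                alt_rows.append({"sample_id": sid, "feature": gene})
    subtype_map = dict(zip(manifest["sample_id"], manifest["subtype"]))
    subtype_map = {s: subtype_map[s] for s in analyzed_ids}
    if alt_rows:
        matrix = build_alteration_matrix(
            pd.DataFrame(alt_rows), analyzed_ids,
            pathways=config.pathways, subtypes=subtype_map)
        overlap = overlap_analysis(matrix, min_mutant=config.min_mutant,
                                   pathway_members=config.pathways)
    else:
        matrix = pd.DataFrame()
        overlap = pd.DataFrame()

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples.to_csv(out / "sample_profiles.tsv", sep="\t", index=False)
    if len(events):
        events.to_csv(out / "focal_events.tsv", sep="\t", index=False)
    if len(overlap):
        overlap.to_csv(out / "overlap_results.tsv", sep="\t", index=False)
    if len(matrix):
        matrix.to_csv(out / "alteration_matrix.tsv", sep="\t",
                      index_label="feature")
        long = matrix.reset_index(names="feature").melt(
            id_vars="feature", var_name="sample_id", value_name="altered")
        long[long["altered"] == 1].to_csv(out / "tiling_long.tsv", sep="\t",
                                          index=False)
    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": int(len(manifest)),
        "n_quarantined": int(len(quarantined)),
        "thresholds": {k: v for k, v in asdict(config).items()
                       if isinstance(v, (int, float, bool))},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return {"samples": samples, "overlap": overlap, "events": events,
            "matrix": matrix, "quarantined": quarantined}
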