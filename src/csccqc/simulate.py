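"""Synthetic tumor/reference cohort generator with known ground truth.

Produces cohorts in exactly the flat-file dialects the pipeline consumes, so
every downstream stage can be exercised and validated without controlled-
access data. The sampling model mirrors the two-population mixture that the
estimators invert:

* a fraction rho of cells are neoplastic; read counts at any locus are
  binomial draws whose success probability is the mixture-expected allele
  fraction ``rho * m_t / (rho * c_t + 2 * (1 - rho))`` with ``m_t`` mutant
  (or B-allele) copies and ``c_t`` total tumor copies at the locus;
* trinucleotide contexts of somatic SNVs are multinomial draws from
  ``S @ w``, a per-sample mixture ``w`` of the signature catalog ``S``;
* depth varies smoothly along the territory via a GC-like covariate with
  negative-binomial overdispersion, reproducing the coverage-variability
  failure mode that the callable-footprint machinery exists to absorb;
* a configurable fraction of mutations is subclonal (cancer-cell fraction
  ~ U(0.05, 0.35)) so the 40% clonality filter has true positives and
  negatives;
* arm-level deletions, copy-neutral LOH, focal amplifications and focal deep
  deletions are planted per sample; germline het SNPs inside them are
  oriented with the B allele on the lost/minor haplotype (phase-consistent
  within a segment, as a BAF-segmented CN caller would report them).

The default configuration emulates a five-subtype skin-cancer cohort
(xeroderma pigmentosum, sporadic, azathioprine-treated immunosuppressed,
other immunosuppressed, recessive dystrophic epidermolysis bullosa) with
subtype-specific burden levels, signature mixtures and CASP8 enrichment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .signatures import CONTEXTS_96, synthetic_signature_matrix, uv_content_of_mixture

__all__ = [
    "SubtypeSpec",
    "SimConfig",
    "SampleData",
    "CohortBundle",
    "GroundTruth",
    "simulate_cohort",
    "write_cohort",
    "simulate_het_snp_counts",
    "simulate_clonal_read_counts",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Gene catalog: genes live in the first half of each chromosome's territory;
# arm-level CN events occupy the second half, so they never collide.
GENES_BY_CHROM = {
    "chr1": ["CCND1", "MDM2", "YAP1", "RAP1B", "NOTCH1", "NOTCH2"],
    "chr2": ["CASP8", "CHUK", "NFE2L2", "TP53", "EP300", "CREBBP"],
    "chr3": ["CDKN2A", "PBRM1", "ARID2", "EZH2", "FAT1", "AJUBA"],
    "chr4": ["PTEN", "PIK3CA", "HRAS", "KRAS", "MTOR", "USP28"],
    "chrX": ["KMT2D"],
}
AMP_TARGET_GENES = ("CCND1", "MDM2", "YAP1", "RAP1B")
DEEP_DEL_TARGET_GENES = ("CDKN2A", "PTEN")

_CHROM_FRACTIONS = {"chr1": 0.24, "chr2": 0.24, "chr3": 0.24, "chr4": 0.24,
                    "chrX": 0.04}
_TERRITORY_OFFSET = 1_000_000  # genomic start of each chromosome's bait block

_EFFECTS = ("missense", "nonsense", "splice", "silent")
_EFFECT_PROBS = (0.60, 0.12, 0.05, 0.23)


@dataclass
class SubtypeSpec:
    """Ground-truth profile of one clinical subtype."""

    label: str
    proportion: float
    burden_log_mu: float      # lognormal location of mutations/Mb
    burden_log_sigma: float   # lognormal scale
    signature_alpha: dict[str, float]  # Dirichlet weights over catalog columns
    casp8_enrichment_prob: float = 0.0
    dinucleotide_rate: float = 0.0  # CC>TT events per clonal SNV


def default_subtypes() -> list[SubtypeSpec]:
    """Five-subtype cohort profile (burden medians in mutations/Mb)."""
    return [
        SubtypeSpec("xp", 0.05, np.log(60.0), 0.4,
                    {"UV_XP": 12, "UV": 2, "FLAT": 1}, 0.10, 0.08),
        SubtypeSpec("sporadic", 0.45, np.log(25.0), 0.5,
                    {"UV": 12, "AGEING": 1, "FLAT": 1}, 0.15, 0.06),
        SubtypeSpec("immunosuppressed_aza", 0.15, np.log(45.0), 0.4,
                    {"AZA": 8, "UV": 4, "FLAT": 1}, 0.15, 0.03),
        SubtypeSpec("immunosuppressed_other", 0.20, np.log(10.0), 0.5,
                    {"UV": 8, "AGEING": 2, "FLAT": 1}, 0.15, 0.04),
        SubtypeSpec("rdeb", 0.15, np.log(3.0), 0.5,
                    {"APOBEC": 8, "UV": 2, "FLAT": 1}, 0.70, 0.01),
    ]


@dataclass
class SimConfig:
    """Cohort-level simulation parameters."""

    n_samples: int = 88
    subtype_specs: list[SubtypeSpec] = field(default_factory=default_subtypes)
    cellularity_range: tuple[float, float] = (0.12, 0.99)
    bait_territory_bp: int = 5_000_000
    mean_depth_range: tuple[float, float] = (30.0, 200.0)
    depth_dispersion: float = 8.0   # NB size parameter; larger = less noise
    subclonal_fraction: float = 0.15
    het_snp_density: float = 1.0 / 2000.0  # SNPs per territory bp
    coverage_window_bp: int = 500
    amp_total_copies: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cellularity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("cellularity bounds must lie in (0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.subtype_specs:
            raise ValueError("at least one subtype spec required")
        for spec in self.subtype_specs:
            if any(a < 0 for a in spec.signature_alpha.values()):
                raise ValueError("Dirichlet weights must be non-negative")
        if not 0.0 <= self.subclonal_fraction < 1.0:
            raise ValueError("subclonal_fraction must lie in [0, 1)")


def genome_layout(bait_territory_bp: int) -> pd.DataFrame:
    """Chromosome blocks composing the bait territory (BED-like)."""
    rows = []
    for chrom, frac in _CHROM_FRACTIONS.items():
        length = int(round(bait_territory_bp * frac))
        rows.append({"chrom": chrom, "start": _TERRITORY_OFFSET,
                     "end": _TERRITORY_OFFSET + length})
    return pd.DataFrame(rows)


def gene_intervals(bait_territory_bp: int) -> pd.DataFrame:
    """Deterministic gene catalog laid out in each chromosome's first half."""
    layout = genome_layout(bait_territory_bp)
    rows = []
    for _, blk in layout.iterrows():
        genes = GENES_BY_CHROM[blk["chrom"]]
        half = (blk["end"] - blk["start"]) // 2
        m = len(genes)
        for i, gene in enumerate(genes):
            g_start = blk["start"] + half * i // m
            g_len = max(1000, half // (2 * m))
            rows.append({"chrom": blk["chrom"], "start": int(g_start),
                         "end": int(g_start + g_len), "name": gene})
    return pd.DataFrame(rows)


@dataclass
class SampleData:
    sample_id: str
    subtype: str
    sex: str
    variants: pd.DataFrame
    tumor_coverage: pd.DataFrame
    reference_coverage: pd.DataFrame
    het_snps: pd.DataFrame
    segments: pd.DataFrame


@dataclass
class CohortBundle:
    samples: list[SampleData]
    baits: pd.DataFrame
    genes: pd.DataFrame
    signature_matrix: pd.DataFrame
    config: SimConfig


@dataclass
class GroundTruth:
    """Simulation truth: one row per sample plus the planted CN events."""

    samples: pd.DataFrame       # rho, burden, weights, subtype, sex, ...
    cn_events: pd.DataFrame     # per-event truth incl. expected log2
    signature_names: list[str]


def expected_allele_fraction(rho: float, m_t: float, c_t: float) -> float:
    """Mixture-expected read fraction of an allele with m_t of c_t tumor copies."""
    denom = rho * c_t + 2.0 * (1.0 - rho)
    if denom <= 0:
        return 0.0
    return rho * m_t / denom


def simulate_het_snp_counts(rho: float, region_label: str, n_snps: int,
                            depth: float, rng: np.random.Generator) -> pd.DataFrame:
    """Standalone het-SNP count generator for one CN region type.

    Depth per SNP is Poisson(depth); the B allele is the lost/minor
    haplotype: deletion c_t=1 (B copies 0), cnLOH c_t=2 (B copies 0),
    neutral c_t=2 (B copies 1).
    """
    c_t, m_b = {"deletion": (1, 0), "cnLOH": (2, 0), "neutral": (2, 1)}[region_label]
    # tumor B copies plus one of the two normal copies
    f = (rho * m_b + (1.0 - rho)) / (rho * c_t + 2.0 * (1.0 - rho))
    depths = rng.poisson(depth, size=n_snps)
    depths = np.maximum(depths, 1)
    b = rng.binomial(depths, f)
    a = depths - b
    return pd.DataFrame({
        "chrom": ["chr1"] * n_snps,
        "pos": np.arange(1, n_snps + 1),
        "a_reads": a,
        "b_reads": b,
        "region_label": [region_label] * n_snps,
    })


def simulate_clonal_read_counts(rho: float, n: int, depth: float,
                                rng: np.random.Generator,
                                m_t: int = 1, c_t: int = 2,
                                ccf: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """(alt, ref) read counts for n mutations at the mixture-expected VAF."""
    vaf = expected_allele_fraction(rho, m_t, c_t) * ccf
    depths = np.maximum(rng.poisson(depth, size=n), 1)
    alt = rng.binomial(depths, min(1.0, vaf))
    return alt, depths - alt


def _gc_curve(n_windows: int) -> np.ndarray:
    """Smooth GC-like covariate along the territory, in [~0.3, ~0.6]."""
    x = np.arange(n_windows)
    return 0.45 + 0.10 * np.sin(2 * np.pi * x / 200.0) \
        + 0.05 * np.sin(2 * np.pi * x / 37.0)


def _nb_depths(mean_depth: float, gc: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    mu = mean_depth * np.exp(3.0 * (gc - 0.45))
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _coverage_frame(layout: pd.DataFrame, window: int, mean_depth: float,
                    dispersion: float, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for _, blk in layout.iterrows():
        length = blk["end"] - blk["start"]
        n_win = int(np.ceil(length / window))
        starts = blk["start"] + np.arange(n_win) * window
        ends = np.minimum(starts + window, blk["end"])
        depths = _nb_depths(mean_depth, _gc_curve(n_win), dispersion, rng)
        frames.append(pd.DataFrame({"chrom": blk["chrom"], "start": starts,
                                    "end": ends, "depth": depths}))
    return pd.concat(frames, ignore_index=True)


def _dosage_factor(rho: float, c_t: float) -> float:
    return (rho * c_t + 2.0 * (1.0 - rho)) / 2.0


def _plant_cn_events(sample_id: str, rho: float, layout: pd.DataFrame,
                     genes: pd.DataFrame, amp_copies: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Choose this sample's CN events; all lie within the bait territory."""
    autosomes = [c for c in layout["chrom"] if c != "chrX"]
    events = []
    arm_chroms = list(rng.permutation(autosomes))
    if rng.random() < 0.6:  # arm-level hemizygous deletion
        chrom = arm_chroms.pop()
        blk = layout[layout["chrom"] == chrom].iloc[0]
        mid = (blk["start"] + blk["end"]) // 2
        events.append((chrom, int(mid), int(blk["end"]), "deletion", 1, 0))
    if rng.random() < 0.5:  # arm-level copy-neutral LOH
        chrom = arm_chroms.pop()
        blk = layout[layout["chrom"] == chrom].iloc[0]
        mid = (blk["start"] + blk["end"]) // 2
        events.append((chrom, int(mid), int(blk["end"]), "cnLOH", 2, 0))
    if rng.random() < 0.4:  # focal amplification over a target oncogene
        gene = genes[genes["name"] == rng.choice(AMP_TARGET_GENES)].iloc[0]
        width = max(40_000, 4 * (gene["end"] - gene["start"]))
        start = max(int(gene["start"]) - width // 4,
                    int(layout[layout["chrom"] == gene["chrom"]].iloc[0]["start"]))
        events.append((gene["chrom"], start, start + width, "amplification",
                       amp_copies, 1))
    if rng.random() < 0.3:  # focal homozygous deletion over a suppressor
        gene = genes[genes["name"] == rng.choice(DEEP_DEL_TARGET_GENES)].iloc[0]
        width = max(24_000, 2 * (gene["end"] - gene["start"]))
        start = max(int(gene["start"]) - width // 4,
                    int(layout[layout["chrom"] == gene["chrom"]].iloc[0]["start"]))
        events.append((gene["chrom"], start, start + width, "deep_deletion", 0, 0))
    rows = [{
        "sample_id": sample_id, "chrom": c, "start": s, "end": e,
        "event_type": t, "tumor_copies": ct, "b_copies": mb,
        "true_log2": float(np.log2(max(_dosage_factor(rho, ct), 1e-6))),
    } for c, s, e, t, ct, mb in events]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                       "event_type", "tumor_copies", "b_copies",
                                       "true_log2"])


def _event_tuples(cn_events: pd.DataFrame) -> list[tuple]:
    return list(zip(cn_events["chrom"], cn_events["start"], cn_events["end"],
                    cn_events["event_type"], cn_events["tumor_copies"],
                    cn_events["b_copies"]))


def _local_state(chrom: str, pos0: int, events: list[tuple]) -> tuple[float, float, str]:
    """(c_t, b_copies, event_type) at a 0-based position."""
    for ev_chrom, start, end, ev_type, c_t, m_b in events:
        if ev_chrom == chrom and start <= pos0 < end:
            return float(c_t), float(m_b), ev_type
    return 2.0, 1.0, "neutral"


def _apply_cn_to_coverage(cov: pd.DataFrame, rho: float,
                          cn_events: pd.DataFrame) -> pd.DataFrame:
    """Scale tumor coverage windows by the local dosage factor."""
    cov = cov.copy()
    depth = cov["depth"].to_numpy(dtype=float)
    for _, ev in cn_events.iterrows():
        mask = (cov["chrom"] == ev["chrom"]).to_numpy() & \
            (cov["start"].to_numpy() < ev["end"]) & \
            (cov["end"].to_numpy() > ev["start"])
        depth[mask] = np.round(depth[mask] * _dosage_factor(rho, ev["tumor_copies"]))
    cov["depth"] = depth.astype(int)
    return cov


def _depth_index(cov: pd.DataFrame, layout: pd.DataFrame,
                 window: int) -> dict[str, tuple[int, np.ndarray]]:
    """Per-chromosome (block_start, depth_array) for O(1) window lookups."""
    starts = dict(zip(layout["chrom"], layout["start"]))
    return {chrom: (int(starts[chrom]), grp["depth"].to_numpy())
            for chrom, grp in cov.groupby("chrom")}


def _depth_at(index: dict[str, tuple[int, np.ndarray]], window: int,
              chrom: str, pos0: int) -> int:
    start, depths = index[chrom]
    i = min((pos0 - start) // window, len(depths) - 1)
    return int(depths[i])


def _segments_frame(sample_id: str, rho: float, layout: pd.DataFrame,
                    cn_events: pd.DataFrame, window: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """SEG table tiling the territory: planted events plus neutral remainder."""
    rows = []
    for _, blk in layout.iterrows():
        chrom = blk["chrom"]
        evs = cn_events[cn_events["chrom"] == chrom].sort_values("start")
        cursor = blk["start"]
        pieces = []
        for _, ev in evs.iterrows():
            if ev["start"] > cursor:
                pieces.append((cursor, ev["start"], 2.0))
            pieces.append((ev["start"], ev["end"], float(ev["tumor_copies"])))
            cursor = ev["end"]
        if cursor < blk["end"]:
            pieces.append((cursor, blk["end"], 2.0))
        for start, end, c_t in pieces:
            true_log2 = float(np.log2(max(_dosage_factor(rho, c_t), 1e-6)))
            rows.append({
                "sample_id": sample_id, "chrom": chrom,
                "start": int(start), "end": int(end),
                "n_probes": max(1, int((end - start) // 1500)),
                "log2_ratio": true_log2 + rng.normal(0.0, 0.03),
            })
    return pd.DataFrame(rows)


def _het_snps_frame(rho: float, layout: pd.DataFrame,
                    depth_idx: dict[str, tuple[int, np.ndarray]],
                    cn_events: pd.DataFrame, sex: str, density: float,
                    window: int, rng: np.random.Generator) -> pd.DataFrame:
    events = _event_tuples(cn_events)
    rows = []
    for _, blk in layout.iterrows():
        chrom = blk["chrom"]
        if chrom == "chrX" and sex == "male":
            continue  # hemizygous: no het SNPs
        length = blk["end"] - blk["start"]
        n = rng.poisson(length * density)
        if n == 0:
            continue
        offs = np.sort(rng.choice(length, size=min(n, length), replace=False))
        for off in offs:
            pos0 = int(blk["start"] + off)
            c_t, m_b, ev_type = _local_state(chrom, pos0, events)
            denom = rho * c_t + 2.0 * (1.0 - rho)
            f = (rho * m_b + (1.0 - rho)) / denom if denom > 0 else 0.5
            depth = _depth_at(depth_idx, window, chrom, pos0)
            if depth < 1:
                continue
            b = int(rng.binomial(depth, min(1.0, f)))
            label = ev_type if ev_type in ("deletion", "cnLOH") else "neutral"
            rows.append({"chrom": chrom, "pos": pos0 + 1, "a_reads": depth - b,
                         "b_reads": b, "region_label": label})
    return pd.DataFrame(rows, columns=["chrom", "pos", "a_reads", "b_reads",
                                       "region_label"])


def _context_of_bin(bin_idx: int, rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, alt, trinucleotide) for a 96-class index, random strand."""
    label = CONTEXTS_96[bin_idx]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    tri = five + ref + three
    if rng.random() < 0.5:  # report on the purine strand
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
        tri = "".join(_COMPLEMENT[b] for b in reversed(tri))
    return ref, alt, tri


def _gene_at(genes: pd.DataFrame, chrom: str, pos0: int) -> str:
    hit = genes[(genes["chrom"] == chrom) & (genes["start"] <= pos0)
                & (pos0 < genes["end"])]
    return hit["name"].iloc[0] if len(hit) else ""


def _simulate_sample(sample_id: str, spec: SubtypeSpec, config: SimConfig,
                     sigs: pd.DataFrame, layout: pd.DataFrame,
                     genes: pd.DataFrame,
                     rng: np.random.Generator) -> tuple[SampleData, dict, pd.DataFrame]:
    rho = float(rng.uniform(*config.cellularity_range))
    sex = "male" if rng.random() < 0.5 else "female"
    tumor_mean = float(rng.uniform(*config.mean_depth_range))
    ref_mean = float(rng.uniform(*config.mean_depth_range))
    window = config.coverage_window_bp

    ref_cov = _coverage_frame(layout, window, ref_mean,
                              config.depth_dispersion, rng)
    tumor_cov_raw = _coverage_frame(layout, window, tumor_mean,
                                    config.depth_dispersion, rng)
    cn_events = _plant_cn_events(sample_id, rho, layout, genes,
                                 config.amp_total_copies, rng)
    tumor_cov = _apply_cn_to_coverage(tumor_cov_raw, rho, cn_events)
    depth_idx = _depth_index(tumor_cov, layout, window)
    events = _event_tuples(cn_events)

    het_snps = _het_snps_frame(rho, layout, depth_idx, cn_events, sex,
                               config.het_snp_density, window, rng)
    segments = _segments_frame(sample_id, rho, layout, cn_events, window, rng)

    # signature mixture and mutation counts
    alpha = np.array([spec.signature_alpha.get(c, 0.0) for c in sigs.columns])
    if len(spec.signature_alpha) and not set(spec.signature_alpha) <= set(sigs.columns):
        unknown = sorted(set(spec.signature_alpha) - set(sigs.columns))
        raise ValueError(f"subtype {spec.label!r} references unknown signatures {unknown}")
    if alpha.sum() <= 0:
        raise ValueError(f"subtype {spec.label!r} has an all-zero Dirichlet weight vector")
    w = rng.dirichlet(np.where(alpha > 0, alpha, 1e-9))
    context_probs = sigs.to_numpy() @ w
    context_probs = context_probs / context_probs.sum()

    territory_mb = config.bait_territory_bp / 1e6
    true_burden = float(rng.lognormal(spec.burden_log_mu, spec.burden_log_sigma))
    n_clonal = int(rng.poisson(true_burden * territory_mb))
    n_sub = int(rng.poisson(true_burden * territory_mb * config.subclonal_fraction))

    blocks = layout.set_index("chrom")
    chrom_labels = layout["chrom"].to_numpy()
    chrom_lengths = (layout["end"] - layout["start"]).to_numpy()
    chrom_p = chrom_lengths / chrom_lengths.sum()

    var_rows = []

    def add_snv(clonal: bool, forced_gene: str | None = None) -> None:
        if forced_gene:
            g = genes[genes["name"] == forced_gene].iloc[0]
            chrom = g["chrom"]
            pos0 = int(rng.integers(g["start"], g["end"]))
        else:
            chrom = str(rng.choice(chrom_labels, p=chrom_p))
            blk = blocks.loc[chrom]
            pos0 = int(rng.integers(blk["start"], blk["end"]))
        bin_idx = int(rng.choice(96, p=context_probs))
        ref, alt, tri = _context_of_bin(bin_idx, rng)
        is_sex = chrom == "chrX"
        c_t, _, _ = _local_state(chrom, pos0, events)
        m_t = 1.0
        if is_sex and sex == "male":
            c_t = 1.0
        ccf = 1.0 if clonal else float(rng.uniform(0.05, 0.35))
        vaf = expected_allele_fraction(rho, m_t, c_t) * ccf
        depth = _depth_at(depth_idx, window, chrom, pos0)
        alt_reads = int(rng.binomial(depth, min(1.0, vaf))) if depth > 0 else 0
        gene = forced_gene or _gene_at(genes, chrom, pos0)
        effect = str(rng.choice(_EFFECTS, p=_EFFECT_PROBS)) if gene else "other"
        var_rows.append({
            "sample_id": sample_id, "chrom": chrom, "pos": pos0 + 1,
            "ref": ref, "alt": alt, "ref_reads": depth - alt_reads,
            "alt_reads": alt_reads, "trinucleotide_context": tri,
            "variant_class": "SNV", "gene": gene, "effect": effect,
            "is_sex_chrom": is_sex, "true_clonal": clonal,
        })

    for _ in range(n_clonal):
        add_snv(clonal=True)
    for _ in range(n_sub):
        add_snv(clonal=False)
    if spec.casp8_enrichment_prob > 0 and rng.random() < spec.casp8_enrichment_prob:
        add_snv(clonal=True, forced_gene="CASP8")
        n_clonal += 1

    n_dinuc = int(rng.binomial(n_clonal, min(1.0, spec.dinucleotide_rate))) \
        if n_clonal else 0
    for _ in range(n_dinuc):
        chrom = str(rng.choice(chrom_labels, p=chrom_p))
        blk = blocks.loc[chrom]
        pos0 = int(rng.integers(blk["start"], blk["end"]))
        c_t, _, _ = _local_state(chrom, pos0, events)
        if chrom == "chrX" and sex == "male":
            c_t = 1.0
        vaf = expected_allele_fraction(rho, 1.0, c_t)
        depth = _depth_at(depth_idx, window, chrom, pos0)
        alt_reads = int(rng.binomial(depth, min(1.0, vaf))) if depth > 0 else 0
        var_rows.append({
            "sample_id": sample_id, "chrom": chrom, "pos": pos0 + 1,
            "ref": "CC", "alt": "TT", "ref_reads": depth - alt_reads,
            "alt_reads": alt_reads, "trinucleotide_context": "TCC",
            "variant_class": "dinucleotide", "gene": _gene_at(genes, chrom, pos0),
            "effect": "other", "is_sex_chrom": chrom == "chrX",
            "true_clonal": True,
        })

    variants = pd.DataFrame(var_rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads",
        "trinucleotide_context", "variant_class", "gene", "effect",
        "is_sex_chrom", "true_clonal",
    ])
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort") \
        .reset_index(drop=True)

    truth_row = {
        "sample_id": sample_id, "subtype": spec.label, "sex": sex, "rho": rho,
        "true_burden": true_burden,
        "n_clonal": int(n_clonal + n_dinuc), "n_subclonal": n_sub,
        "tumor_mean_depth": tumor_mean, "reference_mean_depth": ref_mean,
        "uv_content": uv_content_of_mixture(sigs, w),
    }
    for name, wi in zip(sigs.columns, w):
        truth_row[f"w_{name}"] = float(wi)
    sample = SampleData(sample_id, spec.label, sex, variants, tumor_cov,
                        ref_cov, het_snps, segments)
    return sample, truth_row, cn_events


def simulate_cohort(config: SimConfig,
                    signature_matrix: pd.DataFrame | None = None
                    ) -> tuple[CohortBundle, GroundTruth]:
    """Generate a cohort bundle plus its ground truth (seed-deterministic)."""
    sigs = signature_matrix if signature_matrix is not None \
        else synthetic_signature_matrix()
    if sigs.shape[0] != 96:
        raise ValueError("signature matrix must have 96 context rows")
    rng = np.random.default_rng(config.seed)
    layout = genome_layout(config.bait_territory_bp)
    genes = gene_intervals(config.bait_territory_bp)

    props = np.array([s.proportion for s in config.subtype_specs], dtype=float)
    props = props / props.sum()
    samples, truth_rows, cn_frames = [], [], []
    for i in range(config.n_samples):
        spec = config.subtype_specs[int(rng.choice(len(props), p=props))]
        sample_id = f"S{i + 1:03d}"
        sample, truth_row, cn_events = _simulate_sample(
            sample_id, spec, config, sigs, layout, genes, rng)
        samples.append(sample)
        truth_rows.append(truth_row)
        if len(cn_events):
            cn_frames.append(cn_events)
    truth = GroundTruth(
        samples=pd.DataFrame(truth_rows),
        cn_events=pd.concat(cn_frames, ignore_index=True) if cn_frames
        else pd.DataFrame(columns=["sample_id", "chrom", "start", "end",
                                   "event_type", "tumor_copies", "b_copies",
                                   "true_log2"]),
        signature_names=list(sigs.columns),
    )
    bundle = CohortBundle(samples=samples, baits=layout, genes=genes,
                          signature_matrix=sigs, config=config)
    return bundle, truth


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write every cohort file plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qio.write_bed(bundle.baits.assign(name="bait"), out / "baits.bed")
    qio.write_bed(bundle.genes, out / "genes.bed")
    qio.write_signature_matrix(bundle.signature_matrix, out / "signatures.tsv")
    rows = []
    for s in bundle.samples:
        paths = {
            "variants": f"{s.sample_id}.variants.tsv",
            "tumor_coverage": f"{s.sample_id}.tumor.bedgraph",
            "reference_coverage": f"{s.sample_id}.reference.bedgraph",
            "het_snps": f"{s.sample_id}.hetsnps.tsv",
            "segments": f"{s.sample_id}.seg.tsv",
        }
        qio.write_variants(s.variants, out / paths["variants"])
        qio.write_bedgraph(s.tumor_coverage, out / paths["tumor_coverage"])
        qio.write_bedgraph(s.reference_coverage, out / paths["reference_coverage"])
        qio.write_het_snps(s.het_snps, out / paths["het_snps"])
        qio.write_segments(s.segments, out / paths["segments"])
        rows.append({"sample_id": s.sample_id, "subtype": s.subtype,
                     "sex": s.sex, **paths})
    manifest = pd.DataFrame(rows)
    manifest_path = out / "manifest.tsv"
    qio.write_manifest(manifest, manifest_path)
    return manifest_path


def cohort_hash(out_dir: str | Path) -> str:
    """SHA-256 over every file in a written cohort (order-stable)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).glob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
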