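"""Mutation burden, 96-context spectra, signature refitting, UV fraction.

The trinucleotide spectrum uses the standard strand-collapsed convention:
every single-nucleotide substitution is expressed with a pyrimidine (C or T)
reference base, reverse-complementing context and alleles when the call is
reported on the purine strand. The 96 classes are ordered by substitution
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' base (A, C, G, T), then 3' base.

Signature attribution refits a sample spectrum against a fixed catalog of
signature probability vectors by nonnegative least squares — the same
objective as iterative refitting tools, solved directly and
deterministically. The UV fraction is a simpler, signature-free statistic:
the fraction of substitution events that are C>T at the 3' base of a
dipyrimidine or CC>TT dinucleotide changes, the canonical UV photoproduct
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXTS_96",
    "SignatureAttribution",
    "mutation_burden",
    "pyrimidine_context",
    "context_bin",
    "build_spectrum",
    "fit_signature_weights",
    "uv_fraction",
    "synthetic_signature_matrix",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 strand-collapsed classes, e.g. "A[C>T]G".
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_context(ref: str, alt: str, trinucleotide: str) -> tuple[str, str, str]:
    """Collapse a substitution onto the pyrimidine strand.

    Returns (ref, alt, trinucleotide) with ref in {C, T}. ``trinucleotide``
    is the 3-mer centered on the reference base as reported.
    """
    ref, alt = ref.upper(), alt.upper()
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in _BASES for b in tri) or tri[1] != ref:
        raise ValueError(f"malformed trinucleotide context {trinucleotide!r} for ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in ("A", "G"):
        return _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(tri)
    return ref, alt, tri


def context_bin(ref: str, alt: str, trinucleotide: str) -> int:
    """Index of a substitution in the 96-class spectrum."""
    ref, alt, tri = pyrimidine_context(ref, alt, trinucleotide)
    label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
    return _CONTEXT_INDEX[label]


def mutation_burden(n_clonal_mutations: int, callable_footprint_bp: int) -> float:
    """Clonal mutations per megabase of callable footprint."""
    if callable_footprint_bp <= 0:
        raise ValueError("callable footprint must be positive")
    if n_clonal_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    return n_clonal_mutations / (callable_footprint_bp / 1e6)


def build_spectrum(variants: pd.DataFrame) -> np.ndarray:
    """96-bin trinucleotide spectrum of the SNVs in a variant table.

    Non-SNV rows (indels, dinucleotides) are ignored. The total equals the
    number of contributing SNVs.
    """
    spectrum = np.zeros(96, dtype=float)
    if len(variants) == 0:
        return spectrum
    snvs = variants[variants["variant_class"] == "SNV"]
    for ref, alt, tri in zip(snvs["ref"], snvs["alt"],
                             snvs["trinucleotide_context"]):
        spectrum[context_bin(ref, alt, tri)] += 1
    return spectrum


@dataclass
class SignatureAttribution:
    """Result of refitting a spectrum against a signature catalog."""

    weights: pd.Series  # indexed by signature name, >= 0
    unattributed: float
    reconstruction_error: float

    def __post_init__(self) -> None:
        total = float(self.weights.sum()) + self.unattributed
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weights + unattributed must sum to 1, got {total}")


def _validate_signature_matrix(sigs: pd.DataFrame) -> None:
    if sigs.shape[0] != 96:
        raise ValueError(f"signature matrix must have 96 context rows, got {sigs.shape[0]}")
    if (sigs.values < 0).any():
        raise ValueError("signature probabilities must be non-negative")
    colsums = sigs.sum(axis=0).to_numpy()
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("each signature column must sum to 1")


def fit_signature_weights(
    spectrum: np.ndarray,
    sigs: pd.DataFrame,
    prune_below: float = 0.0,
) -> SignatureAttribution:
    """Nonnegative least-squares refit of a spectrum onto a signature catalog.

    The spectrum is normalized to a probability vector p and
    min ||p - S w||_2 subject to w >= 0 is solved exactly. Weights below
    ``prune_below`` are zeroed and the survivors rescaled to preserve the
    attributed total (mirroring the pruning convention of iterative refitting
    tools). ``unattributed = max(0, 1 - sum(w))``; if the solver attributes
    slightly more than 1, weights are renormalized onto the simplex.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.sum() <= 0:
        raise ValueError("empty spectrum")
    _validate_signature_matrix(sigs)
    p = spectrum / spectrum.sum()
    w, _ = nnls(sigs.to_numpy(), p)
    if prune_below > 0:
        pre_total = w.sum()
        w[w < prune_below] = 0.0
        retained = w.sum()
        if retained > 0:
            w *= pre_total / retained
    total = w.sum()
    if total > 1.0:
        w /= total
        total = 1.0
    unattributed = max(0.0, 1.0 - total)
    residual = float(np.linalg.norm(p - sigs.to_numpy() @ w))
    return SignatureAttribution(
        weights=pd.Series(w, index=sigs.columns, name="weight"),
        unattributed=float(unattributed),
        reconstruction_error=residual,
    )


def uv_fraction(variants: pd.DataFrame) -> float:
    """Fraction of substitution events bearing the canonical UV stamp.

    Numerator: C>T SNVs whose 5' neighbor on the pyrimidine strand is a
    pyrimidine (the mutated C is the 3' base of a dipyrimidine), plus CC>TT
    dinucleotide events (each counted once). Denominator: all SNV plus
    dinucleotide events. Returns 0.0 on an empty denominator.
    """
    if len(variants) == 0:
        return 0.0
    snvs = variants[variants["variant_class"] == "SNV"]
    dinucs = variants[variants["variant_class"] == "dinucleotide"]
    denom = len(snvs) + len(dinucs)
    if denom == 0:
        return 0.0
    n_uv = 0
    for ref, alt, tri in zip(snvs["ref"], snvs["alt"],
                             snvs["trinucleotide_context"]):
        pref, palt, ptri = pyrimidine_context(ref, alt, tri)
        if pref == "C" and palt == "T" and ptri[0] in ("C", "T"):
            n_uv += 1
    for ref, alt in zip(dinucs["ref"], dinucs["alt"]):
        ra = (ref.upper(), alt.upper())
        if ra == ("CC", "TT") or ra == ("GG", "AA"):
            n_uv += 1
    return n_uv / denom


def uv_content_of_mixture(sigs: pd.DataFrame, weights: np.ndarray) -> float:
    """Expected dipyrimidine-C>T fraction of SNVs drawn from S @ w."""
    probs = sigs.to_numpy() @ np.asarray(weights, dtype=float)
    probs = probs / probs.sum()
    mask = np.array([
        label[2:5] == "C>T" and label[0] in ("C", "T") for label in CONTEXTS_96
    ])
    return float(probs[mask].sum())


def aggregate_spectra(spectra: list[np.ndarray]) -> np.ndarray:
    """Subtype-level 96 spectrum: plain sum over sample spectra."""
    if not spectra:
        return np.zeros(96, dtype=float)
    return np.sum(np.stack(spectra), axis=0)


def _context_probs(weight_fn) -> np.ndarray:
    probs = np.array([weight_fn(label) for label in CONTEXTS_96], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ValueError("signature has no support")
    return probs / total


def synthetic_signature_matrix() -> pd.DataFrame:
    """A deterministic synthetic catalog of 6 mutational processes.

    Synthetic stand-in for a published signature catalog (which is
    third-party data and must be supplied by the user): one UV-like column
    concentrated on C>T at dipyrimidines, an XP-variant UV column with a
    shifted context preference, an azathioprine-like T>C column, an
    APOBEC-like column (C>T/C>G at TpCpW), an ageing-like CpG deamination
    column, and a flat background. Columns sum to 1.
    """
    def uv(label: str) -> float:
        sub, five, three = label[2:5], label[0], label[6]
        if sub != "C>T" or five not in ("C", "T"):
            return 0.0
        return 3.0 if five == "T" else 1.5

    def uv_xp(label: str) -> float:
        sub, five, three = label[2:5], label[0], label[6]
        if sub != "C>T" or five not in ("C", "T"):
            return 0.0
        # XP tumors lack transcription-coupled repair; shift the 3' preference.
        return 2.5 if three in ("A", "T") else 0.5

    def aza(label: str) -> float:
        sub, five = label[2:5], label[0]
        if sub != "T>C":
            return 0.0
        return 2.0 if five in ("G", "C") else 1.0

    def apobec(label: str) -> float:
        sub, five, three = label[2:5], label[0], label[6]
        if five == "T" and sub in ("C>T", "C>G") and three in ("A", "T"):
            return 1.0
        return 0.0

    def ageing(label: str) -> float:
        sub, three = label[2:5], label[6]
        if sub == "C>T" and three == "G":
            return 1.0
        return 0.0

    def flat(label: str) -> float:
        return 1.0

    columns = {
        "UV": uv, "UV_XP": uv_xp, "AZA": aza,
        "APOBEC": apobec, "AGEING": ageing, "FLAT": flat,
    }
    data = {name: _context_probs(fn) for name, fn in columns.items()}
    return pd.DataFrame(data, index=list(CONTEXTS_96))
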