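"""Conservation-guided simulated variants.

Enumerates every missense change reachable from a coding transcript by a
single nucleotide substitution (the codon context constrains which amino
acids are reachable), labels candidates from the conservation profile —
pathogenic-like when the residue is conserved (one amino acid above 50% of
aligned sequences), benign-like when the mutant amino acid itself is seen
in more than 10% of aligned sequences — and subsamples a fixed fraction to
keep training tractable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .curation import AA1_TO_3, ProteinVariant, VariantClass
from .msa import AA_INDEX, ConservationProfile

__all__ = [
    "CodingTranscript",
    "SimulatedVariant",
    "SimLabel",
    "SimConfig",
    "reachable_missense",
    "enumerate_candidates",
    "classify_candidate",
    "sample_simulated",
    "simulate_transcript",
]

NUCLEOTIDES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = set(_STANDARD.stop_codons)


class SimLabel(str, enum.Enum):
    PATHOGENIC_LIKE = "pathogenic_like"
    BENIGN_LIKE = "benign_like"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class CodingTranscript:
    """Protein sequence plus its coding nucleotides (stop codon excluded)."""

    transcript_id: str
    protein: str
    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) != 3 * len(self.protein):
            raise ValueError(
                f"cds length {len(self.cds)} is not 3x protein length "
                f"{len(self.protein)}"
            )
        if self.protein and str(Seq(self.cds).translate()) != self.protein:
            raise ValueError(
                f"cds of {self.transcript_id} does not translate to its protein"
            )

    def codon(self, position: int) -> str:
        """Codon for a 1-based residue position."""
        return self.cds[3 * (position - 1): 3 * position]


@dataclass(frozen=True)
class SimulatedVariant:
    variant: ProteinVariant
    sim_label: SimLabel

    def __post_init__(self) -> None:
        if self.sim_label is SimLabel.UNLABELED:
            raise ValueError("simulated variants must carry a definite label")


@dataclass(frozen=True)
class SimConfig:
    conserved_threshold: float = 0.5     # strict >
    benign_freq_threshold: float = 0.1   # strict >
    sample_fraction: float = 0.10
    seed: int = 0
    precedence: str = "benign_first"     # or "pathogenic_first"

    def __post_init__(self) -> None:
        for name in ("conserved_threshold", "benign_freq_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")
        if self.precedence not in {"benign_first", "pathogenic_first"}:
            raise ValueError(f"unknown precedence {self.precedence!r}")


def reachable_missense(codon: str) -> set[str]:
    """Amino acids reachable from ``codon`` by one nucleotide substitution.

    Excludes the reference amino acid and stop codons, so the result is the
    set of missense changes the trinucleotide context allows (at most 9
    candidate codons exist).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} encodes no residue")
    ref = CODON_TO_AA[codon]
    out: set[str] = set()
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            alt_codon = codon[:i] + nt + codon[i + 1:]
            if alt_codon in STOP_CODONS:
                continue
            aa = CODON_TO_AA[alt_codon]
            if aa != ref:
                out.add(aa)
    return out


def enumerate_candidates(tx: CodingTranscript) -> list[ProteinVariant]:
    """All single-nucleotide missense candidates of a transcript.

    Deterministic order: position ascending, then alternate residue
    alphabetically. One candidate per (position, alt) pair even when
    several substitutions reach the same amino acid.
    """
    out: list[ProteinVariant] = []
    for pos in range(1, len(tx.protein) + 1):
        ref = tx.protein[pos - 1]
        for alt in sorted(reachable_missense(tx.codon(pos))):
            term = f"p.{AA1_TO_3[ref]}{pos}{AA1_TO_3[alt]}"
            out.append(
                ProteinVariant(tx.transcript_id, term, VariantClass.MISSENSE,
                               pos, ref_aa=ref, alt_aa=alt)
            )
    return out


def classify_candidate(
    v: ProteinVariant, profile: ConservationProfile, cfg: SimConfig | None = None
) -> SimLabel:
    """Label one candidate from the conservation profile.

    Benign-like when the mutant amino acid's frequency exceeds the 10%
    tolerance threshold; pathogenic-like when the residue is conserved (max
    frequency above 50%). When both rules fire (a conserved column with a
    tolerated minor residue) ``cfg.precedence`` decides — the default
    ``benign_first`` treats observed tolerance as direct evidence.
    Unreliable residues give no label.
    """
    cfg = cfg or SimConfig()
    if not 1 <= v.position <= profile.length:
        raise IndexError(
            f"position {v.position} outside profile (1..{profile.length})"
        )
    if not profile.reliable[v.position - 1]:
        return SimLabel.UNLABELED
    row = profile.freq[v.position - 1]
    benign = row[AA_INDEX[v.alt_aa]] > cfg.benign_freq_threshold
    pathogenic = row.max() > cfg.conserved_threshold
    if benign and pathogenic:
        return (SimLabel.BENIGN_LIKE if cfg.precedence == "benign_first"
                else SimLabel.PATHOGENIC_LIKE)
    if benign:
        return SimLabel.BENIGN_LIKE
    if pathogenic:
        return SimLabel.PATHOGENIC_LIKE
    return SimLabel.UNLABELED


def sample_simulated(
    labeled: list[SimulatedVariant], cfg: SimConfig | None = None
) -> list[SimulatedVariant]:
    """Seeded uniform subsample without replacement, input order preserved.

    Selects ``round(sample_fraction * len(labeled))`` variants.
    """
    cfg = cfg or SimConfig()
    if not labeled:
        raise ValueError("no labeled variants to sample")
    k = int(round(cfg.sample_fraction * len(labeled)))
    if k >= len(labeled):
        return list(labeled)
    rng = np.random.default_rng(cfg.seed)
    idx = np.sort(rng.choice(len(labeled), size=k, replace=False))
    return [labeled[i] for i in idx]


def simulate_transcript(
    tx: CodingTranscript,
    profile: ConservationProfile,
    cfg: SimConfig | None = None,
    sample: bool = True,
) -> list[SimulatedVariant]:
    """Enumerate, label and (optionally) subsample one transcript's candidates."""
    cfg = cfg or SimConfig()
    labeled = [
        SimulatedVariant(v, lab)
        for v in enumerate_candidates(tx)
        if (lab := classify_candidate(v, profile, cfg)) is not SimLabel.UNLABELED
    ]
    if sample and labeled:
        labeled = sample_simulated(labeled, cfg)
    return labeled
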