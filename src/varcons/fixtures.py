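"""Seeded synthetic fixtures for every input the pipeline consumes.

Generates random coding transcripts, alignments with planted conserved and
polymorphic columns, ClinVar-like report tables with injected conflicts
and unreliable review statuses, gnomAD-like allele-frequency tables,
random substitution-feature tables, and patient cohorts with designated
causal variants. Clinical labels are planted from the conservation
structure (pathogenic at conserved residues, benign at tolerated
polymorphisms, flipped with a small noise rate), so the transfer of
knowledge from conservation data to the clinical task is a learnable,
testable property of the fixtures.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import (AA1_TO_3, CANONICAL_AA, CuratedVariant, ProteinVariant,
                       VariantClass)
from .featurize import (SNVBOX_DIM, FeatureDataset, FeaturizerConfig,
                        build_example)
from .metrics import PatientCohort
from .msa import (Alignment, ConservationProfile, MsaFilterConfig,
                  build_profile, filter_alignment)
from .simulate import (CODON_TO_AA, STOP_CODONS, CodingTranscript, SimConfig,
                       SimLabel, classify_candidate, enumerate_candidates,
                       reachable_missense)

__all__ = [
    "FixtureConfig",
    "ColumnPlan",
    "TrainingBundle",
    "make_transcript",
    "make_msa",
    "make_clinical_labels",
    "make_report_table",
    "make_af_table",
    "make_snvbox_table",
    "make_patient_cohort",
    "make_training_bundle",
    "write_fixture_dir",
]

_NONSTOP_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)


@dataclass(frozen=True)
class FixtureConfig:
    n_transcripts: int = 30
    protein_length: int = 200
    msa_rows: int = 60
    fraction_conserved_columns: float = 0.30
    fraction_polymorphic_columns: float = 0.30
    mean_segment_length: int = 60
    tolerated_alternative_freq: float = 0.30
    background_query_freq: float = 0.45
    gap_rate: float = 0.04
    label_noise: float = 0.10
    n_patients: int = 20
    background_variants_per_patient: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_conserved_columns", "fraction_polymorphic_columns",
                     "tolerated_alternative_freq", "background_query_freq",
                     "gap_rate", "label_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.protein_length < 2 or self.n_transcripts < 1:
            raise ValueError("lengths and counts must be positive")


@dataclass(frozen=True)
class ColumnPlan:
    """Which columns of a planted alignment carry which structure."""

    conserved: frozenset[int]                 # 1-based positions
    polymorphic: dict[int, str] = field(default_factory=dict)  # pos -> tolerated alt


def make_transcript(cfg: FixtureConfig, rng: np.random.Generator,
                    transcript_id: str = "TX0001") -> CodingTranscript:
    """Random coding transcript: initiator Met, then random non-stop codons."""
    codons = ["ATG"]
    codons += [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), cfg.protein_length - 1)
    ]
    cds = "".join(codons)
    protein = "".join(CODON_TO_AA[c] for c in codons)
    return CodingTranscript(transcript_id, protein, cds)


def make_msa(tx: CodingTranscript, cfg: FixtureConfig,
             rng: np.random.Generator) -> tuple[Alignment, ColumnPlan]:
    """Alignment with planted conserved and polymorphic columns.

    Conserved columns carry the query residue in every row (above the
    >50% conservation rule by construction); polymorphic columns carry a
    single-nucleotide-reachable alternative residue at the tolerated
    frequency (above the 10% tolerance rule). Background columns keep the
    query residue just below the conservation threshold. Column kinds are
    assigned in contiguous segments of geometric length
    (``mean_segment_length``), emulating the domain structure of real
    proteins where conservation is spatially autocorrelated. Three
    deliberately bad rows (two low-overlap, one low-identity) exercise row
    filtering.
    """
    n = len(tx.protein)
    f_cons = cfg.fraction_conserved_columns
    f_poly = cfg.fraction_polymorphic_columns
    kinds = np.empty(n + 1, dtype=object)  # 1-based
    pos = 1
    while pos <= n:
        seg_len = int(rng.geometric(1.0 / max(1, cfg.mean_segment_length)))
        u = rng.random()
        kind = ("conserved" if u < f_cons
                else "polymorphic" if u < f_cons + f_poly else "background")
        kinds[pos: pos + seg_len] = kind
        pos += seg_len
    conserved = {int(p) for p in range(1, n + 1) if kinds[p] == "conserved"}
    polymorphic: dict[int, str] = {}
    for p in range(1, n + 1):
        if kinds[p] != "polymorphic":
            continue
        reachable = sorted(reachable_missense(tx.codon(p)))
        if reachable:
            polymorphic[p] = reachable[int(rng.integers(0, len(reachable)))]
    aa = CANONICAL_AA
    rows = []
    for _ in range(cfg.msa_rows):
        chars = []
        for pos in range(1, n + 1):
            q = tx.protein[pos - 1]
            if pos in conserved:
                c = q
            elif pos in polymorphic:
                c = polymorphic[pos] if rng.random() < cfg.tolerated_alternative_freq else q
            else:
                if rng.random() < cfg.background_query_freq:
                    c = q
                else:
                    c = aa[int(rng.integers(0, 20))]
            if rng.random() < cfg.gap_rate:
                c = "-"
            chars.append(c)
        rows.append("".join(chars))
    # Deliberately filtered rows: sparse coverage and unrelated sequence.
    low_overlap = "".join(
        tx.protein[i] if rng.random() > 0.85 else "-" for i in range(n)
    )
    rows.append(low_overlap)
    rows.append(low_overlap[::-1] if n > 1 else "-")
    rows.append("".join(aa[int(i)] for i in rng.integers(0, 20, n)))
    ids = tuple(f"{tx.transcript_id}_hom{i}" for i in range(len(rows)))
    return Alignment(tx.protein, tuple(rows), ids), ColumnPlan(
        frozenset(conserved), polymorphic)


def make_clinical_labels(
    tx: CodingTranscript,
    profile: ConservationProfile,
    plan: ColumnPlan,
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> list[CuratedVariant]:
    """Planted clinical truth: pathogenic at conserved residues, benign at
    tolerated polymorphisms, each flipped with probability ``label_noise``."""
    out: list[CuratedVariant] = []
    for pos in sorted(plan.conserved):
        alts = sorted(reachable_missense(tx.codon(pos)))
        if not alts:
            continue
        alt = alts[int(rng.integers(0, len(alts)))]
        label = "pathogenic" if rng.random() >= cfg.label_noise else "benign"
        out.append(CuratedVariant(_mk_missense(tx, pos, alt), label, "clinical"))
    for pos in sorted(plan.polymorphic):
        alt = plan.polymorphic[pos]
        label = "benign" if rng.random() >= cfg.label_noise else "pathogenic"
        out.append(CuratedVariant(_mk_missense(tx, pos, alt), label, "clinical"))
    return out


def _mk_missense(tx: CodingTranscript, pos: int, alt: str) -> ProteinVariant:
    ref = tx.protein[pos - 1]
    term = f"p.{AA1_TO_3[ref]}{pos}{AA1_TO_3[alt]}"
    return ProteinVariant(tx.transcript_id, term, VariantClass.MISSENSE, pos,
                          ref_aa=ref, alt_aa=alt)


GOOD_STATUS = "criteria provided, single submitter"
BAD_STATUSES = (
    "no assertion for the individual variant",
    "no assertion criteria provided",
    "no assertion provided",
)


def make_report_table(
    transcripts: list[CodingTranscript],
    curated: list[CuratedVariant],
    cfg: FixtureConfig,
    rng: np.random.Generator,
    n_vus_only: int = 30,
    n_conflicting: int = 30,
    n_bad_review: int = 30,
    n_rescued: int = 20,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Raw ClinVar-like report table plus the expected curation outcome map.

    Clean variants get one or two concordant reports with a reliable review
    status. Injected rows cover the curation edge cases: VUS-only variants,
    variants with contrary reports, variants whose only report has an
    excluded review status (all expected EXCLUDED), and "rescued" variants
    whose contrary report carries an excluded status and is therefore
    filtered before merging (expected to keep the reliable label).
    """
    used: set[tuple[str, str]] = {cv.variant.key for cv in curated}
    rows: list[dict] = []
    expected: dict[str, str] = {}

    def emit(tx_id: str, term: str, label: str, status: str) -> None:
        rows.append({
            "transcript_id": tx_id, "hgvs_p": term, "label": label,
            "review_status": status, "allele_frequency": "",
        })

    for cv in curated:
        v = cv.variant
        primary = ("P" if rng.random() < 0.5 else "LP") \
            if cv.label == "pathogenic" else ("B" if rng.random() < 0.5 else "LB")
        emit(v.transcript_id, v.hgvs_p, primary, GOOD_STATUS)
        if rng.random() < 0.3:  # occasional concordant second report
            emit(v.transcript_id, v.hgvs_p, "VUS", GOOD_STATUS)
        expected[f"{v.transcript_id}:{v.hgvs_p}"] = cv.label

    def fresh_variant() -> ProteinVariant:
        while True:
            tx = transcripts[int(rng.integers(0, len(transcripts)))]
            pos = int(rng.integers(1, len(tx.protein) + 1))
            alts = sorted(reachable_missense(tx.codon(pos)))
            if not alts:
                continue
            v = _mk_missense(tx, pos, alts[int(rng.integers(0, len(alts)))])
            if v.key not in used:
                used.add(v.key)
                return v

    for _ in range(n_vus_only):
        v = fresh_variant()
        for _ in range(int(rng.integers(1, 3))):
            emit(v.transcript_id, v.hgvs_p, "VUS", GOOD_STATUS)
        expected[f"{v.transcript_id}:{v.hgvs_p}"] = "EXCLUDED"
    for _ in range(n_conflicting):
        v = fresh_variant()
        emit(v.transcript_id, v.hgvs_p, "P" if rng.random() < 0.5 else "LP",
             GOOD_STATUS)
        emit(v.transcript_id, v.hgvs_p, "B" if rng.random() < 0.5 else "LB",
             GOOD_STATUS)
        expected[f"{v.transcript_id}:{v.hgvs_p}"] = "EXCLUDED"
    for _ in range(n_bad_review):
        v = fresh_variant()
        emit(v.transcript_id, v.hgvs_p, "P",
             BAD_STATUSES[int(rng.integers(0, len(BAD_STATUSES)))])
        expected[f"{v.transcript_id}:{v.hgvs_p}"] = "EXCLUDED"
    for _ in range(n_rescued):
        v = fresh_variant()
        keep = "pathogenic" if rng.random() < 0.5 else "benign"
        emit(v.transcript_id, v.hgvs_p, "P" if keep == "pathogenic" else "B",
             GOOD_STATUS)
        emit(v.transcript_id, v.hgvs_p, "B" if keep == "pathogenic" else "P",
             BAD_STATUSES[int(rng.integers(0, len(BAD_STATUSES)))])
        expected[f"{v.transcript_id}:{v.hgvs_p}"] = keep

    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True), expected


def make_af_table(
    transcripts: list[CodingTranscript],
    clinical: list[CuratedVariant],
    cfg: FixtureConfig,
    rng: np.random.Generator,
    n_common: int = 60,
    n_rare: int = 30,
    n_overlap: int = 10,
) -> list[tuple[ProteinVariant, float]]:
    """gnomAD-like allele-frequency table.

    ``n_common`` variants above the 0.1% threshold, ``n_rare`` below it,
    and ``n_overlap`` above-threshold variants duplicating clinical entries
    (which curation must drop).
    """
    used = {cv.variant.key for cv in clinical}
    out: list[tuple[ProteinVariant, float]] = []

    def fresh() -> ProteinVariant:
        while True:
            tx = transcripts[int(rng.integers(0, len(transcripts)))]
            pos = int(rng.integers(1, len(tx.protein) + 1))
            alts = sorted(reachable_missense(tx.codon(pos)))
            if not alts:
                continue
            v = _mk_missense(tx, pos, alts[int(rng.integers(0, len(alts)))])
            if v.key not in used:
                used.add(v.key)
                return v

    for _ in range(n_common):
        out.append((fresh(), float(10 ** rng.uniform(-2.8, -0.5))))
    for _ in range(n_rare):
        out.append((fresh(), float(10 ** rng.uniform(-6, -3.2))))
    clin_missense = [cv.variant for cv in clinical
                     if cv.variant.variant_class is VariantClass.MISSENSE]
    if clin_missense:
        picks = rng.choice(len(clin_missense), size=min(n_overlap, len(clin_missense)),
                           replace=False)
        for i in picks:
            out.append((clin_missense[int(i)], float(10 ** rng.uniform(-2.8, -0.5))))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def make_snvbox_table(
    variants: list[ProteinVariant], rng: np.random.Generator,
    coverage: float = 0.7,
) -> dict[tuple[str, str], np.ndarray]:
    """Random 85-dimensional substitution-feature vectors for a subset of
    variants; the remainder stay absent (zero-filled downstream)."""
    out = {}
    for v in variants:
        if rng.random() < coverage:
            out[v.key] = rng.normal(0, 1, SNVBOX_DIM).astype(np.float32)
    return out


def make_patient_cohort(
    cfg: FixtureConfig, rng: np.random.Generator,
    recessive_fraction: float = 0.2,
) -> PatientCohort:
    """Patients with planted causal variants among background variants.

    Causal scores are drawn from a higher distribution than background
    scores (but overlap, so top-k recall is non-trivial); a fraction of
    patients are recessive cases with two causal variants.
    """
    patients = []
    for _ in range(cfg.n_patients):
        n_causal = 2 if rng.random() < recessive_fraction else 1
        n_bg = cfg.background_variants_per_patient
        scores = np.concatenate([
            rng.beta(6, 2, n_causal),   # causal: skewed high
            rng.beta(2, 4, n_bg),       # background: skewed low
        ])
        causal = np.array([True] * n_causal + [False] * n_bg)
        order = rng.permutation(len(scores))
        patients.append((scores[order].tolist(), causal[order].tolist()))
    return PatientCohort.from_lists(patients)


# ---------------------------------------------------------------------------
# Featurized training bundle


@dataclass
class TrainingBundle:
    clinical: FeatureDataset
    conservation: FeatureDataset
    transcripts: list[CodingTranscript]
    profiles: dict[str, ConservationProfile]
    plans: dict[str, ColumnPlan]


def make_training_bundle(
    cfg: FixtureConfig | None = None,
    window_length: int = 41,
    n_clinical: int = 2000,
    n_conservation: int = 6000,
    sim_cfg: SimConfig | None = None,
    msa_cfg: MsaFilterConfig | None = None,
) -> TrainingBundle:
    """End-to-end desk-scale training data.

    Builds transcripts, planted alignments and profiles, plants clinical
    labels, enumerates and labels simulated variants, then featurizes and
    subsamples to the requested dataset sizes. The conservation sample is
    drawn uniformly from all labeled candidates (the labeled pool at desk
    scale is far smaller than genome scale, so the bundle samples to an
    explicit count rather than a fixed fraction).
    """
    cfg = cfg or FixtureConfig()
    sim_cfg = sim_cfg or SimConfig()
    msa_cfg = msa_cfg or MsaFilterConfig()
    rng = np.random.default_rng(cfg.seed)
    fcfg = FeaturizerConfig(window_length=window_length)
    transcripts, profiles, plans = [], {}, {}
    clin_examples, clin_sources = [], []
    cons_examples = []
    for t in range(cfg.n_transcripts):
        tx = make_transcript(cfg, rng, transcript_id=f"TX{t:04d}")
        aln, plan = make_msa(tx, cfg, rng)
        profile = build_profile(filter_alignment(aln, msa_cfg), msa_cfg)
        transcripts.append(tx)
        profiles[tx.transcript_id] = profile
        plans[tx.transcript_id] = plan
        for cv in make_clinical_labels(tx, profile, plan, cfg, rng):
            ex = build_example(cv.variant, tx.protein, profile, None, fcfg,
                               label=1 if cv.label == "pathogenic" else 0)
            clin_examples.append(ex)
            clin_sources.append("clinical")
        for v in enumerate_candidates(tx):
            lab = classify_candidate(v, profile, sim_cfg)
            if lab is SimLabel.UNLABELED:
                continue
            ex = build_example(v, tx.protein, profile, None, fcfg,
                               label=1 if lab is SimLabel.PATHOGENIC_LIKE else 0)
            cons_examples.append(ex)
    if len(clin_examples) > n_clinical:
        keep = np.sort(rng.choice(len(clin_examples), n_clinical, replace=False))
        clin_examples = [clin_examples[i] for i in keep]
        clin_sources = [clin_sources[i] for i in keep]
    if len(cons_examples) > n_conservation:
        keep = np.sort(rng.choice(len(cons_examples), n_conservation, replace=False))
        cons_examples = [cons_examples[i] for i in keep]
    return TrainingBundle(
        clinical=FeatureDataset.from_examples(clin_examples, clin_sources),
        conservation=FeatureDataset.from_examples(
            cons_examples, ["conservation"] * len(cons_examples)),
        transcripts=transcripts,
        profiles=profiles,
        plans=plans,
    )


# ---------------------------------------------------------------------------
# On-disk fixture directory (plain-text formats)


def write_fixture_dir(out_dir, cfg: FixtureConfig | None = None) -> dict:
    """Write FASTA/A3M/TSV/JSON fixtures for the shell pipeline.

    Emits protein and CDS FASTA files, one A3M per transcript, a raw
    report table, an allele-frequency table, a substitution-feature table
    and an expected-outcomes JSON consumed by the test suite. Returns the
    manifest of written paths.
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    (out / "msa").mkdir(parents=True, exist_ok=True)
    transcripts, alignments, plans = [], {}, {}
    for t in range(cfg.n_transcripts):
        tx = make_transcript(cfg, rng, transcript_id=f"TX{t:04d}")
        aln, plan = make_msa(tx, cfg, rng)
        transcripts.append(tx)
        alignments[tx.transcript_id] = aln
        plans[tx.transcript_id] = plan
    with open(out / "proteins.fasta", "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.transcript_id}\n{tx.protein}\n")
    with open(out / "cds.fasta", "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.transcript_id}\n{tx.cds}\n")
    for tx in transcripts:
        aln = alignments[tx.transcript_id]
        with open(out / "msa" / f"{tx.transcript_id}.a3m", "w") as fh:
            fh.write(f">{tx.transcript_id}\n{aln.query}\n")
            for name, row in zip(aln.ids, aln.rows):
                fh.write(f">{name}\n{row}\n")
    msa_cfg = MsaFilterConfig()
    curated: list[CuratedVariant] = []
    for tx in transcripts:
        profile = build_profile(filter_alignment(alignments[tx.transcript_id],
                                                 msa_cfg), msa_cfg)
        curated.extend(
            make_clinical_labels(tx, profile, plans[tx.transcript_id], cfg, rng))
    reports, expected = make_report_table(transcripts, curated, cfg, rng)
    reports.to_csv(out / "reports.tsv", sep="\t", index=False)
    af_table = make_af_table(transcripts, curated, cfg, rng)
    pd.DataFrame([
        {"transcript_id": v.transcript_id, "hgvs_p": v.hgvs_p,
         "allele_frequency": af}
        for v, af in af_table
    ]).to_csv(out / "allele_frequencies.tsv", sep="\t", index=False)
    snv = make_snvbox_table([cv.variant for cv in curated], rng)
    snv_rows = []
    for (tx_id, term), vec in snv.items():
        row = {"transcript_id": tx_id, "hgvs_p": term}
        row.update({f"f{i:02d}": float(x) for i, x in enumerate(vec)})
        snv_rows.append(row)
    pd.DataFrame(snv_rows).to_csv(out / "snvbox.tsv", sep="\t", index=False)
    with open(out / "expected_outcomes.json", "w") as fh:
        json.dump(expected, fh, indent=1, sort_keys=True)
    return {
        "proteins": str(out / "proteins.fasta"),
        "cds": str(out / "cds.fasta"),
        "msa_dir": str(out / "msa"),
        "reports": str(out / "reports.tsv"),
        "allele_frequencies": str(out / "allele_frequencies.tsv"),
        "snvbox": str(out / "snvbox.tsv"),
        "expected_outcomes": str(out / "expected_outcomes.json"),
        "n_transcripts": len(transcripts),
        "n_report_rows": int(len(reports)),
    }
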