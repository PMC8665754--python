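"""Clinical-variant curation.

Parses HGVS protein terms, filters pathogenicity reports by review status,
merges multiple reports per variant into a single binary label, folds in
common population variants (allele frequency above a threshold) as benign,
and balances the resulting training set by oversampling the pathogenic
class.

Label semantics follow standard clinical practice: each report carries one
of the five ClinVar classes pathogenic (P), likely pathogenic (LP),
uncertain significance (VUS), likely benign (LB) and benign (B). A variant
with any P/LP report and no contrary B/LB report is pathogenic; the mirror
rule gives benign; variants with contrary reports or VUS-only evidence are
excluded.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantClass",
    "ProteinVariant",
    "PathogenicityReport",
    "CuratedVariant",
    "CurationConfig",
    "MergedLabel",
    "HgvsParseError",
    "AlphabetError",
    "parse_hgvs_p",
    "passes_review",
    "merge_reports",
    "curate_common",
    "balance_training_set",
    "curate_report_table",
    "read_report_table",
    "write_curated_tsv",
]

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


class HgvsParseError(ValueError):
    """Malformed HGVS protein term."""


class AlphabetError(HgvsParseError):
    """Unrecognised amino-acid code inside an HGVS term."""


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    START_LOST = "start_lost"
    STOP_GAIN = "stop_gain"
    DELETION = "deletion"
    FRAMESHIFT = "frameshift"


class MergedLabel(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class ProteinVariant:
    """One protein-level variant on one transcript.

    ``position`` is the 1-based residue used to center the sequence window:
    the substituted residue for missense, the new initiation site for
    start-lost, the new termination site for stop-gain/frameshift, and the
    first deleted residue for in-frame deletions. ``del_start``/``del_end``
    record the deleted span for deletion-type terms (including the span
    removed by a start-lost variant).
    """

    transcript_id: str
    hgvs_p: str
    variant_class: VariantClass
    position: int
    ref_aa: str | None = None
    alt_aa: str | None = None
    del_start: int | None = None
    del_end: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.variant_class is VariantClass.MISSENSE:
            if self.ref_aa not in AA1_TO_3 or self.alt_aa not in AA1_TO_3:
                raise AlphabetError(
                    f"missense residues must be canonical amino acids: "
                    f"{self.ref_aa!r}>{self.alt_aa!r}"
                )
            if self.ref_aa == self.alt_aa:
                raise ValueError("missense ref_aa must differ from alt_aa")
        elif self.alt_aa is not None:
            raise ValueError(
                f"{self.variant_class.value} variants carry no alt_aa"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Identity for deduplication: transcript + one-letter-normalized term."""
        return (self.transcript_id, normalize_hgvs_p(self.hgvs_p))


@dataclass(frozen=True)
class PathogenicityReport:
    label: str  # one of P, LP, VUS, LB, B
    review_status: str = ""

    def __post_init__(self) -> None:
        if self.label not in {"P", "LP", "VUS", "LB", "B"}:
            raise ValueError(f"unknown pathogenicity class {self.label!r}")


@dataclass(frozen=True)
class CuratedVariant:
    variant: ProteinVariant
    label: str  # pathogenic | benign
    source: str  # clinical | common

    def __post_init__(self) -> None:
        if self.label not in {"pathogenic", "benign"}:
            raise ValueError(f"label must be binary, got {self.label!r}")
        if self.source not in {"clinical", "common"}:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "common" and self.label != "benign":
            raise ValueError("common-population variants are benign by construction")


#: Review-status strings treated as unreliable and dropped before merging.
DEFAULT_EXCLUDED_REVIEW_STATUSES = (
    "no assertion for the individual variant",
    "no assertion criteria provided",
    "no assertion provided",
)


@dataclass(frozen=True)
class CurationConfig:
    af_threshold: float = 0.001
    excluded_review_statuses: tuple[str, ...] = DEFAULT_EXCLUDED_REVIEW_STATUSES
    oversample_factor: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError("af_threshold must lie in [0, 1]")
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")


_RE_SUB = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|\*)$")
_RE_SUB1 = re.compile(r"^p\.([A-Z])(\d+)([A-Z]|\*)$")
_RE_DEL_RANGE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)_([A-Z][a-z]{2})(\d+)del$")
_RE_DEL_ONE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)del$")
_RE_FS = re.compile(
    r"^p\.([A-Z][a-z]{2})(\d+)(?:([A-Z][a-z]{2}))?fs(?:Ter(?:\d+|\?))?$"
)


def _aa1(code3: str, term: str) -> str:
    try:
        return AA3_TO_1[code3]
    except KeyError:
        raise AlphabetError(
            f"unknown amino-acid code {code3!r} in {term!r}"
        ) from None


def parse_hgvs_p(term: str, transcript_id: str = "") -> ProteinVariant:
    """Parse an HGVS protein term into a :class:`ProteinVariant`.

    Supported patterns: substitutions ``p.Gly54Glu``, stop-gains
    ``p.Tyr5Ter``, in-frame deletions ``p.Ala3del`` / ``p.Gly2_Met46del``
    and frameshifts ``p.Thr7fs`` / ``p.Thr7IlefsTer12``. A deletion range
    starting at residue 2 removes everything between the initiator and a
    new start site and is classified start-lost with the range end as the
    centering anchor.
    """
    term = term.strip()
    m = _RE_SUB.match(term)
    if m:
        ref3, pos, alt3 = m.groups()
        ref = _aa1(ref3, term)
        if alt3 in ("Ter", "*"):
            return ProteinVariant(
                transcript_id, term, VariantClass.STOP_GAIN, int(pos), ref_aa=ref
            )
        alt = _aa1(alt3, term)
        if ref == alt:
            raise HgvsParseError(
                f"synonymous term {term!r}: reference equals alternate"
            )
        return ProteinVariant(
            transcript_id, term, VariantClass.MISSENSE, int(pos),
            ref_aa=ref, alt_aa=alt,
        )
    m = _RE_SUB1.match(term)
    if m:
        ref, pos, alt = m.groups()
        if ref not in AA1_TO_3:
            raise AlphabetError(f"unknown amino-acid code {ref!r} in {term!r}")
        if alt == "*":
            return ProteinVariant(
                transcript_id, term, VariantClass.STOP_GAIN, int(pos), ref_aa=ref
            )
        if alt not in AA1_TO_3:
            raise AlphabetError(f"unknown amino-acid code {alt!r} in {term!r}")
        if ref == alt:
            raise HgvsParseError(
                f"synonymous term {term!r}: reference equals alternate"
            )
        return ProteinVariant(
            transcript_id, term, VariantClass.MISSENSE, int(pos),
            ref_aa=ref, alt_aa=alt,
        )
    m = _RE_DEL_RANGE.match(term)
    if m:
        ref3a, start, ref3b, end = m.groups()
        _aa1(ref3a, term), _aa1(ref3b, term)
        start_i, end_i = int(start), int(end)
        if end_i < start_i:
            raise HgvsParseError(f"inverted deletion range in {term!r}")
        if start_i == 2:
            # Everything after the initiator up to a new start site is lost.
            return ProteinVariant(
                transcript_id, term, VariantClass.START_LOST, end_i,
                ref_aa=_aa1(ref3b, term), del_start=start_i, del_end=end_i,
            )
        return ProteinVariant(
            transcript_id, term, VariantClass.DELETION, start_i,
            ref_aa=_aa1(ref3a, term), del_start=start_i, del_end=end_i,
        )
    m = _RE_DEL_ONE.match(term)
    if m:
        ref3, pos = m.groups()
        pos_i = int(pos)
        return ProteinVariant(
            transcript_id, term, VariantClass.DELETION, pos_i,
            ref_aa=_aa1(ref3, term), del_start=pos_i, del_end=pos_i,
        )
    m = _RE_FS.match(term)
    if m:
        ref3, pos, _new3 = m.groups()
        return ProteinVariant(
            transcript_id, term, VariantClass.FRAMESHIFT, int(pos),
            ref_aa=_aa1(ref3, term),
        )
    raise HgvsParseError(f"unsupported HGVS protein term {term!r}")


def normalize_hgvs_p(term: str) -> str:
    """Collapse three-letter codes to one-letter for identity comparison."""
    out = term.strip()
    for code3, code1 in AA3_TO_1.items():
        out = out.replace(code3, code1)
    return out


def passes_review(report: PathogenicityReport, cfg: CurationConfig) -> bool:
    """True unless the report's review status is on the excluded list.

    Matching is exact after case/whitespace normalization, never substring,
    so e.g. "criteria provided, single submitter" is retained.
    """
    status = " ".join(report.review_status.lower().split())
    excluded = {" ".join(s.lower().split()) for s in cfg.excluded_review_statuses}
    return status not in excluded


def merge_reports(reports: list[PathogenicityReport]) -> MergedLabel:
    """Integrate multiple pathogenicity reports into one binary call.

    Any P/LP with no B/LB gives pathogenic; any B/LB with no P/LP gives
    benign; contrary reports, VUS-only evidence, or no reports at all are
    excluded. Permutation-invariant by construction.
    """
    labels = {r.label for r in reports}
    has_path = bool(labels & {"P", "LP"})
    has_ben = bool(labels & {"B", "LB"})
    if has_path and not has_ben:
        return MergedLabel.PATHOGENIC
    if has_ben and not has_path:
        return MergedLabel.BENIGN
    return MergedLabel.EXCLUDED


def curate_common(
    af_table: list[tuple[ProteinVariant, float]],
    clinical: set[ProteinVariant] | list[ProteinVariant],
    cfg: CurationConfig,
) -> list[CuratedVariant]:
    """Select common population variants as benign training examples.

    Keeps variants with allele frequency strictly above ``cfg.af_threshold``
    that are absent from the clinical set (identity = transcript +
    normalized HGVS term), avoiding duplicate samples across sources.
    """
    clinical_keys = {v.key for v in clinical}
    out: list[CuratedVariant] = []
    for variant, af in af_table:
        if af < 0.0 or af > 1.0:
            raise ValueError(f"allele frequency out of range: {af}")
        if af > cfg.af_threshold and variant.key not in clinical_keys:
            out.append(CuratedVariant(variant, "benign", "common"))
    return out


def balance_training_set(
    data: list[CuratedVariant], cfg: CurationConfig, seed: int
) -> list[CuratedVariant]:
    """Oversample pathogenic variants ``oversample_factor``-fold and shuffle.

    Benign variants appear exactly once; the output order is a seeded
    permutation so repeated runs are bit-identical.
    """
    if not data:
        raise ValueError("empty training set")
    expanded: list[CuratedVariant] = []
    for cv in data:
        expanded.extend([cv] * (cfg.oversample_factor if cv.label == "pathogenic" else 1))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(expanded))
    return [expanded[i] for i in order]


# ---------------------------------------------------------------------------
# Tabular I/O

REPORT_COLUMNS = [
    "transcript_id", "hgvs_p", "label", "review_status", "allele_frequency",
]


def read_report_table(path) -> pd.DataFrame:
    """Read a variant report TSV (one row per report, several per variant)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report table missing columns: {sorted(missing)}")
    return df


def curate_report_table(
    reports: pd.DataFrame, cfg: CurationConfig | None = None
) -> tuple[list[CuratedVariant], dict[str, str]]:
    """Run the full clinical curation over a report table.

    Reports failing the review-status filter are dropped first; remaining
    reports are merged per (transcript, term). Returns the curated clinical
    variants plus a per-variant outcome map (``pathogenic`` / ``benign`` /
    ``EXCLUDED``) keyed by ``transcript_id:hgvs_p``.
    """
    cfg = cfg or CurationConfig()
    outcomes: dict[str, str] = {}
    curated: list[CuratedVariant] = []
    grouped: dict[tuple[str, str], list[PathogenicityReport]] = {}
    order: list[tuple[str, str]] = []
    for row in reports.itertuples(index=False):
        key = (row.transcript_id, row.hgvs_p)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        rep = PathogenicityReport(row.label, row.review_status)
        if passes_review(rep, cfg):
            grouped[key].append(rep)
    for tx_id, term in order:
        merged = merge_reports(grouped[(tx_id, term)])
        outcomes[f"{tx_id}:{term}"] = merged.value
        if merged is MergedLabel.EXCLUDED:
            continue
        variant = parse_hgvs_p(term, tx_id)
        curated.append(CuratedVariant(variant, merged.value, "clinical"))
    return curated, outcomes


def write_curated_tsv(curated: list[CuratedVariant], path) -> None:
    rows = [
        {
            "transcript_id": cv.variant.transcript_id,
            "hgvs_p": cv.variant.hgvs_p,
            "variant_class": cv.variant.variant_class.value,
            "position": cv.variant.position,
            "ref_aa": cv.variant.ref_aa or "",
            "alt_aa": cv.variant.alt_aa or "",
            "label": cv.label,
            "source": cv.source,
        }
        for cv in curated
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curated_tsv(path) -> list[CuratedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CuratedVariant(parse_hgvs_p(row.hgvs_p, row.transcript_id),
                           row.label, row.source)
        )
    return out
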