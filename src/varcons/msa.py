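"""Alignment parsing, filtering and conservation profiles.

A multiple sequence alignment of homologs against a query protein is
reduced to a per-residue amino-acid frequency profile. Rows must share
more than 30% identity and at least 80% overlap with the query to count,
and a column needs more than 10 aligned residues from non-query rows
before its frequencies are considered reliable; unreliable columns are
reported as all-zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import CANONICAL_AA

__all__ = [
    "Alignment",
    "MsaFilterConfig",
    "ConservationProfile",
    "parse_a3m",
    "parse_aligned_fasta",
    "sequence_identity",
    "sequence_overlap",
    "filter_alignment",
    "build_profile",
]

GAP = "-"
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class Alignment:
    """Query protein plus gapped homolog rows projected onto query columns."""

    query: str
    rows: tuple[str, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.query)
        for i, row in enumerate(self.rows):
            if len(row) != n:
                raise ValueError(
                    f"row {i} has length {len(row)}, query has {n}"
                )


@dataclass(frozen=True)
class MsaFilterConfig:
    min_identity: float = 0.30   # strict >
    min_overlap: float = 0.80    # >=
    min_depth: int = 10          # strict >
    include_query_in_frequencies: bool = True

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-residue amino-acid frequencies with reliability flags.

    ``freq`` is an N x 20 matrix in the fixed alphabet order; reliable rows
    sum to 1, unreliable rows are all zero. ``depth`` counts aligned
    non-gap residues from non-query rows.
    """

    freq: np.ndarray
    depth: np.ndarray
    reliable: np.ndarray

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def row(self, position: int) -> np.ndarray:
        """Frequency row for a 1-based residue position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside profile (1..{self.length})")
        return self.freq[position - 1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(CANONICAL_AA))
        df.insert(0, "residue", np.arange(1, self.length + 1))
        df["depth"] = self.depth
        df["reliable"] = self.reliable
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ConservationProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            freq=df[list(CANONICAL_AA)].to_numpy(float),
            depth=df["depth"].to_numpy(int),
            reliable=df["reliable"].to_numpy(bool),
        )

    def save_npz(self, path) -> None:
        np.savez(path, freq=self.freq, depth=self.depth, reliable=self.reliable)

    @classmethod
    def load_npz(cls, path) -> "ConservationProfile":
        with np.load(path) as z:
            return cls(freq=z["freq"], depth=z["depth"], reliable=z["reliable"])


def _read_fasta_records(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0] if len(line) > 1 else "", []
        else:
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def parse_a3m(text: str) -> Alignment:
    """Parse an A3M alignment (first record = query).

    Lowercase letters and '.' mark insertions relative to the query and are
    removed, so every surviving column maps 1:1 onto a query residue. A row
    that projects to a different length than the query is a format error.
    """
    records = _read_fasta_records(text)
    if not records:
        raise ValueError("empty alignment")
    query_id, query_raw = records[0]
    query = "".join(c for c in query_raw if not c.islower() and c != ".").upper()
    rows, ids = [], []
    for name, seq in records[1:]:
        projected = "".join(c for c in seq if not c.islower() and c != ".")
        if len(projected) != len(query):
            raise ValueError(
                f"row {name!r} projects to length {len(projected)}, "
                f"query has {len(query)}"
            )
        rows.append(projected.upper())
        ids.append(name)
    return Alignment(query=query, rows=tuple(rows), ids=tuple(ids))


def parse_aligned_fasta(text: str) -> Alignment:
    """Parse an already-aligned FASTA (no insertion states); query first."""
    return parse_a3m(text)


def sequence_identity(query: str, row: str) -> float:
    """Fraction of identical residue pairs over the row's aligned positions."""
    if len(query) != len(row):
        raise ValueError("query and row lengths differ")
    aligned = matches = 0
    for q, r in zip(query, row):
        if r != GAP:
            aligned += 1
            if r == q:
                matches += 1
    return matches / aligned if aligned else 0.0


def sequence_overlap(query: str, row: str) -> float:
    """Fraction of query positions covered by the row (non-gap)."""
    if len(query) != len(row):
        raise ValueError("query and row lengths differ")
    if not query:
        return 0.0
    return sum(1 for c in row if c != GAP) / len(query)


def filter_alignment(aln: Alignment, cfg: MsaFilterConfig | None = None) -> Alignment:
    """Drop rows below the identity (strict) or overlap (inclusive) cutoffs."""
    cfg = cfg or MsaFilterConfig()
    keep_rows, keep_ids = [], []
    ids = aln.ids if aln.ids else ("",) * len(aln.rows)
    for row, name in zip(aln.rows, ids):
        if (sequence_identity(aln.query, row) > cfg.min_identity
                and sequence_overlap(aln.query, row) >= cfg.min_overlap):
            keep_rows.append(row)
            keep_ids.append(name)
    return Alignment(aln.query, tuple(keep_rows),
                     tuple(keep_ids) if aln.ids else ())


def build_profile(aln: Alignment, cfg: MsaFilterConfig | None = None) -> ConservationProfile:
    """Tally per-column amino-acid frequencies from a filtered alignment.

    Depth counts non-gap characters from non-query rows only; the query
    itself contributes to the frequency bins when
    ``include_query_in_frequencies`` is set (default), reflecting the human
    residue in the conservation signal. Non-canonical residues (B, Z, X, U,
    ...) count toward depth but fall into no frequency bin.
    """
    cfg = cfg or MsaFilterConfig()
    n = len(aln.query)
    counts = np.zeros((n, 20), dtype=np.float64)
    depth = np.zeros(n, dtype=np.int64)
    for row in aln.rows:
        for i, c in enumerate(row):
            if c == GAP:
                continue
            depth[i] += 1
            j = AA_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    if cfg.include_query_in_frequencies:
        for i, c in enumerate(aln.query):
            j = AA_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    reliable = depth > cfg.min_depth
    freq = np.zeros_like(counts)
    totals = counts.sum(axis=1)
    ok = reliable & (totals > 0)
    freq[ok] = counts[ok] / totals[ok, None]
    return ConservationProfile(freq=freq, depth=depth, reliable=reliable & (totals > 0))
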