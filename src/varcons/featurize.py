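"""Sequence-window featurization.

Each variant becomes three L x 20 matrices: a one-hot wild-type window, a
one-hot mutant window and the matching slice of the conservation profile.
Windows are centred on the variant site (for truncating classes, on the
residue where the truncation starts or ends); positions outside the
protein, truncated residues and unreliable profile columns all encode to
all-zero rows. An optional 85-dimensional precomputed feature vector
(SNVBox-style substitution descriptors) rides along, zero-filled when the
variant is not in the lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import CANONICAL_AA, ProteinVariant, VariantClass
from .msa import AA_INDEX, ConservationProfile

__all__ = [
    "FeaturizerConfig",
    "EncodedExample",
    "FeatureDataset",
    "ReferenceMismatchError",
    "center_residue",
    "extract_window",
    "apply_mutation",
    "encode_window",
    "decode_window",
    "slice_profile",
    "build_example",
    "SNVBOX_DIM",
]

PAD = "-"
SNVBOX_DIM = 85


class ReferenceMismatchError(ValueError):
    """Window residue disagrees with the variant's stated reference."""


@dataclass(frozen=True)
class FeaturizerConfig:
    """Window geometry and encoding conventions.

    ``window_length`` is odd so the variant sits exactly at the centre
    (201 residues by default). ``pad_stop_site``: a stop codon contributes
    no residue, so the termination site itself is padded along with
    everything beyond it; set False to keep the centre residue.
    ``shift_deletions``: pad deleted spans in place (default) rather than
    shifting downstream sequence into the gap.
    """

    window_length: int = 201
    alphabet: str = CANONICAL_AA
    pad_symbol: str = PAD
    pad_stop_site: bool = True
    shift_deletions: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and positive")
        if len(set(self.alphabet)) != 20:
            raise ValueError("alphabet must contain 20 unique letters")

    @property
    def half(self) -> int:
        return (self.window_length - 1) // 2


@dataclass
class EncodedExample:
    """Model input triple plus optional extras for one variant."""

    wt_mat: np.ndarray
    mut_mat: np.ndarray
    msa_mat: np.ndarray
    snvbox: np.ndarray | None = None
    label: int | None = None
    key: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        shape = self.wt_mat.shape
        if self.mut_mat.shape != shape or self.msa_mat.shape != shape:
            raise ValueError("wt/mut/msa matrices must share one L x 20 shape")
        if shape[1] != 20:
            raise ValueError("matrices must have 20 columns")
        if self.snvbox is not None and self.snvbox.shape != (SNVBOX_DIM,):
            raise ValueError(f"snvbox vector must have length {SNVBOX_DIM}")


def center_residue(v: ProteinVariant) -> int:
    """1-based residue on which the window is centred.

    Missense: the substituted residue. Start-lost: the new initiation
    site. Stop-gain and frameshift: the new termination site (frameshifts
    are treated as terminating at the indel site). Deletion: the first
    deleted residue. Parsing already stores this anchor in ``position``.
    """
    return v.position


def extract_window(protein: str, center: int, cfg: FeaturizerConfig) -> str:
    """Window of ``window_length`` residues centred at ``center`` (1-based).

    Positions hanging over either terminus are filled with the pad symbol.
    """
    if not 1 <= center <= len(protein):
        raise IndexError(
            f"center {center} outside protein (1..{len(protein)})"
        )
    c = center - 1
    lo, hi = c - cfg.half, c + cfg.half + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(protein))
    core = protein[max(0, lo): min(len(protein), hi)]
    return cfg.pad_symbol * left_pad + core + cfg.pad_symbol * right_pad


def apply_mutation(wt_window: str, v: ProteinVariant, cfg: FeaturizerConfig) -> str:
    """Mutant window from a wild-type window extracted at the variant centre.

    Missense substitutes the centre residue. Stop-gain/frameshift pad from
    the centre to the end of the window (the termination site itself is
    padded unless ``pad_stop_site`` is off). Start-lost pads everything
    before the centre (the new initiation site is retained). Deletions pad
    the deleted span in place.
    """
    L = len(wt_window)
    c = cfg.half
    chars = list(wt_window)
    cls = v.variant_class
    if cls is VariantClass.MISSENSE:
        if wt_window[c] != v.ref_aa:
            raise ReferenceMismatchError(
                f"window centre {wt_window[c]!r} does not match "
                f"reference {v.ref_aa!r} for {v.hgvs_p}"
            )
        chars[c] = v.alt_aa
    elif cls in (VariantClass.STOP_GAIN, VariantClass.FRAMESHIFT):
        start = c if cfg.pad_stop_site else c + 1
        for i in range(start, L):
            chars[i] = cfg.pad_symbol
    elif cls is VariantClass.START_LOST:
        for i in range(c):
            chars[i] = cfg.pad_symbol
    elif cls is VariantClass.DELETION:
        del_start = v.del_start if v.del_start is not None else v.position
        del_end = v.del_end if v.del_end is not None else v.position
        # Window position i covers protein residue center - half + i.
        for i in range(L):
            residue = v.position - cfg.half + i
            if del_start <= residue <= del_end:
                chars[i] = cfg.pad_symbol
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown variant class {cls}")
    return "".join(chars)


def encode_window(window: str, cfg: FeaturizerConfig) -> np.ndarray:
    """One-hot encode a window; pad and non-canonical letters are zero rows."""
    mat = np.zeros((len(window), 20), dtype=np.float32)
    for i, ch in enumerate(window):
        j = AA_INDEX.get(ch)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def decode_window(mat: np.ndarray, cfg: FeaturizerConfig) -> str:
    """Inverse of :func:`encode_window` (zero rows decode to the pad symbol)."""
    out = []
    for row in mat:
        if row.sum() == 0:
            out.append(cfg.pad_symbol)
        else:
            out.append(cfg.alphabet[int(row.argmax())])
    return "".join(out)


def slice_profile(
    profile: ConservationProfile, center: int, cfg: FeaturizerConfig
) -> np.ndarray:
    """Profile rows for the window; zero rows outside the transcript."""
    mat = np.zeros((cfg.window_length, 20), dtype=np.float32)
    c = center - 1
    for i in range(cfg.window_length):
        pos = c - cfg.half + i
        if 0 <= pos < profile.length:
            mat[i] = profile.freq[pos]
    return mat


def build_example(
    v: ProteinVariant,
    protein: str,
    profile: ConservationProfile,
    snvbox_lookup: dict[tuple[str, str], np.ndarray] | None = None,
    cfg: FeaturizerConfig | None = None,
    label: int | None = None,
) -> EncodedExample:
    """Assemble the full model input for one variant.

    The SNVBox-style vector is looked up by the variant's identity key and
    zero-filled when absent, the convention for variants missing from the
    feature database.
    """
    cfg = cfg or FeaturizerConfig()
    center = center_residue(v)
    wt = extract_window(protein, center, cfg)
    mut = apply_mutation(wt, v, cfg)
    snv = None
    if snvbox_lookup is not None:
        snv = np.asarray(
            snvbox_lookup.get(v.key, np.zeros(SNVBOX_DIM)), dtype=np.float32
        )
    return EncodedExample(
        wt_mat=encode_window(wt, cfg),
        mut_mat=encode_window(mut, cfg),
        msa_mat=slice_profile(profile, center, cfg),
        snvbox=snv,
        label=label,
        key=v.key,
    )


@dataclass
class FeatureDataset:
    """Stacked featurized examples ready for batching.

    Arrays: ``wt``, ``mut``, ``msa`` of shape (n, L, 20); ``snvbox``
    (n, 85); ``labels`` (n,) int8 with -1 for unknown; ``keys`` parallel
    list of (transcript_id, normalized term); ``sources`` parallel list of
    example provenance (clinical/common/conservation).
    """

    wt: np.ndarray
    mut: np.ndarray
    msa: np.ndarray
    snvbox: np.ndarray
    labels: np.ndarray
    keys: list[tuple[str, str]] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.wt.shape[0]

    @property
    def window_length(self) -> int:
        return self.wt.shape[1]

    @classmethod
    def from_examples(
        cls, examples: list[EncodedExample], sources: list[str] | None = None
    ) -> "FeatureDataset":
        if not examples:
            raise ValueError("no examples")
        n = len(examples)
        L = examples[0].wt_mat.shape[0]
        wt = np.stack([e.wt_mat for e in examples]).astype(np.float32)
        mut = np.stack([e.mut_mat for e in examples]).astype(np.float32)
        msa = np.stack([e.msa_mat for e in examples]).astype(np.float32)
        snv = np.stack([
            e.snvbox if e.snvbox is not None else np.zeros(SNVBOX_DIM, np.float32)
            for e in examples
        ]).astype(np.float32)
        labels = np.array(
            [e.label if e.label is not None else -1 for e in examples],
            dtype=np.int8,
        )
        keys = [e.key if e.key is not None else ("", "") for e in examples]
        if sources is None:
            sources = ["clinical"] * n
        assert wt.shape == (n, L, 20)
        return cls(wt, mut, msa, snv, labels, keys, list(sources))

    def subset(self, idx) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(
            self.wt[idx], self.mut[idx], self.msa[idx], self.snvbox[idx],
            self.labels[idx],
            [self.keys[i] for i in idx],
            [self.sources[i] for i in idx],
        )

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            wt=self.wt, mut=self.mut, msa=self.msa, snvbox=self.snvbox,
            labels=self.labels,
            keys=np.array(["\t".join(k) for k in self.keys]),
            sources=np.array(self.sources),
        )

    @classmethod
    def load_npz(cls, path) -> "FeatureDataset":
        with np.load(path, allow_pickle=False) as z:
            keys = [tuple(s.split("\t")) for s in z["keys"]]
            return cls(
                z["wt"], z["mut"], z["msa"], z["snvbox"], z["labels"],
                keys, [str(s) for s in z["sources"]],
            )
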