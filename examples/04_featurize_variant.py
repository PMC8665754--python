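"""Sequence windows and matrices for different variant classes.

Shows the centering and zero-padding conventions: missense substitutes
the centre; a stop-gain pads from the new termination site; a start-lost
pads everything before the new initiation site.
"""

from varcons.curation import parse_hgvs_p
from varcons.featurize import (FeaturizerConfig, apply_mutation,
                               encode_window, extract_window)

protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
cfg = FeaturizerConfig(window_length=11)

for term in ("p.Tyr5Phe", "p.Lys8Ter", "p.Gly2_Ile12del", "p.Phe14fs"):
    v = parse_hgvs_p(term, "NP_TOY")
    wt = extract_window(protein, v.position, cfg)
    mut = apply_mutation(wt, v, cfg)
    print(f"{term:16s} ({v.variant_class.value:10s})  wt={wt}  mut={mut}")

mat = encode_window("AY-", FeaturizerConfig(window_length=3))
print("\none-hot rows for 'AY-' (pad row is all zero):")
print(mat.astype(int))
# The '-' rows in the mutant windows are exactly the truncated residues;
# they one-hot encode to zero rows, which the network reads as absence.
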