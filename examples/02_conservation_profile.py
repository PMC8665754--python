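"""From a raw alignment to a per-residue conservation profile.

Parses a tiny A3M alignment (lowercase = insertion relative to the
query), filters rows by identity/overlap, and prints the frequency
profile with reliability flags.
"""

from varcons.msa import MsaFilterConfig, build_profile, filter_alignment, parse_a3m

a3m = """>query
MKTAY
>hom1
MKTAY
>hom2
MKSAY
>hom3
MKsSAY
>too_short
MK---
>unrelated
QQQQQ
"""

aln = parse_a3m(a3m)
cfg = MsaFilterConfig(min_depth=1)  # tiny example: one aligned residue suffices
kept = filter_alignment(aln, cfg)
print(f"{len(aln.rows)} rows parsed, {len(kept.rows)} survive the "
      f">30% identity / >=80% overlap filter")

profile = build_profile(kept, cfg)
print(profile.to_frame().round(2).to_string(index=False))
# Conserved positions (M, K, Y) show a single frequency near 1; the
# polymorphic position 3 splits between T and S. 'reliable' marks columns
# with enough aligned homologs to trust the frequencies.
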