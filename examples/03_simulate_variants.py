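"""Conservation-labelled simulated variants under codon constraints.

Enumerates every missense change one nucleotide substitution away,
labels each from a hand-built conservation profile, and prints the
result. Only amino acids reachable in the codon context appear.
"""

from varcons.msa import Alignment, build_profile
from varcons.simulate import (CodingTranscript, SimConfig,
                              reachable_missense, simulate_transcript)

tx = CodingTranscript("TOY", "MAVG", "ATGGCAGTAGGA")
print("reachable from GCA (Ala):", sorted(reachable_missense("GCA")))

# 15 homologs: Ala2 and Gly4 fully conserved, Val3 tolerates Leu at 40%
rows = tuple("MA" + ("L" if i < 6 else "V") + "G" for i in range(15))
profile = build_profile(Alignment(tx.protein, rows))

for sv in simulate_transcript(tx, profile, SimConfig(sample_fraction=1.0, seed=0)):
    print(f"{sv.variant.hgvs_p:14s} {sv.sim_label.value}")
# Substitutions at the conserved columns come out pathogenic-like; the
# observed V->L exchange at the polymorphic column is benign-like. Codons
# limit the candidates: e.g. Ala (GCA) can reach S/P/T/E/G/V but not W.
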