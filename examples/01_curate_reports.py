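"""Merge conflicting pathogenicity reports into binary training labels.

Builds a small ClinVar-like report table containing a clean pathogenic
variant, a variant rescued by review-status filtering, a conflict and a
VUS-only record, then runs the curation rules over it.
"""

import pandas as pd

from varcons.curation import CurationConfig, curate_report_table

rows = [
    # two concordant reports -> pathogenic
    ("NP_0001", "p.Gly54Glu", "P", "criteria provided, single submitter"),
    ("NP_0001", "p.Gly54Glu", "LP", "reviewed by expert panel"),
    # contrary report carries an excluded review status -> stays benign
    ("NP_0001", "p.Leu10Pro", "B", "criteria provided, single submitter"),
    ("NP_0001", "p.Leu10Pro", "P", "no assertion provided"),
    # genuine conflict -> excluded
    ("NP_0002", "p.Arg7Trp", "P", "criteria provided, single submitter"),
    ("NP_0002", "p.Arg7Trp", "LB", "criteria provided, single submitter"),
    # VUS-only -> excluded
    ("NP_0002", "p.Ala3Val", "VUS", "criteria provided, single submitter"),
]
table = pd.DataFrame(rows, columns=["transcript_id", "hgvs_p", "label",
                                    "review_status"])
table["allele_frequency"] = ""

curated, outcomes = curate_report_table(table, CurationConfig())

for key, outcome in outcomes.items():
    print(f"{key:28s} -> {outcome}")
print(f"\n{len(curated)} of {len(outcomes)} variants retained for training.")
# Each line shows the merged verdict: P/LP evidence wins unless reliable
# contrary reports exist; unreliable review statuses are ignored entirely.
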