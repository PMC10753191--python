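"""Myosin heavy chain isoform abundance from Cq values.

Builds a small Cq table for one wild-type-like and one affected-like sample
(the affected sample expresses the embryonic and neonatal isoforms strongly),
collapses replicates, and prints reference-normalised relative expression and
within-sample isoform proportions.
"""

import numpy as np
import pandas as pd

from musclephys import expression_summary
from musclephys.qpcr import MHC_ISOFORMS, REGENERATIVE_GENES

rng = np.random.default_rng(0)
base_cq = {
    # reference genes
    "HPRT1": (24.0, 24.0), "RPL13A": (22.0, 22.0), "SDHA": (25.0, 25.0),
    # myosin panel: (WT-like, affected-like)
    "MYH7": (20.0, 22.0),   # slow MHC1b: reduced in affected
    "MYH2": (19.0, 19.0),   # MHC2A
    "MYH1": (21.0, 20.5),   # MHC2X
    "MYH4": (30.0, 30.0),   # MHC2B: scarcely expressed in dog limb muscle
    "MYH3": (29.0, 22.0),   # embryonic: strongly induced by regeneration
    "MYH8": (28.0, 23.0),   # neonatal
}

rows = []
for idx, (sample, genotype) in enumerate((("WT-01", "WT"), ("MD-01", "DE50-MD"))):
    for gene, cqs in base_cq.items():
        for rep in (1, 2, 3):
            rows.append(dict(sample_id=sample, genotype=genotype, gene=gene,
                             Cq=cqs[idx] + rng.normal(0, 0.08), replicate=rep))
table = pd.DataFrame(rows)

summary = expression_summary(table)
pd.set_option("display.width", 120)
print(summary.round(4).to_string(index=False))

print("\nregenerative burden (share of all MHC transcripts):")
for sample, sub in summary.groupby("sample_id"):
    regen = sub.loc[sub["gene"].isin(REGENERATIVE_GENES), "proportion_all"].sum()
    print(f"  {sample}: {100 * regen:5.1f} %  "
          f"({' + '.join(MHC_ISOFORMS[g] for g in REGENERATIVE_GENES)})")
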