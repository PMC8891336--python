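"""Compute the four standard diet indices from a read-count table.

%FOO says how often a prey occurs; POO and wPOO rescale occurrences into
compositional summaries; RRA keeps the read-count signal and is the index
used as a proportional-biomass estimate.
"""

import pandas as pd

from sealdiet.metrics import foo_percent, occurrence_table, poo, rra, wpoo

counts = pd.DataFrame(
    {
        "Clupea_pallasii": [300, 150, 0, 80],
        "Merluccius_productus": [50, 0, 400, 20],
        "Oncorhynchus_tshawytscha": [0, 350, 100, 0],
    },
    index=["scat1", "scat2", "scat3", "scat4"],
)
occ = occurrence_table(counts)
summary = pd.DataFrame({
    "FOO%": foo_percent(occ),
    "POO": poo(occ),
    "wPOO": wpoo(occ),
    "RRA%": rra(counts),
})
print(summary.round(3))
# FOO% is per-taxon (does not sum to 100); POO and wPOO sum to 1; RRA sums
# to 100 and is the unweighted mean of per-sample read fractions.
print("\ncolumn sums:", summary.sum().round(3).to_dict())
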