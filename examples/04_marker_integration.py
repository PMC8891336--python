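"""Split a 16S salmonid fraction across salmon species using COI.

The 16S marker quantifies all prey but cannot separate coho from
steelhead; the salmonid COI mini-barcode resolves the species mix inside
the 16S salmonid fraction.
"""

import pandas as pd

from sealdiet.markers import MarkerPair, integrate_sample

pair = MarkerPair(
    counts_16s=pd.DataFrame(
        {"Clupea_pallasii": [600],
         "Oncorhynchus_kisutch_OR_Oncorhynchus_mykiss": [400]},
        index=["scat1"],
    ),
    counts_coi=pd.DataFrame(
        {"Oncorhynchus_kisutch": [75], "Oncorhynchus_mykiss": [25]},
        index=["scat1"],
    ),
)
out = integrate_sample(pair, "scat1")
print(out.round(3))
# Herring keeps its 16S fraction (0.6); the 0.4 salmonid fraction is split
# 75/25 by COI into coho 0.3 and steelhead 0.1. The output sums to 1.
print("sum:", out.sum())
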