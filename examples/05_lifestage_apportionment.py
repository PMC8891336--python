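"""Apportion salmonid DNA percentages into juvenile and adult components.

The split ratio comes from the sample's own classified salmon bones, else
from bones pooled over the collection month, else from a seasonal rule
(spring = juvenile out-migration, fall = adult returns).
"""

from sealdiet.lifestage import apportion_sample

cases = [
    ("own bones 1:1", dict(sample_bones=(1, 1), month_pool_bones=None, month=9)),
    ("month pool 3:1", dict(sample_bones=None, month_pool_bones=(3, 1), month=9)),
    ("seasonal, May", dict(sample_bones=None, month_pool_bones=None, month=5)),
    ("seasonal, Oct", dict(sample_bones=None, month_pool_bones=None, month=10)),
]
for label, kwargs in cases:
    r = apportion_sample(5.0, species="Oncorhynchus_tshawytscha", **kwargs)
    print(f"{label:16s} -> juvenile {r.juvenile_percent:.2f}%  "
          f"adult {r.adult_percent:.2f}%  (rule: {r.rule_used})")
# Each case starts from 5% Chinook DNA; juvenile + adult always equals 5%.
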