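"""Design a 96-tag, 10 bp edit-distance-5 primer tag code.

Any two tags differ by at least 5 insertions/substitutions/deletions, so a
read cannot migrate between samples without 5 independent errors; the
demultiplexer's 2-mismatch tolerance is therefore unambiguous.
"""

from sealdiet.amplicon import design_tags, min_pairwise_distance

tags = design_tags(length=10, min_distance=5, target_count=96, seed=0)
print(f"designed {len(tags.tags)} tags of length {tags.length}")
print(f"verified minimum pairwise Levenshtein distance: "
      f"{min_pairwise_distance(tags.tags)}")
print("first five tags:", ", ".join(tags.tags[:5]))
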