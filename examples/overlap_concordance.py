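"""How many shared DEGs would two unrelated datasets produce by chance?

Two laboratories analyse the same knockout line and publish DEG lists.
Direction-matched overlap sounds like replication — but with thousands of
DEGs out of ~15,000 tested genes, hundreds of shared genes are expected
under pure independence.
"""

from powerdeg import expected_shared, overlap_robustness, shared_degs
from powerdeg.de import DEGSet

# the worked example: 15,092 genes tested in both datasets,
# list A: 2,193 down / 2,074 up;  list B: 1,244 down / 1,489 up
expected = expected_shared(15092, 2193, 2074, 1244, 1489)
print(f"expected direction-matched shared DEGs by chance: {expected:.1f} "
      f"(~{round(expected)})")

# direction-matched sharing on small explicit lists
a = DEGSet("labA", frozenset({("g1", "up"), ("g2", "down"), ("g3", "up")}))
b = DEGSet("labB", frozenset({("g1", "up"), ("g2", "up"), ("g4", "down")}))
s = shared_degs(a, b)
print(f"shared between labA and labB: {sorted(s.members)} "
      "(g2 disagrees in direction, so it does not count)")

# robustness of enriched-term sets between a subsample and the full data
sub_terms = {"GO:0006412", "GO:0006396"}
full_terms = {"GO:0006412", "GO:0006396", "GO:0042254", "GO:0008152"}
p = overlap_robustness(sub_terms, full_terms)
print(f"overlap robustness P(sub vs full) = {p:.2f}")
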