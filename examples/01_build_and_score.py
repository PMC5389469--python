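"""Build an iPWM from aligned binding sites and score candidate sites.

Constructs a small ESR1-like alignment, derives the information weight
matrix, and scores two candidate sequences.  The Ri difference converts to
an affinity fold change via 2^dRi.
"""

import ipwmkit as k

# thirty aligned 6-nt half sites (a toy alignment; real ones come from
# entropy minimization over ChIP-seq peaks)
sites = (
    ["AGGTCA"] * 18 + ["AGTTCA"] * 6 + ["GGGTCA"] * 4 + ["AGGACA"] * 2
)
alignment = k.AlignedSites(sites, k.contiguous(6),
                           offsets=[0] * len(sites), strands=["+"] * len(sites))
model = k.ipwm_from_sites(alignment)

print(f"Rsequence = {model.rsequence:.2f} bits over {model.length} positions "
      f"({model.rsequence_per_nt:.2f} bits/nt), n = {model.n} sites")
print(f"consensus  = {model.consensus}")

strong = k.score_site(model, "AGGTCA", 0)
weak = k.score_site(model, "AGTTCA", 0)
print(f"Ri(AGGTCA) = {strong:.2f} bits;  Ri(AGTTCA) = {weak:.2f} bits")
print(f"affinity fold = 2^({strong - weak:.2f}) = "
      f"{k.affinity_fold(strong, weak):.2f}x")

# a variant in the site: G -> T at position 2 weakens binding by the
# weight difference at that column
d = k.delta_ri(model, "AGGTCA", 2, "G", "T")
print(f"dRi for G>T at position 2 = {d.delta:+.2f} bits "
      "(negative = weakened binding)")
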