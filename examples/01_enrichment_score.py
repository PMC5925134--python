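"""Score a single gene's network neighbourhood against a functional term.

Builds a toy six-gene interaction network and one term, then prints the
hypergeometric upper-tail p-value and the −log10 enrichment score.
"""

import termrank as tr
from termrank.model import EnrichmentCounts

net = tr.InteractionNetwork.from_edges(
    [("VEGFA", "FGF2"), ("VEGFA", "KDR"), ("VEGFA", "FLT1"),
     ("FGF2", "FGFR1"), ("KDR", "NRP1")]
)
term = tr.Term(
    "GO:0001525", "biological_process",
    frozenset({"KDR", "FLT1", "NRP1", "FGFR1"}), "angiogenesis",
)

# background of N = 6 genes; G2 = neighbours of VEGFA, G1 = term members
g2 = net.neighbors("VEGFA")
g1 = term.members
counts = EnrichmentCounts(N=6, M=len(g1), n=len(g2), m=len(g1 & g2))
p = tr.upper_tail_p(counts)
score = tr.enrichment_score("VEGFA", term, net, n_background=6)

print(f"neighbourhood of VEGFA: {sorted(g2)}")
print(f"term members:           {sorted(g1)}")
print(f"counts: N={counts.N}, M={counts.M}, n={counts.n}, overlap m={counts.m}")
print(f"P(X >= {counts.m}) = {p:.6f}")
print(f"enrichment score = -log10(p) = {score:.4f}")
print()
print("A large score means the gene's interaction partners overlap the term's")
print("member set more than chance would allow: the gene is 'close' to the term.")
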