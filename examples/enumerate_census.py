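"""Exhaustive census of small connected graphs.

Enumerates one representative per isomorphism class of connected simple
graphs for n = 1..7 and prints the counts.  These match the classical
census of connected graphs (1, 1, 2, 6, 21, 112, 853); the n = 9 class,
used by the full uniqueness study, has 261,080 members.
"""

import topodisc as td

for n in range(1, 8):
    coll = td.enumerate_connected(n)
    print(f"n = {n}: {len(coll):5d} connected non-isomorphic graphs")

g = td.enumerate_connected(5)[0]
print("\nfirst 5-vertex graph (graph6):", td.write_graph6(g),
      "| edges:", sorted(g.edges))
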