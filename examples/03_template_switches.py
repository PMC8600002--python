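"""Derive child alleles from parents by template switching.

Reproduces the two canonical architectures: a one-finger deletion
(single switch within one parent, like the N allele arising from A) and
a displaced four-finger duplication (double switch, like L4 arising
from C), then scans a child against a whole catalog for candidate
parental pairs.
"""

import zfarray as z

catalog, _, _ = z.simulate_typed_catalog(n_a=4, n_c=4, seed=17)
fingers = list(catalog.fingers.values())
parent = "".join(f.dna for f in fingers[:13])
units = [parent[i:i + 84] for i in range(0, len(parent), 84)]

deletion = "".join(units[:9] + units[10:])       # one finger lost
duplication = "".join(units[:10] + units[4:8] + units[10:])  # block copied

for label, child in (("one-finger deletion", deletion),
                     ("displaced 4-finger duplication", duplication)):
    path = z.greedy_switch_path(child, parent, parent)
    exact = z.min_switches_dp(child, parent, parent)
    print(f"{label}: greedy {path.n_switches} switch(es), exact minimum {exact}")

# scan: which catalog pairs can produce this recombinant child?
p1 = "".join(f.dna for f in fingers[:6])
p2 = "".join(f.dna for f in fingers[6:12])
child = p1[: 3 * 84] + p2[3 * 84:]
scan = z.scan_parents("child", child, {"P1": p1, "P2": p2})
print(f"scan: origin={scan.origin_class}, minimal switches={scan.best}")
# 'bi' means every minimal derivation needs both parents — the junction
# joins sequence that neither parent carries alone.
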