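"""Define functionalization spaces and count what's in them.

A hexaphyrin redox switch exposes five site sets: two core sets (X, Y,
pyrrole NH replaceable by O/S/Se) and three meso pairs (R1,4; R2,5;
R3,6) taking peripheral substituents.  Patterns are named by the
fragments in site order, e.g. NH_S_NO2_CN_NH2.
"""

from nloswitch import (
    count_core_modified_sets,
    count_substituent_classes,
    hexaphyrin_scaffold,
    parse_pattern,
    space_size,
    toy_scaffold,
)

# A generic 4-site/5-fragment photoswitch scaffold spans 5^4 compounds.
toy = toy_scaffold(4, ("H", "CH3", "F", "NH2", "NO2"))
print(f"4 sites x 5 fragments -> {space_size(toy)} patterns")

# The 26R-based switch pins X to NH (O/S/Se there would charge the 26R
# state), so only 4 x 7^3 of the naive 4^2 x 7^3 patterns are valid.
s26 = hexaphyrin_scaffold("26R")
s30 = hexaphyrin_scaffold("30R")
print(f"26R->28R valid space: {space_size(s26)} patterns (X fixed to NH)")
print(f"30R->28R valid space: {space_size(s30)} patterns (X modifiable)")

# Composition analysis of the two published optima: strong donors
# (OH/NH2) and strong acceptors (CN/NO2) per meso pair, core changes.
for name, scaffold in (("NH_NH_NH2_CN_NH2", s26), ("O_O_NH2_CN_CN", s30)):
    p = parse_pattern(name, scaffold)
    edg, ewg = count_substituent_classes(p, scaffold)
    core = count_core_modified_sets(p, scaffold)
    print(
        f"{name}: {edg} donor pair(s), {ewg} acceptor pair(s), "
        f"{core} core-modified set(s)"
    )
# The 26R optimum is a donor-rich push-pull pattern without core
# changes; the 30R optimum inverts the donor/acceptor balance and
# modifies all four core positions.
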