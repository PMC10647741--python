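"""Compare switch figures of merit on three representative switches.

Switch 1: strong ON (1.72e4 a.u.), small but nonzero OFF (198 a.u.).
Switch 2: strong ON (2.0e4 a.u.), large OFF (2.13e3 a.u.).
Switch 3: strong ON (2.07e4 a.u.), centrosymmetric OFF (0 a.u.).

The ratio metric explodes for centrosymmetric OFF states (legacy floor
0.001 a.u.) and undervalues Switch 1; the difference metric promotes
the leaky Switch 2; the revised metric (ON-OFF)^2/(ON+OFF) keeps 1 and
3 on top while penalizing 2.
"""

from nloswitch import (
    contrast_difference,
    contrast_ratio_legacy,
    contrast_revised,
    three_state_components,
)

switches = {
    "switch 1": (1.72e4, 198.0),
    "switch 2": (2.00e4, 2.13e3),
    "switch 3": (2.07e4, 0.0),
}

print(f"{'':10s} {'ratio(legacy)':>14s} {'difference':>12s} {'revised':>10s}")
for name, (on, off) in switches.items():
    print(
        f"{name:10s} {contrast_ratio_legacy(on, off):14.3g} "
        f"{contrast_difference(on, off):12.4g} {contrast_revised(on, off):10.4g}"
    )

# Three-state target: average the two ON channels' revised contrasts,
# divided by how dissimilar the ON responses are.  The unsubstituted
# three-state switch (contrasts 2.09e3 / 2.18e3 a.u.):
comp = three_state_components(2.09e3, 2.18e3, 0.0)
print(
    f"\nthree-state parent: average {comp.average:.4g} a.u., "
    f"penalty {comp.penalty:.3f}, function {comp.value:.4g} a.u."
)
# A 1.04 penalty barely reduces the average: both ON states respond
# almost equally, which is exactly what the metric rewards.
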