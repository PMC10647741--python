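"""Attribute an optimum's performance to its individual substitutions.

Steepest ascent rebuilds the best three-state switch NH_S_NO2_CN_NH2
from the unsubstituted parent, installing one optimum fragment per step
along the largest gradient of the three-state function.  The oracle is
the reconstructed per-state response table of the published build-up.
%(B-P) measures each intermediate's share of the total parent->optimum
improvement; the big jump in the last step is the synergy headline.
"""

from nloswitch import (
    LookupOracle,
    SwitchEvaluator,
    build_fixture_db,
    hexaphyrin_scaffold,
)
from nloswitch.steepest_ascent import ascent_table, chosen_increments, run_steepest_ascent

scaffold = hexaphyrin_scaffold("three_state")
db = build_fixture_db()
oracle = LookupOracle(db[db.source == "table2"])
evaluator = SwitchEvaluator(oracle, scaffold, metric="three_state")

steps = run_steepest_ascent("NH_NH_H_H_H", "NH_S_NO2_CN_NH2", evaluator)
parent_value = evaluator.evaluate("NH_NH_H_H_H").value
table = ascent_table(steps, parent_value=parent_value)
cols = ["step", "pattern", "value", "pct_b", "pct_bp", "pct_cb", "chosen"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

increments = chosen_increments(steps)
print("\nper-step %(B-P) increments of the chosen path:",
      [f"{x:.0f}" for x in increments])
print(
    "the first three substitutions carry only "
    f"{sum(increments[:-1]):.0f}% of the improvement; the final NO2 pair "
    f"delivers the remaining {increments[-1]:.0f}% by keeping the OFF "
    "state centrosymmetric (thanks to the S core modification)."
)
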