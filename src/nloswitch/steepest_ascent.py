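"""Build-up attribution: steepest ascent from the parent to an optimum.

Starting from the unsubstituted parent, the optimum's functionalizations
are installed one per step, always choosing the not-yet-applied site
whose substitution gives the largest figure of merit.  The number of
steps equals the number of site sets where the optimum differs from the
parent, and every candidate of every step is logged with three
percentage measures of its metric value v:

* %B      = 100 * v / max              (share of the optimum's metric)
* %(B-P)  = 100 * (v - parent) / (max - parent)
            (share of the total parent→optimum improvement)
* %(CB)   = 100 * (v - parent) / (step_best - parent)
            (improvement relative to the current best of the step)

Percentages are reported rounded to the nearest integer (ties away from
zero) but stored at full precision.  The per-step increments of the
chosen path expose substituent synergy: when the final functionalization
contributes far more than it did in isolation, the groups act
cooperatively (the push–pull effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .property_oracle import SwitchEvaluator
from .scaffold_space import Pattern, parse_pattern

__all__ = [
    "AscentRow",
    "AscentStep",
    "percentages",
    "round_half_away",
    "run_steepest_ascent",
    "ascent_table",
    "chosen_increments",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentages(
    value: float,
    parent_value: float,
    max_value: float,
    step_best_value: Optional[float] = None,
) -> tuple[float, float, Optional[float]]:
    """(%B, %(B-P), %(CB)) at full precision; %(CB) None when untestable.

    Raises on degenerate denominators (optimum not better than parent,
    or a step best equal to the parent for %(CB)).
    """
    if max_value <= 0:
        raise ValueError("max_value must be positive for %B")
    if max_value == parent_value:
        raise ValueError("degenerate %(B-P): max_value equals parent_value")
    pct_b = 100.0 * value / max_value
    pct_bp = 100.0 * (value - parent_value) / (max_value - parent_value)
    if step_best_value is None:
        return pct_b, pct_bp, None
    if step_best_value == parent_value:
        raise ValueError("degenerate %(CB): step best equals parent value")
    pct_cb = 100.0 * (value - parent_value) / (step_best_value - parent_value)
    return pct_b, pct_bp, pct_cb


@dataclass(frozen=True)
class AscentRow:
    """One candidate of one build-up step."""

    pattern: Pattern
    site: str
    fragment: str
    value: float
    responses: dict
    pct_b: float
    pct_bp: float
    pct_cb: Optional[float]
    chosen: bool


@dataclass(frozen=True)
class AscentStep:
    """All candidates of one step; exactly one row is chosen."""

    step_index: int
    rows: tuple[AscentRow, ...]

    @property
    def chosen_row(self) -> AscentRow:
        (row,) = [r for r in self.rows if r.chosen]
        return row


def run_steepest_ascent(
    parent: Union[Pattern, str],
    optimum: Union[Pattern, str],
    evaluator: SwitchEvaluator,
) -> list[AscentStep]:
    """Reconstruct the optimum from the parent along the largest gradient.

    Candidate moves install the *optimum's* fragment at exactly one site
    where the current pattern still matches the parent; arbitrary
    fragments are never tried.  Returns one :class:`AscentStep` per
    functionalized site ([] when parent == optimum).  The maximum used
    for %B / %(B-P) is the optimum's metric value.
    """
    scaffold = evaluator.scaffold
    if isinstance(parent, str):
        parent = parse_pattern(parent, scaffold)
    if isinstance(optimum, str):
        optimum = parse_pattern(optimum, scaffold)

    remaining = [
        site
        for site in scaffold.site_names
        if parent.assignment[site] != optimum.assignment[site]
    ]
    parent_value = evaluator.evaluate(parent).value
    max_value = evaluator.evaluate(optimum).value

    steps: list[AscentStep] = []
    current = parent
    step_index = 0
    while remaining:
        step_index += 1
        scored = []
        for site in remaining:
            frag = optimum.assignment[site]
            cand = current.replace(scaffold, site, frag)
            ev = evaluator.evaluate(cand)
            scored.append((site, frag, ev))
        best_value = max(ev.value for _, _, ev in scored)
        chosen_site = next(
            site for site, _, ev in scored if ev.value == best_value
        )
        rows = []
        for site, frag, ev in scored:
            pct_b, pct_bp, pct_cb = percentages(
                ev.value, parent_value, max_value, best_value
            )
            rows.append(
                AscentRow(
                    ev.pattern,
                    site,
                    frag,
                    ev.value,
                    dict(ev.responses),
                    pct_b,
                    pct_bp,
                    pct_cb,
                    chosen=site == chosen_site,
                )
            )
        steps.append(AscentStep(step_index, tuple(rows)))
        current = current.replace(
            scaffold, chosen_site, optimum.assignment[chosen_site]
        )
        remaining.remove(chosen_site)
    return steps


def ascent_table(
    steps: Sequence[AscentStep],
    parent_value: Optional[float] = None,
    parent_pattern: Optional[Pattern] = None,
    max_value: Optional[float] = None,
) -> pd.DataFrame:
    """Flatten an ascent into the published table layout.

    Columns: step, pattern, metric value, per-state responses, %B,
    %(B-P), %(CB) (rounded integers) and the chosen flag; an optional
    parent row (step 0, %(CB) empty) is prepended when its value is
    given.
    """
    rows = []
    if parent_value is not None:
        if max_value is None:
            max_value = steps[-1].chosen_row.value if steps else parent_value
        pct_b, pct_bp, _ = percentages(parent_value, parent_value, max_value)
        rows.append(
            {
                "step": 0,
                "pattern": parent_pattern.canonical_name
                if parent_pattern
                else "parent",
                "value": parent_value,
                "pct_b": round_half_away(pct_b),
                "pct_bp": round_half_away(pct_bp),
                "pct_cb": None,
                "chosen": False,
            }
        )
    for step in steps:
        for r in step.rows:
            row = {
                "step": step.step_index,
                "pattern": r.pattern.canonical_name,
                "value": r.value,
                "pct_b": round_half_away(r.pct_b),
                "pct_bp": round_half_away(r.pct_bp),
                "pct_cb": None if r.pct_cb is None else round_half_away(r.pct_cb),
                "chosen": r.chosen,
            }
            row.update({f"beta_{k}": v for k, v in r.responses.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def chosen_increments(steps: Sequence[AscentStep]) -> list[float]:
    """Per-step increments of the chosen path's %(B-P), first step from 0.

    The last increment is the share of the total improvement delivered
    by the final functionalization — the synergy headline number.
    """
    out = []
    previous = 0.0
    for step in steps:
        current = step.chosen_row.pct_bp
        out.append(current - previous)
        previous = current
    return out
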