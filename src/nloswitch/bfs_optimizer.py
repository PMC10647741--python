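"""Greedy best-first search over functionalization patterns.

The search optimizes one site set at a time: from the incumbent
pattern, every allowed fragment on the visited site is substituted in
turn (the incumbent's own fragment included, so the candidate count
equals the library size), each candidate is scored by the figure of
merit, and the best is installed before moving to the next site.  One
pass over all modifiable sites is a *global iteration*; when a full
pass returns the pattern it started from, the search has converged.
Re-sweeping relaxes the independent-site assumption the greedy step
makes, letting earlier sites react to later choices.

Because the greedy path only ever moves to the best local candidate it
can stall on local optima of a rugged landscape; the multi-start driver
runs several configurations (different start patterns and site
sequences), merges everything evaluated into one deduplicated database
and reports how many runs reached the best optimum found.

Evaluations are cached by canonical pattern name, so revisiting a
pattern costs no oracle call and cannot change the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .property_oracle import EvaluatedSwitch, SwitchEvaluator, _OracleBase
from .scaffold_space import Pattern, Scaffold, parse_pattern

__all__ = [
    "BFSConfig",
    "BFSStep",
    "BFSTrajectory",
    "MultiStartResult",
    "optimize_site",
    "run_bfs",
    "multi_start_driver",
]


@dataclass(frozen=True)
class BFSConfig:
    """One search configuration.

    ``site_sequence`` defaults to the scaffold's modifiable sites in
    declaration order; ``tie_policy`` is ``keep-incumbent`` (the
    incumbent survives unless strictly beaten, stabilizing convergence)
    or ``first-in-library``.
    """

    scaffold: Scaffold
    start_pattern: Union[Pattern, str]
    metric: str = "revised"
    site_sequence: Optional[tuple[str, ...]] = None
    max_global_iterations: int = 10
    tie_policy: str = "keep-incumbent"

    def __post_init__(self) -> None:
        if self.max_global_iterations < 1:
            raise ValueError("max_global_iterations must be >= 1")
        if self.tie_policy not in ("keep-incumbent", "first-in-library"):
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        seq = self.site_sequence
        modifiable = self.scaffold.modifiable_sites()
        if seq is None:
            object.__setattr__(self, "site_sequence", modifiable)
        else:
            seq = tuple(seq)
            if sorted(seq) != sorted(modifiable):
                raise ValueError(
                    f"site_sequence {seq} must be a permutation of the "
                    f"modifiable site sets {modifiable}"
                )
            object.__setattr__(self, "site_sequence", seq)
        if isinstance(self.start_pattern, str):
            object.__setattr__(
                self,
                "start_pattern",
                parse_pattern(self.start_pattern, self.scaffold),
            )


@dataclass(frozen=True)
class BFSStep:
    """One candidate evaluation within a site iteration."""

    global_iteration: int
    site: str
    fragment: str
    pattern: Pattern
    responses: dict
    value: float
    accepted: bool


@dataclass
class BFSTrajectory:
    """Complete log of a search run."""

    config: BFSConfig
    steps: list[BFSStep] = field(default_factory=list)
    optimum: Optional[Pattern] = None
    optimum_value: float = float("nan")
    converged: bool = False
    global_iterations: int = 0
    evaluations: int = 0  # distinct oracle-backed pattern evaluations

    def to_frame(self) -> pd.DataFrame:
        """One row per evaluated candidate (CSV-ready)."""
        rows = []
        for s in self.steps:
            row = {
                "global_iteration": s.global_iteration,
                "site": s.site,
                "fragment": s.fragment,
                "pattern": s.pattern.canonical_name,
                "metric_value": s.value,
                "accepted": s.accepted,
            }
            row.update({f"beta_{k}": v for k, v in s.responses.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def accepted_values(self) -> list[float]:
        return [s.value for s in self.steps if s.accepted]


class _CachedEvaluator:
    """Canonical-name cache in front of a SwitchEvaluator."""

    def __init__(self, evaluator: SwitchEvaluator, enabled: bool = True):
        self.evaluator = evaluator
        self.enabled = enabled
        self._cache: dict[str, EvaluatedSwitch] = {}
        self.misses = 0

    def __call__(self, pattern: Pattern) -> EvaluatedSwitch:
        key = pattern.canonical_name
        if self.enabled and key in self._cache:
            return self._cache[key]
        ev = self.evaluator.evaluate(pattern)
        self.misses += 1
        if self.enabled:
            self._cache[key] = ev
        return ev

    @property
    def seen(self) -> dict[str, EvaluatedSwitch]:
        return self._cache


def _pick(
    candidates: list[tuple[str, EvaluatedSwitch]],
    incumbent_fragment: str,
    tie_policy: str,
) -> tuple[str, EvaluatedSwitch]:
    best_value = max(ev.value for _, ev in candidates)
    if tie_policy == "keep-incumbent":
        for frag, ev in candidates:
            if frag == incumbent_fragment and ev.value == best_value:
                return frag, ev
    # first-in-library (and fallback when the incumbent is not tied at top)
    for frag, ev in candidates:
        if ev.value == best_value:
            return frag, ev
    raise AssertionError("unreachable")


def optimize_site(
    current: Pattern,
    site: str,
    evaluator: Union[SwitchEvaluator, _CachedEvaluator],
    tie_policy: str = "keep-incumbent",
    global_iteration: int = 1,
) -> tuple[Pattern, list[BFSStep]]:
    """Greedy step: try every allowed fragment on one site, keep the best.

    Returns the winning pattern and the per-candidate log.  Fragments
    excluded by the scaffold's validity rules never appear among the
    candidates (the corresponding log rows are simply absent).
    """
    if not isinstance(evaluator, _CachedEvaluator):
        evaluator = _CachedEvaluator(evaluator)
    scaffold = evaluator.evaluator.scaffold
    incumbent_fragment = current.assignment[site]
    candidates: list[tuple[str, EvaluatedSwitch]] = []
    for frag in scaffold.allowed(site):
        cand = current.replace(scaffold, site, frag)
        candidates.append((frag, evaluator(cand)))
    best_frag, best_ev = _pick(candidates, incumbent_fragment, tie_policy)
    steps = [
        BFSStep(
            global_iteration,
            site,
            frag,
            ev.pattern,
            dict(ev.responses),
            ev.value,
            frag == best_frag,
        )
        for frag, ev in candidates
    ]
    return best_ev.pattern, steps


def run_bfs(
    config: BFSConfig,
    oracle: _OracleBase,
    evaluator: Optional[SwitchEvaluator] = None,
    use_cache: bool = True,
) -> BFSTrajectory:
    """Run the site-by-site search to convergence (or the iteration cap).

    Non-convergence within ``max_global_iterations`` is reported through
    ``converged=False`` on the trajectory, not an exception.
    """
    if evaluator is None:
        evaluator = SwitchEvaluator(oracle, config.scaffold, config.metric)
    cached = _CachedEvaluator(evaluator, enabled=use_cache)
    traj = BFSTrajectory(config=config)
    current = config.start_pattern

    for iteration in range(1, config.max_global_iterations + 1):
        traj.global_iterations = iteration
        sweep_input = current.canonical_name
        for site in config.site_sequence:
            current, steps = optimize_site(
                current, site, cached, config.tie_policy, iteration
            )
            traj.steps.extend(steps)
        if current.canonical_name == sweep_input:
            traj.converged = True
            break

    traj.optimum = current
    traj.optimum_value = cached(current).value
    traj.evaluations = cached.misses
    return traj


@dataclass
class MultiStartResult:
    """Merged outcome of several search runs."""

    trajectories: list[BFSTrajectory]
    database: pd.DataFrame  # one row per distinct pattern evaluated
    optima: pd.DataFrame  # per-run optimum, value, converged
    best_pattern: str = ""
    best_value: float = float("nan")
    basin_fraction: float = float("nan")  # share of runs reaching the best

    def __post_init__(self) -> None:
        if len(self.optima):
            idx = self.optima["value"].idxmax()
            self.best_pattern = self.optima.loc[idx, "pattern"]
            self.best_value = float(self.optima.loc[idx, "value"])
            reached = (self.optima["pattern"] == self.best_pattern).mean()
            self.basin_fraction = float(reached)


def multi_start_driver(
    configs: Sequence[BFSConfig], oracle: _OracleBase
) -> MultiStartResult:
    """Run every configuration and merge all evaluations.

    The merged database holds one row per distinct pattern across all
    runs (pattern, per-state responses, metric value); per-run optima
    and the fraction of runs landing in the best optimum's basin are
    tabulated alongside.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    trajectories = [run_bfs(cfg, oracle) for cfg in configs]

    merged: dict[str, dict] = {}
    for traj in trajectories:
        for step in traj.steps:
            name = step.pattern.canonical_name
            if name not in merged:
                row = {"pattern": name, "metric_value": step.value}
                row.update(
                    {f"beta_{k}": v for k, v in step.responses.items()}
                )
                merged[name] = row
    database = pd.DataFrame(list(merged.values()))

    optima = pd.DataFrame(
        {
            "run": range(len(trajectories)),
            "pattern": [t.optimum.canonical_name for t in trajectories],
            "value": [t.optimum_value for t in trajectories],
            "converged": [t.converged for t in trajectories],
            "evaluations": [t.evaluations for t in trajectories],
        }
    )
    return MultiStartResult(trajectories, database, optima)
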