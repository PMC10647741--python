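"""Descriptive statistics over switch-pattern databases.

The search runs leave behind databases of evaluated patterns (one row
per pattern with per-state βHRS responses and metric values).  The
analyses here are the ones used to distill design rules from such
databases: quartile partitions of the metric distribution (the target
group being the best 25%), core-modification occupancy per quartile,
heatmaps of strong-donor versus strong-acceptor meso counts, fixed-width
response histograms and threshold exceedance fractions.

Everything is a pure function of the input table: re-running an
analysis on the same CSV is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scaffold_space import (
    Pattern,
    Scaffold,
    count_core_modified_sets,
    count_substituent_classes,
    parse_pattern,
)

__all__ = [
    "SwitchRecord",
    "QuartileGroups",
    "DegenerateDistributionError",
    "records_to_frame",
    "quartile_partition",
    "core_modification_occupancy",
    "edg_ewg_heatmap",
    "binned_distribution",
    "GROUP_LABELS",
]


class DegenerateDistributionError(ValueError):
    """The metric distribution cannot be partitioned (e.g. all equal)."""


GROUP_LABELS = ("Q0-Q1", "Q1-Q2", "Q2-Q3", "Q3-Q4")


@dataclass(frozen=True)
class SwitchRecord:
    """One evaluated pattern: responses, metrics and derived counts."""

    pattern: str
    scaffold_name: str
    responses: dict
    metrics: dict
    n_core_modified: int = 0
    n_strong_edg: int = 0
    n_strong_ewg: int = 0

    @classmethod
    def from_pattern(
        cls,
        pattern: Union[Pattern, str],
        scaffold: Scaffold,
        responses: dict,
        metrics: dict,
    ) -> "SwitchRecord":
        if isinstance(pattern, str):
            pattern = parse_pattern(pattern, scaffold)
        n_edg, n_ewg = count_substituent_classes(pattern, scaffold)
        return cls(
            pattern.canonical_name,
            scaffold.name,
            dict(responses),
            dict(metrics),
            count_core_modified_sets(pattern, scaffold),
            n_edg,
            n_ewg,
        )


def records_to_frame(records: Sequence[SwitchRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "pattern": r.pattern,
            "scaffold": r.scaffold_name,
            "n_core_modified": r.n_core_modified,
            "n_strong_edg": r.n_strong_edg,
            "n_strong_ewg": r.n_strong_ewg,
        }
        row.update({f"beta_{k}": v for k, v in r.responses.items()})
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class QuartileGroups:
    """A database split at the metric's empirical quartiles.

    Boundaries are the 25/50/75 linear-interpolation percentiles; a
    record exactly on a boundary goes to the lower group, so the split
    is deterministic.  ``labels`` aligns with ``frame`` row order.
    """

    frame: pd.DataFrame
    metric: str
    q1: float
    q2: float
    q3: float
    labels: pd.Series = field(repr=False, default=None)

    def group(self, label: str) -> pd.DataFrame:
        if label not in GROUP_LABELS:
            raise KeyError(f"unknown group {label!r}")
        return self.frame[self.labels == label]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(GROUP_LABELS, fill_value=0)


def quartile_partition(db: pd.DataFrame, metric: str) -> QuartileGroups:
    """Partition a database into Q0-Q1 .. Q3-Q4 by a metric column."""
    if metric not in db.columns:
        raise KeyError(f"metric column {metric!r} not in database")
    values = db[metric].to_numpy(dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 records for a quartile partition")
    if np.ptp(values) == 0:
        raise DegenerateDistributionError(
            f"metric {metric!r} is constant; quartiles undefined"
        )
    q1, q2, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    labels = np.select(
        [values <= q1, values <= q2, values <= q3],
        GROUP_LABELS[:3],
        default=GROUP_LABELS[3],
    )
    return QuartileGroups(
        frame=db,
        metric=metric,
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        labels=pd.Series(labels, index=db.index, name="quartile_group"),
    )


def core_modification_occupancy(
    groups: QuartileGroups, max_sets: int = 2
) -> pd.DataFrame:
    """Percentage of records per quartile group with 0..max_sets
    core-modified site sets (needs an ``n_core_modified`` column)."""
    if "n_core_modified" not in groups.frame.columns:
        raise KeyError("database lacks an 'n_core_modified' column")
    out = {}
    for label in GROUP_LABELS:
        grp = groups.group(label)
        counts = (
            grp["n_core_modified"]
            .value_counts()
            .reindex(range(max_sets + 1), fill_value=0)
        )
        total = len(grp)
        out[label] = 100.0 * counts / total if total else counts * 0.0
    result = pd.DataFrame(out)
    result.index.name = "n_core_modified"
    return result


def edg_ewg_heatmap(group: pd.DataFrame, max_sets: int = 3) -> np.ndarray:
    """(max_sets+1) x (max_sets+1) count matrix of strong-EDG vs strong-EWG
    meso set counts (rows: donors, columns: acceptors).

    Weak substituents (F, CH3) never enter the counts — the columns used
    are the precomputed strong-class counts.
    """
    needed = {"n_strong_edg", "n_strong_ewg"}
    if not needed.issubset(group.columns):
        raise KeyError(f"database lacks columns {sorted(needed)}")
    matrix = np.zeros((max_sets + 1, max_sets + 1), dtype=int)
    for edg, ewg in zip(group["n_strong_edg"], group["n_strong_ewg"]):
        matrix[int(edg), int(ewg)] += 1
    return matrix


def binned_distribution(
    values: Sequence[float],
    bin_width: float,
    threshold: Optional[float] = None,
) -> tuple[pd.Series, Optional[float]]:
    """Histogram on half-open bins [k*w, (k+1)*w) plus a threshold fraction.

    Returns (counts indexed by bin lower edge, fraction of values
    strictly above ``threshold`` or None).  The published pies use bin
    widths of 7.5e3 a.u. (responses) and 4.0e3 a.u. (contrasts).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return pd.Series(dtype=int), None
    idx = np.floor(arr / bin_width).astype(int)
    counts = pd.Series(idx).value_counts().sort_index()
    counts.index = counts.index * bin_width
    counts.index.name = "bin_lower_edge"
    fraction = None
    if threshold is not None:
        fraction = float(np.mean(arr > threshold))
    return counts, fraction
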