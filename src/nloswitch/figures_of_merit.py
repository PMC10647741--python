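"""Figures of merit for ON/OFF nonlinear-optical switches.

Four two-state contrast definitions are in use for βHRS switches:

* ``ratio``         —  βON / βOFF, the traditional metric.  Diverges for
  a centrosymmetric OFF state (βOFF = 0).
* ``ratio_legacy``  —  the historical workaround: βOFF below a 10 a.u.
  cutoff is replaced by an arbitrary 0.001 a.u. floor before dividing.
* ``difference``    —  βON − βOFF.
* ``revised``       —  (βON − βOFF)² / (βON + βOFF).  Total over
  nonnegative inputs (0 at βON = βOFF = 0); for a centrosymmetric OFF
  state it reduces to βON, and excessively large OFF responses are
  penalized.

For a three-state switch with two ON states (26R and 30R of the
hexaphyrin redox ladder) sharing one OFF state (28R), the target
function averages the two revised contrasts and divides by the
dissimilarity of the ON responses, max(β26, β30)/min(β26, β30), so that
only switches whose two ON channels respond comparably score high.

All responses are βHRS magnitudes in atomic units; ratios are
dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

__all__ = [
    "SwitchResponse",
    "ThreeStateComponents",
    "contrast_ratio",
    "contrast_ratio_legacy",
    "contrast_difference",
    "contrast_revised",
    "three_state_function",
    "three_state_components",
    "METRICS",
    "get_metric",
]


@dataclass(frozen=True)
class SwitchResponse:
    """Per-state βHRS responses of one switch (a.u., nonnegative).

    ``on`` maps each ON-state label to its response; two-state switches
    have a single entry.
    """

    on: Mapping[str, float]
    off: float

    def __post_init__(self) -> None:
        if self.off < 0 or any(v < 0 for v in self.on.values()):
            raise ValueError("beta_hrs responses are nonnegative")
        object.__setattr__(self, "on", dict(self.on))

    @classmethod
    def two_state(cls, beta_on: float, beta_off: float, on_label: str = "ON"):
        return cls({on_label: beta_on}, beta_off)

    @property
    def single_on(self) -> float:
        if len(self.on) != 1:
            raise ValueError(
                f"expected a single ON state, got {sorted(self.on)}"
            )
        return next(iter(self.on.values()))


def _check_nonneg(*values: float) -> None:
    for v in values:
        if v < 0:
            raise ValueError("beta_hrs responses are nonnegative")


def contrast_ratio(beta_on: float, beta_off: float) -> float:
    """βON / βOFF (strict: raises on a vanishing OFF response)."""
    _check_nonneg(beta_on, beta_off)
    if beta_off == 0:
        raise ZeroDivisionError(
            "ratio contrast undefined for a centrosymmetric OFF state; "
            "use contrast_ratio_legacy or contrast_revised"
        )
    return beta_on / beta_off


def contrast_ratio_legacy(
    beta_on: float,
    beta_off: float,
    cutoff: float = 10.0,
    floor: float = 0.001,
) -> float:
    """Ratio with the historical floor substitution.

    An OFF response strictly below ``cutoff`` (near-centrosymmetric) is
    replaced by ``floor`` before dividing, making the metric total; at
    the cutoff itself no substitution happens.
    """
    _check_nonneg(beta_on, beta_off)
    if not cutoff > floor > 0:
        raise ValueError("require cutoff > floor > 0")
    effective = floor if beta_off < cutoff else beta_off
    return beta_on / effective


def contrast_difference(beta_on: float, beta_off: float) -> float:
    """βON − βOFF (may be negative)."""
    _check_nonneg(beta_on, beta_off)
    return beta_on - beta_off


def contrast_revised(beta_on: float, beta_off: float) -> float:
    """(βON − βOFF)² / (βON + βOFF), with value 0 when both vanish.

    Identities: contrast_revised(c, 0) = c and contrast_revised(x, x) = 0.
    """
    _check_nonneg(beta_on, beta_off)
    total = beta_on + beta_off
    if total == 0:
        return 0.0
    return (beta_on - beta_off) ** 2 / total


@dataclass(frozen=True)
class ThreeStateComponents:
    """Breakdown of the three-state target function."""

    contrast_a: float
    contrast_b: float
    average: float = field(init=False)
    penalty: float
    value: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "average", 0.5 * (self.contrast_a + self.contrast_b)
        )


def three_state_components(
    beta_on_a: float,
    beta_on_b: float,
    beta_off: float,
    contrast: Callable[[float, float], float] = contrast_revised,
) -> ThreeStateComponents:
    """Target function of a two-ON/one-OFF multistate switch, with parts.

    ``contrast`` evaluates each individual ON→OFF switch (the revised
    definition by default); the average of the two contrasts is divided
    by the penalty max(βa, βb)/min(βa, βb) >= 1, equal ON responses
    giving the plain average.  One vanishing ON response with the other
    nonzero is the infinite-penalty limit: the function value is 0 (a
    warning is emitted).
    """
    _check_nonneg(beta_on_a, beta_on_b, beta_off)
    ca = contrast(beta_on_a, beta_off)
    cb = contrast(beta_on_b, beta_off)
    avg = 0.5 * (ca + cb)
    if beta_on_a == beta_on_b:
        return ThreeStateComponents(ca, cb, penalty=1.0, value=avg)
    if beta_on_a == 0 or beta_on_b == 0:
        warnings.warn(
            "one ON response is zero: infinite dissimilarity penalty, "
            "function value set to 0",
            stacklevel=2,
        )
        return ThreeStateComponents(ca, cb, penalty=float("inf"), value=0.0)
    hi, lo = max(beta_on_a, beta_on_b), min(beta_on_a, beta_on_b)
    penalty = hi / lo
    return ThreeStateComponents(ca, cb, penalty=penalty, value=avg / penalty)


def three_state_function(
    beta_on_a: float,
    beta_on_b: float,
    beta_off: float,
    contrast: Callable[[float, float], float] = contrast_revised,
) -> float:
    """Scalar value of :func:`three_state_components`."""
    return three_state_components(beta_on_a, beta_on_b, beta_off, contrast).value


def _metric_ratio(r: SwitchResponse) -> float:
    return contrast_ratio(r.single_on, r.off)


def _metric_ratio_legacy(r: SwitchResponse) -> float:
    return contrast_ratio_legacy(r.single_on, r.off)


def _metric_difference(r: SwitchResponse) -> float:
    return contrast_difference(r.single_on, r.off)


def _metric_revised(r: SwitchResponse) -> float:
    return contrast_revised(r.single_on, r.off)


def _metric_three_state(r: SwitchResponse) -> float:
    if len(r.on) != 2:
        raise ValueError("three-state metric needs exactly two ON states")
    a, b = r.on.values()
    return three_state_function(a, b, r.off)


METRICS: dict[str, Callable[[SwitchResponse], float]] = {
    "ratio": _metric_ratio,
    "ratio_legacy": _metric_ratio_legacy,
    "difference": _metric_difference,
    "revised": _metric_revised,
    "three_state": _metric_three_state,
}


def get_metric(name: str) -> Callable[[SwitchResponse], float]:
    """Look up a metric by name (ratio, ratio_legacy, difference, revised,
    three_state); hyphens are accepted in place of underscores."""
    key = name.replace("-", "_")
    try:
        return METRICS[key]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; choose from {sorted(METRICS)}"
        ) from None
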