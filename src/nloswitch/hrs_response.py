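"""Hyper-Rayleigh-scattering invariants of the first hyperpolarizability.

For a freely tumbling molecule probed by HRS with the scattered light
collected perpendicular to a vertically polarized incident beam, the
measured quantity is

    beta_HRS = sqrt(<beta_ZZZ^2> + <beta_ZXX^2>),

where the brackets denote an isotropic average over molecular
orientations of the squared laboratory-frame tensor components.  Both
averages are quadratic forms in the 27 molecular-frame components
``beta_ijk`` and are evaluated here *exactly* by contracting the tensor
with the sixth-order orientation-moment tensors of the rotation group:

* the laboratory Z row of a uniformly random rotation matrix is a
  uniform unit vector u, whose sixth moments are the symmetrized
  Kronecker-delta pairings divided by 105;
* the X row is, conditionally on u, a uniform unit vector v in the
  plane orthogonal to u, whose conditional moments follow from the 2D
  projector P = I - u u^T; averaging the resulting polynomial in u over
  the sphere gives the mixed moments in closed form.

No Kleinman (full index-permutation) symmetry is assumed; a Kleinman-
symmetrized evaluation is available as an explicit option since many
tabulated tensors are reported in that convention.  A brute-force Euler
angle quadrature is provided as an independent numerical oracle.

All magnitudes are in atomic units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.spatial.transform import Rotation

__all__ = [
    "BetaTensor",
    "HRSInvariants",
    "orientational_invariants",
    "numerical_orientational_average",
    "is_effectively_centrosymmetric",
    "beta_hrs",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class BetaTensor:
    """A 3x3x3 first-hyperpolarizability tensor (atomic units).

    No permutation symmetry is imposed at storage level; Kleinman
    symmetrization is an explicit operation.  ``omega`` is metadata only
    (the optical frequency the tensor was computed at, 0 for static).
    """

    components: np.ndarray
    omega: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.components, dtype=float)
        if arr.shape != (3, 3, 3):
            raise ValueError(f"beta tensor must be 3x3x3, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("beta tensor contains non-finite components")
        object.__setattr__(self, "components", arr)

    @classmethod
    def zero(cls, omega: float = 0.0) -> "BetaTensor":
        return cls(np.zeros((3, 3, 3)), omega)

    @classmethod
    def from_flat(cls, values, omega: float = 0.0) -> "BetaTensor":
        """From 27 values ordered with the last index fastest (xxx, xxy, ...)."""
        arr = np.asarray(values, dtype=float).reshape(3, 3, 3)
        return cls(arr, omega)

    @classmethod
    def from_table(cls, table: pd.DataFrame, omega: float = 0.0) -> "BetaTensor":
        """From a delimited table with columns i, j, k (x/y/z) and value."""
        arr = np.zeros((3, 3, 3))
        for _, row in table.iterrows():
            idx = tuple(_AXES[str(row[c]).lower()] for c in ("i", "j", "k"))
            arr[idx] = float(row["value"])
        return cls(arr, omega)

    def rotated(self, rotation: np.ndarray) -> "BetaTensor":
        """The tensor expressed in a frame rotated by matrix ``rotation``."""
        r = np.asarray(rotation, dtype=float)
        out = np.einsum("ia,jb,kc,abc->ijk", r, r, r, self.components)
        return BetaTensor(out, self.omega)

    def kleinman_symmetrized(self) -> "BetaTensor":
        """Average over all 6 index permutations (Kleinman symmetry)."""
        b = self.components
        sym = sum(
            np.transpose(b, perm) for perm in itertools.permutations((0, 1, 2))
        ) / 6.0
        return BetaTensor(sym, self.omega)


@dataclass(frozen=True)
class HRSInvariants:
    """The two orientational averages and the HRS response they define."""

    mean_sq_ZZZ: float
    mean_sq_ZXX: float
    beta_hrs: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.mean_sq_ZZZ < 0 or self.mean_sq_ZXX < 0:
            raise ValueError("orientational averages are means of squares, >= 0")
        object.__setattr__(
            self, "beta_hrs", float(np.sqrt(self.mean_sq_ZZZ + self.mean_sq_ZXX))
        )

    @property
    def depolarization_free_total(self) -> float:
        return self.mean_sq_ZZZ + self.mean_sq_ZXX


def _delta_pairings(n: int):
    """All perfect matchings of n (even) index slots."""
    slots = list(range(n))

    def rec(remaining):
        if not remaining:
            yield []
            return
        a = remaining[0]
        for i in range(1, len(remaining)):
            b = remaining[i]
            rest = remaining[1:i] + remaining[i + 1 :]
            for tail in rec(rest):
                yield [(a, b)] + tail

    yield from rec(slots)


def _isotropic_moment(n: int) -> np.ndarray:
    """<u_{i1} ... u_{in}> for u uniform on the unit sphere in R^3.

    Equals the sum over perfect matchings of delta products divided by
    3 * 5 * ... * (n + 1).
    """
    eye = np.eye(3)
    out = np.zeros((3,) * n)
    for pairing in _delta_pairings(n):
        term = np.ones(())
        # build by outer products then transpose slots into place
        mats = [eye for _ in pairing]
        term = mats[0]
        for m in mats[1:]:
            term = np.multiply.outer(term, m)
        # term currently has slot order (a1,b1,a2,b2,...): map to pairing
        order = [slot for pair in pairing for slot in pair]
        inv = np.argsort(order)
        out += np.transpose(term, inv)
    norm = 1.0
    for k in range(n // 2):
        norm *= 2 * k + 3  # 3, 5, 7, ...
    return out / norm


@lru_cache(maxsize=1)
def _moment_tensors() -> tuple[np.ndarray, np.ndarray]:
    """Sixth-order moment tensors T1, T2 of a random rotation's Z/X rows.

    T1[i,j,k,l,m,n] = <R_Zi R_Zj R_Zk R_Zl R_Zm R_Zn>
    T2[i,j,k,l,m,n] = <R_Zi R_Xj R_Xk R_Zl R_Xm R_Xn>

    so that <beta_ZZZ^2> = b_ijk b_lmn T1[ijklmn] and
    <beta_ZXX^2> = b_ijk b_lmn T2[ijklmn].
    """
    t1 = _isotropic_moment(6)

    eye = np.eye(3)
    m2 = _isotropic_moment(2)  # <u_i u_l> ; slots (i, l)
    m4 = _isotropic_moment(4)  # slots (i, l, a, b)
    m6 = _isotropic_moment(6)  # slots (i, l, a, b, c, d)

    def e_term(slots_ab: tuple[int, int], slots_cd: tuple[int, int]) -> np.ndarray:
        """<u_i u_l P_ab P_cd> as a 6-slot tensor, slots (i,j,k,l,m,n).

        P = I - u u^T; slots_ab/slots_cd name which of the four X slots
        (j,k,m,n) carry the two projectors.
        """
        out = np.zeros((3,) * 6)
        i, l = 0, 3
        a, b = slots_ab
        c, d = slots_cd

        # delta_ab delta_cd <u_i u_l>
        t = np.multiply.outer(np.multiply.outer(m2, eye), eye)
        out += _arrange(t, [i, l, a, b, c, d])
        # - delta_ab <u_i u_l u_c u_d>
        t = np.multiply.outer(m4, eye)
        out -= _arrange(t, [i, l, c, d, a, b])
        # - delta_cd <u_i u_l u_a u_b>
        t = np.multiply.outer(m4, eye)
        out -= _arrange(t, [i, l, a, b, c, d])
        # + <u_i u_l u_a u_b u_c u_d>
        out += _arrange(m6, [i, l, a, b, c, d])
        return out

    j, k, m, n = 1, 2, 4, 5
    t2 = (
        e_term((j, k), (m, n)) + e_term((j, m), (k, n)) + e_term((j, n), (k, m))
    ) / 8.0
    return t1, t2


def _arrange(tensor: np.ndarray, slot_targets: list[int]) -> np.ndarray:
    """Permute a 6-axis tensor whose axes map to slot_targets into slot order."""
    inv = np.argsort(slot_targets)
    return np.transpose(tensor, inv)


def orientational_invariants(
    tensor: BetaTensor, kleinman: bool = False
) -> HRSInvariants:
    """Closed-form <beta_ZZZ^2>, <beta_ZXX^2> and beta_HRS.

    ``kleinman=True`` symmetrizes the tensor over all index permutations
    before averaging (the convention many tabulations assume); the
    default uses the full non-symmetrized expressions.
    """
    if kleinman:
        tensor = tensor.kleinman_symmetrized()
    b = tensor.components
    t1, t2 = _moment_tensors()
    zzz = float(np.einsum("ijk,lmn,ijklmn->", b, b, t1))
    zxx = float(np.einsum("ijk,lmn,ijklmn->", b, b, t2))
    # guard tiny negative round-off
    return HRSInvariants(max(zzz, 0.0), max(zxx, 0.0))


def beta_hrs(tensor: BetaTensor, kleinman: bool = False) -> float:
    """Convenience scalar: sqrt(<beta_ZZZ^2> + <beta_ZXX^2>)."""
    return orientational_invariants(tensor, kleinman=kleinman).beta_hrs


def numerical_orientational_average(
    tensor: BetaTensor,
    n_alpha: int = 16,
    n_beta: int = 24,
    n_gamma: int = 16,
) -> HRSInvariants:
    """Brute-force Euler-angle quadrature oracle for the HRS averages.

    Averages the squared laboratory-frame components of the rotated
    tensor over SO(3) with the Haar measure: uniform grids in the first
    and third ZYZ Euler angles (trapezoid on the periodic interval is
    spectrally accurate) and Gauss-Legendre in the middle angle with the
    sin(beta)/2 weight.  Converges to :func:`orientational_invariants`
    as the grid is refined; used in tests to arbitrate the closed form.
    """
    if n_alpha < 2 or n_beta < 2 or n_gamma < 2:
        raise ValueError("degenerate quadrature grid")
    b = tensor.components
    alphas = np.linspace(0.0, 2.0 * np.pi, n_alpha, endpoint=False)
    gammas = np.linspace(0.0, 2.0 * np.pi, n_gamma, endpoint=False)
    nodes, weights = leggauss(n_beta)  # on [-1, 1]
    betas = 0.5 * np.pi * (nodes + 1.0)
    wbeta = 0.25 * np.pi * weights * np.sin(betas)  # integral of .5*sin = 1

    angles = np.array(
        [
            (a, be, g)
            for a, wb in zip(alphas, np.ones(n_alpha))
            for be in betas
            for g in gammas
        ]
    )
    w = np.array(
        [
            wb / (n_alpha * n_gamma)
            for _ in alphas
            for wb in wbeta
            for _ in gammas
        ]
    )
    rots = Rotation.from_euler("ZYZ", angles).as_matrix()  # (N, 3, 3)
    zrow = rots[:, 2, :]
    xrow = rots[:, 0, :]
    b_zzz = np.einsum("ni,nj,nk,ijk->n", zrow, zrow, zrow, b)
    b_zxx = np.einsum("ni,nj,nk,ijk->n", zrow, xrow, xrow, b)
    zzz = float(np.sum(w * b_zzz**2))
    zxx = float(np.sum(w * b_zxx**2))
    return HRSInvariants(max(zzz, 0.0), max(zxx, 0.0))


def is_effectively_centrosymmetric(
    beta_hrs_off: float, threshold: float = 10.0
) -> bool:
    """True iff an OFF-state response is strictly below the threshold.

    Near-centrosymmetric OFF states (response below 10 a.u. by default)
    are the ones the legacy ratio rule replaces by the 0.001 a.u. floor.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if beta_hrs_off < 0:
        raise ValueError("beta_hrs is nonnegative by construction")
    return beta_hrs_off < threshold
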