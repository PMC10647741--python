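"""Combinatorial functionalization spaces for macrocyclic scaffolds.

A *scaffold* (e.g. a hexaphyrin redox switch) exposes a small number of
modifiable *site sets* — symmetric pairs of positions that are always
functionalized identically.  Meso site sets (the carbon bridges R1,4 /
R2,5 / R3,6) accept peripheral substituents; core site sets (X, Y)
accept NH→O/S/Se heteroatom replacements of the pyrrole rings.  A
*pattern* assigns one fragment from the library to every site set, and
is named by the underscore-joined fragment labels in canonical site
order, e.g. ``NH_S_NO2_CN_NH2``.

The module is deliberately free of any 3D chemistry: it is the discrete
search space over which the best-first search, steepest ascent and
database analytics operate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "Fragment",
    "SiteSet",
    "Scaffold",
    "Pattern",
    "ScaffoldError",
    "PatternError",
    "SpaceTooLargeError",
    "MESO_LIBRARY",
    "CORE_LIBRARY",
    "STRONG_EDG",
    "STRONG_EWG",
    "electronic_class",
    "hexaphyrin_scaffold",
    "toy_scaffold",
    "load_scaffold",
    "space_size",
    "parse_pattern",
    "format_pattern",
    "count_substituent_classes",
    "count_core_modified_sets",
    "enumerate_space",
]


class ScaffoldError(ValueError):
    """Raised for an inconsistent scaffold or site-set definition."""


class PatternError(ValueError):
    """Raised when a pattern string or assignment violates the scaffold."""


class SpaceTooLargeError(RuntimeError):
    """Raised when an enumeration would exceed the configured cap."""


# Strong donor/acceptor classification.  Only OH/NH2 count as strong
# electron donors and CN/NO2 as strong acceptors; F and CH3 are weak and
# are never counted in push-pull statistics, H and core fragments carry
# no class at all.
STRONG_EDG = frozenset({"OH", "NH2"})
STRONG_EWG = frozenset({"CN", "NO2"})
_WEAK = frozenset({"F", "CH3"})


def electronic_class(label: str, site_kind: str) -> str:
    """Classify a fragment label: strong_EDG, strong_EWG, weak or none."""
    if site_kind == "core":
        return "none"
    if label in STRONG_EDG:
        return "strong_EDG"
    if label in STRONG_EWG:
        return "strong_EWG"
    if label in _WEAK:
        return "weak"
    return "none"


@dataclass(frozen=True)
class Fragment:
    """One library member: a peripheral substituent or a core heteroatom."""

    label: str
    site_kind: str  # "meso" | "core"
    electronic_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.site_kind not in ("meso", "core"):
            raise ScaffoldError(f"unknown site kind {self.site_kind!r}")
        expected = electronic_class(self.label, self.site_kind)
        if not self.electronic_class:
            object.__setattr__(self, "electronic_class", expected)
        elif self.electronic_class != expected:
            raise ScaffoldError(
                f"fragment {self.label!r} must have electronic class "
                f"{expected!r}, got {self.electronic_class!r}"
            )


#: Default peripheral substituent library (editable via config files).
MESO_LIBRARY: tuple[str, ...] = ("H", "CH3", "F", "OH", "NH2", "CN", "NO2")
#: Default core-modification library: pyrrole (NH), furan (O),
#: thiophene (S), selenophene (Se).
CORE_LIBRARY: tuple[str, ...] = ("NH", "O", "S", "Se")


@dataclass(frozen=True)
class SiteSet:
    """A named set of symmetry-equivalent positions modified as one unit."""

    name: str
    kind: str  # "meso" | "core"
    allowed_fragments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.allowed_fragments:
            raise ScaffoldError(f"site set {self.name!r} has an empty library")
        if self.kind not in ("meso", "core"):
            raise ScaffoldError(f"site set {self.name!r}: bad kind {self.kind!r}")
        if len(set(self.allowed_fragments)) != len(self.allowed_fragments):
            raise ScaffoldError(f"site set {self.name!r}: duplicate fragments")


@dataclass(frozen=True)
class Scaffold:
    """A switchable scaffold: ordered states, ordered site sets, validity rules.

    ``forbidden`` holds (state, site, fragment) triples that are excluded
    because the combination is chemically invalid in that state (e.g. O/S/Se
    on the X core sites of any scaffold containing the 26R state, which
    would make the 26R structure charged).  Rules are data, not code.
    """

    name: str
    states: tuple[str, ...]
    site_sets: tuple[SiteSet, ...]
    forbidden: frozenset[tuple[str, str, str]] = frozenset()
    off_state: str = ""

    def __post_init__(self) -> None:
        if not self.site_sets:
            raise ScaffoldError("scaffold needs at least one site set")
        names = [s.name for s in self.site_sets]
        if len(set(names)) != len(names):
            raise ScaffoldError("duplicate site-set names")
        if not self.off_state and self.states:
            object.__setattr__(self, "off_state", self.states[-1])
        if self.states and self.off_state not in self.states:
            raise ScaffoldError(f"off_state {self.off_state!r} not in states")

    @property
    def on_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != self.off_state)

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.site_sets)

    def site(self, name: str) -> SiteSet:
        for s in self.site_sets:
            if s.name == name:
                return s
        raise ScaffoldError(f"no site set named {name!r}")

    def allowed(self, site_name: str) -> tuple[str, ...]:
        """Allowed fragments on a site after validity rules, library order."""
        site = self.site(site_name)
        banned = {f for (st, si, f) in self.forbidden if si == site.name}
        out = tuple(f for f in site.allowed_fragments if f not in banned)
        if not out:
            raise ScaffoldError(
                f"site set {site.name!r}: validity rules exclude every fragment"
            )
        return out

    def modifiable_sites(self) -> tuple[str, ...]:
        """Site sets with more than one allowed fragment."""
        return tuple(s.name for s in self.site_sets if len(self.allowed(s.name)) > 1)


@dataclass(frozen=True)
class Pattern:
    """One point of the space: a fragment assigned to every site set."""

    assignment: Mapping[str, str]
    canonical_name: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name

    def replace(self, scaffold: Scaffold, site: str, fragment: str) -> "Pattern":
        """Return a copy with ``site`` reassigned to ``fragment`` (validated)."""
        new = dict(self.assignment)
        new[site] = fragment
        return _make_pattern(new, scaffold)


def _make_pattern(assignment: Mapping[str, str], scaffold: Scaffold) -> Pattern:
    ordered: dict[str, str] = {}
    for site in scaffold.site_sets:
        try:
            frag = assignment[site.name]
        except KeyError:
            raise PatternError(f"site set {site.name!r} unassigned") from None
        if frag not in site.allowed_fragments:
            raise PatternError(
                f"fragment {frag!r} is not in the {site.kind} library of "
                f"site set {site.name!r}"
            )
        if frag not in scaffold.allowed(site.name):
            raise PatternError(
                f"fragment {frag!r} on site {site.name!r} is excluded by a "
                f"validity rule of scaffold {scaffold.name!r}"
            )
        ordered[site.name] = frag
    if len(assignment) != len(ordered):
        extra = set(assignment) - set(ordered)
        raise PatternError(f"unknown site sets in assignment: {sorted(extra)}")
    name = "_".join(ordered[s.name] for s in scaffold.site_sets)
    return Pattern(assignment=ordered, canonical_name=name)


def parse_pattern(name: str, scaffold: Scaffold) -> Pattern:
    """Parse an underscore-joined canonical pattern name.

    Round-trips with :func:`format_pattern` for every valid pattern.
    """
    tokens = name.split("_")
    if len(tokens) != len(scaffold.site_sets):
        raise PatternError(
            f"pattern {name!r} has {len(tokens)} tokens, scaffold "
            f"{scaffold.name!r} expects {len(scaffold.site_sets)}"
        )
    assignment = {s.name: t for s, t in zip(scaffold.site_sets, tokens)}
    return _make_pattern(assignment, scaffold)


def format_pattern(pattern: Pattern) -> str:
    return pattern.canonical_name


def space_size(scaffold: Scaffold) -> int:
    """Number of valid patterns: product of per-site allowed-library sizes."""
    n = 1
    for site in scaffold.site_sets:
        n *= len(scaffold.allowed(site.name))
    return n


def enumerate_space(scaffold: Scaffold, max_size: int = 100_000) -> Iterator[Pattern]:
    """Yield every valid pattern once, site-major in library order."""
    n = space_size(scaffold)
    if n > max_size:
        raise SpaceTooLargeError(
            f"space of {scaffold.name!r} has {n} patterns, cap is {max_size}"
        )
    choices = [scaffold.allowed(s.name) for s in scaffold.site_sets]
    names = scaffold.site_names
    for combo in itertools.product(*choices):
        yield _make_pattern(dict(zip(names, combo)), scaffold)


def _site_kind(scaffold_or_kind, site_name: str) -> str:
    return scaffold_or_kind.site(site_name).kind


def count_substituent_classes(
    pattern: Pattern, scaffold: Scaffold
) -> tuple[int, int]:
    """(number of strong-EDG meso sets, number of strong-EWG meso sets).

    Each site set counts once (a set is a symmetric pair of positions);
    F, CH3, H and core fragments never count.
    """
    n_edg = n_ewg = 0
    for site in scaffold.site_sets:
        if site.kind != "meso":
            continue
        frag = pattern.assignment[site.name]
        if frag in STRONG_EDG:
            n_edg += 1
        elif frag in STRONG_EWG:
            n_ewg += 1
    return n_edg, n_ewg


def count_core_modified_sets(pattern: Pattern, scaffold: Scaffold) -> int:
    """Number of core site sets carrying a non-NH heteroatom (O, S or Se)."""
    return sum(
        1
        for site in scaffold.site_sets
        if site.kind == "core" and pattern.assignment[site.name] != "NH"
    )


# ---------------------------------------------------------------------------
# Scaffold factories


def hexaphyrin_scaffold(
    kind: str = "three_state",
    meso_library: Sequence[str] = MESO_LIBRARY,
    core_library: Sequence[str] = CORE_LIBRARY,
) -> Scaffold:
    """Build a hexaphyrin redox-switch scaffold.

    ``kind`` selects the state manifold:

    * ``"26R"`` — two-state 26R→28R switch.  The X core sites are fixed
      to NH because O/S/Se there would give charged 26R structures; the
      canonical name still prints NH in position 1.
    * ``"30R"`` — two-state 30R→28R switch, X fully modifiable.
    * ``"three_state"`` — 26R→28R→30R, X fixed to NH (the 26R rule).

    Site order, hence pattern naming, is X_Y_R1,4_R2,5_R3,6.
    """
    sites = (
        SiteSet("X", "core", tuple(core_library)),
        SiteSet("Y", "core", tuple(core_library)),
        SiteSet("R1,4", "meso", tuple(meso_library)),
        SiteSet("R2,5", "meso", tuple(meso_library)),
        SiteSet("R3,6", "meso", tuple(meso_library)),
    )
    charged_26r = frozenset(
        ("26R", "X", frag) for frag in core_library if frag != "NH"
    )
    if kind == "26R":
        return Scaffold("26R->28R", ("26R", "28R"), sites, charged_26r, "28R")
    if kind == "30R":
        return Scaffold("30R->28R", ("30R", "28R"), sites, frozenset(), "28R")
    if kind == "three_state":
        return Scaffold(
            "26R->28R->30R", ("26R", "28R", "30R"), sites, charged_26r, "28R"
        )
    raise ScaffoldError(f"unknown hexaphyrin scaffold kind {kind!r}")


def toy_scaffold(
    n_sites: int = 4,
    fragments: Sequence[str] = ("H", "CH3", "F", "NH2", "NO2"),
    states: Sequence[str] = ("ON", "OFF"),
) -> Scaffold:
    """A generic n-site meso-only scaffold (azoheteroarene-like benchmark)."""
    sites = tuple(
        SiteSet(f"R{i + 1}", "meso", tuple(fragments)) for i in range(n_sites)
    )
    return Scaffold("toy", tuple(states), sites, frozenset(), states[-1])


def load_scaffold(path) -> Scaffold:
    """Load a scaffold from a YAML config file.

    Expected keys: ``name``, ``states`` (list, last or ``off_state`` is the
    OFF state), ``site_sets`` (list of {name, kind, allowed_fragments}),
    optional ``forbidden`` (list of [state, site, fragment]).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sites = tuple(
        SiteSet(s["name"], s["kind"], tuple(s["allowed_fragments"]))
        for s in cfg["site_sets"]
    )
    forbidden = frozenset(tuple(rule) for rule in cfg.get("forbidden", []))
    return Scaffold(
        cfg["name"],
        tuple(cfg["states"]),
        sites,
        forbidden,
        cfg.get("off_state", ""),
    )
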