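"""Chemical-compound-space maps: structures, fingerprints, embeddings.

To place functionalization patterns in a continuous chemical space, each
pattern is first instantiated as a molecular structure, hashed into an
extended-connectivity fingerprint (ECFP, radius 2 / 2048 bits by
default) and embedded in 2D with t-SNE.  Databases from different
switches can then be overlaid and colored by any measure (core
modification count, per-switch contrast, three-state function value).

Two structure templates ship:

* :class:`SmilesTemplate` — a SMILES string with ``{site}`` placeholders
  (a site name may occur once per symmetric position) plus a fragment →
  substituent-SMILES map; good for toy scaffolds such as a
  para-disubstituted benzene.
* :class:`HexaphyrinTemplate` — builds a hexaphyrin(1.1.1.1.1.1)-like
  macrocycle atom by atom: six five-membered heterole rings bridged by
  six meso carbons in a consistent Kekulé pattern, core site sets
  replacing ring NH by O/S/Se and meso site sets attaching both
  substituents of each symmetric pair.  The Kekulé assignment is one
  localized resonance structure (alternating pyrrole / exocyclic-diene
  units); ring-current topology is deliberately not modeled.

A one-hot descriptor over site assignments is provided as a clearly
labeled non-ECFP fallback for fingerprint-free pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.manifold import TSNE

from .scaffold_space import Pattern, Scaffold, parse_pattern

__all__ = [
    "TemplateError",
    "SmilesTemplate",
    "HexaphyrinTemplate",
    "pattern_to_structure",
    "fingerprint",
    "tanimoto",
    "one_hot_descriptor",
    "EmbeddingResult",
    "embed",
]


class TemplateError(ValueError):
    """A template could not produce a parseable structure."""


#: Substituent SMILES used when splicing fragments into a template.
FRAGMENT_SMILES: dict[str, str] = {
    "H": "[H]",
    "CH3": "C",
    "F": "F",
    "OH": "O",
    "NH2": "N",
    "CN": "C#N",
    "NO2": "[N+](=O)[O-]",
}


@dataclass(frozen=True)
class SmilesTemplate:
    """A SMILES scaffold with ``{site}`` placeholders."""

    template: str
    fragment_smiles: Mapping[str, str] = None

    def __post_init__(self) -> None:
        if self.fragment_smiles is None:
            object.__setattr__(self, "fragment_smiles", dict(FRAGMENT_SMILES))

    def to_smiles(self, pattern: Pattern) -> str:
        smiles = self.template
        for site, frag in pattern.assignment.items():
            token = "{" + site + "}"
            if token not in smiles:
                raise TemplateError(f"template lacks a placeholder for {site!r}")
            try:
                sub = self.fragment_smiles[frag]
            except KeyError:
                raise TemplateError(
                    f"no substituent SMILES for fragment {frag!r}"
                ) from None
            smiles = smiles.replace(token, sub)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise TemplateError(f"template produced unparseable SMILES {smiles!r}")
        return Chem.MolToSmiles(Chem.RemoveHs(mol))


_CHALCOGENS = {"NH": "N", "O": "O", "S": "S", "Se": "Se"}


@dataclass(frozen=True)
class HexaphyrinTemplate:
    """Atom-level builder for a hexaphyrin-like macrocycle.

    ``core_sites`` maps core site-set names to the two ring indices they
    modify; ``meso_sites`` maps meso site-set names to the two meso
    bridge indices carrying the substituent pair.  Ring/meso indices run
    0–5 around the macrocycle; meso bridge i links ring i to ring i+1.
    """

    core_sites: Mapping[str, tuple[int, int]] = None
    meso_sites: Mapping[str, tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.core_sites is None:
            object.__setattr__(self, "core_sites", {"X": (0, 3), "Y": (1, 4)})
        if self.meso_sites is None:
            object.__setattr__(
                self,
                "meso_sites",
                {"R1,4": (0, 3), "R2,5": (1, 4), "R3,6": (2, 5)},
            )

    def to_smiles(self, pattern: Pattern) -> str:
        ring_hetero = {i: "N" for i in range(6)}
        for site, rings in self.core_sites.items():
            frag = pattern.assignment.get(site, "NH")
            if frag not in _CHALCOGENS:
                raise TemplateError(
                    f"core site {site!r}: unknown heteroatom fragment {frag!r}"
                )
            for r in rings:
                ring_hetero[r] = _CHALCOGENS[frag]
        meso_subst = {i: "H" for i in range(6)}
        for site, mesos in self.meso_sites.items():
            frag = pattern.assignment.get(site, "H")
            if frag not in FRAGMENT_SMILES:
                raise TemplateError(
                    f"meso site {site!r}: no substituent SMILES for {frag!r}"
                )
            for m in mesos:
                meso_subst[m] = frag
        mol = _build_macrocycle(ring_hetero, meso_subst)
        return Chem.MolToSmiles(mol)


def _build_macrocycle(
    ring_hetero: Mapping[int, str], meso_subst: Mapping[int, str]
) -> Chem.Mol:
    """Assemble the Kekulé macrocycle with RDKit's editable molecule."""
    rw = Chem.RWMol()
    single, double = Chem.BondType.SINGLE, Chem.BondType.DOUBLE

    def add(symbol: str, charge: int = 0) -> int:
        atom = Chem.Atom(symbol)
        if charge:
            atom.SetFormalCharge(charge)
        return rw.AddAtom(atom)

    rings = []  # per ring: (a1, b1, b2, a2)
    for i in range(6):
        a1, b1, b2, a2 = add("C"), add("C"), add("C"), add("C")
        z = add(ring_hetero[i])
        type_a = i % 2 == 0  # pyrrole-type Kekulé unit
        rw.AddBond(a1, b1, double if type_a else single)
        rw.AddBond(b1, b2, single if type_a else double)
        rw.AddBond(b2, a2, double if type_a else single)
        rw.AddBond(a1, z, single)
        rw.AddBond(a2, z, single)
        rings.append((a1, b1, b2, a2))

    mesos = []
    for i in range(6):
        m = add("C")
        a2_this = rings[i][3]
        a1_next = rings[(i + 1) % 6][0]
        # the double bond of each meso carbon points at the
        # exocyclic-diene (odd) ring
        if i % 2 == 0:  # ring i even (type A), ring i+1 odd (type B)
            rw.AddBond(m, a2_this, single)
            rw.AddBond(m, a1_next, double)
        else:
            rw.AddBond(m, a2_this, double)
            rw.AddBond(m, a1_next, single)
        mesos.append(m)

    for i, frag in meso_subst.items():
        _attach_substituent(rw, mesos[i], frag)

    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise TemplateError(f"macrocycle failed sanitization: {exc}") from exc
    return Chem.RemoveHs(mol)


def _attach_substituent(rw: Chem.RWMol, anchor: int, frag: str) -> None:
    single, double, triple = (
        Chem.BondType.SINGLE,
        Chem.BondType.DOUBLE,
        Chem.BondType.TRIPLE,
    )
    if frag == "H":
        return  # implicit hydrogen
    if frag == "CH3":
        c = rw.AddAtom(Chem.Atom("C"))
        rw.AddBond(anchor, c, single)
    elif frag in ("F", "OH", "NH2"):
        sym = {"F": "F", "OH": "O", "NH2": "N"}[frag]
        a = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(anchor, a, single)
    elif frag == "CN":
        c = rw.AddAtom(Chem.Atom("C"))
        n = rw.AddAtom(Chem.Atom("N"))
        rw.AddBond(anchor, c, single)
        rw.AddBond(c, n, triple)
    elif frag == "NO2":
        n = Chem.Atom("N")
        n.SetFormalCharge(1)
        ni = rw.AddAtom(n)
        o1 = rw.AddAtom(Chem.Atom("O"))
        o2 = Chem.Atom("O")
        o2.SetFormalCharge(-1)
        oi = rw.AddAtom(o2)
        rw.AddBond(anchor, ni, single)
        rw.AddBond(ni, o1, double)
        rw.AddBond(ni, oi, single)
    else:
        raise TemplateError(f"no attachment rule for fragment {frag!r}")


def pattern_to_structure(
    pattern: Union[Pattern, str],
    template,
    scaffold: Optional[Scaffold] = None,
) -> str:
    """Canonical SMILES of a pattern under a template."""
    if isinstance(pattern, str):
        if scaffold is None:
            raise ValueError("parsing a pattern string needs the scaffold")
        pattern = parse_pattern(pattern, scaffold)
    return template.to_smiles(pattern)


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """ECFP-style circular fingerprint as a 0/1 vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity of two bit vectors (1.0 for two empty ones)."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def one_hot_descriptor(pattern: Pattern, scaffold: Scaffold) -> np.ndarray:
    """One-hot site-assignment vector — a non-ECFP fallback descriptor.

    Purely categorical (no substructure information); use only when a
    structure template is unavailable.
    """
    chunks = []
    for site in scaffold.site_sets:
        allowed = scaffold.allowed(site.name)
        vec = np.zeros(len(allowed), dtype=np.uint8)
        vec[allowed.index(pattern.assignment[site.name])] = 1
        chunks.append(vec)
    return np.concatenate(chunks)


@dataclass
class EmbeddingResult:
    """2D embedding plus the measures used for coloring."""

    coordinates: pd.DataFrame  # columns x, y (+ measure columns)
    perplexity: float
    seed: int


def embed(
    fingerprints: Sequence[np.ndarray],
    seed: int,
    perplexity: float = 30.0,
    measures: Optional[pd.DataFrame] = None,
) -> EmbeddingResult:
    """t-SNE embedding of fingerprint vectors (Jaccard distances).

    The effective perplexity is clamped below the sample count as t-SNE
    requires; the seed fixes the embedding completely.  ``measures``
    columns (same row order as the fingerprints) are joined onto the
    output for downstream coloring.
    """
    fps = np.asarray(list(fingerprints), dtype=bool)
    n = len(fps)
    if n < 5:
        raise ValueError("need at least 5 records to embed")
    eff_perplexity = min(float(perplexity), (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        metric="jaccard",
        init="random",
        random_state=seed,
    )
    coords = tsne.fit_transform(fps)
    frame = pd.DataFrame(coords, columns=["x", "y"])
    if measures is not None:
        if len(measures) != n:
            raise ValueError("measures must align with the fingerprints")
        frame = pd.concat(
            [frame, measures.reset_index(drop=True)], axis=1
        )
    return EmbeddingResult(frame, eff_perplexity, seed)
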