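"""Parsing, canonicalization and stoichiometric checking of reaction equations.

A reaction equation is written in a SMILES dialect::

    2[H][H] + O=O >> 2O
    [O]=[C]=[O] + 2[H][H] → [H][C]([H])=[O] + [H][O][H]

Each side is a " + "-separated list of species terms; a term is an optional
integer stoichiometric coefficient glued to a SMILES string.  Both the ASCII
``>>`` and the arrow ``→`` are accepted as side separators; ``>>`` is emitted
on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem
from rdkit import RDLogger

from .errors import ReactionParseError, SpeciesValidityError

RDLogger.DisableLog("rdApp.*")

#: Side separators accepted on input, in match priority order.
SEPARATORS = ("→", ">>")
#: Separator emitted by :func:`format_reaction`.
OUTPUT_SEPARATOR = ">>"

_COEF_RE = re.compile(r"^(\d+)(.*)$")


@lru_cache(maxsize=65536)
def _analyze_smiles(smiles: str) -> tuple[str, tuple[tuple[str, int], ...], int]:
    """Canonical SMILES, element composition and net formal charge for one SMILES.

    Raises :class:`SpeciesValidityError` if RDKit cannot parse/sanitize it.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SpeciesValidityError(f"invalid species SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    molh = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in molh.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    charge = Chem.GetFormalCharge(mol)
    return canonical, tuple(sorted(counts.items())), charge


@dataclass(frozen=True)
class Species:
    """A molecular species, identified by its input-dialect SMILES.

    Canonical form, composition (implicit hydrogens resolved) and net formal
    charge are computed lazily through RDKit and cached per SMILES string.
    """

    smiles: str

    @property
    def canonical_smiles(self) -> str:
        return _analyze_smiles(self.smiles)[0]

    @property
    def composition(self) -> dict[str, int]:
        return dict(_analyze_smiles(self.smiles)[1])

    @property
    def net_charge(self) -> int:
        return _analyze_smiles(self.smiles)[2]

    def is_valid(self) -> bool:
        """True iff RDKit can parse and sanitize the SMILES."""
        try:
            _analyze_smiles(self.smiles)
        except SpeciesValidityError:
            return False
        return True


@dataclass(frozen=True)
class CompositionVector:
    """Coefficient-weighted per-element totals and net charge of one side."""

    elements: tuple[tuple[str, int], ...]
    total_charge: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.elements)


@dataclass(frozen=True)
class ReactionEquation:
    """Ordered reactant and product sides of (coefficient, species) pairs."""

    reactants: tuple[tuple[int, Species], ...]
    products: tuple[tuple[int, Species], ...]
    source_string: str = ""

    def species(self) -> list[Species]:
        """All species in source order (reactants then products)."""
        return [sp for _, sp in self.reactants] + [sp for _, sp in self.products]

    def swapped(self) -> "ReactionEquation":
        """The reverse reaction (products and reactants exchanged)."""
        return ReactionEquation(self.products, self.reactants, self.source_string)

    def max_species_per_side(self) -> int:
        """Larger of the two distinct-species counts."""
        return max(len(self.reactants), len(self.products))


def _parse_side(side_text: str, side_name: str, source: str) -> tuple[tuple[int, Species], ...]:
    terms = side_text.split(" + ")
    out: list[tuple[int, Species]] = []
    for term in terms:
        term = term.strip()
        # "+" may legally occur inside bracket atoms, so species are split on
        # " + " only; a leftover bare "+" or internal whitespace means a
        # malformed (e.g. empty) term
        if not term or term == "+" or any(ch.isspace() for ch in term):
            raise ReactionParseError(
                f"empty or malformed species term {term!r} on {side_name} side of {source!r}"
            )
        m = _COEF_RE.match(term)
        if m and m.group(1):
            coef = int(m.group(1))
            smiles = m.group(2)
            if coef == 0:
                raise ReactionParseError(f"zero coefficient in term {term!r}")
            if not smiles:
                raise ReactionParseError(f"coefficient without species in term {term!r}")
        else:
            coef, smiles = 1, term
        out.append((coef, Species(smiles)))
    return tuple(out)


def parse_reaction_string(text: str, separators: tuple[str, ...] = SEPARATORS) -> ReactionEquation:
    """Parse a reaction-dialect string into a :class:`ReactionEquation`.

    The text must contain exactly one side separator; species SMILES are kept
    verbatim in source order and coefficients default to 1.
    """
    text = text.strip()
    sep_found = None
    for sep in separators:
        if sep in text:
            sep_found = sep
            break
    if sep_found is None:
        raise ReactionParseError(f"no side separator in {text!r}")
    parts = text.split(sep_found)
    if len(parts) != 2:
        raise ReactionParseError(f"more than one side separator in {text!r}")
    left, right = parts[0].strip(), parts[1].strip()
    if not left:
        raise ReactionParseError(f"empty reactant side in {text!r}")
    if not right:
        raise ReactionParseError(f"empty product side in {text!r}")
    return ReactionEquation(
        reactants=_parse_side(left, "reactant", text),
        products=_parse_side(right, "product", text),
        source_string=text,
    )


def format_reaction(eq: ReactionEquation, canonical: bool = False) -> str:
    """Serialize an equation back to the dialect (``>>`` separator).

    Coefficient 1 is implicit.  With ``canonical=True`` species are replaced
    by their canonical SMILES.
    """

    def fmt_side(side: tuple[tuple[int, Species], ...]) -> str:
        terms = []
        for coef, sp in side:
            smiles = sp.canonical_smiles if canonical else sp.smiles
            terms.append(f"{coef}{smiles}" if coef != 1 else smiles)
        return " + ".join(terms)

    return f"{fmt_side(eq.reactants)} {OUTPUT_SEPARATOR} {fmt_side(eq.products)}"


def elemental_composition(species: Species) -> CompositionVector:
    """Element -> atom count (implicit hydrogens included) and formal charge."""
    canonical, elements, charge = _analyze_smiles(species.smiles)
    return CompositionVector(elements=elements, total_charge=charge)


def side_composition(side: tuple[tuple[int, Species], ...]) -> CompositionVector:
    """Coefficient-weighted elemental totals and charge of one reaction side."""
    totals: dict[str, int] = {}
    charge = 0
    for coef, sp in side:
        comp = elemental_composition(sp)
        for el, n in comp.elements:
            totals[el] = totals.get(el, 0) + coef * n
        charge += coef * comp.total_charge
    return CompositionVector(elements=tuple(sorted(totals.items())), total_charge=charge)


def is_balanced(eq: ReactionEquation, check_charge: bool = True) -> bool:
    """True iff per-element totals (and, by default, net charge) match."""
    left = side_composition(eq.reactants)
    right = side_composition(eq.products)
    if left.elements != right.elements:
        return False
    if check_charge and left.total_charge != right.total_charge:
        return False
    return True


def canonical_key(eq: ReactionEquation, direction_sensitive: bool = True) -> str:
    """Direction-preserving duplicate-detection key.

    Each side is treated as a multiset of canonical SMILES (one entry per
    stoichiometric unit): counts are aggregated per canonical species, sorted,
    and the sides joined with the output separator.  Equal keys identify
    duplicate equations.  With ``direction_sensitive=False`` the two side
    keys are themselves sorted, so A>>B and B>>A collide.
    """

    def side_key(side: tuple[tuple[int, Species], ...]) -> str:
        # aggregated counts rather than literal expansion: identical multiset
        # semantics, but safe against absurd generated coefficients
        counts: dict[str, int] = {}
        for coef, sp in side:
            key = sp.canonical_smiles
            counts[key] = counts.get(key, 0) + coef
        return " + ".join(f"{n}*{s}" for s, n in sorted(counts.items()))

    left, right = side_key(eq.reactants), side_key(eq.products)
    if not direction_sensitive:
        left, right = sorted((left, right))
    return f"{left} {OUTPUT_SEPARATOR} {right}"


def molecular_formula(species: Species) -> str:
    """Hill-order formula string (C first, then H, then alphabetical)."""
    comp = species.composition
    parts = []
    for el in ["C", "H"] + sorted(set(comp) - {"C", "H"}):
        n = comp.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def export_species_csv(species_list, path) -> None:
    """Write canonical_smiles, formula, charge rows (unique, sorted)."""
    seen: dict[str, Species] = {}
    for sp in species_list:
        seen.setdefault(sp.canonical_smiles, sp)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("canonical_smiles,formula,charge\n")
        for canonical in sorted(seen):
            sp = seen[canonical]
            fh.write(f"{canonical},{molecular_formula(sp)},{sp.net_charge}\n")


def read_reaction_file(path) -> list[ReactionEquation]:
    """Read a UTF-8 reaction text file: one equation per line, ``#`` comments."""
    equations = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            equations.append(parse_reaction_string(line))
    return equations


def write_reaction_file(path, equations) -> None:
    """Write equations one per line in the output dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for eq in equations:
            fh.write(format_reaction(eq) + "\n")
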