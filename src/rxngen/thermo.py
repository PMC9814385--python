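"""Reaction-level thermodynamic combination layer over per-species tables.

Per-species standard-state enthalpy (eV), entropy (eV/K) and dipole magnitude
(debye) come from a pluggable property table — any adapter mapping canonical
SMILES to these three numbers can stand in for an electronic-structure code.
Reaction quantities are coefficient-weighted product-minus-reactant sums:

    dG_reaction = sum_c c*G(products) - sum_c c*G(reactants)
    dS_reaction = sum_c c*S(products) - sum_c c*S(reactants)
    dmu         = sum_c c*mu(products) - sum_c c*mu(reactants)

Per-species Gibbs energy defaults to the standard G = H - T*S; a
``sign_mode="paper"`` variant computing H + T*S is kept for comparison with
sources that print that form.  A +-bound stability filter (default 5 eV) keeps
reactions with |dG| <= bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rdkit import Chem

from .errors import ConfigurationError, LookupMissingError
from .reaction import ReactionEquation, Species, format_reaction

STANDARD_TEMPERATURE = 298.15  # K

#: Required property-table columns; names carry the unit contract.
TABLE_COLUMNS = ("canonical_smiles", "H_eV", "S_eV_per_K", "dipole_debye")


@dataclass(frozen=True)
class SpeciesThermo:
    """Standard-state per-species properties."""

    canonical_smiles: str
    enthalpy_H: float  # eV
    entropy_S: float  # eV / K
    dipole_mu: float  # debye, magnitude >= 0

    def __post_init__(self) -> None:
        vals = (self.enthalpy_H, self.entropy_S, self.dipole_mu)
        if not all(np.isfinite(v) for v in vals):
            raise ConfigurationError("species thermo values must be finite")
        if self.dipole_mu < 0:
            raise ConfigurationError("dipole magnitude must be >= 0")


@dataclass(frozen=True)
class ReactionThermo:
    """Per-reaction aggregate quantities."""

    delta_G: float  # eV
    delta_S: float  # eV / K
    delta_mu: float  # debye
    temperature_T: float = STANDARD_TEMPERATURE


class PropertyTable:
    """Canonical-SMILES keyed table of :class:`SpeciesThermo` rows."""

    def __init__(self, rows: dict[str, SpeciesThermo]) -> None:
        self.rows = rows

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PropertyTable":
        missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(
                f"property table missing unit-bearing columns: {missing} "
                f"(expected {list(TABLE_COLUMNS)})"
            )
        rows = {}
        for rec in frame.itertuples(index=False):
            canonical = Chem.CanonSmiles(rec.canonical_smiles)
            rows[canonical] = SpeciesThermo(
                canonical, float(rec.H_eV), float(rec.S_eV_per_K), float(rec.dipole_debye)
            )
        return cls(rows)

    @classmethod
    def read_csv(cls, path) -> "PropertyTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.canonical_smiles, t.enthalpy_H, t.entropy_S, t.dipole_mu)
             for t in self.rows.values()],
            columns=list(TABLE_COLUMNS),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def lookup(self, species: Species) -> SpeciesThermo:
        key = species.canonical_smiles
        if key not in self.rows:
            raise LookupMissingError(f"species {key!r} not in property table")
        return self.rows[key]


def gibbs_of_species(
    t: SpeciesThermo,
    temperature: float = STANDARD_TEMPERATURE,
    sign_mode: str = "standard",
) -> float:
    """Per-species Gibbs energy in eV.

    ``standard``: H - T*S.  ``paper``: H + T*S (printed-form variant).
    """
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be positive, got {temperature}")
    if sign_mode == "standard":
        return t.enthalpy_H - temperature * t.entropy_S
    if sign_mode == "paper":
        return t.enthalpy_H + temperature * t.entropy_S
    raise ConfigurationError(f"unknown sign_mode {sign_mode!r}")


def _weighted_sum(side, table: PropertyTable, value) -> float:
    return sum(coef * value(table.lookup(sp)) for coef, sp in side)


def reaction_gibbs(
    eq: ReactionEquation,
    table: PropertyTable,
    temperature: float = STANDARD_TEMPERATURE,
    sign_mode: str = "standard",
) -> float:
    """Coefficient-weighted product-minus-reactant Gibbs energy (eV)."""
    g = lambda t: gibbs_of_species(t, temperature, sign_mode)
    return _weighted_sum(eq.products, table, g) - _weighted_sum(eq.reactants, table, g)


def reaction_entropy_diff(eq: ReactionEquation, table: PropertyTable) -> float:
    """Coefficient-weighted product-minus-reactant entropy (eV/K)."""
    s = lambda t: t.entropy_S
    return _weighted_sum(eq.products, table, s) - _weighted_sum(eq.reactants, table, s)


def reaction_dipole_diff(eq: ReactionEquation, table: PropertyTable) -> float:
    """Coefficient-weighted product-minus-reactant dipole magnitude (debye)."""
    mu = lambda t: t.dipole_mu
    return _weighted_sum(eq.products, table, mu) - _weighted_sum(eq.reactants, table, mu)


@dataclass(frozen=True)
class AtomCharge:
    """One atom's element, partial charge (e) and position (angstrom)."""

    element: str
    partial_charge_q: float
    position_r: tuple[float, float, float]


def dipole_moment(
    atoms: list[AtomCharge], origin: str | tuple[float, float, float] = "charge_center"
) -> tuple[np.ndarray, float]:
    """Dipole vector mu = sum_a q_a * (r_a - origin) and its magnitude.

    ``origin`` is the center of nuclear charge by default, the geometric
    centroid with ``"centroid"``, or an explicit 3-vector.  The result is
    origin-independent exactly when the partial charges sum to zero.
    """
    if not atoms:
        raise ConfigurationError("dipole of an empty atom list is undefined")
    r = np.array([a.position_r for a in atoms], dtype=float)
    q = np.array([a.partial_charge_q for a in atoms], dtype=float)
    if isinstance(origin, str):
        if origin == "charge_center":
            pt = Chem.GetPeriodicTable()
            z = np.array([pt.GetAtomicNumber(a.element) for a in atoms], dtype=float)
            o = (z[:, None] * r).sum(axis=0) / z.sum()
        elif origin == "centroid":
            o = r.mean(axis=0)
        else:
            raise ConfigurationError(f"unknown dipole origin {origin!r}")
    else:
        o = np.asarray(origin, dtype=float)
    vec = (q[:, None] * (r - o)).sum(axis=0)
    return vec, float(np.linalg.norm(vec))


def evaluate_reactions(
    equations: list[ReactionEquation],
    table: PropertyTable,
    temperature: float = STANDARD_TEMPERATURE,
    sign_mode: str = "standard",
    bound: float = 5.0,
) -> pd.DataFrame:
    """Per-reaction dG/dS/dmu plus the stability-filter verdict as a frame."""
    rows = []
    for eq in equations:
        dg = reaction_gibbs(eq, table, temperature, sign_mode)
        rows.append(
            (
                format_reaction(eq),
                dg,
                reaction_entropy_diff(eq, table),
                reaction_dipole_diff(eq, table),
                abs(dg) <= bound,
            )
        )
    return pd.DataFrame(
        rows, columns=["equation", "delta_G_eV", "delta_S_eV_per_K", "delta_mu_debye", "kept"]
    )


def stability_filter(values, bound: float = 5.0):
    """Split items by |dG| <= bound (boundary kept).

    ``values`` is a sequence of (item, delta_G) pairs or bare delta_G numbers;
    returns (kept, removed) lists in input order.
    """
    kept, removed = [], []
    for v in values:
        dg = v[1] if isinstance(v, tuple) else v
        (kept if abs(dg) <= bound else removed).append(v)
    return kept, removed
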