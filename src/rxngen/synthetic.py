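"""Seeded synthetic reaction corpora for testing and toy-scale training.

Clean equations are balanced by construction: a reactant side is sampled from
a small gas-phase molecule library (H/C/O/N, radicals included) and a product
side with an identical elemental composition is drawn from a precomputed
enumeration of all sides up to the configured size.  Controlled fractions of
the corpus are then corrupted (unbalanced coefficients, unparseable species,
verbatim duplicates) and every line carries a ground-truth label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .reaction import ReactionEquation, Species, canonical_key, format_reaction

#: Small gas-phase molecules over {H, C, O, N}, radicals included.
DEFAULT_LIBRARY: tuple[str, ...] = (
    "[H][H]", "O=O", "O", "O=C=O", "C", "C=O", "CO", "CC",
    "N#N", "N", "OO", "O=CO", "C=C", "C#C", "CCO", "CN", "NN",
    "C#N", "N=O",
    "[H]", "[OH]", "[CH3]", "[O]", "[N]", "[CH2]",
)

#: Subset of short-SMILES species: keeps toy corpus strings compact, which
#: matters for desk-scale VAE training runs.
SHORT_LIBRARY: tuple[str, ...] = (
    "O", "C", "N", "CO", "CC", "OO", "NN", "CN", "C=C", "C#C", "C#N",
    "C=O", "N=O", "O=CO", "CCO", "[H]", "[O]", "[N]",
)

CLEAN, UNBALANCED, INVALID_SPECIES, DUPLICATE = (
    "clean", "unbalanced", "invalid_species", "duplicate",
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator."""

    library: tuple[str, ...] = DEFAULT_LIBRARY
    n_equations: int = 500
    max_species_per_side: int = 3
    max_coefficient: int = 4
    unbalanced_fraction: float = 0.0
    invalid_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.library = tuple(self.library)
        fracs = (self.unbalanced_fraction, self.invalid_fraction, self.duplicate_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ConfigurationError("corruption fractions must lie in [0,1] and sum to <= 1")
        if not self.library:
            raise ConfigurationError("molecule library is empty")
        if self.max_species_per_side < 1 or self.max_coefficient < 1:
            raise ConfigurationError("side size and coefficient bounds must be >= 1")


def _composition_tuple(smiles: str) -> tuple[tuple[str, int], int]:
    sp = Species(smiles)
    return tuple(sorted(sp.composition.items())), sp.net_charge


_SIDE_CACHE: dict[tuple, dict] = {}


def _enumerate_sides(cfg: GeneratorConfig) -> dict[tuple, list[tuple[tuple[int, int], ...]]]:
    """Map composition signature -> all sides realizing it.

    A side is a tuple of (library index, coefficient) pairs with at most
    ``max_species_per_side`` distinct species and coefficients up to
    ``max_coefficient``.  Cached per (library, bounds) since the enumeration
    is pure.
    """
    cache_key = (cfg.library, cfg.max_species_per_side, cfg.max_coefficient)
    if cache_key in _SIDE_CACHE:
        return _SIDE_CACHE[cache_key]
    comps = [_composition_tuple(s) for s in cfg.library]
    table: dict[tuple, list[tuple[tuple[int, int], ...]]] = {}
    n = len(cfg.library)
    coefs = range(1, cfg.max_coefficient + 1)
    for k in range(1, cfg.max_species_per_side + 1):
        for combo in itertools.combinations(range(n), k):
            for cs in itertools.product(coefs, repeat=k):
                totals: dict[str, int] = {}
                charge = 0
                for idx, c in zip(combo, cs):
                    elements, q = comps[idx]
                    for el, cnt in elements:
                        totals[el] = totals.get(el, 0) + c * cnt
                    charge += c * q
                sig = (tuple(sorted(totals.items())), charge)
                table.setdefault(sig, []).append(tuple(zip(combo, cs)))
    _SIDE_CACHE[cache_key] = table
    return table


def _side_to_pairs(side: tuple[tuple[int, int], ...], library: tuple[str, ...]):
    return tuple((coef, Species(library[idx])) for idx, coef in side)


def generate_corpus(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a labeled corpus.

    Returns a DataFrame with columns ``line`` (reaction-dialect string) and
    ``label`` (one of clean / unbalanced / invalid_species / duplicate).
    Clean lines are unique by canonical key and balanced by construction;
    duplicates always appear after the clean line they copy.
    """
    rng = np.random.default_rng(cfg.seed)
    side_table = _enumerate_sides(cfg)
    signatures = sorted(side_table.keys())  # deterministic ordering

    n_unbalanced = int(cfg.unbalanced_fraction * cfg.n_equations)
    n_invalid = int(cfg.invalid_fraction * cfg.n_equations)
    n_duplicate = int(cfg.duplicate_fraction * cfg.n_equations)
    n_clean = cfg.n_equations - n_unbalanced - n_invalid - n_duplicate
    if n_clean < 1:
        raise ConfigurationError("corruption fractions leave no clean equations")

    clean_eqs: list[ReactionEquation] = []
    seen_keys: set[str] = set()
    attempts = 0
    max_attempts = 200 * cfg.n_equations
    while len(clean_eqs) < n_clean:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "could not assemble enough unique balanced equations from the library"
            )
        sig = signatures[rng.integers(len(signatures))]
        sides = side_table[sig]
        if len(sides) < 2:
            continue
        i, j = rng.choice(len(sides), size=2, replace=False)
        left, right = sides[int(i)], sides[int(j)]
        eq = ReactionEquation(
            _side_to_pairs(left, cfg.library), _side_to_pairs(right, cfg.library)
        )
        key = canonical_key(eq)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        clean_eqs.append(eq)

    rows: list[tuple[str, str]] = [(format_reaction(eq), CLEAN) for eq in clean_eqs]

    def pick_clean() -> ReactionEquation:
        return clean_eqs[int(rng.integers(len(clean_eqs)))]

    for _ in range(n_unbalanced):
        eq = pick_clean()
        # bumping one coefficient always breaks balance (no species is empty)
        side = list(eq.reactants)
        k = int(rng.integers(len(side)))
        coef, sp = side[k]
        side[k] = (coef + 1, sp)
        rows.append((format_reaction(ReactionEquation(tuple(side), eq.products)), UNBALANCED))

    for _ in range(n_invalid):
        eq = pick_clean()
        side = list(eq.products)
        k = int(rng.integers(len(side)))
        coef, sp = side[k]
        side[k] = (coef, Species(sp.smiles + "("))  # unbalanced parenthesis: never parseable
        rows.append((format_reaction(ReactionEquation(eq.reactants, tuple(side))), INVALID_SPECIES))

    for _ in range(n_duplicate):
        rows.append((format_reaction(pick_clean()), DUPLICATE))

    return pd.DataFrame(rows, columns=["line", "label"])


def write_corpus(df: pd.DataFrame, lines_path, labels_path=None) -> None:
    """Write corpus lines to a reaction text file and labels to a sidecar CSV."""
    with open(lines_path, "w", encoding="utf-8") as fh:
        for line in df["line"]:
            fh.write(line + "\n")
    if labels_path is not None:
        df.to_csv(labels_path, index=False)


#: Exact property values planted for hand-computable expectations
#: (canonical SMILES -> (H in eV, S in eV/K, dipole in debye)).
PLANTED_THERMO: dict[str, tuple[float, float, float]] = {
    "[H][H]": (0.0, 0.00135, 0.0),
    "O=O": (0.0, 0.00213, 0.0),
    "O": (-2.506, 0.00196, 1.85),
}


def synth_species_thermo(
    canonical_smiles: str,
    seed: int = 0,
    h_range: tuple[float, float] = (-3.0, 3.0),
    s_range: tuple[float, float] = (5e-4, 5e-3),
    dipole_range: tuple[float, float] = (0.0, 4.0),
) -> tuple[float, float, float]:
    """Deterministic plausible (H, S, dipole) for any species.

    Stands in for a per-species electronic-structure calculation: the same
    (seed, canonical SMILES) always yields the same values, independent of
    the order species are requested in.
    """
    import zlib

    entropy = np.random.SeedSequence([seed, zlib.crc32(canonical_smiles.encode())])
    rng = np.random.default_rng(entropy)
    return (
        float(rng.uniform(*h_range)),
        float(rng.uniform(*s_range)),
        float(rng.uniform(*dipole_range)),
    )


def generate_thermo_table(
    library: tuple[str, ...] = DEFAULT_LIBRARY,
    seed: int = 0,
    h_range: tuple[float, float] = (-3.0, 3.0),
    s_range: tuple[float, float] = (5e-4, 5e-3),
    dipole_range: tuple[float, float] = (0.0, 4.0),
    planted: dict[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Seeded plausible standard-state property table for a molecule library.

    Designated species get exact planted values so that reaction-level
    answers have closed-form expectations.
    """
    if not library:
        raise ConfigurationError("molecule library is empty")
    if planted is None:
        planted = PLANTED_THERMO
    rows = []
    seen = set()
    for smiles in library:
        canonical = Species(smiles).canonical_smiles
        if canonical in seen:
            continue
        seen.add(canonical)
        if canonical in planted:
            h, s, mu = planted[canonical]
        else:
            h, s, mu = synth_species_thermo(canonical, seed, h_range, s_range, dipole_range)
        rows.append((canonical, h, s, mu))
    return pd.DataFrame(rows, columns=["canonical_smiles", "H_eV", "S_eV_per_K", "dipole_debye"])
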