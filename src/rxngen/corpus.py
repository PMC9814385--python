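"""Corpus ingestion, cleaning, character-level encoding and splitting.

The cleaning cascade retains equations that are fully SMILES-resolvable,
species-valid, balanced, have at most three distinct species per side and are
unique by canonical key; every dropped row gets one reason code.

Encoding is strictly per character against a corpus-wide vocabulary: each
distinct character maps to one positive integer code, 0 is the pad, and every
string is padded to the length of the longest retained equation string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, VocabularyError
from .reaction import (
    ReactionEquation,
    Species,
    canonical_key,
    format_reaction,
    is_balanced,
    parse_reaction_string,
)

# rejection reason codes, in cascade order
UNRESOLVABLE = "unresolvable"
INVALID_SPECIES = "invalid_species"
UNBALANCED = "unbalanced"
TOO_MANY_SPECIES = "too_many_species"
DUPLICATE = "duplicate"
UNPARSEABLE = "unparseable"


@dataclass
class SpeciesTable:
    """Integer id -> SMILES mapping emulating the two-CSV corpus dialect.

    ``smiles_alt`` emulates a second name-resolution service: when present
    and disagreeing (by canonical form) with ``smiles``, the species is
    dropped, which invalidates every equation referencing it.
    """

    frame: pd.DataFrame  # columns: id, smiles, optionally smiles_alt

    def __post_init__(self) -> None:
        if self.frame["id"].duplicated().any():
            raise ConfigurationError("species table contains duplicate ids")

    @classmethod
    def read_csv(cls, path, **kwargs) -> "SpeciesTable":
        return cls(pd.read_csv(path, **kwargs))

    def resolve(self, species_id: int) -> str | None:
        """SMILES for an id, or None if absent, missing, or cross-check fails."""
        rows = self.frame[self.frame["id"] == species_id]
        if rows.empty:
            return None
        row = rows.iloc[0]
        smiles = row.get("smiles")
        if not isinstance(smiles, str) or not smiles:
            return None
        alt = row.get("smiles_alt") if "smiles_alt" in self.frame.columns else None
        if isinstance(alt, str) and alt:
            a, b = Species(smiles), Species(alt)
            if not (a.is_valid() and b.is_valid()):
                return None
            if a.canonical_smiles != b.canonical_smiles:
                return None  # the two resolution services disagree: drop
        return smiles


def resolve_id_reactions(
    reactions: pd.DataFrame, table: SpeciesTable
) -> tuple[list[ReactionEquation], list[tuple[int, str]]]:
    """Turn id-referenced reaction rows into equations.

    ``reactions`` needs columns ``reactant_ids`` and ``product_ids`` holding
    whitespace-separated id lists.  Returns (equations, rejections); a row
    referencing an unresolvable id is rejected with reason ``unresolvable``.
    """
    out: list[ReactionEquation] = []
    rejections: list[tuple[int, str]] = []
    for i, row in reactions.reset_index(drop=True).iterrows():
        try:
            sides = []
            for col in ("reactant_ids", "product_ids"):
                ids = [int(x) for x in str(row[col]).split()]
                if not ids:
                    raise ValueError
                pairs = []
                for sid in ids:
                    smiles = table.resolve(sid)
                    if smiles is None:
                        raise KeyError(sid)
                    pairs.append((1, Species(smiles)))
                sides.append(tuple(pairs))
        except (KeyError, ValueError):
            rejections.append((i, UNRESOLVABLE))
            continue
        eq = ReactionEquation(sides[0], sides[1])
        out.append(ReactionEquation(sides[0], sides[1], format_reaction(eq)))
    return out, rejections


def clean_dataset(
    equations,
    table: SpeciesTable | None = None,
    max_species_per_side: int = 3,
    check_charge: bool = True,
) -> tuple[list[ReactionEquation], list[tuple[int, str]]]:
    """Apply the cleaning cascade; rejections are data, not errors.

    ``equations`` is either a list of :class:`ReactionEquation` or, together
    with ``table``, an id-referenced reaction DataFrame (see
    :func:`resolve_id_reactions`).  Returns (retained, rejections) where each
    rejection is (input index, reason code).  First occurrence wins for
    duplicates.
    """
    if table is not None:
        resolved, pre_rejections = resolve_id_reactions(equations, table)
        retained, sub = clean_dataset(
            resolved, max_species_per_side=max_species_per_side, check_charge=check_charge
        )
        # indices in `sub` refer to the resolved subset; map them back
        resolved_rows = [
            i for i in range(len(equations))
            if i not in {j for j, _ in pre_rejections}
        ]
        rejections = sorted(pre_rejections + [(resolved_rows[j], r) for j, r in sub])
        return retained, rejections
    retained: list[ReactionEquation] = []
    rejections: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i, eq in enumerate(equations):
        if not all(sp.is_valid() for sp in eq.species()):
            rejections.append((i, INVALID_SPECIES))
            continue
        if not is_balanced(eq, check_charge=check_charge):
            rejections.append((i, UNBALANCED))
            continue
        if eq.max_species_per_side() > max_species_per_side:
            rejections.append((i, TOO_MANY_SPECIES))
            continue
        key = canonical_key(eq)
        if key in seen:
            rejections.append((i, DUPLICATE))
            continue
        seen.add(key)
        retained.append(eq)
    return retained, rejections


def clean_corpus_lines(
    lines: list[str], **kwargs
) -> tuple[list[ReactionEquation], list[tuple[int, str]]]:
    """Like :func:`clean_dataset` but from raw text lines; adds the
    ``unparseable`` reason for lines that do not parse as the dialect."""
    equations: list[ReactionEquation | None] = []
    pre_rejections: dict[int, str] = {}
    for i, line in enumerate(lines):
        try:
            equations.append(parse_reaction_string(line))
        except Exception:
            equations.append(None)
            pre_rejections[i] = UNPARSEABLE
    parseable = [(i, eq) for i, eq in enumerate(equations) if eq is not None]
    retained, sub_rej = clean_dataset([eq for _, eq in parseable], **kwargs)
    index_map = [i for i, _ in parseable]
    rejections = [(index_map[j], reason) for j, reason in sub_rej]
    rejections += list(pre_rejections.items())
    rejections.sort()
    return retained, rejections


@dataclass(frozen=True)
class Vocabulary:
    """Bijective character <-> positive-integer code map with pad code 0."""

    char_to_code: dict[str, int]
    n_max: int

    pad_code: int = 0

    def __post_init__(self) -> None:
        codes = list(self.char_to_code.values())
        if len(set(codes)) != len(codes) or self.pad_code in codes:
            raise ConfigurationError("vocabulary codes must be distinct and exclude the pad")

    @property
    def code_to_char(self) -> dict[int, str]:
        return {v: k for k, v in self.char_to_code.items()}

    @property
    def size(self) -> int:
        """Number of symbols including the pad."""
        return len(self.char_to_code) + 1

    def to_dict(self) -> dict:
        return {"char_to_code": self.char_to_code, "n_max": self.n_max}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(char_to_code=dict(d["char_to_code"]), n_max=int(d["n_max"]))


def build_vocabulary(strings: list[str]) -> Vocabulary:
    """Universal alphabet over all equation strings; deterministic codes.

    Characters are sorted and coded from 1; two-letter element symbols are two
    characters and therefore two codes (character-level by design).
    """
    if not strings:
        raise ConfigurationError("cannot build a vocabulary from an empty corpus")
    alphabet = sorted({ch for s in strings for ch in s})
    return Vocabulary(
        char_to_code={ch: i + 1 for i, ch in enumerate(alphabet)},
        n_max=max(len(s) for s in strings),
    )


def encode_string(s: str, vocab: Vocabulary) -> np.ndarray:
    """Fixed-length integer code vector (trailing pads) for one string."""
    if len(s) > vocab.n_max:
        raise VocabularyError(f"string longer than n_max={vocab.n_max}: {s!r}")
    codes = np.full(vocab.n_max, vocab.pad_code, dtype=np.int64)
    for i, ch in enumerate(s):
        try:
            codes[i] = vocab.char_to_code[ch]
        except KeyError:
            raise VocabularyError(f"character {ch!r} not in vocabulary") from None
    return codes


def decode_sequence(codes: np.ndarray, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode_string`; trailing pads are stripped, and a pad
    anywhere terminates the string (fixed-length decoder convention)."""
    lookup = vocab.code_to_char
    chars = []
    for code in np.asarray(codes).tolist():
        if code == vocab.pad_code:
            break
        try:
            chars.append(lookup[int(code)])
        except KeyError:
            raise VocabularyError(f"code {code} not in vocabulary") from None
    return "".join(chars)


@dataclass
class EncodedEquation:
    """A fixed-length code vector paired with its source equation string."""

    codes: np.ndarray
    source: str


def encode_equation(eq: ReactionEquation | str, vocab: Vocabulary) -> EncodedEquation:
    s = eq if isinstance(eq, str) else format_reaction(eq)
    return EncodedEquation(codes=encode_string(s, vocab), source=s)


@dataclass
class CorpusSplit:
    """Disjoint 70/20/10 train/validation/test partition."""

    train: list[EncodedEquation]
    validation: list[EncodedEquation]
    test: list[EncodedEquation]
    seed: int


def split_dataset(
    corpus: list[EncodedEquation],
    seed: int,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
) -> CorpusSplit:
    """Seeded shuffle then partition; validation/test sizes round down and
    train takes the remainder."""
    n = len(corpus)
    if n < 10:
        raise ConfigurationError(f"corpus too small to split: {n} < 10")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(fractions[1] * n)
    n_test = int(fractions[2] * n)
    n_train = n - n_val - n_test
    shuffled = [corpus[i] for i in order]
    return CorpusSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
    )
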