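"""Latent-space sampling and the validation cascade for generated equations.

Latent points are drawn i.i.d. from the standard-normal prior (the
distribution the KL term regularizes the posterior toward), decoded greedily,
and passed through the cascade: dialect parse -> species validity -> duplicate
keying (against the training set and the batch emitted so far) -> balance.
Survivors are annotated with the canonical species they contain that the
training set never saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SpeciesValidityError
from .reaction import (
    ReactionEquation,
    Species,
    canonical_key,
    is_balanced,
    parse_reaction_string,
)

# rejection stage labels
UNPARSEABLE = "unparseable"
INVALID_SPECIES = "invalid_species"
DUPLICATE_TRAINING = "duplicate_of_training"
DUPLICATE_GENERATED = "duplicate_of_generated"
UNBALANCED = "unbalanced"

STAGES = (UNPARSEABLE, INVALID_SPECIES, DUPLICATE_TRAINING, DUPLICATE_GENERATED, UNBALANCED)


@dataclass
class GenerationRecord:
    """One decoded string with its validation verdicts."""

    raw_string: str
    parseable: bool = False
    species_valid: bool = False
    duplicate: bool = False
    balanced: bool = False
    equation: ReactionEquation | None = None
    novel_species: tuple[str, ...] = ()

    @property
    def survived(self) -> bool:
        return self.parseable and self.species_valid and self.balanced and not self.duplicate


@dataclass
class GenerationStats:
    """Bookkeeping for one generation run; sampled = survivors + rejections."""

    sampled: int = 0
    survivors: int = 0
    rejections: dict[str, int] = field(default_factory=lambda: {s: 0 for s in STAGES})

    @property
    def total_rejections(self) -> int:
        return sum(self.rejections.values())

    def to_dict(self) -> dict:
        return {
            "sampled": self.sampled,
            "survivors": self.survivors,
            "rejections": dict(self.rejections),
        }


def sample_latent(k: int, latent_dim: int, seed: int | np.random.Generator) -> np.ndarray:
    """k i.i.d. standard-normal prior points of dimension latent_dim."""
    if k < 0:
        raise ConfigurationError("sample count must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((k, latent_dim))


def classify_string(
    raw: str,
    training_keys: set[str],
    emitted_keys: set[str],
    check_charge: bool = True,
) -> tuple[GenerationRecord, str | None]:
    """Run one decoded string through the cascade.

    Returns the record and the rejection stage (None for survivors).
    """
    rec = GenerationRecord(raw_string=raw)
    try:
        eq = parse_reaction_string(raw)
    except Exception:
        return rec, UNPARSEABLE
    rec.parseable = True
    rec.equation = eq
    if not all(sp.is_valid() for sp in eq.species()):
        return rec, INVALID_SPECIES
    rec.species_valid = True
    key = canonical_key(eq)
    if key in training_keys:
        rec.duplicate = True
        return rec, DUPLICATE_TRAINING
    if key in emitted_keys:
        rec.duplicate = True
        return rec, DUPLICATE_GENERATED
    if not is_balanced(eq, check_charge=check_charge):
        return rec, UNBALANCED
    rec.balanced = True
    emitted_keys.add(key)
    return rec, None


def generate(
    model,
    training_keys: set[str],
    training_species: set[str],
    count: int,
    seed: int,
    mode: str = "samples",
    dedup_against_training: bool = True,
    max_samples: int | None = None,
    batch_size: int = 200,
    source: str = "prior",
    encoded_corpus=None,
    perturbation_scale: float = 1.0,
    check_charge: bool = True,
) -> tuple[list[GenerationRecord], GenerationStats]:
    """Sample, decode and validate equations from a trained model.

    ``mode="samples"`` draws exactly ``count`` latent points; ``mode="survivors"``
    keeps sampling until ``count`` survivors exist (bounded by ``max_samples``,
    default 1000x count).  ``source="perturb"`` draws around the posterior
    means of ``encoded_corpus`` instead of the prior.
    """
    if mode not in ("samples", "survivors"):
        raise ConfigurationError(f"unknown generation mode {mode!r}")
    if source not in ("prior", "perturb"):
        raise ConfigurationError(f"unknown latent source {source!r}")
    if source == "perturb" and not encoded_corpus:
        raise ConfigurationError("perturb mode needs an encoded corpus")
    rng = np.random.default_rng(seed)
    latent_dim = model.config.latent_dim
    training_keys = set(training_keys) if dedup_against_training else set()
    emitted_keys: set[str] = set()
    records: list[GenerationRecord] = []
    stats = GenerationStats()
    if max_samples is None:
        max_samples = count if mode == "samples" else 1000 * max(count, 1)

    def latent_batch(k: int) -> np.ndarray:
        if source == "prior":
            return sample_latent(k, latent_dim, rng)
        picks = rng.integers(len(encoded_corpus), size=k)
        codes = np.stack([encoded_corpus[i].codes for i in picks])
        mean, _ = model.encode(codes)
        return mean + perturbation_scale * rng.standard_normal(mean.shape)

    done = lambda: (
        stats.sampled >= count if mode == "samples" else stats.survivors >= count
    )
    while not done() and stats.sampled < max_samples:
        k = min(batch_size, max_samples - stats.sampled)
        if mode == "samples":
            k = min(k, count - stats.sampled)
        strings = model.greedy_decode(latent_batch(k))
        for raw in strings:
            stats.sampled += 1
            rec, stage = classify_string(raw, training_keys, emitted_keys, check_charge)
            if stage is None:
                stats.survivors += 1
                rec.novel_species = tuple(
                    sorted(
                        {sp.canonical_smiles for sp in rec.equation.species()}
                        - training_species
                    )
                )
            else:
                stats.rejections[stage] += 1
            records.append(rec)
            if done():
                break
    return records, stats


def novelty_report(
    records: list[GenerationRecord], training_species: set[str]
) -> tuple[set[str], dict[str, int]]:
    """Novel canonical species across survivors, plus per-species counts of
    surviving equations containing each species."""
    novel: set[str] = set()
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.survived:
            continue
        present = {sp.canonical_smiles for sp in rec.equation.species()}
        for s in present:
            counts[s] = counts.get(s, 0) + 1
        novel |= present - training_species
    return novel, counts


def filter_by_species(
    equations: list[ReactionEquation], query_smiles: str
) -> list[ReactionEquation]:
    """Equations containing the query species (canonical match, either side)."""
    query = Species(query_smiles)
    if not query.is_valid():
        raise SpeciesValidityError(f"unparseable query SMILES {query_smiles!r}")
    target = query.canonical_smiles
    out = []
    for eq in equations:
        if any(sp.canonical_smiles == target for sp in eq.species()):
            out.append(eq)
    return out


def records_to_frame(records: list[GenerationRecord]) -> pd.DataFrame:
    """Full audit trail as a DataFrame (CSV-ready)."""
    rows = [
        (
            r.raw_string, r.parseable, r.species_valid, r.duplicate, r.balanced,
            r.survived, " ".join(r.novel_species),
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "raw_string", "parseable", "species_valid", "duplicate", "balanced",
            "survived", "novel_species",
        ],
    )
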