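"""Exception hierarchy for rxngen."""


class RxngenError(Exception):
    """Base class for all rxngen errors."""


class ReactionParseError(RxngenError):
    """A reaction string does not follow the reaction dialect."""


class SpeciesValidityError(RxngenError):
    """A species SMILES cannot be parsed or sanitized by the chemistry toolkit."""


class VocabularyError(RxngenError):
    """A character or code is absent from the vocabulary."""


class ConfigurationError(RxngenError):
    """Invalid configuration or unusable input shape/size."""


class LookupMissingError(RxngenError, KeyError):
    """A species is missing from a property table."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class TrainingDivergedError(RxngenError):
    """Training produced a non-finite loss."""
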