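"""Exception hierarchy for the AGNC nomenclature toolkit."""


class AgncError(Exception):
    """Base class for all toolkit errors."""


class MalformedNameError(AgncError, ValueError):
    """A species name is empty or unusable after normalization."""


class CollisionExhaustionError(AgncError):
    """No unique abbreviation can be built from the epithet's letters."""

    def __init__(self, epithet: str, tried: tuple[str, ...]):
        self.epithet = epithet
        self.tried = tried
        super().__init__(
            f"cannot build a unique code for {epithet!r}: "
            f"all candidates taken ({', '.join(tried)})"
        )


class RegistryIntegrityError(AgncError):
    """The packaged canonical registry is corrupt or inconsistent."""


class InvalidSymbolError(AgncError, ValueError):
    """A gene symbol contains disallowed characters."""


class ProvisionalNameError(AgncError, ValueError):
    """A provisional ortholog identifier (KIAA#, C#orf#) was used as a basis."""


class UnsupportedCountError(AgncError, ValueError):
    """Duplication suffixing was requested for more copies than one round supports."""


class UnsupportedSpeciesError(AgncError, ValueError):
    """No styling convention is defined for the requested species."""


class VocabularyError(AgncError, ValueError):
    """A token is not a member of its controlled vocabulary."""

    def __init__(self, token: str, field: str, valid: tuple[str, ...]):
        self.token = token
        self.field = field
        self.valid = tuple(valid)
        super().__init__(
            f"unknown {field} token {token!r}; valid tokens: {', '.join(self.valid)}"
        )


class StructureError(AgncError, ValueError):
    """A serialized record has the wrong shape (e.g. field count)."""


class DomainError(AgncError, ValueError):
    """A numeric argument is outside its documented domain."""


class SequenceError(AgncError, ValueError):
    """A nucleotide sequence contains characters outside the allowed alphabet."""


class GrammarError(AgncError, ValueError):
    """An identifier does not match its naming grammar."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ConfigError(AgncError, ValueError):
    """A configuration file contains unknown keys or invalid values."""
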