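"""Four-character *Anolis* species abbreviations.

Every abbreviation is a capital ``A`` (for the genus) followed by three
lowercase letters drawn from the species epithet: by default the first two
letters plus an identifying third letter.  When the default third letter
collides with an established code, the next epithet letter that yields a
unique code is used instead (``grahami`` → ``Agra``, then ``gracilipes`` →
``Agrc``, ``granuliceps`` → ``Agrn``).  Precedence between species competing
for the same letters follows publication date, supplied here as an explicit
rank.

The canonical registry of 378 abbreviations ships with the package and is
authoritative: a handful of its entries were fixed by committee rather than
by the greedy rule, so the generator is only ever applied to names absent
from the registry.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

from .errors import (
    CollisionExhaustionError,
    MalformedNameError,
    RegistryIntegrityError,
)

CODE_PATTERN = re.compile(r"^A[a-z]{3}$")

CANONICAL_REGISTRY_SIZE = 378

_GENUS_PREFIX = re.compile(r"^(anolis\s+|a\.\s*)", re.IGNORECASE)


@dataclass(frozen=True)
class SpeciesRecord:
    """One species epithet bound to its unique abbreviation code."""

    epithet: str
    code: str
    precedence_rank: int = 0

    def __post_init__(self) -> None:
        if not CODE_PATTERN.match(self.code):
            raise MalformedNameError(
                f"code {self.code!r} must be 'A' plus three lowercase letters"
            )
        if not self.epithet or not self.epithet.isalpha() or not self.epithet.islower():
            raise MalformedNameError(
                f"epithet {self.epithet!r} must be lowercase letters only"
            )
        if self.precedence_rank < 0:
            raise MalformedNameError("precedence_rank must be non-negative")


@dataclass(frozen=True)
class SpeciesRegistry:
    """An ordered, duplicate-free collection of species records."""

    records: tuple[SpeciesRecord, ...]
    frozen: bool = False

    def __post_init__(self) -> None:
        codes = [r.code for r in self.records]
        epithets = [r.epithet for r in self.records]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise RegistryIntegrityError(f"duplicate codes in registry: {dup}")
        if len(set(epithets)) != len(epithets):
            dup = sorted({e for e in epithets if epithets.count(e) > 1})
            raise RegistryIntegrityError(f"duplicate epithets in registry: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(r.code for r in self.records)

    def by_code(self, code: str) -> SpeciesRecord | None:
        for r in self.records:
            if r.code == code:
                return r
        return None

    def by_epithet(self, epithet: str) -> SpeciesRecord | None:
        for r in self.records:
            if r.epithet == epithet:
                return r
        return None


@dataclass
class ValidationFinding:
    level: str  # "error" | "warning" | "info"
    message: str


@dataclass
class ValidationReport:
    ok: bool
    findings: list[ValidationFinding] = field(default_factory=list)
    epithet: str | None = None


def normalize_epithet(raw_name: str) -> str:
    """Reduce a species name to a bare lowercase epithet.

    Strips an optional genus prefix (``Anolis `` or ``A. ``), folds case,
    decomposes diacritics, and drops every non-Latin-letter character
    (hyphens included).
    """
    name = raw_name.strip()
    if not name:
        raise MalformedNameError("empty species name")
    name = _GENUS_PREFIX.sub("", name)
    name = unicodedata.normalize("NFKD", name)
    letters = "".join(c for c in name.lower() if "a" <= c <= "z")
    if not letters:
        raise MalformedNameError(
            f"nothing left of {raw_name!r} after normalization"
        )
    return letters


def generate_code(epithet: str, taken_codes: Iterable[str] = ()) -> str:
    """Build the abbreviation for ``epithet``, avoiding ``taken_codes``.

    The candidate third letters are the epithet's letters from position 3
    onward, in epithet order; a letter already tried is not retried.  If
    every candidate collides the search fails loudly — there is no silent
    fallback to letters outside the epithet.
    """
    if len(epithet) < 3:
        raise MalformedNameError(
            f"epithet {epithet!r} has fewer than 3 letters; no code rule applies"
        )
    if not epithet.isalpha() or not epithet.islower():
        raise MalformedNameError(
            f"epithet {epithet!r} must be normalized (lowercase letters only)"
        )
    taken = set(taken_codes)
    prefix = "A" + epithet[:2]
    tried: list[str] = []
    seen_letters: set[str] = set()
    for letter in epithet[2:]:
        if letter in seen_letters:
            continue
        seen_letters.add(letter)
        candidate = prefix + letter
        if candidate not in taken:
            return candidate
        tried.append(candidate)
    raise CollisionExhaustionError(epithet, tuple(tried))


def assign_codes(names: Iterable[tuple[str, int] | str]) -> SpeciesRegistry:
    """Assign codes to a batch of epithets in precedence order.

    ``names`` is a sequence of ``(epithet, precedence_rank)`` pairs (bare
    epithets get rank 0).  Lower ranks are served first; ties keep input
    order.  Each code is generated against everything assigned before it.
    """
    normalized: list[tuple[int, int, str]] = []
    for i, item in enumerate(names):
        if isinstance(item, str):
            epithet, rank = item, 0
        else:
            epithet, rank = item
        normalized.append((rank, i, normalize_epithet(epithet)))
    epithets = [e for _, _, e in normalized]
    if len(set(epithets)) != len(epithets):
        dup = sorted({e for e in epithets if epithets.count(e) > 1})
        raise MalformedNameError(f"duplicate epithets in input: {dup}")
    normalized.sort(key=lambda t: (t[0], t[1]))
    taken: set[str] = set()
    records = []
    for rank, _, epithet in normalized:
        code = generate_code(epithet, taken)
        taken.add(code)
        records.append(SpeciesRecord(epithet=epithet, code=code, precedence_rank=rank))
    return SpeciesRegistry(records=tuple(records))


def validate_code(code: str, registry: SpeciesRegistry | None = None) -> ValidationReport:
    """Check a code against the format rules and, optionally, a registry.

    Returns findings rather than raising: format problems are errors, an
    unregistered but well-formed code is a warning when a registry was given.
    """
    findings: list[ValidationFinding] = []
    if len(code) != 4:
        findings.append(
            ValidationFinding("error", f"code must be 4 characters, got {len(code)}")
        )
    if code and code[0] != "A":
        findings.append(
            ValidationFinding("error", "leading character must be 'A' (genus Anolis)")
        )
    if len(code) == 4 and code[0] == "A" and not CODE_PATTERN.match(code):
        findings.append(
            ValidationFinding("error", "positions 2-4 must be lowercase Latin letters")
        )
    epithet = None
    if registry is not None and not findings:
        record = registry.by_code(code)
        if record is None:
            findings.append(
                ValidationFinding("warning", f"code {code!r} is not registered")
            )
        else:
            epithet = record.epithet
            findings.append(
                ValidationFinding("info", f"{code} is registered to {epithet!r}")
            )
    ok = not any(f.level in ("error", "warning") for f in findings)
    return ValidationReport(ok=ok, findings=findings, epithet=epithet)


_CANONICAL: SpeciesRegistry | None = None


def load_canonical_registry() -> SpeciesRegistry:
    """Load the packaged committee registry of 378 abbreviations (cached)."""
    global _CANONICAL
    if _CANONICAL is not None:
        return _CANONICAL
    text = resources.files("agnc.data").joinpath("species_registry.json").read_text()
    mapping: Mapping[str, str] = json.loads(text)
    records = tuple(
        SpeciesRecord(epithet=e, code=c, precedence_rank=i)
        for i, (e, c) in enumerate(mapping.items())
    )
    registry = SpeciesRegistry(records=records, frozen=True)
    if len(registry) != CANONICAL_REGISTRY_SIZE:
        raise RegistryIntegrityError(
            f"canonical registry has {len(registry)} records, "
            f"expected {CANONICAL_REGISTRY_SIZE}"
        )
    _CANONICAL = registry
    return registry
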