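"""Anolis gene-symbol derivation, styling, and validation.

Anolis gene symbols are the lowercase counterpart of the ortholog's symbol
(human ``GENE2`` → anole ``gene2``), written all-lowercase so the species can
be inferred from casing alone: all-caps for human and chicken, capitalized
for mouse, lowercase for *Xenopus*, zebrafish and *Anolis*.  Punctuation is
carried over only when the source symbol has it (``NKX3-1`` → ``nkx3-1``);
provisional identifiers (KIAA#, C#orf#) are rejected as a basis for naming.
Lineage-specific duplications get alphabetic suffixes (``gene2a``/``gene2b``;
an already-suffixed stem gains a second letter: ``gene4aa``/``gene4ab``).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

from . import species_codes
from .errors import (
    InvalidSymbolError,
    ProvisionalNameError,
    UnsupportedCountError,
    UnsupportedSpeciesError,
)
from .species_codes import ValidationFinding, ValidationReport

STYLED_SPECIES = ("human", "mouse", "chicken", "xenopus", "zebrafish", "anolis")

#: casing convention per species: "upper" | "capitalized" | "lower"
_CASE_CLASS = {
    "human": "upper",
    "chicken": "upper",
    "mouse": "capitalized",
    "xenopus": "lower",
    "zebrafish": "lower",
    "anolis": "lower",
}

_SYMBOL_OK = re.compile(r"^[a-z0-9-]+$")
_PROVISIONAL = (
    re.compile(r"^KIAA\d+$", re.IGNORECASE),
    re.compile(r"^C\d+orf\d+$", re.IGNORECASE),
)
_MOL_WEIGHT_SYMBOL = re.compile(r"^p\d+$", re.IGNORECASE)
_MOL_WEIGHT_NAME = re.compile(r"\b\d+\s*k ?Dal?\b", re.IGNORECASE)
_HOMOLOGY_PAREN = re.compile(r"\s*\(([A-Z][A-Za-z. ]*)\)\s*$")


@dataclass(frozen=True)
class SymbolStyle:
    case_class: str
    italic: bool


@dataclass(frozen=True)
class GeneSymbolRecord:
    symbol: str
    name: str = ""
    source_symbol: str = ""
    source_species: str = "human"
    duplicate_suffix: str = ""

    def __post_init__(self) -> None:
        if not _SYMBOL_OK.match(self.symbol):
            raise InvalidSymbolError(
                f"symbol {self.symbol!r} must be lowercase letters, digits, dash"
            )
        if "-" in self.symbol and "-" not in self.source_symbol and self.source_symbol:
            raise InvalidSymbolError(
                "dash allowed only when present in the source ortholog symbol"
            )
        if self.source_species not in STYLED_SPECIES:
            raise UnsupportedSpeciesError(self.source_species)


def is_provisional(symbol_or_name: str) -> bool:
    """True for provisional ortholog identifiers like KIAA0101 or C10orf54."""
    token = symbol_or_name.strip()
    return any(p.match(token) for p in _PROVISIONAL)


def derive_symbol(source_symbol: str, source_species: str = "human") -> str:
    """Lowercase an ortholog symbol into the Anolis symbol.

    Raises if the source is non-ASCII, carries punctuation other than a
    dash, or is a provisional identifier.
    """
    if source_species not in STYLED_SPECIES:
        raise UnsupportedSpeciesError(source_species)
    sym = source_symbol.strip()
    if not sym:
        raise InvalidSymbolError("empty source symbol")
    if not sym.isascii():
        raise InvalidSymbolError(f"{sym!r} contains non-ASCII characters")
    if is_provisional(sym):
        raise ProvisionalNameError(
            f"{sym!r} is a provisional identifier and cannot seed an Anolis symbol"
        )
    lowered = sym.lower()
    if not _SYMBOL_OK.match(lowered):
        bad = sorted({c for c in lowered if not re.match(r"[a-z0-9-]", c)})
        raise InvalidSymbolError(
            f"{sym!r} contains disallowed characters: {bad}"
        )
    return lowered


def suffix_duplicates(base_symbol: str, copy_count: int) -> list[str]:
    """Name ``copy_count`` lineage-specific duplicates of ``base_symbol``.

    Appends ``a``, ``b``, … to the stem.  A stem that already carries a
    duplication-suffix letter naturally gains a second letter this way, so
    ``gene4a`` yields ``gene4aa``/``gene4ab``.  One alphabetic round only.
    """
    if copy_count < 2:
        raise UnsupportedCountError("duplication suffixing needs copy_count >= 2")
    if copy_count > 26:
        raise UnsupportedCountError(
            f"copy_count {copy_count} exceeds one alphabetic round (26)"
        )
    if not _SYMBOL_OK.match(base_symbol):
        raise InvalidSymbolError(f"invalid base symbol {base_symbol!r}")
    return [base_symbol + string.ascii_lowercase[i] for i in range(copy_count)]


def protein_symbol(gene_symbol: str) -> str:
    """Protein symbols are the gene symbol in all caps (and not italicized)."""
    if not _SYMBOL_OK.match(gene_symbol):
        raise InvalidSymbolError(f"invalid gene symbol {gene_symbol!r}")
    return gene_symbol.upper()


def style_for_species(symbol: str, species: str) -> tuple[str, SymbolStyle]:
    """Render a symbol in the casing convention of ``species``.

    All gene symbols are italicized; only the case class differs between
    species, which is what lets a reader infer the species from the symbol.
    """
    if species not in STYLED_SPECIES:
        raise UnsupportedSpeciesError(
            f"{species!r}; supported: {', '.join(STYLED_SPECIES)}"
        )
    case_class = _CASE_CLASS[species]
    base = symbol.lower()
    if case_class == "upper":
        styled = base.upper()
    elif case_class == "capitalized":
        styled = base[:1].upper() + base[1:]
    else:
        styled = base
    return styled, SymbolStyle(case_class=case_class, italic=True)


def interspecies_suffix(symbol: str, species_code: str) -> str:
    """Tag a symbol with a species abbreviation for cross-species tables.

    ``gene2`` + ``Asag`` → ``gene2-Asag``.
    """
    if not _SYMBOL_OK.match(symbol):
        raise InvalidSymbolError(f"invalid gene symbol {symbol!r}")
    report = species_codes.validate_code(species_code)
    if not report.ok:
        raise InvalidSymbolError(
            f"bad species code {species_code!r}: "
            + "; ".join(f.message for f in report.findings)
        )
    return f"{symbol}-{species_code}"


def check_species_prefix(symbol: str, source_symbol: str | None = None) -> bool:
    """True if the symbol illegitimately starts with an 'a'/'ac' species prefix.

    Symbols must not start with "a"/"ac" standing for *Anolis carolinensis*;
    they may when the source ortholog itself starts with those letters
    (``actb``).  Without a source symbol nothing can be flagged.
    """
    if source_symbol is None:
        return False
    return symbol.lower().startswith("a") and not source_symbol.lower().startswith("a")


def validate_gene_name(name: str, check_proper_names: bool = False) -> ValidationReport:
    """Screen a full gene name against the committee's naming rules.

    Findings (never exceptions): trailing homology parentheticals such as
    "(Drosophila)", provisional identifiers, and molecular-weight references
    (``p35``, "35 kDal").  A capitalized-token heuristic for proper or
    commercial names is available but off by default — it is too subjective
    to fail on.
    """
    findings: list[ValidationFinding] = []
    m = _HOMOLOGY_PAREN.search(name)
    if m:
        suggested = _HOMOLOGY_PAREN.sub("", name).strip()
        findings.append(
            ValidationFinding(
                "warning",
                f"homology reference {m.group(0).strip()!r}; suggested: {suggested!r}",
            )
        )
    for token in re.findall(r"[A-Za-z0-9]+", name):
        if is_provisional(token):
            findings.append(
                ValidationFinding("warning", f"provisional identifier {token!r}")
            )
    if _MOL_WEIGHT_SYMBOL.match(name.strip()) or _MOL_WEIGHT_NAME.search(name):
        findings.append(
            ValidationFinding("warning", "molecular-weight reference in gene name")
        )
    if check_proper_names:
        for token in name.split():
            if token[:1].isupper() and token.isalpha() and len(token) > 1:
                findings.append(
                    ValidationFinding(
                        "info", f"capitalized token {token!r} may be a proper name"
                    )
                )
    ok = not any(f.level in ("error", "warning") for f in findings)
    return ValidationReport(ok=ok, findings=findings)
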