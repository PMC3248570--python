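"""Evolutionary character code (ECC) strings.

An ECC condenses one gene's evolutionary annotation into a single
colon-separated string of seven fields::

    <gene>:<span>:<prot>,<nuc>:<relation>:<score>:<up>,<down>:<expr>

    gene2:chordates:80,55:1-1:5:3,4:TS

read as: *gene2* has detectable orthology only within chordates, with 80%
protein and 55% nucleotide identity, a one-to-one copy relation with the
reference genome, a transcript evidence score of 5 (gene prediction + EST),
3 upstream and 4 downstream genes with conserved synteny, and
tissue-specific expression.  dN/dS may replace the identity percentages; the
pair is then serialized with a ``dnds=`` prefix so the two modes are never
ambiguous.

The taxonomic span is a token from a ladder of nested clades around
*Anolis* (most-nested first): squamates ⊂ reptiles ⊂ amniotes ⊂ tetrapods ⊂
vertebrates ⊂ chordates.  :func:`assign_span` picks the most inclusive clade
demanded by the comparison taxa in which a reliable alignment exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from .errors import DomainError, StructureError, VocabularyError

#: nested clades around Anolis, most-nested first
DEFAULT_CLADE_LADDER: tuple[str, ...] = (
    "squamates",
    "reptiles",
    "amniotes",
    "tetrapods",
    "vertebrates",
    "chordates",
)

#: expression-comparison tokens: tissue-specific, conserved expression, no data
DEFAULT_EXPRESSION_CODES: tuple[str, ...] = ("TS", "CE", "ND")

#: comparison taxa → most-nested ladder clade containing that taxon and Anolis
COMPARISON_TAXA: dict[str, str] = {
    "non_avian_reptiles": "reptiles",
    "birds": "reptiles",
    "mammals": "amniotes",
    "amphibians": "tetrapods",
    "teleosts": "vertebrates",
    "non_vertebrate_chordates": "chordates",
}

RELATION_TOKENS = ("1-1", "1-n", "n-1", "n-n")

CopyCount = int | Literal["n"]


def classify_relation(copies_query: int, copies_reference: int) -> str:
    """Class a copy-number pair as 1-1, 1-n, n-1 or n-n.

    A zero count means no ortholog at all — that is a span/absence question,
    not a relation, and is rejected here.
    """
    for c in (copies_query, copies_reference):
        if not isinstance(c, int) or c < 1:
            raise DomainError(f"copy counts must be integers >= 1, got {c!r}")
    q = "1" if copies_query == 1 else "n"
    r = "1" if copies_reference == 1 else "n"
    return f"{q}-{r}"


def _normalize_copy(value: CopyCount) -> CopyCount:
    if value == "n":
        return "n"
    if not isinstance(value, int) or value < 1:
        raise DomainError(f"copy count must be a positive integer or 'n', got {value!r}")
    return 1 if value == 1 else "n"


def _fmt_metric(x: float) -> str:
    """Render a metric without trailing zeros (80.0 → '80', 1.30 → '1.3')."""
    s = f"{float(x):.10g}"
    return s


@dataclass(frozen=True)
class ECCRecord:
    """Structured form of one gene's evolutionary character code.

    Copy counts are stored canonically as ``1`` or the marker ``"n"`` (any
    integer > 1 is collapsed on construction), so parsing a serialized record
    reproduces it exactly.
    """

    gene_id: str
    taxonomic_span: str
    protein_metric: float
    nucleotide_metric: float
    copies_query: CopyCount
    copies_reference: CopyCount
    evidence_score: int
    synteny_up: int
    synteny_down: int
    expression_code: str
    identity_mode: Literal["percent_identity", "dn_ds"] = "percent_identity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "copies_query", _normalize_copy(self.copies_query))
        object.__setattr__(
            self, "copies_reference", _normalize_copy(self.copies_reference)
        )
        if self.identity_mode not in ("percent_identity", "dn_ds"):
            raise VocabularyError(
                self.identity_mode, "identity_mode", ("percent_identity", "dn_ds")
            )
        lo_ok = self.protein_metric >= 0 and self.nucleotide_metric >= 0
        if not lo_ok:
            raise DomainError("identity/divergence metrics must be non-negative")
        if self.identity_mode == "percent_identity":
            if self.protein_metric > 100 or self.nucleotide_metric > 100:
                raise DomainError("percent identities must lie in [0, 100]")
        if not (0 <= self.evidence_score <= 15):
            raise DomainError(f"evidence_score {self.evidence_score} outside [0, 15]")
        if self.synteny_up < 0 or self.synteny_down < 0:
            raise DomainError("synteny counts must be non-negative")

    @property
    def relation(self) -> str:
        q = "1" if self.copies_query == 1 else "n"
        r = "1" if self.copies_reference == 1 else "n"
        return f"{q}-{r}"


def serialize(
    record: ECCRecord,
    ladder: tuple[str, ...] = DEFAULT_CLADE_LADDER,
    expression_codes: tuple[str, ...] = DEFAULT_EXPRESSION_CODES,
) -> str:
    """Render an :class:`ECCRecord` as its canonical colon-separated string."""
    if record.taxonomic_span not in ladder:
        raise VocabularyError(record.taxonomic_span, "taxonomic span", ladder)
    if record.expression_code not in expression_codes:
        raise VocabularyError(record.expression_code, "expression", expression_codes)
    metrics = f"{_fmt_metric(record.protein_metric)},{_fmt_metric(record.nucleotide_metric)}"
    if record.identity_mode == "dn_ds":
        metrics = "dnds=" + metrics
    return ":".join(
        (
            record.gene_id,
            record.taxonomic_span,
            metrics,
            record.relation,
            str(record.evidence_score),
            f"{record.synteny_up},{record.synteny_down}",
            record.expression_code,
        )
    )


def parse(
    ecc_string: str,
    ladder: tuple[str, ...] = DEFAULT_CLADE_LADDER,
    expression_codes: tuple[str, ...] = DEFAULT_EXPRESSION_CODES,
) -> ECCRecord:
    """Parse a serialized ECC back into a validated :class:`ECCRecord`."""
    fields = ecc_string.split(":")
    if len(fields) != 7:
        raise StructureError(
            f"expected 7 colon-separated fields, got {len(fields)}: {ecc_string!r}"
        )
    gene_id, span, metrics, relation, score_s, synteny, expr = fields
    if not gene_id:
        raise StructureError("empty gene id field")
    if span not in ladder:
        raise VocabularyError(span, "taxonomic span", ladder)
    mode: Literal["percent_identity", "dn_ds"] = "percent_identity"
    if metrics.startswith("dnds="):
        mode = "dn_ds"
        metrics = metrics[len("dnds="):]
    try:
        prot_s, nuc_s = metrics.split(",")
        prot, nuc = float(prot_s), float(nuc_s)
    except ValueError as exc:
        raise StructureError(f"bad identity metrics field {metrics!r}") from exc
    if relation not in RELATION_TOKENS:
        raise VocabularyError(relation, "relation", RELATION_TOKENS)
    cq: CopyCount = 1 if relation[0] == "1" else "n"
    cr: CopyCount = 1 if relation[-1] == "1" else "n"
    try:
        score = int(score_s)
    except ValueError as exc:
        raise StructureError(f"non-integer evidence score {score_s!r}") from exc
    try:
        up_s, down_s = synteny.split(",")
        up, down = int(up_s), int(down_s)
    except ValueError as exc:
        raise StructureError(f"bad synteny field {synteny!r}") from exc
    if expr not in expression_codes:
        raise VocabularyError(expr, "expression", expression_codes)
    return ECCRecord(
        gene_id=gene_id,
        taxonomic_span=span,
        protein_metric=prot,
        nucleotide_metric=nuc,
        copies_query=cq,
        copies_reference=cr,
        evidence_score=score,
        synteny_up=up,
        synteny_down=down,
        expression_code=expr,
        identity_mode=mode,
    )


def _canonical_taxon(token: str) -> str:
    return token.strip().lower().replace("-", "_").replace(" ", "_")


def assign_span(
    alignment_presence: Mapping[str, bool],
    ladder: tuple[str, ...] = DEFAULT_CLADE_LADDER,
) -> str | None:
    """Pick the taxonomic-span token demanded by where alignments exist.

    ``alignment_presence`` maps comparison-taxon tokens (mammals, birds,
    non-avian reptiles, amphibians, teleosts, non-vertebrate chordates) to
    whether a reliable alignment was found.  The result is the most
    inclusive ladder clade required to cover every taxon with presence;
    presence only among the reptile comparison taxa gives the most nested
    covering clade.  No presence at all (empty map or all false) returns
    ``None`` — the no-detectable-homolog signal, deliberately not an error.
    """
    required_idx = -1
    for token, present in alignment_presence.items():
        canon = _canonical_taxon(token)
        if canon not in COMPARISON_TAXA:
            raise VocabularyError(token, "comparison taxon", tuple(COMPARISON_TAXA))
        if not present:
            continue
        clade = COMPARISON_TAXA[canon]
        if clade not in ladder:
            raise VocabularyError(clade, "taxonomic span", ladder)
        required_idx = max(required_idx, ladder.index(clade))
    if required_idx < 0:
        return None
    return ladder[required_idx]
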