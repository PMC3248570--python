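"""Name grammars for conserved sequences, STRs, and transposable elements.

Three identifier families, all anchored on the four-character species code:

* **Conserved sequences (CS)** — highly conserved segments without defining
  sequence content.  Name = species code + 1-indexed number + length class
  (``s`` ≤ 99 bp, ``m`` 100–499 bp, ``l`` ≥ 500 bp) + conservation class
  (``1`` 95–100%, ``2`` 90–94%, ``3`` 85–89%) + taxon letters, always
  serialized in the order S (Sauropsida), M (Mammalia), B (Batrachia),
  G (Gymnophiona).  Example: ``Acar1000l1SMB``.

* **STRs (microsatellites)** — ``<SpeciesCode>_str_<index>``, e.g.
  ``Acar_str_8``; descriptive per-locus metadata (unit, copies, location)
  lives in a sidecar registry keyed by name, not in the name itself.

* **Transposable elements** — ``<lineage>-[HT]<id>[N<id>]_<SpeciesCode>``:
  superfamily or clade token, family number (``HT`` prefix when the family
  arrived by horizontal transfer), ``N<k>`` for the *k*-th non-autonomous
  family amplified by that family.  Examples: ``Helitron-1_Acar``,
  ``Helitron-1N1_Acar``, ``hAT-HT1_Acar``, ``hobo-1_Acar``.

A deliberately minimal perfect-tandem-repeat scanner is included so STR
naming and registry plumbing can be exercised end to end from a FASTA; it is
not a general-purpose repeat finder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .errors import DomainError, GrammarError, SequenceError
from .species_codes import CODE_PATTERN

TAXON_ORDER = "SMBG"  # Sauropsida, Mammalia, Batrachia, Gymnophiona


# ---------------------------------------------------------------- conserved


def length_class(length_bp: int) -> str:
    """s / m / l length class for a conserved sequence."""
    if length_bp < 1:
        raise DomainError("length must be a positive number of base pairs")
    if length_bp <= 99:
        return "s"
    if length_bp <= 499:
        return "m"
    return "l"


#: class → inclusive (min_bp, max_bp); None = unbounded
LENGTH_CLASS_BOUNDS = {"s": (1, 99), "m": (100, 499), "l": (500, None)}

#: class → inclusive (min_pct, max_pct)
CONSERVATION_CLASS_BOUNDS = {1: (95, 100), 2: (90, 94), 3: (85, 89)}


def conservation_class(conservation_pct: float) -> int:
    """1 / 2 / 3 conservation class; values below 85% have no class.

    Class boundaries are printed as integers, so fractional inputs are
    rounded half-up to an integer percent before classing (94.5% → class 1).
    """
    rounded = int(
        Decimal(str(conservation_pct)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
    if rounded > 100:
        raise DomainError(f"conservation {conservation_pct}% exceeds 100%")
    for cls, (lo, hi) in CONSERVATION_CLASS_BOUNDS.items():
        if lo <= rounded <= hi:
            return cls
    raise DomainError(
        f"conservation {conservation_pct}% is below the 85% floor of the CS classes"
    )


def _check_code(species_code: str) -> None:
    if not CODE_PATTERN.match(species_code):
        raise GrammarError(f"bad species code {species_code!r}")


def _canonical_taxa(taxa: Iterable[str]) -> str:
    letters = set(taxa)
    if not letters:
        raise DomainError("taxon set must be non-empty")
    bad = letters - set(TAXON_ORDER)
    if bad:
        raise DomainError(f"unknown taxon letters {sorted(bad)}; valid: S, M, B, G")
    return "".join(t for t in TAXON_ORDER if t in letters)


@dataclass(frozen=True)
class ConservedSequenceDescriptor:
    """Full description of a conserved sequence prior to naming."""

    species_code: str
    index: int
    length_bp: int
    conservation_pct: float
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        _check_code(self.species_code)
        if self.index < 1:
            raise DomainError("CS indices are 1-based")
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        _canonical_taxa(self.taxa)


@dataclass(frozen=True)
class CSNameFields:
    """Parsed CS name.  Length and conservation come back as class bounds,
    because the name encodes classes, not exact values."""

    species_code: str
    index: int
    length_class: str
    length_bounds: tuple[int, int | None]
    conservation_class: int
    conservation_bounds: tuple[int, int]
    taxa: frozenset[str]


def cs_name(descriptor: ConservedSequenceDescriptor) -> str:
    """Serialize a descriptor, e.g. 600 bp at 100% shared S,M,B →
    ``Acar1000l1SMB``."""
    return (
        descriptor.species_code
        + str(descriptor.index)
        + length_class(descriptor.length_bp)
        + str(conservation_class(descriptor.conservation_pct))
        + _canonical_taxa(descriptor.taxa)
    )


_CS_RE = re.compile(r"^(A[a-z]{3})(\d+)([sml])([123])([SMBG]+)$")


def cs_parse(name: str) -> CSNameFields:
    """Parse a CS name back into its fields (classes as intervals)."""
    m = _CS_RE.match(name)
    if not m:
        for i, ch in enumerate(name):
            if i < 4:
                if not (ch == "A" if i == 0 else ch.islower()):
                    raise GrammarError(f"bad species code in {name!r}", position=i)
            else:
                break
        raise GrammarError(f"{name!r} does not match the CS grammar", position=4)
    code, index_s, lcls, ccls_s, taxa_s = m.groups()
    if len(set(taxa_s)) != len(taxa_s):
        raise GrammarError(f"repeated taxon letter in {name!r}")
    ccls = int(ccls_s)
    return CSNameFields(
        species_code=code,
        index=int(index_s),
        length_class=lcls,
        length_bounds=LENGTH_CLASS_BOUNDS[lcls],
        conservation_class=ccls,
        conservation_bounds=CONSERVATION_CLASS_BOUNDS[ccls],
        taxa=frozenset(taxa_s),
    )


# --------------------------------------------------------------------- STRs


def str_name(species_code: str, index: int) -> str:
    """``Acar_str_8`` for the 8th STR described in *A. carolinensis*."""
    _check_code(species_code)
    if index < 1:
        raise DomainError("STR indices are 1-based")
    return f"{species_code}_str_{index}"


_STR_RE = re.compile(r"^(A[a-z]{3})_str_([1-9]\d*)$")


def str_parse(name: str) -> tuple[str, int]:
    """Recover (species_code, index) from an STR name."""
    m = _STR_RE.match(name)
    if not m:
        raise GrammarError(f"{name!r} does not match the STR grammar")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class STRRecord:
    """One perfect tandem repeat: naming fields plus locus metadata."""

    species_code: str
    index: int
    unit: str
    copies: int
    seq_id: str = ""
    start: int = 0  # 0-based, half-open
    end: int = 0

    @property
    def name(self) -> str:
        return str_name(self.species_code, self.index)


def _min_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repeat of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def scan_strs(
    sequence: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_copies: int = 2,
    species_code: str = "Acar",
    seq_id: str = "",
) -> list[STRRecord]:
    """Find maximal non-overlapping perfect tandem repeats.

    Whole-copy perfect repeats only, unit lengths ``min_unit``–``max_unit``.
    Overlaps are resolved longest-first, then leftmost; the survivors are
    reported leftmost-first with indices 1, 2, … in scan order.  The unit is
    reported in its lexicographically minimal rotation.
    """
    if not (1 <= min_unit <= max_unit):
        raise DomainError("need 1 <= min_unit <= max_unit")
    if min_copies < 2:
        raise DomainError("min_copies must be at least 2")
    _check_code(species_code)
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")

    # maximal runs: unit primitive, not extendable by one more full copy on
    # the left, copies maximal to the right
    candidates: list[tuple[int, int, str, int]] = []  # (start, length, unit, copies)
    n = len(seq)
    for u in range(min_unit, max_unit + 1):
        for i in range(0, n - u * 2 + 1):
            unit = seq[i : i + u]
            if not _is_primitive(unit):
                continue
            if i >= u and seq[i - u : i] == unit:
                continue  # not leftmost occurrence of this run
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k >= min_copies:
                candidates.append((i, k * u, unit, k))

    candidates.sort(key=lambda c: (-c[1], c[0]))
    chosen: list[tuple[int, int, str, int]] = []
    occupied: list[tuple[int, int]] = []
    for start, length, unit, copies in candidates:
        end = start + length
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        chosen.append((start, length, unit, copies))
    chosen.sort(key=lambda c: c[0])
    return [
        STRRecord(
            species_code=species_code,
            index=i,
            unit=_min_rotation(unit),
            copies=copies,
            seq_id=seq_id,
            start=start,
            end=start + length,
        )
        for i, (start, length, unit, copies) in enumerate(chosen, start=1)
    ]


class STRRegistry:
    """Ordered registry of STR loci for one species.

    Indices are assigned 1, 2, … in submission order and never reused; the
    registry round-trips through a TSV sidecar
    (``name, unit, copies, seq_id, start, end``; coordinates 0-based
    half-open).
    """

    def __init__(self, species_code: str = "Acar"):
        _check_code(species_code)
        self.species_code = species_code
        self.records: list[STRRecord] = []

    def add(self, unit: str, copies: int, seq_id: str = "", start: int = 0, end: int = 0) -> STRRecord:
        rec = STRRecord(
            species_code=self.species_code,
            index=len(self.records) + 1,
            unit=unit,
            copies=copies,
            seq_id=seq_id,
            start=start,
            end=end,
        )
        self.records.append(rec)
        return rec

    def extend(self, found: Iterable[STRRecord]) -> list[STRRecord]:
        return [
            self.add(r.unit, r.copies, seq_id=r.seq_id, start=r.start, end=r.end)
            for r in found
        ]

    def by_name(self, name: str) -> STRRecord:
        code, index = str_parse(name)
        if code != self.species_code or not (1 <= index <= len(self.records)):
            raise DomainError(f"{name!r} is not in this registry")
        return self.records[index - 1]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tunit\tcopies\tseq_id\tstart\tend\n")
            for r in self.records:
                fh.write(
                    f"{r.name}\t{r.unit}\t{r.copies}\t{r.seq_id}\t{r.start}\t{r.end}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "STRRegistry":
        registry: STRRegistry | None = None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["name", "unit", "copies", "seq_id", "start", "end"]:
                raise GrammarError(f"unexpected STR registry header {header}")
            for lineno, line in enumerate(fh, start=2):
                name, unit, copies, seq_id, start, end = line.rstrip("\n").split("\t")
                code, index = str_parse(name)
                if registry is None:
                    registry = cls(code)
                if index != len(registry.records) + 1:
                    raise GrammarError(
                        f"registry indices must be gap-free; got {name!r} at line {lineno}"
                    )
                registry.add(unit, int(copies), seq_id=seq_id, start=int(start), end=int(end))
        return registry if registry is not None else cls()


# ------------------------------------------------------- transposable elems

_TE_RE = re.compile(
    r"^(?P<lineage>[A-Za-z][A-Za-z0-9]*)-(?P<ht>HT)?(?P<family>[1-9]\d*)"
    r"(?:N(?P<nonauto>[1-9]\d*))?_(?P<code>A[a-z]{3})$"
)


@dataclass(frozen=True)
class TEName:
    """Parsed transposable-element name.

    ``lineage`` is the superfamily or, when the diversity below superfamily
    level is well characterized, the monophyletic clade (``hobo`` rather
    than ``hAT``).  ``horizontally_transferred`` renders as an ``HT`` prefix
    on the family number; ``nonautonomous_id`` identifies a non-autonomous
    family amplified by the autonomous one.
    """

    lineage: str
    family_id: int
    species_code: str
    nonautonomous_id: int | None = None
    horizontally_transferred: bool = False

    def __post_init__(self) -> None:
        if not re.match(r"^[A-Za-z][A-Za-z0-9]*$", self.lineage):
            raise GrammarError(
                f"lineage {self.lineage!r} must be alphanumeric without dash/underscore"
            )
        if self.family_id < 1:
            raise DomainError("family_id must be a positive integer")
        if self.nonautonomous_id is not None and self.nonautonomous_id < 1:
            raise DomainError("nonautonomous_id must be a positive integer")
        _check_code(self.species_code)


def te_name(name: TEName) -> str:
    """Serialize a :class:`TEName` (``Helitron-1N1_Acar`` and kin)."""
    ht = "HT" if name.horizontally_transferred else ""
    na = f"N{name.nonautonomous_id}" if name.nonautonomous_id is not None else ""
    return f"{name.lineage}-{ht}{name.family_id}{na}_{name.species_code}"


def te_parse(name: str) -> TEName:
    """Parse a TE name string back into a :class:`TEName`."""
    m = _TE_RE.match(name)
    if not m:
        dash = name.find("-")
        raise GrammarError(
            f"{name!r} does not match the TE grammar "
            "<lineage>-[HT]<family>[N<k>]_<SpeciesCode>",
            position=dash if dash >= 0 else None,
        )
    return TEName(
        lineage=m.group("lineage"),
        family_id=int(m.group("family")),
        species_code=m.group("code"),
        nonautonomous_id=int(m.group("nonauto")) if m.group("nonauto") else None,
        horizontally_transferred=m.group("ht") is not None,
    )
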