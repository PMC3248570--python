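"""Flank-conservation counting against a reference gene order.

Synteny (conserved gene order) is evidence for orthology when sequence
similarity alone is equivocal.  Around a focal gene, each flank (5' and 3')
is walked nearest-first; the conserved count is the length of the maximal
prefix whose genes all have reference orthologs occupying strictly
monotonic, consecutive rank positions in the reference genome (the
"sequential order" requirement).  An unmapped gene, a direction flip, or a
rank gap larger than ``max_gap`` (0 by default) terminates the prefix.

The minimal recognition rule: orthology can be recognized when at least two
sequentially ordered reference orthologs sit on a single flank.  The
reference is typically *Gallus gallus*, but any gene-order table works.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Literal, Mapping, NamedTuple

import pandas as pd

from .errors import DomainError

Flank = Literal["up", "down"]

#: a reference position: plain coordinate, or (sequence id, coordinate)
Position = float | int | tuple[Hashable, float | int]


@dataclass(frozen=True)
class FlankContext:
    """A focal gene, its ordered flanks, and the reference mapping.

    ``upstream_genes``/``downstream_genes`` are nearest-first.
    ``ortholog_map`` is a partial map from query genes to reference genes;
    ``reference_order`` maps reference genes to positions (optionally
    ``(seq_id, position)`` tuples — genes on different reference sequences
    are never rank-adjacent).
    """

    focal_gene: str
    upstream_genes: tuple[str, ...]
    downstream_genes: tuple[str, ...]
    ortholog_map: Mapping[str, str]
    reference_order: Mapping[str, Position]

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream_genes", tuple(self.upstream_genes))
        object.__setattr__(self, "downstream_genes", tuple(self.downstream_genes))
        for flank in (self.upstream_genes, self.downstream_genes):
            if self.focal_gene in flank:
                raise DomainError("focal gene must not appear in its own flank")
            if len(set(flank)) != len(flank):
                raise DomainError("flank lists must not contain duplicates")
        positions = list(self.reference_order.values())
        if len(set(positions)) != len(positions):
            raise DomainError("reference positions must be unique (ties are input errors)")


def _reference_ranks(reference_order: Mapping[str, Position]) -> dict[str, tuple[Hashable, int]]:
    """Ordinal ranks (1-based) per reference sequence from raw positions."""
    by_seq: dict[Hashable, list[tuple[float, str]]] = {}
    for gene, pos in reference_order.items():
        seq: Hashable
        if isinstance(pos, tuple):
            seq, coord = pos
        else:
            seq, coord = "_ref", pos
        by_seq.setdefault(seq, []).append((float(coord), gene))
    ranks: dict[str, tuple[Hashable, int]] = {}
    for seq, items in by_seq.items():
        items.sort()
        for i, (_, gene) in enumerate(items, start=1):
            ranks[gene] = (seq, i)
    return ranks


def flank_conservation(context: FlankContext, flank: Flank, max_gap: int = 0) -> int:
    """Length of the maximal conserved nearest-first prefix of one flank."""
    if flank not in ("up", "down"):
        raise DomainError(f"flank must be 'up' or 'down', got {flank!r}")
    if max_gap < 0:
        raise DomainError("max_gap must be non-negative")
    genes = context.upstream_genes if flank == "up" else context.downstream_genes
    ranks = _reference_ranks(context.reference_order)

    count = 0
    prev: tuple[Hashable, int] | None = None
    direction = 0
    for gene in genes:
        ref = context.ortholog_map.get(gene)
        if ref is None or ref not in ranks:
            break
        seq, rank = ranks[ref]
        if prev is None:
            count = 1
        else:
            prev_seq, prev_rank = prev
            step = rank - prev_rank
            if seq != prev_seq or step == 0:
                break
            if abs(step) > 1 + max_gap:
                break
            sign = 1 if step > 0 else -1
            if direction and sign != direction:
                break
            direction = sign
            count += 1
        prev = (seq, rank)
    return count


class OrthologyCall(NamedTuple):
    met: bool
    up_count: int
    down_count: int


def minimal_orthology_met(context: FlankContext, max_gap: int = 0) -> OrthologyCall:
    """Apply the at-least-2-sequential-orthologs-on-one-flank rule."""
    up = flank_conservation(context, "up", max_gap=max_gap)
    down = flank_conservation(context, "down", max_gap=max_gap)
    return OrthologyCall(met=up >= 2 or down >= 2, up_count=up, down_count=down)


def ecc_synteny_fields(context: FlankContext, max_gap: int = 0) -> tuple[int, int]:
    """(upstream, downstream) conserved counts for the ECC synteny field."""
    return (
        flank_conservation(context, "up", max_gap=max_gap),
        flank_conservation(context, "down", max_gap=max_gap),
    )


def context_from_tables(
    focal_gene: str,
    query_order: pd.DataFrame,
    reference_order: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    flank_len: int | None = None,
) -> FlankContext:
    """Build a :class:`FlankContext` from gene-order tables.

    ``query_order`` / ``reference_order`` need columns ``gene_id``,
    ``seq_id``, ``position``; ``ortholog_map`` needs ``query_gene``,
    ``reference_gene``.  Upstream is the lower-coordinate side of the focal
    gene on its query sequence.
    """
    for df, cols, label in (
        (query_order, ("gene_id", "seq_id", "position"), "query_order"),
        (reference_order, ("gene_id", "seq_id", "position"), "reference_order"),
        (ortholog_map, ("query_gene", "reference_gene"), "ortholog_map"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DomainError(f"{label} table lacks columns {missing}")
    focal_rows = query_order[query_order["gene_id"] == focal_gene]
    if len(focal_rows) != 1:
        raise DomainError(
            f"focal gene {focal_gene!r} occurs {len(focal_rows)} times in query order"
        )
    seq = focal_rows["seq_id"].iloc[0]
    pos = focal_rows["position"].iloc[0]
    same_seq = query_order[query_order["seq_id"] == seq].sort_values("position")
    before = same_seq[same_seq["position"] < pos]["gene_id"].tolist()
    after = same_seq[same_seq["position"] > pos]["gene_id"].tolist()
    upstream = tuple(reversed(before))  # nearest-first
    downstream = tuple(after)
    if flank_len is not None:
        upstream = upstream[:flank_len]
        downstream = downstream[:flank_len]
    omap = dict(zip(ortholog_map["query_gene"], ortholog_map["reference_gene"]))
    ref_positions: dict[str, Position] = {
        g: (s, p)
        for g, s, p in zip(
            reference_order["gene_id"],
            reference_order["seq_id"],
            reference_order["position"],
        )
    }
    return FlankContext(
        focal_gene=focal_gene,
        upstream_genes=upstream,
        downstream_genes=downstream,
        ortholog_map=omap,
        reference_order=ref_positions,
    )
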