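"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from agnc.synteny import FlankContext

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def oracle_flank_count(context: FlankContext, flank: str, max_gap: int = 0) -> int:
    """Brute-force flank-conservation count: test every prefix length and
    both monotone directions directly against the definition."""
    genes = context.upstream_genes if flank == "up" else context.downstream_genes
    # independent rank computation: sort (seq, coord) pairs per sequence
    items = []
    for gene, pos in context.reference_order.items():
        if isinstance(pos, tuple):
            items.append((pos[0], float(pos[1]), gene))
        else:
            items.append(("_ref", float(pos), gene))
    ranks: dict[str, tuple[object, int]] = {}
    for seq in {s for s, _, _ in items}:
        seq_items = sorted((c, g) for s, c, g in items if s == seq)
        for i, (_, g) in enumerate(seq_items):
            ranks[g] = (seq, i)

    def prefix_ok(k: int) -> bool:
        rs = []
        for gene in genes[:k]:
            ref = context.ortholog_map.get(gene)
            if ref is None or ref not in ranks:
                return False
            rs.append(ranks[ref])
        if len({s for s, _ in rs}) > 1:
            return False
        vals = [r for _, r in rs]
        if len(set(vals)) != len(vals):
            return False
        for direction in (1, -1):
            steps = [(b - a) * direction for a, b in zip(vals, vals[1:])]
            if all(1 <= s <= 1 + max_gap for s in steps):
                return True
        return k <= 1

    best = 0
    for k in range(1, len(genes) + 1):
        if prefix_ok(k):
            best = k
    return best


def random_context(rng: random.Random, max_flank: int = 12) -> FlankContext:
    """A random flank context: random mapping density and reference shuffling."""
    n_up = rng.randint(0, max_flank)
    n_down = rng.randint(0, max_flank)
    upstream = tuple(f"u{i}" for i in range(n_up))
    downstream = tuple(f"d{i}" for i in range(n_down))
    n_ref = rng.randint(1, 2 * max_flank + 4)
    ref_genes = [f"r{i}" for i in range(n_ref)]
    positions = rng.sample(range(10 * n_ref), n_ref)
    reference_order = dict(zip(ref_genes, positions))
    ortholog_map = {}
    for gene in upstream + downstream:
        if rng.random() < 0.8:
            ortholog_map[gene] = rng.choice(ref_genes)
    return FlankContext(
        focal_gene="focal",
        upstream_genes=upstream,
        downstream_genes=downstream,
        ortholog_map=ortholog_map,
        reference_order=reference_order,
    )


def oracle_tandem_candidates(seq: str, min_unit: int, max_unit: int, min_copies: int):
    """Enumerate maximal perfect whole-copy tandem runs by direct substring
    comparison (quadratic; independent of the scanner's loop structure)."""
    out = []
    n = len(seq)
    for i in range(n):
        for u in range(min_unit, max_unit + 1):
            if i + 2 * u > n:
                continue
            unit = seq[i : i + u]
            # primitive unit
            if any(u % d == 0 and unit == unit[:d] * (u // d) for d in range(1, u)):
                continue
            # leftmost start of this run
            if i >= u and seq[i - u : i] == unit:
                continue
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k >= min_copies:
                out.append((i, k * u, unit, k))
    return out


def oracle_scan(seq: str, min_unit=1, max_unit=6, min_copies=2):
    """Reference STR scan: candidates longest-first then leftmost, greedy
    non-overlap, reported leftmost-first."""
    cands = sorted(
        oracle_tandem_candidates(seq, min_unit, max_unit, min_copies),
        key=lambda c: (-c[1], c[0]),
    )
    taken = []
    for start, length, unit, copies in cands:
        if all(start >= e or start + length <= s for s, e in taken):
            taken.append((start, start + length))
            taken.sort()
    result = []
    for s, e in taken:
        for start, length, unit, copies in cands:
            if start == s and start + length == e:
                result.append((start, e, copies))
                break
    return result


@pytest.fixture(scope="session")
def canonical_registry():
    from agnc.species_codes import load_canonical_registry

    return load_canonical_registry()
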