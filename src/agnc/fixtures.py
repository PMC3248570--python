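"""Seed-deterministic synthetic fixtures.

Every module can be exercised without external data: species lists with a
controllable rate of three-letter prefix collisions (the situation that
forces fallback-letter resolution), and flank contexts engineered to carry
an exact number of conserved genes per flank.
"""

from __future__ import annotations

import random

from .errors import CollisionExhaustionError, DomainError
from .species_codes import generate_code
from .synteny import FlankContext

_VOWELS = "aeiou"
_CONSONANTS = "bcdfghjklmnpqrstvwz"


def _pseudo_epithet(rng: random.Random, n_syllables: int) -> str:
    out = []
    for _ in range(n_syllables):
        out.append(rng.choice(_CONSONANTS))
        out.append(rng.choice(_VOWELS))
    if rng.random() < 0.5:
        out.append(rng.choice("sm"))
    return "".join(out)


def make_species_fixture(
    n: int, collision_rate: float, seed: int
) -> list[tuple[str, int]]:
    """Generate ``n`` distinct pseudo-Latin epithets with precedence ranks.

    Approximately ``collision_rate * n`` of the names share their first
    three letters with another name in the list, so code assignment must
    fall back to later epithet letters.  Deterministic under ``seed``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0.0 <= collision_rate <= 1.0):
        raise DomainError("collision_rate must lie in [0, 1]")
    rng = random.Random(seed)
    names: list[str] = []
    seen: set[str] = set()
    prefixes: set[str] = set()
    taken_codes: set[str] = set()
    while len(names) < n:
        want_collision = names and rng.random() < collision_rate
        if want_collision:
            base = rng.choice(names)
            candidate = base[:3] + _pseudo_epithet(rng, rng.randint(2, 3))
        else:
            candidate = _pseudo_epithet(rng, rng.randint(2, 4))
            if candidate[:3] in prefixes:
                continue  # keep non-collision draws collision-free
        if len(candidate) < 4 or candidate in seen:
            continue
        try:
            # every emitted name must still be codeable after its
            # predecessors claim their codes (ranks follow list order)
            code = generate_code(candidate, taken_codes)
        except CollisionExhaustionError:
            continue
        taken_codes.add(code)
        seen.add(candidate)
        prefixes.add(candidate[:3])
        names.append(candidate)
    return [(name, rank) for rank, name in enumerate(names)]


def make_synteny_fixture(
    up_conserved: int,
    down_conserved: int,
    flank_len: int,
    seed: int,
) -> FlankContext:
    """Build a flank context whose conserved counts are exactly as requested.

    The first ``up_conserved`` upstream genes (nearest-first) map to
    consecutive ascending reference ranks; the gene right after the
    conserved prefix is either left unmapped or mapped far away (a rank
    gap), chosen by the seeded RNG, so the count cannot run long.  Same for
    the downstream flank in a disjoint reference region.
    """
    if not (0 <= up_conserved <= flank_len and 0 <= down_conserved <= flank_len):
        raise DomainError("conserved counts must lie in [0, flank_len]")
    rng = random.Random(seed)
    upstream = tuple(f"u{i}" for i in range(1, flank_len + 1))
    downstream = tuple(f"d{i}" for i in range(1, flank_len + 1))
    ortholog_map: dict[str, str] = {}
    reference_order: dict[str, float] = {}

    # two disjoint reference blocks, far apart, plus a remote decoy region
    def lay_out(genes: tuple[str, ...], conserved: int, base: int, tag: str) -> None:
        for i in range(conserved):
            ref = f"{tag}ref{i}"
            ortholog_map[genes[i]] = ref
            reference_order[ref] = base + i
        if conserved < len(genes):
            breaker = genes[conserved]
            if conserved >= 1 and rng.random() < 0.5:
                # break by rank gap: an unmapped spacer reference gene sits
                # between the conserved block and the breaker's ortholog, so
                # the rank step is >= 2
                reference_order[f"{tag}spacer"] = base + 200
                ref = f"{tag}far"
                ortholog_map[breaker] = ref
                reference_order[ref] = base + 500 + rng.randint(0, 100)
            # else: break by leaving the breaker unmapped
            # genes past the breaker stay unmapped so the count is exact

    lay_out(upstream, up_conserved, base=1000, tag="U")
    lay_out(downstream, down_conserved, base=3000, tag="D")
    # decoy reference genes that no query gene maps to
    for i in range(5):
        reference_order[f"decoy{i}"] = 9000 + i
    return FlankContext(
        focal_gene="focal",
        upstream_genes=upstream,
        downstream_genes=downstream,
        ortholog_map=ortholog_map,
        reference_order=reference_order,
    )
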