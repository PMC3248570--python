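# Methods

This note records the conventions the toolkit implements, the choices made
where the published rules leave room, and what the synthetic fixtures do and
do not emulate.

## Species abbreviation codes

A code is the capital `A` (reserved for the genus *Anolis*) followed by
three lowercase letters. Generation is greedy: the first two epithet
letters are fixed; the third letter is the epithet's third letter, and on
collision the scan continues through the remaining epithet letters in
order, skipping letters already tried (a repeated letter is tried only
once). Precedence between species competing for the same letters follows
publication date; because the publication dates themselves are not part of
the standard's published material, precedence enters the API as an explicit
caller-supplied rank (ties broken by input order). The scan never leaves
the epithet: if every candidate collides, assignment fails loudly rather
than inventing a letter, since a code whose letters are not in the epithet
would no longer be mnemonic.

The packaged registry of 378 codes is **authoritative, not regenerated**.
A few committee-assigned entries deviate from the strict greedy scan (the
registry was fixed by people balancing mnemonics across clusters of similar
epithets), so the registry exempts its own entries from algorithmic
reproduction and the generator is applied only to names absent from it.
Epithets shorter than three letters are a hard error; none exist in the
registry. Normalization strips a `Anolis `/`A. ` genus prefix, folds case,
decomposes diacritics, and drops non-letters.

## Gene symbols

Derivation is deliberately minimal: the anole symbol is the ortholog symbol
lowercased, with punctuation carried over only when the source has it
(dashes allowed; periods and slashes rejected). Provisional identifiers
(`KIAA\d+`, `C\d+orf\d+`) are rejected as a basis for naming. Where human
and mouse symbols disagree, the toolkit reports a conflict and defaults to
the human symbol — the standard asks authors to consult the committee, but
a batch tool needs deterministic behaviour, so the conflict is surfaced as
a finding instead of a stall. Duplication suffixing appends `a`, `b`, … to
the stem; a stem that already carries a suffix letter naturally gains a
second letter (`gene4a` → `gene4aa`, `gene4ab`). One alphabetic round (26
copies) is the supported maximum; no gene family in the source material
comes anywhere near it. The proper/commercial-name screen is a
capitalized-token heuristic and is **off by default**: it cannot
distinguish "Coca Cola" from a legitimate eponymous protein family without
a curated dictionary, so it only warns when explicitly enabled.

## Transcript evidence score

The four evidence categories carry binary place-value weights (EST 1,
protein overlap 2, consistent prediction 4, consistent cDNA 8), so each of
the 16 evidence combinations has a unique score in 0–15 and
`decompose(score(e)) = e` exactly. The standard describes the score as a
single octal digit with an "8 point maximum", which its own weights exceed;
the toolkit keeps the plain sum (clamping would destroy information and the
worked ECC example is consistent with plain summation) and flags scores
above 7 as exceeding a single octal digit via `exceeds_octal_digit`.
Deciding the four booleans from raw alignments is upstream of this package:
the flags are caller-supplied.

## Evolutionary character code

Seven colon-separated fields; colons therefore cannot appear inside any
field, which is why the copy relation is rendered `1-1` (with a dash)
rather than `1:1`. Copy counts are stored canonically as `1` or the marker
`n` — any integer above 1 collapses to `n` on record construction — so
`parse(serialize(r)) = r` holds as a strict identity in both directions.
Identity metrics are rendered without trailing zeros (`80`, not `80.0`).
The dN/dS alternative to percent identity is serialized with a `dnds=`
prefix on the metric field; without a marker the two modes would be
indistinguishable (a dN of 0.9 and an identity of 0.9% read the same).
Metrics are validated, never computed: alignment, identity and dN/dS
estimation belong to external alignment/phylogenetics software.

The clade ladder (squamates, reptiles, amniotes, tetrapods, vertebrates,
chordates, most-nested first) operationalizes the standard comparison set;
it is configurable because deeper ladders (e.g. splitting archosaurs) may
be wanted later. `assign_span` maps each comparison taxon to the smallest
ladder clade containing both it and *Anolis* (birds and non-avian reptiles
→ reptiles, mammals → amniotes, amphibians → tetrapods, teleosts →
vertebrates, non-vertebrate chordates → chordates) and returns the most
inclusive clade demanded by any taxon with a reliable alignment. Because
the standard comparison set contains no second squamate, the `squamates`
token is reachable only through user-supplied vocabularies. A gene with no
alignment anywhere returns `None` — a distinct no-detectable-homolog
signal, not an exception, since absence is a legitimate annotation outcome.
The expression field is a validated token only (`TS` tissue-specific, `CE`
conserved expression, `ND` no data; the latter two are toolkit plumbing,
configurable): scoring expression divergence is explicitly future work in
the standard.

## Synteny flank conservation

"Sequential order" is interpreted strictly: the reference orthologs of a
conserved prefix must occupy strictly monotonic, gap-free consecutive rank
positions among the reference genes (direction chosen by the first step;
ascending and descending are equivalent, so an inverted segment still
counts). Raw reference coordinates are converted to 1-based ordinal ranks
per reference sequence; tied coordinates are an input error. Orthologs on
different reference sequences are never rank-adjacent. A configurable
`max_gap` (default 0) lets a run tolerate reference-only insertions, since
the published rule does not address them; the default stays strict. Gene
orientation/strand is ignored — the rule speaks only of gene order. The
counter is verified against a brute-force oracle that tests every prefix
and both directions directly against the definition, on randomized contexts.

## Element names

Conserved-sequence names encode *classes*, not values: length class
(`s` ≤ 99 bp, `m` 100–499 bp, `l` ≥ 500 bp) and conservation class
(`1` 95–100%, `2` 90–94%, `3` 85–89%). The class boundaries are printed as
integers, leaving fractional conservation values ambiguous; the toolkit
rounds half-up to an integer percent before classing (94.5% → class 1,
94.4% → class 2). Values below 85% (rounded) have no class and are
rejected. The parser returns class intervals rather than fabricating point
values. Taxon letters always serialize in the canonical order S, M, B, G
regardless of input order.

The STR scanner exists to exercise naming and registry plumbing end to end,
not to compete with dedicated repeat finders: it reports perfect,
whole-copy tandem repeats with primitive units of length 1–6, resolves
overlaps longest-first then leftmost, and numbers the survivors 1, 2, … in
scan order. Units are reported in their lexicographically minimal rotation
so the same repeat is always described the same way. Per-locus metadata
(unit, copies, 0-based half-open coordinates) lives in a sidecar TSV
registry keyed by name, mirroring the standard's separation of stable names
from mutable locus descriptions; registry indices are gap-free and never
reused.

TE names follow `<lineage>-[HT]<family>[N<k>]_<SpeciesCode>`. Lineage
tokens are free-form alphanumeric identifiers (no dash/underscore, which
are structural) rather than a controlled superfamily list: transposon
classification below the superfamily level is a moving target, and
enforcing a frozen list would make the parser wrong before the package
aged a year.

## Synthetic fixtures

`make_species_fixture` emits pseudo-Latin epithets (alternating
consonant–vowel syllables, ≥ 4 letters) with a controllable fraction of
three-letter prefix collisions, and guarantees by construction that the
greedy assignment can code every name in list order. It emulates the
combinatorics of epithet prefix collisions, not real Latin morphology or
real publication-date distributions. `make_synteny_fixture` plants exactly
the requested number of consecutively ranked orthologs on each flank and
then breaks the run with either an unmapped gene or a guaranteed rank gap
(an unmapped spacer reference gene sits between the conserved block and the
breaker's ortholog). It does not emulate segmental duplications, tandem
arrays, or assembly fragmentation — passing tests show the counting rule is
implemented exactly, not that the rule is robust to messy assemblies.

Randomized verification sizes: the synteny counter is checked against the
brute-force oracle on 1,000 random contexts of up to 12 genes per flank;
code-assignment uniqueness on 1,000 collision-heavy species fixtures of 12
names; the STR scanner against a quadratic oracle on random sequences up to
500 bp. These sizes give dense coverage of the discrete case space (flank
prefixes, break modes, overlap configurations) while keeping the default
suite fast.

## Known limitations

* Orthology itself is not inferred: copy counts, identity metrics and
  evidence flags are inputs, as the standard intends.
* The registry fixes the 378 species known at standardization time; newly
  described species must be coded with `generate_code` against the frozen
  registry and appended by the community process, not by this tool.
* Sub-species and geographic-race designations are out of scope (the
  standard defers them), as are TE classification, horizontal-transfer
  detection, and discovery of conserved sequences from whole-genome
  alignments.
* The ECC has no serialization for a gene with no detectable homolog; the
  pipeline reports such genes instead of emitting a string.
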