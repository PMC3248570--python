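# agnc — Anolis gene-nomenclature toolkit

With the green anole (*Anolis carolinensis*) genome available, non-avian
reptilian genes can finally be compared against mammalian, avian, amphibian
and teleost homologs — but only if everyone names things the same way.
`agnc` implements the community nomenclature standards for *Anolis*
comparative genomics as a library plus a command-line tool, for genome
annotators, curators of anole community databases, and comparative
biologists who need machine-checkable identifiers:

* **Species abbreviations** — four-character codes (`A` + three lowercase
  letters from the epithet: *A. sagrei* → `Asag`), with the published greedy
  collision-resolution rule driven by publication precedence, and the
  canonical frozen registry of 378 species codes shipped as package data.
* **Gene, protein and cross-species symbols** — lowercase anole symbols
  derived from mammalian/avian orthologs (`GENE2` → *gene2*, `NKX3-1` →
  *nkx3-1*), duplication suffixing (*gene2a*/*gene2b*, *gene4aa*/*gene4ab*),
  all-caps protein symbols, per-species casing conventions, and screening of
  gene names for provisional identifiers (KIAA#, C#orf#), homology
  parentheticals and molecular-weight references.
* **Transcript evidence score** — the additive confidence score over four
  evidence categories with binary weights: 1 (EST alignment), 2 (protein
  similarity overlap), 4 (consistent gene prediction), 8 (consistent cDNA).
* **Evolutionary character code (ECC)** — build, parse and validate the
  per-gene summary string
  `<gene>:<span>:<prot>,<nuc>:<relation>:<score>:<up>,<down>:<expr>`,
  including the 1-1 / 1-n / n-1 / n-n copy-relation classifier and the
  taxonomic-span assignment over a nested clade ladder
  (squamates ⊂ reptiles ⊂ amniotes ⊂ tetrapods ⊂ vertebrates ⊂ chordates).
* **Synteny flank conservation** — count sequentially ordered reference
  orthologs on each flank of a focal gene (reference gene order typically
  from chicken) and apply the minimal orthology-recognition rule:
  at least 2 sequential orthologs on a single flank.
* **Element-name grammars** — conserved sequences (`Acar1000l1SMB`), STRs
  (`Acar_str_8`) with a minimal perfect-tandem-repeat scanner and a
  persistent locus registry, and transposable elements
  (`Helitron-1N1_Acar`, `hAT-HT1_Acar`, `hobo-1_Acar`).

## Worked example

```python
>>> from agnc import assign_codes
>>> [r.code for r in assign_codes([("grahami", 0), ("gracilipes", 1),
...                                ("granuliceps", 2)])]
['Agra', 'Agrc', 'Agrn']
```

*grahami* (published first) takes the default code `Agra`; the later species
fall back to the next unique epithet letter (`Agrc`, `Agrn`).

```python
>>> from agnc import EvidenceSet, score
>>> score(EvidenceSet(est_aligned=True, prediction_consistent=True))
5
```

A transcript with gene-prediction (4) and EST (1) support scores 5. That
score is the fifth field of the gene's ECC:

```python
>>> from agnc import ECCRecord, ecc
>>> record = ECCRecord(gene_id="gene2", taxonomic_span="chordates",
...                    protein_metric=80, nucleotide_metric=55,
...                    copies_query=1, copies_reference=1, evidence_score=5,
...                    synteny_up=3, synteny_down=4, expression_code="TS")
>>> ecc.serialize(record)
'gene2:chordates:80,55:1-1:5:3,4:TS'
```

read as: *gene2* has orthology only within chordates, 80% protein and 55%
nucleotide identity, no within- or between-species paralogs, prediction+EST
evidence, 3 upstream and 4 downstream genes with conserved synteny, and
tissue-specific expression. The same operations are available from the
shell:

```console
$ agnc species code "Anolis grahami" gracilipes granuliceps
epithet	code
grahami	Agra
gracilipes	Agrc
granuliceps	Agrn
$ agnc ecc parse "gene2:chordates:80,55:1-1:5:3,4:TS" --format json
$ agnc str scan genome.fa --code Acar --registry strs.tsv
```

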