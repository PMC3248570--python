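"""Additive transcript-confidence score.

Each annotated transcript receives the sum of four evidence weights:

======================  ======  ==========================================
evidence                weight  meaning
======================  ======  ==========================================
EST alignment              1    one or more ESTs align to the transcript
protein overlap            2    an annotated exon intersects aligned
                                protein similarity (self-similarity
                                excluded)
prediction consistency     4    some gene prediction is fully consistent
cDNA consistency           8    one or more aligned cDNAs fully consistent
======================  ======  ==========================================

The weights are the binary place values 1/2/4/8, so every combination of
evidence has a unique score in 0–15 and the score decomposes back into its
evidence set.  Scores above 7 exceed a single octal digit; :func:`score`
reports that as a warning rather than clamping, since clamping would destroy
information.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

WEIGHT_EST = 1
WEIGHT_PROTEIN = 2
WEIGHT_PREDICTION = 4
WEIGHT_CDNA = 8

MAX_SCORE = WEIGHT_EST + WEIGHT_PROTEIN + WEIGHT_PREDICTION + WEIGHT_CDNA


@dataclass(frozen=True)
class EvidenceSet:
    """Four boolean evidence flags for one transcript."""

    est_aligned: bool = False
    protein_overlap: bool = False
    prediction_consistent: bool = False
    cdna_consistent: bool = False


def score(evidence: EvidenceSet) -> int:
    """Sum the evidence weights; result in [0, 15]."""
    return (
        WEIGHT_EST * evidence.est_aligned
        + WEIGHT_PROTEIN * evidence.protein_overlap
        + WEIGHT_PREDICTION * evidence.prediction_consistent
        + WEIGHT_CDNA * evidence.cdna_consistent
    )


def exceeds_octal_digit(value: int) -> bool:
    """True when a score cannot be written as a single octal digit (> 7)."""
    return value > 7


def decompose(value: int) -> EvidenceSet:
    """Invert :func:`score`: recover the unique evidence set for a score."""
    if not (0 <= value <= MAX_SCORE):
        raise DomainError(f"score {value} outside [0, {MAX_SCORE}]")
    return EvidenceSet(
        est_aligned=bool(value & WEIGHT_EST),
        protein_overlap=bool(value & WEIGHT_PROTEIN),
        prediction_consistent=bool(value & WEIGHT_PREDICTION),
        cdna_consistent=bool(value & WEIGHT_CDNA),
    )
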