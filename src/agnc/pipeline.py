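"""Join the per-gene annotation tables into evolutionary character codes.

The pipeline is a thin orchestration layer: evidence flags become the
transcript score, ortholog copy counts become the relation class, alignment
presence across the comparison taxa becomes the taxonomic span, gene-order
tables become the flank-conservation counts, and everything is serialized
as one ECC string per gene.  Genes missing from any required table are
reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ecc, evidence_score, synteny
from .config import ToolConfig
from .errors import AgncError, DomainError

_EVIDENCE_COLS = ("gene_id", "est", "protein", "prediction", "cdna")
_ORTHOLOG_COLS = (
    "gene_id",
    "reference_gene",
    "copies_query",
    "copies_reference",
    "protein_metric",
    "nucleotide_metric",
)


@dataclass
class PipelineResult:
    ecc_strings: dict[str, str] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)  # gene -> reason

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.ecc_strings), "ecc": list(self.ecc_strings.values())}
        )


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DomainError(f"{label} table lacks columns {missing}")


def run_ecc_pipeline(
    evidence_table: pd.DataFrame,
    ortholog_table: pd.DataFrame,
    gene_order_tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    presence_table: pd.DataFrame,
    config: ToolConfig | None = None,
) -> PipelineResult:
    """Assemble one ECC string per gene in ``ortholog_table``.

    ``evidence_table``: ``gene_id, est, protein, prediction, cdna`` booleans.
    ``ortholog_table``: ``gene_id, reference_gene, copies_query,
    copies_reference, protein_metric, nucleotide_metric`` plus optional
    ``identity_mode`` and ``expression_code`` columns (defaults:
    percent_identity, ND).
    ``gene_order_tables``: ``(query_order, reference_order, ortholog_map)``
    as accepted by :func:`agnc.synteny.context_from_tables`.
    ``presence_table``: ``gene_id, taxon, present`` long-form alignment
    presence across the comparison taxa.
    """
    config = config or ToolConfig()
    _require_columns(evidence_table, _EVIDENCE_COLS, "evidence")
    _require_columns(ortholog_table, _ORTHOLOG_COLS, "ortholog")
    _require_columns(presence_table, ("gene_id", "taxon", "present"), "presence")
    query_order, reference_order, ortholog_map = gene_order_tables

    evidence_by_gene = evidence_table.set_index("gene_id")
    presence_by_gene = dict(tuple(presence_table.groupby("gene_id")))

    result = PipelineResult()
    for row in ortholog_table.itertuples(index=False):
        gene = row.gene_id
        try:
            if gene not in evidence_by_gene.index:
                raise DomainError("no evidence row")
            ev = evidence_by_gene.loc[gene]
            score = evidence_score.score(
                evidence_score.EvidenceSet(
                    est_aligned=bool(ev["est"]),
                    protein_overlap=bool(ev["protein"]),
                    prediction_consistent=bool(ev["prediction"]),
                    cdna_consistent=bool(ev["cdna"]),
                )
            )
            if gene not in presence_by_gene:
                raise DomainError("no alignment-presence rows")
            pres = presence_by_gene[gene]
            span = ecc.assign_span(
                dict(zip(pres["taxon"], pres["present"].astype(bool))),
                ladder=config.clade_ladder,
            )
            if span is None:
                raise DomainError("no detectable homolog in any comparison taxon")
            context = synteny.context_from_tables(
                gene, query_order, reference_order, ortholog_map
            )
            up, down = synteny.ecc_synteny_fields(
                context, max_gap=config.synteny_max_gap
            )
            record = ecc.ECCRecord(
                gene_id=gene,
                taxonomic_span=span,
                protein_metric=float(row.protein_metric),
                nucleotide_metric=float(row.nucleotide_metric),
                copies_query=int(row.copies_query),
                copies_reference=int(row.copies_reference),
                evidence_score=score,
                synteny_up=up,
                synteny_down=down,
                expression_code=getattr(row, "expression_code", "ND") or "ND",
                identity_mode=getattr(row, "identity_mode", "percent_identity")
                or "percent_identity",
            )
            result.ecc_strings[gene] = ecc.serialize(
                record,
                ladder=config.clade_ladder,
                expression_codes=config.expression_codes,
            )
        except (AgncError, KeyError) as exc:
            result.skipped[gene] = f"{type(exc).__name__}: {exc}"
    return result
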