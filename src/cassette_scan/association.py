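"""Bacteriocin association: attach each complete transporter cassette to a
structural gene, or declare it orphan.

A cassette belongs to a bacteriocinogenic cluster when a structural-gene hit
(passing the same >40% identity / >70% coverage / 1e-6 filter) sits at the
expected distance from the transporter, +/- 500 bp.  Expected distances come
from reference gene clusters; the offset is measured from the cassette's
nearest boundary to the structural-gene start, signed negative upstream,
after normalizing for cassette orientation.  Structural gene and transporter
must share a contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cassette import CassetteCall, DEFAULT_TOLERANCE_BP
from .search import Hit
from .seqio import ProteinRecord, read_tsv, write_tsv

ORPHAN = "orphan"


@dataclass
class StructuralGeneDB:
    """Bacteriocin structural proteins plus their expected cassette offsets.

    ``family_to_label`` maps a db family to a bacteriocin label, so tandem
    two-peptide bacteriocins (e.g. L50-like A and B genes) can map to one
    label; either hit suffices.  ``reference_offsets`` maps a family to the
    expected signed bp distance from the cassette boundary to the structural
    gene start (negative = upstream of the cassette); families without an
    offset fall back to a maximum gap of the caller's tolerance from the
    cassette boundary.
    """

    entries: list[ProteinRecord]
    reference_offsets: dict[str, int] = field(default_factory=dict)
    family_to_label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.family:
                raise ValueError(f"structural entry {e.protein_id!r} lacks a family")
            self.family_to_label.setdefault(e.family, e.family)

    @property
    def families(self) -> list[str]:
        return sorted({e.family for e in self.entries})

    def label_of(self, family: str) -> str:
        return self.family_to_label.get(family, family)


@dataclass
class AssociationCall:
    genome_id: str
    cassette: CassetteCall
    label: str  # bacteriocin label or "orphan"
    structural_hit: Hit | None = None
    observed_offset_bp: int | None = None

    def __post_init__(self) -> None:
        if (self.label != ORPHAN) != (self.structural_hit is not None):
            raise ValueError("non-orphan label requires a structural hit and vice versa")


def read_offsets_tsv(path: str | Path) -> dict[str, int]:
    """Read a family -> expected offset (bp) table with columns family, offset_bp."""
    frame = read_tsv(path)
    if not {"family", "offset_bp"}.issubset(frame.columns):
        raise ValueError(f"{path}: offsets TSV needs columns family, offset_bp")
    return {str(r.family): int(r.offset_bp) for r in frame.itertuples(index=False)}


def _observed_offset(call: CassetteCall, hit: Hit) -> int:
    """Signed distance from the cassette's nearest boundary to the structural
    gene start, orientation-normalized (negative = upstream of the cassette
    in its own reading direction)."""
    lo, hi = call.span()
    if call.orientation == "reverse":
        # cassette reads right-to-left: its start boundary is hi, the gene
        # "start" is the hit's right edge, and upstream means larger coords
        gene_start = hit.subject_end
        if gene_start > hi:
            return hi - gene_start  # upstream -> negative
        if hit.subject_start < lo:
            return lo - hit.subject_start
        return 0
    gene_start = hit.subject_start
    if gene_start < lo:
        return gene_start - lo  # upstream -> negative
    if hit.subject_end > hi:
        return hit.subject_end - hi
    return 0


def associate(
    cassette_call: CassetteCall,
    structural_hits: Sequence[Hit],
    db: StructuralGeneDB,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> AssociationCall:
    """Label one complete cassette with a bacteriocin, or orphan.

    ``structural_hits`` must already be filtered by the positives rule and
    deduplicated per locus.  Among same-contig hits, a hit qualifies when its
    observed offset is within ``tolerance_bp`` of its family's expected
    offset (or, for families without a reference offset, when the gene lies
    within ``tolerance_bp`` of the cassette boundary).  Of the qualifying
    hits the highest percent identity wins (then bit score, E-value, query
    id); no qualifying hit means orphan.
    """
    if cassette_call.status != "complete":
        raise ValueError(
            f"genome {cassette_call.genome_id}: association is defined only for "
            f"complete cassettes (status={cassette_call.status})"
        )
    candidates: list[tuple[Hit, int]] = []
    for hit in structural_hits:
        if hit.genome_id != cassette_call.genome_id:
            continue
        if hit.contig_id != cassette_call.contig_id:
            continue  # trans-contig association is never made
        offset = _observed_offset(cassette_call, hit)
        expected = db.reference_offsets.get(hit.query_family)
        deviation = abs(offset) if expected is None else abs(offset - expected)
        if deviation <= tolerance_bp:
            candidates.append((hit, offset))
    if not candidates:
        return AssociationCall(cassette_call.genome_id, cassette_call, ORPHAN)
    best, offset = min(
        candidates,
        key=lambda pair: (
            -pair[0].percent_identity,
            -pair[0].bit_score,
            pair[0].evalue,
            pair[0].query_id,
        ),
    )
    return AssociationCall(
        cassette_call.genome_id,
        cassette_call,
        db.label_of(best.query_family),
        structural_hit=best,
        observed_offset_bp=offset,
    )


def summarize_dataset(
    cassette_calls: Sequence[CassetteCall],
    association_calls: Sequence[AssociationCall],
    species_of: Mapping[str, str] | None = None,
    molecule_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species x per-label contingency table of cassette outcomes.

    One row per genome (species, molecule, status, label); the association
    label is "orphan" for unlabeled complete cassettes and "" for genomes
    without a complete cassette.  Aggregate with pandas as needed; row count
    equals the number of genomes, so totals are conserved.
    """
    if not cassette_calls:
        return pd.DataFrame(columns=["genome_id", "species", "molecule", "status", "label"])
    label_by_genome = {a.genome_id: a.label for a in association_calls}
    rows = []
    for c in cassette_calls:
        rows.append(
            {
                "genome_id": c.genome_id,
                "species": (species_of or {}).get(c.genome_id, ""),
                "molecule": (molecule_of or {}).get(c.genome_id, "unknown"),
                "status": c.status,
                "label": label_by_genome.get(c.genome_id, "") if c.status == "complete" else "",
            }
        )
    return pd.DataFrame(rows).sort_values("genome_id").reset_index(drop=True)


def contingency(summary: pd.DataFrame) -> pd.DataFrame:
    """Species x label counts over complete cassettes (labels incl. orphan)."""
    complete = summary[summary["status"] == "complete"]
    if complete.empty:
        return pd.DataFrame()
    return pd.crosstab(complete["species"], complete["label"])


def associations_to_frame(calls: Sequence[AssociationCall]) -> pd.DataFrame:
    rows = []
    for a in calls:
        rows.append(
            {
                "genome_id": a.genome_id,
                "contig_id": a.cassette.contig_id or "",
                "label": a.label,
                "structural_query": a.structural_hit.query_id if a.structural_hit else "",
                "structural_identity": round(a.structural_hit.percent_identity, 2)
                if a.structural_hit
                else "",
                "observed_offset_bp": a.observed_offset_bp if a.observed_offset_bp is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "contig_id", "label", "structural_query",
            "structural_identity", "observed_offset_bp",
        ],
    )
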