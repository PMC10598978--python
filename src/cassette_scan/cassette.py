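"""Cassette calling: decide per genome whether a complete four-gene
ABC-transporter cassette (Mr10EFGH-like) is present.

The rules are the screen's positives filter (identity strictly > 40, query
coverage strictly > 70, E-value <= 1e-6), one best hit per overlapping locus
(highest percent identity), and architecture agreement with a reference gene
cluster: all components on one contig, reference gene order or its full
reversal, and every adjacent inter-gene gap within +/-500 bp of the
reference gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .search import Hit, ScoringScheme, local_align
from .seqio import Contig, read_tsv, reverse_complement, six_frame_translate, write_tsv

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 70.0
DEFAULT_MAX_EVALUE = 1e-6
DEFAULT_TOLERANCE_BP = 500
DEFAULT_WINDOW_BP = 10_000


@dataclass(frozen=True)
class ReferenceCluster:
    """Ordered gene architecture on one reference sequence.

    ``loci`` is an ordered list of (gene_name, strand, start, end) with
    0-based half-open coordinates, sorted by start and non-overlapping.
    """

    cluster_id: str
    loci: tuple[tuple[str, str, int, int], ...]
    tolerance_bp: int = DEFAULT_TOLERANCE_BP

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("reference cluster needs at least one locus")
        names = [l[0] for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("reference gene names must be unique")
        starts = [l[2] for l in self.loci]
        if starts != sorted(starts):
            raise ValueError("reference loci must be sorted by start")
        for (_, _, s1, e1), (_, _, s2, _) in zip(self.loci, self.loci[1:]):
            if s2 < e1:
                raise ValueError("reference loci must not overlap")

    @property
    def gene_order(self) -> list[str]:
        return [l[0] for l in self.loci]

    @property
    def strands(self) -> list[str]:
        return [l[1] for l in self.loci]

    def reference_gaps(self) -> list[int]:
        """Inter-gene gaps (next.start - prev.end) along the reference order."""
        return [n[2] - p[3] for p, n in zip(self.loci, self.loci[1:])]


@dataclass
class CassetteCall:
    """Per-genome cassette verdict with the chosen component hits."""

    genome_id: str
    contig_id: str | None
    status: str  # complete | partial | absent
    components: dict[str, Hit | None]
    orientation: str  # forward | reverse | mixed | n/a

    @property
    def n_components(self) -> int:
        return sum(1 for h in self.components.values() if h is not None)

    def span(self) -> tuple[int, int]:
        """Forward-strand interval covered by the present components."""
        present = [h for h in self.components.values() if h is not None]
        if not present:
            raise ValueError("no components present")
        return min(h.subject_start for h in present), max(h.subject_end for h in present)


def read_reference_cluster(path: str | Path, tolerance_bp: int = DEFAULT_TOLERANCE_BP) -> ReferenceCluster:
    """Read a 5-column reference-cluster TSV (cluster_id, gene, strand, start, end)."""
    frame = read_tsv(path)
    required = {"cluster_id", "gene", "strand", "start", "end"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: reference TSV needs columns {sorted(required)}")
    cluster_ids = frame["cluster_id"].unique()
    if len(cluster_ids) != 1:
        raise ValueError(f"{path}: expected exactly one cluster_id, got {list(cluster_ids)}")
    frame = frame.sort_values("start")
    loci = tuple(
        (str(r.gene), str(r.strand), int(r.start), int(r.end))
        for r in frame.itertuples(index=False)
    )
    return ReferenceCluster(str(cluster_ids[0]), loci, tolerance_bp)


def write_reference_cluster(cluster: ReferenceCluster, path: str | Path) -> None:
    rows = [
        {"cluster_id": cluster.cluster_id, "gene": g, "strand": s, "start": a, "end": b}
        for g, s, a, b in cluster.loci
    ]
    write_tsv(pd.DataFrame(rows), path)


def filter_hits(
    hits: Sequence[Hit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[Hit]:
    """Keep positives only: identity strictly above ``min_identity``, coverage
    strictly above ``min_coverage``, E-value at most ``max_evalue``."""
    return [
        h
        for h in hits
        if h.percent_identity > min_identity
        and h.query_coverage > min_coverage
        and h.evalue <= max_evalue
    ]


def best_hit_per_locus(hits: Sequence[Hit]) -> list[Hit]:
    """Collapse hits whose subject intervals overlap (transitively) to one hit
    per locus: highest percent identity, then highest bit score, then lowest
    E-value, then lexicographically smallest query id.

    Hits must all be on one contig; apply per contig group otherwise.
    """
    if not hits:
        return []
    contigs = {h.contig_id for h in hits}
    if len(contigs) > 1:
        raise ValueError(f"best_hit_per_locus expects one contig, got {sorted(contigs)}")
    ordered = sorted(hits, key=lambda h: (h.subject_start, h.subject_end))
    loci: list[list[Hit]] = [[ordered[0]]]
    locus_end = ordered[0].subject_end
    for h in ordered[1:]:
        if h.subject_start < locus_end:  # >=1 bp overlap with the running locus
            loci[-1].append(h)
            locus_end = max(locus_end, h.subject_end)
        else:
            loci.append([h])
            locus_end = h.subject_end
    best = [
        min(group, key=lambda h: (-h.percent_identity, -h.bit_score, h.evalue, h.query_id))
        for group in loci
    ]
    best.sort(key=lambda h: h.subject_start)
    return best


def dedupe_by_contig(hits: Sequence[Hit]) -> list[Hit]:
    """best_hit_per_locus applied per contig."""
    by_contig: dict[str, list[Hit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    out: list[Hit] = []
    for cid in sorted(by_contig):
        out.extend(best_hit_per_locus(by_contig[cid]))
    return out


def _architecture_ok(
    chosen: Mapping[str, Hit], reference: ReferenceCluster
) -> tuple[bool, str]:
    """Check gene order/orientation and adjacency gaps against the reference.

    Returns (complete?, orientation), where orientation is 'forward' when the
    observed order matches the reference, 'reverse' for its full reversal.
    Internal single-gene inversions (mixed strands) are never complete.
    """
    order = reference.gene_order
    observed = sorted(chosen.items(), key=lambda kv: kv[1].subject_start)
    observed_genes = [g for g, _ in observed]
    strands = {h.strand for _, h in observed}
    if len(strands) != 1:
        return False, "mixed"
    strand = strands.pop()
    ref_strands = reference.strands
    if observed_genes == order:
        orientation = "forward"
        # forward placement keeps each gene on its reference strand
        expected = [ref_strands[order.index(g)] for g in observed_genes]
        if any(h.strand != e for (_, h), e in zip(observed, expected)):
            return False, "mixed"
        gaps = [n.subject_start - p.subject_end for (_, p), (_, n) in zip(observed, observed[1:])]
        ref_gaps = reference.reference_gaps()
    elif observed_genes == order[::-1]:
        orientation = "reverse"
        flip = {"+": "-", "-": "+"}
        expected = [flip[ref_strands[order.index(g)]] for g in observed_genes]
        if any(h.strand != e for (_, h), e in zip(observed, expected)):
            return False, "mixed"
        gaps = [n.subject_start - p.subject_end for (_, p), (_, n) in zip(observed, observed[1:])]
        ref_gaps = reference.reference_gaps()[::-1]
    else:
        return False, "mixed"
    ok = all(abs(g - r) <= reference.tolerance_bp for g, r in zip(gaps, ref_gaps))
    return ok, orientation


def call_cassette(
    filtered_hits: Sequence[Hit],
    reference: ReferenceCluster,
    genome_id: str,
) -> CassetteCall:
    """Call complete/partial/absent for one genome from filtered, deduplicated
    hits whose query families are the reference gene names.

    Complete requires every reference gene on one contig, observed gene order
    equal to the reference order or its full reversal, and every adjacent
    inter-gene gap within ``tolerance_bp`` of the reference gap.  When the
    components are split across contigs the contig holding the most of them is
    reported (ties broken by contig id) and the split is logged.
    """
    genes = reference.gene_order
    relevant = [h for h in filtered_hits if h.genome_id == genome_id and h.query_family in genes]
    if not relevant:
        return CassetteCall(genome_id, None, "absent", {g: None for g in genes}, "n/a")
    by_contig: dict[str, list[Hit]] = {}
    for h in relevant:
        by_contig.setdefault(h.contig_id, []).append(h)

    def contig_score(cid: str) -> tuple[int, str]:
        fams = {h.query_family for h in by_contig[cid]}
        return (-len(fams), cid)

    chosen_contig = min(by_contig, key=contig_score)
    if len(by_contig) > 1:
        logger.warning(
            "genome %s: cassette components split across %d contigs; using %s",
            genome_id, len(by_contig), chosen_contig,
        )
    # one hit per family on the chosen contig: same preference chain as loci
    components: dict[str, Hit | None] = {g: None for g in genes}
    for g in genes:
        candidates = [h for h in by_contig[chosen_contig] if h.query_family == g]
        if candidates:
            components[g] = min(
                candidates, key=lambda h: (-h.percent_identity, -h.bit_score, h.evalue, h.query_id)
            )
    present = {g: h for g, h in components.items() if h is not None}
    if len(present) == len(genes):
        complete, orientation = _architecture_ok(present, reference)
        if complete:
            return CassetteCall(genome_id, chosen_contig, "complete", components, orientation)
        return CassetteCall(genome_id, chosen_contig, "partial", components, orientation)
    return CassetteCall(genome_id, chosen_contig, "partial", components, "n/a")


def extract_window(
    contig: Contig, call: CassetteCall, window_bp: int = DEFAULT_WINDOW_BP
) -> tuple[Contig, dict[str, tuple[int, int, str]]]:
    """A genomic window of ``window_bp`` centred on the cassette span,
    truncated at contig ends, with component coordinates re-expressed in
    window space.  Used for the up/downstream synteny comparison."""
    if call.status == "absent" or call.n_components == 0:
        raise ValueError(f"genome {call.genome_id}: no cassette components to window")
    if call.contig_id != contig.contig_id:
        raise ValueError(
            f"call is on contig {call.contig_id!r}, got contig {contig.contig_id!r}"
        )
    lo, hi = call.span()
    centre = (lo + hi) // 2
    # symmetric window around the cassette midpoint, clipped at contig ends
    start = max(0, centre - window_bp // 2)
    end = min(len(contig), centre + (window_bp - window_bp // 2))
    window = Contig(
        contig_id=f"{contig.contig_id}:{start}-{end}",
        genome_id=contig.genome_id,
        sequence=contig.sequence[start:end],
        molecule_label=contig.molecule_label,
        species=contig.species,
    )
    coords = {
        g: (h.subject_start - start, h.subject_end - start, h.strand)
        for g, h in call.components.items()
        if h is not None
    }
    return window, coords


def _window_protein(window: Contig, span: tuple[int, int, str], table_id: int = 11) -> str:
    """Translate a called gene span out of a window (frame from the span itself)."""
    lo, hi, strand = span
    lo, hi = max(0, lo), min(len(window), hi)
    seq = window.sequence[lo:hi]
    if strand == "-":
        seq = reverse_complement(seq)
    from .seqio import _translate_frame  # same codon machinery as six-frame

    return _translate_frame(seq, table_id).rstrip("*")


def compare_clusters(
    window_a: tuple[Contig, dict[str, tuple[int, int, str]]],
    window_b: tuple[Contig, dict[str, tuple[int, int, str]]],
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Pairwise protein percent identity per shared gene family between two
    cassette windows; families present in only one window are reported as
    unmatched (identity NaN)."""
    from .phylo import global_identity

    contig_a, genes_a = window_a
    contig_b, genes_b = window_b
    rows = []
    for fam in sorted(set(genes_a) | set(genes_b)):
        in_a, in_b = fam in genes_a, fam in genes_b
        if in_a and in_b:
            pa = _window_protein(contig_a, genes_a[fam])
            pb = _window_protein(contig_b, genes_b[fam])
            ident = global_identity(pa, pb, scheme) if pa and pb else float("nan")
            status = "shared"
        else:
            ident, status = float("nan"), "unmatched"
        rows.append(
            {
                "family": fam,
                "window_a": contig_a.contig_id,
                "window_b": contig_b.contig_id,
                "status": status,
                "percent_identity": ident,
            }
        )
    return pd.DataFrame(rows, columns=["family", "window_a", "window_b", "status", "percent_identity"])


def calls_to_frame(calls: Sequence[CassetteCall], gene_order: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict = {
            "genome_id": c.genome_id,
            "contig_id": c.contig_id or "",
            "status": c.status,
            "orientation": c.orientation,
            "n_components": c.n_components,
        }
        for g in gene_order:
            h = c.components.get(g)
            row[f"{g}_identity"] = round(h.percent_identity, 2) if h else ""
            row[f"{g}_start"] = h.subject_start if h else ""
            row[f"{g}_end"] = h.subject_end if h else ""
            row[f"{g}_strand"] = h.strand if h else ""
        rows.append(row)
    return pd.DataFrame(rows)
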