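"""Translated protein-vs-genome search and BLAST tabular ingest.

Emulates a tblastn-style screen: each protein query is aligned locally
(Smith-Waterman, affine gaps, BLOSUM62) against all six reading-frame
translations of each contig, peptide coordinates are mapped back to
forward-strand DNA, and hits are filtered by Karlin-Altschul E-value.

For speed on contig-scale subjects the search seeds candidate regions with
exact amino-acid k-mers and runs the dynamic program only inside merged
windows around the seeds; short queries or short frame peptides fall back to
the full dynamic program, which is the path the brute-force oracle tests
exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import Contig, FramePeptide, ProteinRecord, six_frame_translate

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1,
# mirroring the defaults of the translated-search tool this module emulates.
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267

_SEED_K = 4  # amino-acid seed word length
_FULL_DP_PEPTIDE_LIMIT = 1500  # frames at most this long skip seeding entirely


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap protein scoring plus the statistical constants for E-values."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11  # cost of the first gapped position
    gap_extend: int = 1
    K: float = DEFAULT_K
    lambda_: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.K <= 0 or self.lambda_ <= 0:
            raise ValueError("K and lambda must be positive")

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass
class Hit:
    """One local protein-vs-translated-DNA match.

    DNA coordinates are 0-based half-open on the forward strand regardless of
    strand; ``strand`` is '+' or '-'.
    """

    query_id: str
    query_family: str
    contig_id: str
    genome_id: str
    subject_start: int
    subject_end: int
    strand: str
    frame: int
    percent_identity: float
    query_coverage: float
    alignment_length: int
    raw_score: int
    bit_score: float
    evalue: float
    query_length: int = 0

    def __post_init__(self) -> None:
        if self.subject_start >= self.subject_end:
            raise ValueError(
                f"hit {self.query_id}/{self.contig_id}: subject_start must be < subject_end"
            )
        for name in ("percent_identity", "query_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"hit {self.query_id}/{self.contig_id}: {name}={v} outside [0,100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.subject_end - self.subject_start > 3 * self.alignment_length:
            raise ValueError("subject span exceeds 3x alignment length")


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.matrix()
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    """Map residues outside the matrix alphabet to X so alignment never fails."""
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def local_align(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> tuple[int, tuple[int, int, int, int], int, int]:
    """Optimal Smith-Waterman local alignment under affine gaps.

    Returns ``(raw_score, (qstart, qend, sstart, send), identities,
    alignment_length)`` with 0-based half-open ranges.  A score of zero means
    no positive-scoring local alignment exists ("no hit"); the ranges are then
    empty and identities/length zero.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme, "local")
    alphabet = str(aligner.substitution_matrix.alphabet)
    q = _sanitize(query, alphabet)
    s = _sanitize(subject, alphabet)
    score = aligner.score(q, s)
    if score <= 0:
        return 0, (0, 0, 0, 0), 0, 0
    aln = aligner.align(q, s)[0]
    q_blocks, s_blocks = aln.aligned
    qstart, qend = int(q_blocks[0][0]), int(q_blocks[-1][1])
    sstart, send = int(s_blocks[0][0]), int(s_blocks[-1][1])
    identities = int(aln.counts().identities)
    return int(score), (qstart, qend, sstart, send), identities, int(aln.length)


def evalue(raw_score: float, query_len: int, database_len: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or database_len <= 0:
        raise ValueError("query and database lengths must be positive")
    scheme = scheme or ScoringScheme()
    return scheme.K * query_len * database_len * math.exp(-scheme.lambda_ * raw_score)


def bit_score(raw_score: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.lambda_ * raw_score - math.log(scheme.K)) / math.log(2)


def _seed_windows(query: str, peptide: str, k: int = _SEED_K) -> list[tuple[int, int]]:
    """Candidate peptide windows around exact k-mer matches, merged if overlapping."""
    if len(query) < k or len(peptide) < k:
        return []
    index: dict[str, bool] = {query[i : i + k]: True for i in range(len(query) - k + 1)}
    margin = len(query) + 8
    raw: list[tuple[int, int]] = []
    for j in range(len(peptide) - k + 1):
        if peptide[j : j + k] in index:
            raw.append((max(0, j - margin), min(len(peptide), j + k + margin)))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for lo, hi in raw[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def search_translated(
    queries: Sequence[ProteinRecord],
    contigs: Sequence[Contig],
    scheme: ScoringScheme | None = None,
    max_evalue: float = 1e-6,
    table_id: int = 11,
    max_target_seqs: int | None = 1000,
) -> list[Hit]:
    """Six-frame translated search of every query against every contig.

    The database length for E-values is the total DNA length of ``contigs``.
    Hits with E <= ``max_evalue`` (inclusive) are returned sorted by
    (query_id, contig_id, evalue); at most ``max_target_seqs`` hits are kept
    per query after E-value sorting.
    """
    if not queries or not contigs:
        raise ValueError("queries and contigs must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme, "local")
    alphabet = str(aligner.substitution_matrix.alphabet)
    db_len = sum(len(c) for c in contigs)
    hits: list[Hit] = []
    for contig in contigs:
        if len(contig) < 3:
            continue
        frames = six_frame_translate(contig, table_id)
        for query in queries:
            q = _sanitize(query.sequence, alphabet)
            if not q:
                raise ValueError(f"query {query.protein_id!r} is empty")
            for fp in frames:
                pep = _sanitize(fp.peptide, alphabet)
                if not pep:
                    continue
                if len(q) < 2 * _SEED_K or len(pep) <= _FULL_DP_PEPTIDE_LIMIT:
                    windows = [(0, len(pep))]
                else:
                    windows = _seed_windows(q, pep)
                for lo, hi in windows:
                    sub = pep[lo:hi]
                    score = aligner.score(q, sub)
                    if score <= 0:
                        continue
                    e = evalue(score, len(q), db_len, scheme)
                    if e > max_evalue:
                        continue
                    aln = aligner.align(q, sub)[0]
                    q_blocks, s_blocks = aln.aligned
                    qstart, qend = int(q_blocks[0][0]), int(q_blocks[-1][1])
                    pstart, pend = lo + int(s_blocks[0][0]), lo + int(s_blocks[-1][1])
                    dstart, dend = fp.dna_span(pstart, pend)
                    identities = int(aln.counts().identities)
                    hits.append(
                        Hit(
                            query_id=query.protein_id,
                            query_family=query.family,
                            contig_id=contig.contig_id,
                            genome_id=contig.genome_id,
                            subject_start=dstart,
                            subject_end=dend,
                            strand="+" if fp.frame > 0 else "-",
                            frame=fp.frame,
                            percent_identity=100.0 * identities / aln.length,
                            query_coverage=100.0 * (qend - qstart) / len(q),
                            alignment_length=int(aln.length),
                            raw_score=int(score),
                            bit_score=bit_score(score, scheme),
                            evalue=e,
                            query_length=len(q),
                        )
                    )
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.contig_id, h.subject_start))
    if max_target_seqs is not None:
        capped: list[Hit] = []
        per_query: dict[str, int] = {}
        for h in hits:
            c = per_query.get(h.query_id, 0)
            if c < max_target_seqs:
                capped.append(h)
                per_query[h.query_id] = c + 1
        hits = capped
    hits.sort(key=lambda h: (h.query_id, h.contig_id, h.evalue, h.subject_start))
    return hits


TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_tabular_hits(
    path: str | Path,
    query_lengths: Mapping[str, int],
    query_families: Mapping[str, str] | None = None,
    genome_of: Mapping[str, str] | None = None,
    skip_unknown: bool = False,
) -> list[Hit]:
    """Ingest a 12-column tabular hit file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Input coordinates are 1-based inclusive; ``sstart > send`` marks a
    minus-strand hit.  ``query_lengths`` supplies the query lengths needed for
    coverage; ``query_families`` maps query id to gene family (defaults to the
    query id); ``genome_of`` maps subject/contig id to genome id (defaults to
    the contig id).
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            (qseqid, sseqid, pident, length, _mismatch, _gapopen,
             qstart, qend, sstart, send, ev, bits) = parts
            pident_f = float(pident)
            if not 0 <= pident_f <= 100:
                raise ValueError(f"{path}:{lineno}: pident {pident} outside [0,100]")
            if qseqid not in query_lengths:
                if skip_unknown:
                    continue
                raise ValueError(f"{path}:{lineno}: unknown query {qseqid!r} (no length supplied)")
            qlen = query_lengths[qseqid]
            sstart_i, send_i = int(sstart), int(send)
            if sstart_i <= send_i:
                strand, lo, hi = "+", sstart_i - 1, send_i
            else:
                strand, lo, hi = "-", send_i - 1, sstart_i
            qstart_i, qend_i = int(qstart), int(qend)
            coverage = 100.0 * (abs(qend_i - qstart_i) + 1) / qlen
            ev_f = float(ev)
            aln_len = int(length)
            hits.append(
                Hit(
                    query_id=qseqid,
                    query_family=(query_families or {}).get(qseqid, qseqid),
                    contig_id=sseqid,
                    genome_id=(genome_of or {}).get(sseqid, sseqid),
                    subject_start=lo,
                    subject_end=hi,
                    strand=strand,
                    frame=0,
                    percent_identity=pident_f,
                    query_coverage=coverage,
                    alignment_length=aln_len,
                    raw_score=0,
                    bit_score=float(bits),
                    evalue=ev_f,
                    query_length=qlen,
                )
            )
    return hits


def write_tabular_hits(hits: Sequence[Hit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (1-based inclusive subject
    coordinates, minus-strand rows with sstart > send)."""
    rows = []
    for h in hits:
        if h.strand == "+":
            sstart, send = h.subject_start + 1, h.subject_end
        else:
            sstart, send = h.subject_end, h.subject_start + 1
        qspan = max(1, round(h.query_coverage / 100.0 * h.query_length)) if h.query_length else 1
        identities = round(h.percent_identity / 100.0 * h.alignment_length)
        rows.append(
            [h.query_id, h.contig_id, f"{h.percent_identity:.3f}", h.alignment_length,
             h.alignment_length - identities, 0, 1, qspan, sstart, send,
             f"{h.evalue:.3g}", f"{h.bit_score:.1f}"]
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def hits_to_frame(hits: Sequence[Hit]) -> pd.DataFrame:
    """Hits as a DataFrame in the package's own (richer) column order."""
    cols = [
        "query_id", "query_family", "contig_id", "genome_id", "subject_start",
        "subject_end", "strand", "frame", "percent_identity", "query_coverage",
        "alignment_length", "raw_score", "bit_score", "evalue", "query_length",
    ]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hits], columns=cols)


def hits_from_frame(frame: pd.DataFrame) -> list[Hit]:
    return [
        Hit(
            query_id=str(r.query_id), query_family=str(r.query_family),
            contig_id=str(r.contig_id), genome_id=str(r.genome_id),
            subject_start=int(r.subject_start), subject_end=int(r.subject_end),
            strand=str(r.strand), frame=int(r.frame),
            percent_identity=float(r.percent_identity),
            query_coverage=float(r.query_coverage),
            alignment_length=int(r.alignment_length), raw_score=int(r.raw_score),
            bit_score=float(r.bit_score), evalue=float(r.evalue),
            query_length=int(r.query_length),
        )
        for r in frame.itertuples(index=False)
    ]
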