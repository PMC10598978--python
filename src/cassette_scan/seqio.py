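"""Sequence IO and six-frame translation with coordinate mapping.

Internal coordinates are 0-based half-open on the forward strand throughout
the package; exported hit tables use the 1-based inclusive BLAST convention
(see :mod:`cassette_scan.search`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

MOLECULE_LABELS = ("plasmid", "chromosome", "unknown")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class Contig:
    """A DNA sequence with genome and molecule metadata: the search subject."""

    contig_id: str
    genome_id: str
    sequence: str
    molecule_label: str = "unknown"
    species: str = ""

    def __post_init__(self) -> None:
        if self.molecule_label not in MOLECULE_LABELS:
            raise ValueError(
                f"molecule_label must be one of {MOLECULE_LABELS}, "
                f"got {self.molecule_label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """An amino-acid sequence tagged with its gene/bacteriocin family."""

    protein_id: str
    sequence: str
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"protein {self.protein_id!r}: family must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FramePeptide:
    """One reading-frame translation of a contig.

    ``offset`` is the 0-based forward-strand position where the frame's first
    usable base sits (for minus frames, the offset into the reverse
    complement).  ``dna_start(i)`` maps peptide index ``i`` back to the
    forward-strand start of its codon; it is strictly increasing in ``i`` for
    plus frames and strictly decreasing for minus frames.
    """

    contig_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    peptide: str
    contig_length: int
    offset: int

    def dna_start(self, i: int) -> int:
        """Forward-strand 0-based start of the codon encoding ``peptide[i]``."""
        if not 0 <= i < len(self.peptide):
            raise IndexError(f"peptide index {i} out of range")
        if self.frame > 0:
            return self.offset + 3 * i
        return self.contig_length - self.offset - 3 * i - 3

    def dna_span(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Forward-strand half-open DNA interval covered by peptide[pep_start:pep_end]."""
        if pep_end <= pep_start:
            raise ValueError("empty peptide span")
        if self.frame > 0:
            return self.offset + 3 * pep_start, self.offset + 3 * pep_end
        return (
            self.contig_length - self.offset - 3 * pep_end,
            self.contig_length - self.offset - 3 * pep_start,
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_description_metadata(description: str) -> dict[str, str]:
    """Parse ``key=value`` tokens from a FASTA description line."""
    meta: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_dna_fasta(path: str | Path) -> list[Contig]:
    """Read a DNA FASTA into Contig records.

    Header metadata is taken from ``key=value`` tokens in the description
    (``genome=``, ``molecule=``, ``species=``); genome_id defaults to the
    contig id itself.  Sequences are uppercased and U is mapped to T.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: empty FASTA, returning no contigs")
        return []
    contigs = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        meta = _parse_description_metadata(rec.description)
        contigs.append(
            Contig(
                contig_id=rec.id,
                genome_id=meta.get("genome", rec.id),
                sequence=str(rec.seq).upper().replace("U", "T"),
                molecule_label=meta.get("molecule", "unknown"),
                species=meta.get("species", ""),
            )
        )
    return contigs


def read_protein_fasta(path: str | Path, default_family: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA; family comes from a ``family=`` description token,
    else from the id itself when no default is given."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: empty FASTA, returning no proteins")
        return []
    proteins = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        meta = _parse_description_metadata(rec.description)
        family = meta.get("family", default_family or rec.id)
        proteins.append(ProteinRecord(rec.id, str(rec.seq).upper(), family))
    return proteins


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write Contig or ProteinRecord objects as FASTA with metadata tokens."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Contig):
                header = (
                    f">{rec.contig_id} genome={rec.genome_id} "
                    f"molecule={rec.molecule_label}"
                )
                if rec.species:
                    header += f" species={rec.species}"
                seq = rec.sequence
            else:
                header = f">{rec.protein_id} family={rec.family}"
                seq = rec.sequence
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_TABLE_CACHE: dict[int, dict[str, str]] = {}


def _codon_map(table_id: int) -> dict[str, str]:
    """Codon -> amino acid for the given NCBI table, stops as '*'."""
    if table_id not in _TABLE_CACHE:
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for codon in table.stop_codons:
            mapping[codon] = "*"
        _TABLE_CACHE[table_id] = mapping
    return _TABLE_CACHE[table_id]


def _translate_frame(seq: str, table_id: int) -> str:
    mapping = _codon_map(table_id)
    n = len(seq) // 3
    return "".join(mapping.get(seq[3 * i : 3 * i + 3], "X") for i in range(n))


def six_frame_translate(contig: Contig, table_id: int = 11) -> list[FramePeptide]:
    """Translate all six frames; stops kept as '*', N-containing codons as X.

    Frames +1..+3 read the forward strand from offsets 0..2; frames -1..-3
    read the reverse complement likewise.  Default genetic code is the
    bacterial/archaeal table 11.
    """
    seq = contig.sequence.upper()
    rc = reverse_complement(seq)
    out = []
    for off in range(3):
        out.append(
            FramePeptide(contig.contig_id, off + 1, _translate_frame(seq[off:], table_id), len(seq), off)
        )
    for off in range(3):
        out.append(
            FramePeptide(contig.contig_id, -(off + 1), _translate_frame(rc[off:], table_id), len(seq), off)
        )
    return out


def write_tsv(frame: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a DataFrame as deterministic, UTF-8 TSV (one header row)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(summary: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
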