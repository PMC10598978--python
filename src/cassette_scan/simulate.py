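"""Synthetic genome datasets with the statistical structure the analysis
assumes, plus truth tables.

The generator emulates the observed evolutionary pattern of the transporter:
the F/G/H components (membrane/permease/ATPase) diverge along the carrier
species, while the E component and the bacteriocin structural gene diverge
along the associated bacteriocin, crosscutting species.  Each strain draws a
species, optionally carries a cassette (complete, partial, or orphan), adds
strain-level noise on top of its centroids, and the proteins are
back-translated with uniformly random synonymous codons and implanted into
iid background DNA at the reference spacings +/- a bounded jitter; the whole
cassette region is strand-flipped with probability one half.

Substitutions are uniform over the 19 alternative residues (no rate matrix)
and back-translation has no codon-usage bias — deliberately simple, but
sufficient to create the block structure the downstream analysis detects.
All randomness flows from one seeded numpy PCG64 generator, so outputs are
byte-identical across runs and platforms for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .association import AssociationCall, StructuralGeneDB, ORPHAN
from .cassette import CassetteCall, ReferenceCluster, write_reference_cluster
from .seqio import Contig, ProteinRecord, reverse_complement, write_fasta, write_tsv

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# protein lengths (aa) of the four transporter components and the structural
# peptide; deliberately in the range of the real genes (immunity/membrane
# components a few hundred residues, a leaderless-bacteriocin peptide ~50 aa)
GENE_LENGTHS_AA = {"mr10E": 300, "mr10F": 240, "mr10G": 230, "mr10H": 220}
GENE_ORDER = ("mr10E", "mr10F", "mr10G", "mr10H")
STRUCTURAL_LENGTH_AA = 55
REFERENCE_GAPS_BP = (40, 20, 30)  # inter-gene gaps E-F, F-G, G-H
STRUCTURAL_GAP_BP = 100  # gap between structural gene end and cassette start
TANDEM_GAP_BP = 20  # gap between the two peptide genes of a two-peptide bacteriocin


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 4 species x 12 strains with 3 bacteriocin labels, centroid
    divergence 0.25 and strain noise 0.02 per site — small enough to run the
    full pipeline in minutes, large enough to separate the within/between
    blocks the analysis is meant to detect.
    """

    n_species: int = 4
    strains_per_species: int = 12
    bacteriocin_labels: tuple[str, ...] = ("bacA", "bacB", "bacC")
    p_cassette: float = 0.7
    p_orphan: float = 0.1
    p_partial: float = 0.1
    contig_length_bp: int = 20_000
    gc_content: float = 0.40
    centroid_divergence_aa: float = 0.25
    strain_noise_aa: float = 0.02
    gap_jitter_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cassette", "p_orphan", "p_partial"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("centroid_divergence_aa", "strain_noise_aa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        cassette_bp = _cassette_span_bp()
        needed = cassette_bp + 2 * (STRUCTURAL_GAP_BP + 3 * STRUCTURAL_LENGTH_AA + 3 + self.gap_jitter_bp) + 600
        if self.contig_length_bp < needed:
            raise ValueError(
                f"contig_length_bp={self.contig_length_bp} too short for the cassette "
                f"plus flanks (need >= {needed})"
            )


def _gene_dna_len(aa_len: int) -> int:
    return 3 * aa_len + 3  # coding codons + stop


def _cassette_span_bp() -> int:
    return sum(_gene_dna_len(GENE_LENGTHS_AA[g]) for g in GENE_ORDER) + sum(REFERENCE_GAPS_BP)


@dataclass
class TruthRecord:
    genome_id: str
    species: str
    bacteriocin_label: str  # "" for non-carriers; label even for orphans (lineage)
    status: str  # complete | partial | absent
    orphan: bool
    strand: str  # + | - | ""
    molecule: str
    gene_coords: dict[str, tuple[int, int]] = field(default_factory=dict)
    structural_coords: tuple[int, int] | None = None
    mutation_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SimDataset:
    config: SimConfig
    contigs: list[Contig]
    queries: list[ProteinRecord]  # the four root transporter proteins
    reference: ReferenceCluster
    structural_db: StructuralGeneDB
    truth: list[TruthRecord]
    genome_tree_newick: str
    strain_proteins: dict[str, dict[str, str]]  # genome_id -> gene -> protein

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "genome_id": t.genome_id,
                    "species": t.species,
                    "bacteriocin_label": t.bacteriocin_label,
                    "status": t.status,
                    "orphan": t.orphan,
                    "strand": t.strand,
                    "molecule": t.molecule,
                    "n_genes_implanted": len(t.gene_coords),
                }
            )
        return pd.DataFrame(rows)

    def species_of(self) -> dict[str, str]:
        return {t.genome_id: t.species for t in self.truth}

    def molecule_of(self) -> dict[str, str]:
        return {t.genome_id: t.molecule for t in self.truth}


def _mutate(seq: str, p: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each site with probability p, uniformly over the other 19
    residues; returns the mutated sequence and the substitution count."""
    if p == 0:
        return seq, 0
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out), len(hits)


_SYNONYMOUS: dict[str, list[str]] | None = None
_STOPS: list[str] | None = None


def _codon_choices() -> tuple[dict[str, list[str]], list[str]]:
    global _SYNONYMOUS, _STOPS
    if _SYNONYMOUS is None:
        table = CodonTable.unambiguous_dna_by_id[11]
        syn: dict[str, list[str]] = {}
        for codon, aa in sorted(table.forward_table.items()):
            syn.setdefault(aa, []).append(codon)
        _SYNONYMOUS = syn
        _STOPS = sorted(table.stop_codons)
    return _SYNONYMOUS, _STOPS


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> DNA under code table 11 with uniform synonymous codon choice
    and a uniform stop codon appended."""
    syn, stops = _codon_choices()
    codons = [syn[aa][rng.integers(len(syn[aa]))] for aa in protein]
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _background_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=probs))


def reference_cluster(cluster_id: str = "mr10", start: int = 1000) -> ReferenceCluster:
    """The reference cassette architecture used for implanting and calling."""
    loci = []
    pos = start
    for gene, gap in zip(GENE_ORDER, (*REFERENCE_GAPS_BP, 0)):
        end = pos + _gene_dna_len(GENE_LENGTHS_AA[gene])
        loci.append((gene, "+", pos, end))
        pos = end + gap
    return ReferenceCluster(cluster_id, tuple(loci))


def _random_subtree(leaves: list[str], rng: np.random.Generator, bl: float) -> str:
    if len(leaves) == 1:
        return f"{leaves[0]}:{bl:.4g}"
    order = [leaves[i] for i in rng.permutation(len(leaves))]
    mid = len(order) // 2
    left = _random_subtree(order[:mid], rng, bl)
    right = _random_subtree(order[mid:], rng, bl)
    return f"({left},{right}):{bl:.4g}"


def _genome_tree(strains_by_species: dict[str, list[str]], rng: np.random.Generator) -> str:
    """Fully resolved genome tree: species split deeply, strains shallowly
    (random resolved topology within species — strain noise is iid, so the
    within-species resolution carries no signal, mirroring near-identical
    core genomes)."""
    species_clades = [
        _random_subtree(strains, rng, 0.02) for sp, strains in sorted(strains_by_species.items())
    ]

    def join(clades: list[str]) -> str:
        if len(clades) == 1:
            return clades[0]
        mid = len(clades) // 2
        return f"({join(clades[:mid])},{join(clades[mid:])}):0.5"

    return join(species_clades).rsplit(":", 1)[0] + ";"


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the full dataset: genomes, queries, reference cluster,
    structural DB with expected offsets, truth records, and a genome tree."""
    rng = np.random.default_rng(config.seed)
    ref = reference_cluster()
    # root proteins, generated once from the seed
    roots = {g: _random_protein(GENE_LENGTHS_AA[g], rng) for g in GENE_ORDER}
    structural_root = _random_protein(STRUCTURAL_LENGTH_AA, rng)
    tandem_root = _random_protein(STRUCTURAL_LENGTH_AA, rng)

    species_names = [f"sp{i+1}" for i in range(config.n_species)]
    labels = list(config.bacteriocin_labels)

    # species centroids for F/G/H; bacteriocin centroids for E + structural
    species_centroids = {
        sp: {g: _mutate(roots[g], config.centroid_divergence_aa, rng)[0] for g in GENE_ORDER[1:]}
        for sp in species_names
    }
    bact_centroids = {}
    for lab in labels:
        bact_centroids[lab] = {
            "mr10E": _mutate(roots["mr10E"], config.centroid_divergence_aa, rng)[0],
            "structural": _mutate(structural_root, config.centroid_divergence_aa, rng)[0],
        }
    # the first label is modeled as a two-peptide (tandem) bacteriocin
    tandem_label = labels[0]
    bact_centroids[tandem_label]["structural2"] = _mutate(
        tandem_root, config.centroid_divergence_aa, rng
    )[0]

    # structural database: one entry per label (two for the tandem label)
    struct_len_dna = _gene_dna_len(STRUCTURAL_LENGTH_AA)
    entries, offsets, fam2label = [], {}, {}
    for lab in labels:
        if lab == tandem_label:
            fams = [(f"{lab}.a1", bact_centroids[lab]["structural"], True),
                    (f"{lab}.a2", bact_centroids[lab]["structural2"], False)]
        else:
            fams = [(lab, bact_centroids[lab]["structural"], True)]
        for fam, protein, is_first in fams:
            entries.append(ProteinRecord(fam, protein, fam))
            fam2label[fam] = lab
            if lab == tandem_label:
                if is_first:
                    offsets[fam] = -(STRUCTURAL_GAP_BP + struct_len_dna + TANDEM_GAP_BP + struct_len_dna)
                else:
                    offsets[fam] = -(STRUCTURAL_GAP_BP + struct_len_dna)
            else:
                offsets[fam] = -(STRUCTURAL_GAP_BP + struct_len_dna)
    db = StructuralGeneDB(entries, offsets, fam2label)

    contigs: list[Contig] = []
    truth: list[TruthRecord] = []
    strain_proteins: dict[str, dict[str, str]] = {}
    strains_by_species: dict[str, list[str]] = {sp: [] for sp in species_names}
    ref_gaps = ref.reference_gaps()

    for sp in species_names:
        for k in range(config.strains_per_species):
            gid = f"{sp}_s{k+1:02d}"
            strains_by_species[sp].append(gid)
            molecule = "plasmid" if rng.random() < 0.5 else "chromosome"
            carrier = rng.random() < config.p_cassette
            if not carrier:
                seq = _background_dna(config.contig_length_bp, config.gc_content, rng)
                contigs.append(Contig(f"{gid}.c1", gid, seq, molecule, sp))
                truth.append(TruthRecord(gid, sp, "", "absent", False, "", molecule))
                continue
            lab = labels[rng.integers(len(labels))]
            orphan = rng.random() < config.p_orphan
            partial = rng.random() < config.p_partial
            dropped: set[str] = set()
            if partial:
                n_drop = int(rng.integers(1, len(GENE_ORDER)))  # 1..3
                idx = rng.choice(len(GENE_ORDER), size=n_drop, replace=False)
                dropped = {GENE_ORDER[i] for i in sorted(idx)}

            prots: dict[str, str] = {}
            mut_counts: dict[str, int] = {}
            for g in GENE_ORDER:
                centroid = bact_centroids[lab]["mr10E"] if g == "mr10E" else species_centroids[sp][g]
                prots[g], mut_counts[g] = _mutate(centroid, config.strain_noise_aa, rng)
            struct_prots: list[tuple[str, str]] = []
            if not orphan:
                if lab == tandem_label:
                    p1, _ = _mutate(bact_centroids[lab]["structural"], config.strain_noise_aa, rng)
                    p2, _ = _mutate(bact_centroids[lab]["structural2"], config.strain_noise_aa, rng)
                    struct_prots = [(f"{lab}.a1", p1), (f"{lab}.a2", p2)]
                else:
                    p1, _ = _mutate(bact_centroids[lab]["structural"], config.strain_noise_aa, rng)
                    struct_prots = [(lab, p1)]
            strain_proteins[gid] = dict(prots)

            # assemble the insert: [structural genes] gap [cassette genes]
            jitter = lambda: int(rng.integers(-config.gap_jitter_bp, config.gap_jitter_bp + 1))
            pieces: list[tuple[str | None, str]] = []  # (gene name or None, dna)
            for fam, protein in struct_prots:
                pieces.append((f"struct:{fam}", back_translate(protein, rng)))
                if fam.endswith(".a1"):
                    pieces.append((None, _background_dna(max(1, TANDEM_GAP_BP + jitter()), config.gc_content, rng)))
            if struct_prots:
                pieces.append((None, _background_dna(max(1, STRUCTURAL_GAP_BP + jitter()), config.gc_content, rng)))
            present_genes = [g for g in GENE_ORDER if g not in dropped]
            for i, g in enumerate(GENE_ORDER):
                if g in dropped:
                    continue
                pieces.append((g, back_translate(prots[g], rng)))
                if i < len(GENE_ORDER) - 1:
                    gap = max(1, ref_gaps[i] + jitter())
                    pieces.append((None, _background_dna(gap, config.gc_content, rng)))
            insert = "".join(dna for _, dna in pieces)
            flip = rng.random() < 0.5
            strand = "-" if flip else "+"
            max_pos = config.contig_length_bp - len(insert)
            pos = int(rng.integers(300, max_pos - 300))
            background = _background_dna(config.contig_length_bp - len(insert), config.gc_content, rng)
            if flip:
                insert = reverse_complement(insert)
            seq = background[:pos] + insert + background[pos:]

            # forward-strand coordinates of each implanted gene
            coords: dict[str, tuple[int, int]] = {}
            struct_coords: tuple[int, int] | None = None
            cursor = 0
            for name, dna in pieces:
                lo, hi = cursor, cursor + len(dna)
                cursor = hi
                if name is None:
                    continue
                if flip:
                    span = (pos + len(insert) - hi, pos + len(insert) - lo)
                else:
                    span = (pos + lo, pos + hi)
                if name.startswith("struct:"):
                    struct_coords = span
                else:
                    coords[name] = span
            status = "complete" if not dropped else "partial"
            contigs.append(Contig(f"{gid}.c1", gid, seq, molecule, sp))
            truth.append(
                TruthRecord(gid, sp, lab, status, orphan, strand, molecule,
                            coords, struct_coords, mut_counts)
            )

    queries = [ProteinRecord(f"{g}_ref", roots[g], g) for g in GENE_ORDER]
    tree = _genome_tree(strains_by_species, rng)
    return SimDataset(config, contigs, queries, ref, db, truth, tree, strain_proteins)


def write_dataset(data: SimDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in exactly the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.fna",
        "queries": out / "queries.faa",
        "reference": out / "reference_cluster.tsv",
        "structural": out / "structural_db.faa",
        "offsets": out / "structural_offsets.tsv",
        "truth": out / "truth.tsv",
        "tree": out / "genome_tree.nwk",
    }
    write_fasta(data.contigs, paths["genomes"])
    write_fasta(data.queries, paths["queries"])
    write_reference_cluster(data.reference, paths["reference"])
    with open(paths["structural"], "w") as fh:
        for e in data.structural_db.entries:
            label = data.structural_db.label_of(e.family)
            fh.write(f">{e.protein_id} family={e.family} label={label}\n{e.sequence}\n")
    write_tsv(
        pd.DataFrame(
            [{"family": f, "offset_bp": o} for f, o in sorted(data.structural_db.reference_offsets.items())]
        ),
        paths["offsets"],
    )
    write_tsv(data.truth_frame(), paths["truth"])
    with open(paths["tree"], "w") as fh:
        fh.write(data.genome_tree_newick + "\n")
    return paths


def truth_compare(
    cassette_calls: Sequence[CassetteCall],
    association_calls: Sequence[AssociationCall],
    truth: Sequence[TruthRecord],
) -> dict:
    """Score the pipeline against the generator's truth.

    Returns precision/recall of complete-cassette detection, bacteriocin
    association accuracy over truly associated completes, the orphan
    false-labeling count, and a confusion matrix by bacteriocin label.
    """
    truth_by_id = {t.genome_id: t for t in truth}
    call_ids = {c.genome_id for c in cassette_calls}
    missing = call_ids - set(truth_by_id)
    if missing:
        raise ValueError(f"calls reference unknown genomes: {sorted(missing)}")
    called_complete = {c.genome_id for c in cassette_calls if c.status == "complete"}
    true_complete = {t.genome_id for t in truth if t.status == "complete"}
    tp = len(called_complete & true_complete)
    precision = tp / len(called_complete) if called_complete else 1.0
    recall = tp / len(true_complete) if true_complete else 1.0

    label_by_id = {a.genome_id: a.label for a in association_calls}
    assoc_total = assoc_correct = 0
    orphan_total = orphan_false = 0
    confusion: dict[tuple[str, str], int] = {}
    for gid in sorted(called_complete & true_complete):
        t = truth_by_id[gid]
        pred = label_by_id.get(gid, ORPHAN)
        if t.orphan:
            orphan_total += 1
            if pred != ORPHAN:
                orphan_false += 1
            continue
        assoc_total += 1
        if pred == t.bacteriocin_label:
            assoc_correct += 1
        confusion[(t.bacteriocin_label, pred)] = confusion.get((t.bacteriocin_label, pred), 0) + 1
    return {
        "complete_precision": precision,
        "complete_recall": recall,
        "n_true_complete": len(true_complete),
        "n_called_complete": len(called_complete),
        "association_accuracy": assoc_correct / assoc_total if assoc_total else 1.0,
        "n_associated_truth": assoc_total,
        "orphan_false_labels": orphan_false,
        "n_true_orphans": orphan_total,
        "confusion": {f"{t}->{p}": c for (t, p), c in sorted(confusion.items())},
    }
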