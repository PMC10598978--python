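"""End-to-end orchestration: simulate/load -> search -> call -> associate ->
phylo -> report.

Every stage writes its table under the output directory so runs are
resumable from the hit-table cut point (real tabular search output can
replace the built-in translated search via ``hits_path``).  All outputs are
deterministic under a fixed seed; each file carries the config hash in a
header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import association as assoc_mod
from . import cassette as cassette_mod
from . import phylo as phylo_mod
from . import search as search_mod
from . import seqio
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

TRANSPORTER_GENES = sim_mod.GENE_ORDER


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Either ``simulate=True`` (inputs generated from ``sim``) or explicit
    paths to genomes/queries/reference; a missing structural DB downgrades
    every association to orphan with a warning.
    """

    out_dir: str = "cassette_scan_out"
    simulate: bool = True
    sim: sim_mod.SimConfig | None = None
    genomes_path: str | None = None
    queries_path: str | None = None
    reference_path: str | None = None
    structural_path: str | None = None
    offsets_path: str | None = None
    genome_tree_path: str | None = None
    hits_path: str | None = None  # resume from a precomputed tabular hit file
    min_identity: float = cassette_mod.DEFAULT_MIN_IDENTITY
    min_coverage: float = cassette_mod.DEFAULT_MIN_COVERAGE
    max_evalue: float = cassette_mod.DEFAULT_MAX_EVALUE
    tolerance_bp: int = cassette_mod.DEFAULT_TOLERANCE_BP
    window_bp: int = cassette_mod.DEFAULT_WINDOW_BP
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_identity < 0 or self.min_coverage < 0 or self.max_evalue <= 0:
            raise ValueError("thresholds must be positive")
        if self.tolerance_bp <= 0 or self.window_bp <= 0:
            raise ValueError("tolerance_bp and window_bp must be positive")
        if self.simulate and self.sim is None:
            self.sim = sim_mod.SimConfig(seed=self.seed)
        if not self.simulate:
            for name in ("genomes_path", "queries_path", "reference_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate=False")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded
        so relocated reruns stay comparable)."""
        payload = {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cassette_calls: list
    association_calls: list
    summary: dict
    concordance: dict
    rf: dict
    truth_metrics: dict | None
    out_dir: Path


def extract_component_protein(contig: seqio.Contig, hit: search_mod.Hit) -> str:
    """Translate the DNA span of a called component back into protein."""
    dna = contig.sequence[hit.subject_start : hit.subject_end]
    if hit.strand == "-":
        dna = seqio.reverse_complement(dna)
    return seqio._translate_frame(dna, 11).rstrip("*")


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate:
        data = sim_mod.simulate_dataset(config.sim)
        sim_mod.write_dataset(data, out / "inputs")
        genome_tree = phylo_mod._as_tree(data.genome_tree_newick)
        return (data.contigs, data.queries, data.reference, data.structural_db,
                genome_tree, data)
    contigs = seqio.read_dna_fasta(config.genomes_path)
    queries = seqio.read_protein_fasta(config.queries_path)
    reference = cassette_mod.read_reference_cluster(config.reference_path, config.tolerance_bp)
    db = None
    if config.structural_path:
        db = read_structural_db(config.structural_path, config.offsets_path)
    genome_tree = phylo_mod.read_newick(config.genome_tree_path) if config.genome_tree_path else None
    return contigs, queries, reference, db, genome_tree, None


def read_structural_db(fasta_path: str | Path, offsets_path: str | Path | None = None) -> assoc_mod.StructuralGeneDB:
    """Structural DB from a protein FASTA (family=/label= header tokens) plus
    an optional family -> expected-offset TSV."""
    from Bio import SeqIO

    entries, fam2label = [], {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        meta = seqio._parse_description_metadata(rec.description)
        fam = meta.get("family", rec.id)
        entries.append(seqio.ProteinRecord(rec.id, str(rec.seq).upper(), fam))
        fam2label[fam] = meta.get("label", fam)
    offsets = assoc_mod.read_offsets_tsv(offsets_path) if offsets_path else {}
    return assoc_mod.StructuralGeneDB(entries, offsets, fam2label)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logging.basicConfig(level=logging.INFO)
    logger.info("pipeline start (config hash %s, seed %d)", chash, config.seed)

    try:
        contigs, queries, reference, db, genome_tree, simdata = _load_inputs(config, out)
    except Exception as exc:
        raise RuntimeError(f"stage=inputs: {exc}") from exc

    contig_by_id = {c.contig_id: c for c in contigs}
    genome_ids = sorted({c.genome_id for c in contigs})
    species_of = {c.genome_id: (c.species or c.genome_id.split("_")[0]) for c in contigs}
    molecule_of = {c.genome_id: c.molecule_label for c in contigs}

    # --- search -----------------------------------------------------------
    try:
        if config.hits_path:
            qlens = {q.protein_id: len(q) for q in queries}
            fams = {q.protein_id: q.family for q in queries}
            if db:
                for e in db.entries:
                    qlens[e.protein_id] = len(e)
                    fams[e.protein_id] = e.family
            genome_of = {c.contig_id: c.genome_id for c in contigs}
            hits = search_mod.parse_tabular_hits(
                config.hits_path, qlens, fams, genome_of, skip_unknown=True
            )
        else:
            all_queries = list(queries) + (list(db.entries) if db else [])
            hits = search_mod.search_translated(all_queries, contigs, max_evalue=config.max_evalue)
    except Exception as exc:
        raise RuntimeError(f"stage=search: {exc}") from exc
    seqio.write_tsv(search_mod.hits_to_frame(hits), out / "hits.tsv", f"config={chash}")
    search_mod.write_tabular_hits(hits, out / "hits.outfmt6.tsv")

    # --- cassette calling -------------------------------------------------
    try:
        kept = cassette_mod.filter_hits(hits, config.min_identity, config.min_coverage, config.max_evalue)
        deduped = cassette_mod.dedupe_by_contig(kept)
        transporter_fams = set(reference.gene_order)
        thits = [h for h in deduped if h.query_family in transporter_fams]
        shits = [h for h in deduped if h.query_family not in transporter_fams]
        calls = [cassette_mod.call_cassette(thits, reference, gid) for gid in genome_ids]
    except Exception as exc:
        raise RuntimeError(f"stage=call: {exc}") from exc
    seqio.write_tsv(cassette_mod.calls_to_frame(calls, reference.gene_order),
                    out / "calls.tsv", f"config={chash}")

    # --- association ------------------------------------------------------
    try:
        associations = []
        for call in calls:
            if call.status != "complete":
                continue
            if db is None:
                logger.warning("no structural DB configured; %s reported orphan", call.genome_id)
                associations.append(assoc_mod.AssociationCall(call.genome_id, call, assoc_mod.ORPHAN))
                continue
            associations.append(assoc_mod.associate(call, shits, db, config.tolerance_bp))
    except Exception as exc:
        raise RuntimeError(f"stage=associate: {exc}") from exc
    seqio.write_tsv(assoc_mod.associations_to_frame(associations),
                    out / "associations.tsv", f"config={chash}")

    summary_frame = assoc_mod.summarize_dataset(calls, associations, species_of, molecule_of)
    seqio.write_tsv(summary_frame, out / "summary.tsv", f"config={chash}")

    # --- phylogenetics ----------------------------------------------------
    try:
        concordance, rf_stats, trees = _phylo_stage(
            config, out, chash, calls, associations, contig_by_id, species_of, genome_tree
        )
    except Exception as exc:
        raise RuntimeError(f"stage=phylo: {exc}") from exc

    status_counts = summary_frame["status"].value_counts().to_dict() if not summary_frame.empty else {}
    label_counts = (
        summary_frame.loc[summary_frame["label"] != "", "label"].value_counts().to_dict()
        if not summary_frame.empty else {}
    )
    truth_metrics = None
    if simdata is not None:
        truth_metrics = sim_mod.truth_compare(calls, associations, simdata.truth)
    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_genomes": len(genome_ids),
        "status_counts": status_counts,
        "label_counts": label_counts,
        "parameters": {
            "min_identity": config.min_identity,
            "min_coverage": config.min_coverage,
            "max_evalue": config.max_evalue,
            "tolerance_bp": config.tolerance_bp,
            "window_bp": config.window_bp,
            "n_perm": config.n_perm,
        },
        "truth_metrics": truth_metrics,
        "rf": rf_stats,
    }
    seqio.write_json(summary, out / "summary.json")
    seqio.write_json(concordance, out / "concordance.json")
    logger.info("pipeline done: %s", json.dumps(status_counts))
    return PipelineResult(config, calls, associations, summary, concordance, rf_stats, truth_metrics, out)


def _phylo_stage(config, out, chash, calls, associations, contig_by_id, species_of, genome_tree):
    """Per-gene identity matrices, UPGMA gene trees, RF vs the genome tree and
    the species/bacteriocin concordance tests."""
    complete = [c for c in calls if c.status == "complete"]
    concordance: dict[str, dict] = {}
    rf_stats: dict[str, dict] = {}
    trees: dict[str, object] = {}
    if len(complete) < 4:
        logger.warning("fewer than 4 complete cassettes; skipping phylogenetic stage")
        return concordance, rf_stats, trees
    label_by_genome = {a.genome_id: a.label for a in associations}
    bact_labels = {g: l for g, l in label_by_genome.items() if l != assoc_mod.ORPHAN}
    phylo_dir = out / "phylo"
    phylo_dir.mkdir(exist_ok=True)
    for gi, gene in enumerate(TRANSPORTER_GENES):
        records = {}
        for call in complete:
            hit = call.components.get(gene)
            if hit is None:
                continue
            protein = extract_component_protein(contig_by_id[call.contig_id], hit)
            if protein:
                records[call.genome_id] = protein
        if len(records) < 4:
            continue
        dm = phylo_mod.identity_matrix(records)
        dm.to_tsv(phylo_dir / f"{gene}.dist.tsv")
        tree = phylo_mod.upgma(dm)
        trees[gene] = tree
        phylo_mod.write_newick(tree, phylo_dir / f"{gene}.nwk")
        gene_conc = {}
        for li, (name, labeling) in enumerate(
            (("species", {g: species_of[g] for g in records}),
             ("bacteriocin", {g: bact_labels[g] for g in records if g in bact_labels}))
        ):
            try:
                res = phylo_mod.label_concordance(
                    dm, labeling, n_perm=config.n_perm,
                    seed=config.seed + 101 * gi + 11 * li + 1,
                    gene=gene, labeling_name=name,
                )
                gene_conc[name] = res.as_dict()
            except ValueError as exc:
                logger.warning("concordance %s/%s skipped: %s", gene, name, exc)
        concordance[gene] = gene_conc
        if genome_tree is not None:
            try:
                rf, rf_norm = phylo_mod.robinson_foulds(genome_tree, tree)
                rf_stats[gene] = {"rf": rf, "rf_normalized": rf_norm}
            except ValueError as exc:
                logger.warning("RF %s skipped: %s", gene, exc)
    if genome_tree is not None and "mr10E" in trees:
        annotations = {
            g: {"species": species_of.get(g, ""), "bacteriocin": label_by_genome.get(g, "")}
            for c in complete for g in [c.genome_id]
        }
        try:
            tbl = phylo_mod.tanglegram_table(genome_tree, trees["mr10E"], annotations)
            phylo_mod.write_tanglegram_tsv(tbl, phylo_dir / "tanglegram_mr10E.tsv")
        except ValueError as exc:
            logger.warning("tanglegram skipped: %s", exc)
    return concordance, rf_stats, trees
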