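# Methods

## Problem and model

The package screens bacterial genome assemblies for a conserved four-gene
ABC-transporter cassette (gene order E–F–G–H) that confers bacteriocin
self-immunity, classifies each carrier as bacteriocin-associated or orphan,
and quantifies whether each component's variation follows the associated
bacteriocin or the carrier species. The underlying biological expectation is
asymmetric: the accessory/immunity component E co-evolves with the
bacteriocin it protects against, while the membrane and ATPase components
F, G, H follow the host species.

## Translated search

Each protein query is aligned against all six reading-frame translations of
each contig (stop codons kept as `*`, N-containing codons as `X`).
The alignment core is Smith–Waterman with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62; gap open 11, extend 1, i.e. a gap of length
*k* costs 12 + (k−1)). `*` takes the matrix's worst score (−4), so
alignments effectively stop at frame stops. Significance uses the gapped
Karlin–Altschul parameters for this scoring (K = 0.041, λ = 0.267):
E = K·m·n·exp(−λS), with m the query length in residues and n the **total
DNA length of the searched contigs** — a deliberate, documented convention,
since the statistic's role here is a stable ranking threshold rather than a
database-calibrated significance. `E ≤ 1e−6` is inclusive.

For contig-scale subjects the full dynamic program is avoided by exact
amino-acid 4-mer seeding: windows of one query length around each seed are
merged and aligned; frames shorter than 1 500 residues, or queries shorter
than 8 residues, always take the full dynamic program. The seeded path is
score-equivalent in practice (a homolog above the 40 % identity filter has
hundreds of expected intact 4-mers; the chance of none is negligible), and
the full-DP path is the one verified against a brute-force alignment
enumeration in the tests.

Coordinates are 0-based half-open on the forward strand internally;
exported tabular files use the 1-based inclusive 12-column convention with
minus-strand subject intervals written start > end.

## Cassette and association rules

Positive hits require identity **strictly greater than** 40 and coverage
strictly greater than 70 (coverage is the best HSP's aligned query span over
the query length). Overlapping hits (≥1 bp, transitively) form a locus; the
locus keeps the highest-identity hit, ties broken by bit score, then
E-value, then query id.

A complete cassette needs all four families on one contig, in reference
order or its full reversal, with each adjacent inter-gene gap within
±500 bp (inclusive) of the reference gap. Gaps were chosen over
anchor-based positions because pairwise gaps are invariant to indels outside
the cassette. Mixed strands (an internal inversion) are never complete.
Components split across contigs yield a partial call on the contig with the
most components (ties to the lexicographically first contig) plus a logged
warning.

Association measures the signed distance from the cassette's nearest
boundary to the structural-gene start, orientation-normalized (negative =
upstream in the cassette's reading direction). A family with a reference
offset must match it within ±500 bp; families without one must lie within
500 bp of the cassette boundary. The highest-identity qualifying hit wins;
two-peptide bacteriocins register two families mapping to one label, either
sufficing. Association across contigs is never made, and only complete
cassettes are associated.

## Specificity analysis

Per-gene protein sequences are taken from the called hit spans, translated
in the hit frame. Pairwise identity uses end-to-end (Needleman–Wunsch)
alignment with the same scoring; identity = matches / alignment columns,
gap columns included. Pairwise global identity stands in for MSA-derived
identity: it is deterministic and dependency-free, and the downstream
claims concern relative similarity blocks, which survive the substitution.
Because co-optimal global alignments can differ in match count, the
sequence pair is ordered canonically before aligning, making identity
exactly symmetric.

Distances are D = 100 − identity. UPGMA (average linkage) and neighbor
joining are implemented in-package to guarantee a deterministic tie-break —
merge the pair whose cluster representatives (smallest member label) are
lexicographically smallest — and are cross-checked against a
definition-level average-linkage oracle and scikit-bio's NJ in the tests.
Negative NJ branch lengths are clamped to zero with a warning. Maximum
likelihood trees and bootstrap support are out of scope; distance trees are
the substitute, and a genome tree may be supplied externally as Newick.

Tree discordance is the unrooted Robinson–Foulds distance after restricting
both trees to their shared leaves (≥4 required), normalized by 2(n−3).

The concordance statistic is S = mean(between-label D) − mean(within-label
D), tested one-sidedly by shuffling the label vector with a seeded PCG64
generator; p = (1 + #{S_perm ≥ S_obs}) / (n_perm + 1), default n_perm = 999.
Labels with fewer than two members are excluded with a warning. S was
preferred over silhouette-style scores to keep a single, easily permuted
statistic; the permutation null makes its scale immaterial.

## Synthetic data generator

The generator emulates the study design at desk scale: root proteins for
E/F/G/H (300/240/230/220 aa) and structural peptides (55 aa) are drawn once
from the seed; per-species centroids (F/G/H) and per-bacteriocin centroids
(E + structural gene) diverge from the roots at `centroid_divergence_aa`
(default 0.25 per site), and each strain adds `strain_noise_aa` (default
0.02). Substitutions are uniform over the 19 alternative residues;
back-translation uses code table 11 with uniform synonymous codons and no
usage bias. Genes are implanted at reference gaps (40/20/30 bp) ± uniform
jitter ≤ 100 bp into iid background DNA (GC 0.40), the whole insert
strand-flipped with probability 0.5. Defaults: 4 species × 12 strains,
3 bacteriocin labels (one modeled as a two-peptide tandem), 20 kb contigs,
p_cassette 0.7, p_orphan 0.1, p_partial 0.1 — one genome per contig, sized
so the full pipeline runs in well under a minute per dataset on one CPU.
These divergence settings yield query-to-strain identities around 73 %,
comfortably inside the >40 %/<100 % regime the filter is meant to separate,
and within/between identity blocks of roughly 96 % vs 56 %.

What the generator does **not** emulate: indels, rate heterogeneity and
back-mutation-aware evolution; codon-usage and GC structure of real
replicons; plasmid biology (molecule labels are assigned metadata, not
sequence features); gene gain/loss beyond the modeled partial cassettes;
contig fragmentation across a cassette. Passing tests therefore demonstrate
the correctness of the rules and statistics, not their robustness to those
real-data complications.

The genome tree written with each dataset resolves species deeply and
strains randomly within species (strain noise carries no phylogenetic
signal, mirroring near-identical core genomes); gene trees are expected to
recover the species clades for F/G/H but not for E, which is what the
Robinson–Foulds comparison measures.

## Numerical and degenerate-input choices

* Identity/coverage thresholds are strict inequalities; the E-value
  threshold is inclusive.
* The ±500 bp tolerances are inclusive.
* Six-frame translation of sequences shorter than a codon yields empty
  peptides, not errors; empty FASTA files warn and return empty lists;
  duplicate ids are errors naming the id.
* UPGMA/NJ label-order invariance comes from representative-based
  tie-breaks; permutation results are bit-reproducible given (seed,
  n_perm).
* All pipeline randomness derives from one integer seed; per-test
  permutation seeds are fixed offsets from it. Outputs embed a hash of the
  analysis parameters (excluding the output path) so relocated reruns stay
  comparable.

## Known limitations

* The Karlin–Altschul constants are fixed to the BLOSUM62 11/1 gapped
  values; other matrices would need their own constants.
* One best HSP per candidate window: no HSP chaining, so a homolog split by
  a long insertion may under-report coverage.
* The reference-offset rule assumes structural genes flank the cassette on
  the same contig; trans-contig clusters are reported orphan by design.
* Robinson–Foulds saturates quickly for unrelated resolutions; the
  normalized value should be read comparatively, not absolutely.
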