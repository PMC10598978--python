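"""Identity matrices, dendrograms, tree comparison and the label-concordance
permutation test.

This is the "protein specificity" layer: for each transporter gene an
identity matrix over the called protein sequences is converted into a
distance matrix (100 - identity), clustered by average linkage (UPGMA) or
neighbor joining, and compared with the genome tree via Robinson-Foulds
distance.  Whether a gene's variation tracks the carrier species or the
associated bacteriocin is quantified by a one-sided permutation test on the
mean between-group minus mean within-group distance.

UPGMA and NJ are implemented here rather than delegated because the package
guarantees deterministic tie-breaking (merge the lexicographically smallest
pair on equal criteria); both are cross-checked against independent
implementations in the test suite.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

from .search import ScoringScheme, _make_aligner, _sanitize


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with ordered labels and zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-9).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def restrict(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(k) for k in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        frame.to_csv(path, sep="\t", index_label="id", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in frame.columns], frame.to_numpy(dtype=float))


def global_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Percent identity from an end-to-end (Needleman-Wunsch, affine-gap)
    alignment: 100 * matches / alignment columns, gap columns included."""
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme, "global")
    alphabet = str(aligner.substitution_matrix.alphabet)
    x, y = _sanitize(a, alphabet), _sanitize(b, alphabet)
    if y < x:  # co-optimal alignments can differ in identities; canonicalize
        x, y = y, x
    aln = aligner.align(x, y)[0]
    return 100.0 * aln.counts().identities / aln.length


def identity_matrix(
    records: Mapping[str, str], scheme: ScoringScheme | None = None
) -> DistanceMatrix:
    """Distance matrix D = 100 - pairwise global identity over a mapping of
    id -> protein sequence."""
    labels = list(records)
    if len(labels) < 2:
        raise ValueError("need at least two records")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record ids")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - global_identity(records[labels[i]], records[labels[j]], scheme)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


def _as_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) dendrogram; rooted and ultrametric.

    Ties on merge distance are broken by the lexicographically smallest pair
    of cluster representatives (the smallest leaf name in each cluster), so
    the result is deterministic under label permutation.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("UPGMA needs at least two items")
    # active clusters: key -> (newick, size, height, representative)
    clusters: dict[int, tuple[str, int, float, str]] = {
        i: (_quote(dm.labels[i]), 1, 0.0, dm.labels[i]) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best: tuple[float, str, str, int, int] | None = None
        for ai, i in enumerate(keys):
            for j in keys[ai + 1 :]:
                d = dist[(i, j)]
                reps = tuple(sorted((clusters[i][3], clusters[j][3])))
                cand = (d, reps[0], reps[1], i, j)
                if best is None or cand < best:
                    best = cand
        d, _, _, i, j = best
        ni, si, hi, ri = clusters[i]
        nj, sj, hj, rj = clusters[j]
        height = d / 2.0
        newick = f"({ni}:{max(height - hi, 0.0):.10g},{nj}:{max(height - hj, 0.0):.10g})"
        merged = (newick, si + sj, height, min(ri, rj))
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[tuple(sorted((next_id, k)))] = (si * dik + sj * djk) / (si + sj)
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1
    (newick, _, _, _), = clusters.values()
    return _as_tree(newick + ";")


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted.  Negative branch lengths are
    clamped to zero with a warning."""
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least three items")
    clamped = False

    def bl(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    nodes: dict[int, tuple[str, str]] = {
        i: (_quote(dm.labels[i]), dm.labels[i]) for i in range(n)
    }
    D: dict[tuple[int, int], float] = {
        tuple(sorted((i, j))): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 3:
        keys = sorted(nodes)
        m = len(keys)
        r = {i: sum(D[tuple(sorted((i, k)))] for k in keys if k != i) for i in keys}
        best = None
        for ai, i in enumerate(keys):
            for j in keys[ai + 1 :]:
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                reps = tuple(sorted((nodes[i][1], nodes[j][1])))
                cand = (q, reps[0], reps[1], i, j)
                if best is None or cand < best:
                    best = cand
        _, _, _, i, j = best
        dij = D[(i, j)]
        li = bl(dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = bl(dij - dij / 2.0 - (r[i] - r[j]) / (2.0 * (m - 2)))
        ni, ri_ = nodes[i]
        nj, rj_ = nodes[j]
        newick = f"({ni}:{li:.10g},{nj}:{lj:.10g})"
        for k in keys:
            if k in (i, j):
                continue
            dk = 0.5 * (D[tuple(sorted((i, k)))] + D[tuple(sorted((j, k)))] - dij)
            D[tuple(sorted((next_id, k)))] = dk
        del nodes[i], nodes[j]
        nodes[next_id] = (newick, min(ri_, rj_))
        next_id += 1
    (a, b, c) = sorted(nodes)
    dab, dac, dbc = D[(a, b)], D[(a, c)], D[(b, c)]
    la = bl((dab + dac - dbc) / 2.0)
    lb = bl((dab + dbc - dac) / 2.0)
    lc = bl((dac + dbc - dab) / 2.0)
    newick = (
        f"({nodes[a][0]}:{la:.10g},{nodes[b][0]}:{lb:.10g},{nodes[c][0]}:{lc:.10g});"
    )
    if clamped:
        warnings.warn("neighbor joining produced negative branch lengths; clamped to 0")
    tree = _as_tree(newick)
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Unrooted Robinson-Foulds distance after restriction to the common leaf
    set: (symmetric difference of non-trivial bipartitions, normalization by
    2(n-3))."""
    leaves1 = {l.taxon.label for l in t1.leaf_node_iter()}
    leaves2 = {l.taxon.label for l in t2.leaf_node_iter()}
    shared = sorted(leaves1 & leaves2)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared)}")
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
    a.retain_taxa_with_labels(shared)
    b.retain_taxa_with_labels(shared)
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(a, b))
    n = len(shared)
    return rf, rf / (2.0 * (n - 3)) if n > 3 else 0.0


@dataclass
class ConcordanceResult:
    """Outcome of the label-concordance permutation test."""

    gene: str
    labeling_name: str
    score: float  # mean between-label distance minus mean within-label distance
    p_value: float
    n_perm: int
    seed: int
    n_items: int

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "labeling": self.labeling_name,
            "S": self.score,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_items": self.n_items,
        }


def label_concordance(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    gene: str = "",
    labeling_name: str = "",
) -> ConcordanceResult:
    """One-sided permutation test of whether items sharing a label are closer
    than items with different labels.

    S = mean(between-label D) - mean(within-label D); the null is generated
    by shuffling the label vector; p = (1 + #{S_perm >= S_obs}) / (n_perm+1).
    Labels with fewer than two members are excluded with a warning; at least
    two multi-member labels must remain.
    """
    items = [l for l in dm.labels if l in labels]
    counts: dict[str, int] = {}
    for it in items:
        counts[labels[it]] = counts.get(labels[it], 0) + 1
    dropped = {lab for lab, c in counts.items() if c < 2}
    if dropped:
        warnings.warn(f"excluding singleton labels from concordance test: {sorted(dropped)}")
    items = [it for it in items if labels[it] not in dropped]
    kept_labels = {labels[it] for it in items}
    if len(kept_labels) < 2:
        raise ValueError("concordance test needs >= 2 labels with >= 2 members each")
    sub = dm.restrict(items)
    codes = pd.Categorical([labels[it] for it in items]).codes.astype(np.int64)
    D = sub.values
    n = len(items)
    iu = np.triu_indices(n, k=1)
    dvec = D[iu]

    def score(c: np.ndarray) -> float:
        same = c[iu[0]] == c[iu[1]]
        return float(dvec[~same].mean() - dvec[same].mean())

    s_obs = score(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if score(perm) >= s_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return ConcordanceResult(gene, labeling_name, s_obs, p, n_perm, seed, n)


def tanglegram_table(
    genome_tree: dendropy.Tree,
    gene_tree: dendropy.Tree,
    annotations: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-leaf table linking the genome tree and a gene tree: the leaf's
    position in each tree's leaf ordering plus species/bacteriocin
    annotations; RF statistics in ``DataFrame.attrs['rf']``."""
    order1 = [l.taxon.label for l in genome_tree.leaf_node_iter()]
    order2 = [l.taxon.label for l in gene_tree.leaf_node_iter()]
    shared = [l for l in order1 if l in set(order2)]
    if not shared:
        raise ValueError("tanglegram requires overlapping leaf sets")
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared)}")
    pos2 = {l: i for i, l in enumerate(order2)}
    rows = []
    for i, leaf in enumerate(shared):
        ann = (annotations or {}).get(leaf, {})
        rows.append(
            {
                "leaf": leaf,
                "genome_tree_position": order1.index(leaf),
                "gene_tree_position": pos2[leaf],
                "species": ann.get("species", ""),
                "bacteriocin": ann.get("bacteriocin", ""),
            }
        )
    frame = pd.DataFrame(rows)
    rf, rf_norm = robinson_foulds(genome_tree, gene_tree)
    frame.attrs["rf"] = {"rf": rf, "rf_normalized": rf_norm, "n_shared_leaves": len(shared)}
    return frame


def write_tanglegram_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        rf = frame.attrs.get("rf", {})
        if rf:
            fh.write(
                f"# RF={rf['rf']} normalized={rf['rf_normalized']:.4f} "
                f"shared_leaves={rf['n_shared_leaves']}\n"
            )


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
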