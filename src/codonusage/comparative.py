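"""Cross-species comparison: GC3-gradient distances and RSCU biclustering.

Species are compared two ways: by the Euclidean distance between their
100-bin 5'→3' GC3 gradient vectors (lower = more similar mutational
trend), and by agglomerative hierarchical clustering (Euclidean distance,
complete linkage) of the species × 59-codon RSCU matrix — the 61 sense
codons minus the single-codon families ATG (Met) and TGG (Trp), whose
RSCU is identically 1 and carries no information.

Rows are raw RSCU values, not standardized: RSCU is already
family-normalized, so no further scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .composition import GradientVector
from .genetic_code import SENSE_CODONS, standard_code
from .rscu import RscuTable

#: Fixed lexicographic order of the 59 clustering codons.
CLUSTER_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in ("ATG", "TGG")
)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with species labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "d", d)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class RscuMatrix:
    """Species × 59-codon RSCU matrix for biclustering."""

    species: tuple[str, ...]
    codons: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.species), len(self.codons)):
            raise ValueError("RSCU matrix shape mismatch")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4): node, node, height, size
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Plain Euclidean distance between two equal-length vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((p - q) ** 2)))


def gradient_distance_matrix(
    gradients: Sequence[GradientVector],
) -> DistanceMatrix:
    """Pairwise Euclidean distances between species GC3-gradient vectors."""
    if len(gradients) < 2:
        raise ValueError("need at least 2 gradients")
    modes = {g.mode for g in gradients}
    nbins = {len(g.bins) for g in gradients}
    if len(modes) > 1 or len(nbins) > 1:
        raise ValueError("gradients must share mode and bin count")
    x = np.array([g.bins for g in gradients], dtype=float)
    return DistanceMatrix(
        labels=tuple(g.species for g in gradients),
        d=squareform(pdist(x, metric="euclidean")),
    )


def build_rscu_matrix(tables: Sequence[tuple[str, RscuTable]]) -> RscuMatrix:
    """Stack species RSCU tables into the 59-codon clustering matrix.

    Every species must have every degenerate family observed (true for
    pooled genome-scale counts); a missing family raises an error naming
    the species and codon.
    """
    code = standard_code()
    rows = []
    for label, table in tables:
        row = []
        for codon in CLUSTER_CODONS:
            v = table.values.get(codon)
            if v is None:
                aa = code.codon_to_aa[codon]
                raise ValueError(
                    f"species {label!r}: family of {codon} ({aa}) unobserved; "
                    "RSCU matrix requires every family present"
                )
            row.append(v)
        rows.append(row)
    return RscuMatrix(
        species=tuple(label for label, _ in tables),
        codons=CLUSTER_CODONS,
        values=np.array(rows, dtype=float),
    )


def _cluster(x: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    z = hierarchy.linkage(x, method="complete", metric="euclidean")
    return Dendrogram(linkage=z, labels=tuple(labels))


def bicluster(
    matrix: RscuMatrix,
) -> tuple[Dendrogram, Dendrogram, list[str], list[str]]:
    """Complete-linkage Euclidean clustering of rows and columns.

    Returns (row dendrogram, column dendrogram, row leaf order,
    column leaf order). Deterministic for a given input.
    """
    if len(matrix.species) < 2:
        raise ValueError("need at least 2 species to cluster")
    row_d = _cluster(matrix.values, matrix.species)
    col_d = _cluster(matrix.values.T, matrix.codons)
    return row_d, col_d, row_d.leaf_order(), col_d.leaf_order()


def cut_top_split(dendro: Dendrogram) -> tuple[set[str], set[str]]:
    """Leaf label sets of the two subtrees under the root merge."""
    tree = hierarchy.to_tree(dendro.linkage)

    def leaves(node) -> set[str]:
        if node.is_leaf():
            return {dendro.labels[node.id]}
        return leaves(node.left) | leaves(node.right)

    return leaves(tree.left), leaves(tree.right)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(dm.labels) + "\n")
        for i, lab in enumerate(dm.labels):
            row = "\t".join(f"{v:.6f}" for v in dm.d[i])
            fh.write(f"{lab}\t{row}\n")


def write_rscu_matrix_tsv(m: RscuMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(m.codons) + "\n")
        for i, lab in enumerate(m.species):
            row = "\t".join(f"{v:.6f}" for v in m.values[i])
            fh.write(f"{lab}\t{row}\n")


def write_merge_tsv(dendro: Dendrogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\theight\tsize\n")
        for a, b, h, s in dendro.linkage:
            fh.write(f"{int(a)}\t{int(b)}\t{h:.6f}\t{int(s)}\n")
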