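"""Island typing: Pearson similarity, UPGMA dendrogram, cutoff clustering.

Binary presence/absence profiles are compared with Pearson's r expressed as
a similarity percentage (r × 100); distances are 100 − similarity. The UPGMA
dendrogram is cut at a similarity threshold (default 50%), i.e. at merge
height (100 − cutoff)/2, and each resulting subtree is one island type.
Types are labeled with Roman numerals by decreasing member count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .orthology import PresenceAbsenceMatrix


@dataclass
class SimilarityMatrix:
    strains: list[str]
    entries: np.ndarray  # symmetric, diagonal 100, values in [-100, 100]

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (len(self.strains), len(self.strains)):
            raise ValidationError("similarity matrix shape does not match strain list")
        if not np.allclose(e, e.T, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        self.entries = e

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["strain_id"] + self.strains)
            for i, s in enumerate(self.strains):
                w.writerow([s] + [f"{v:.4f}" for v in self.entries[i]])


def pearson_similarity(matrix: PresenceAbsenceMatrix) -> SimilarityMatrix:
    """Pearson correlation of binary profiles, scaled to percent.

    Zero-variance profiles (a strain with all or none of the families) have
    an undefined r; the defined convention here is 100 when the two profiles
    are identical and 0 otherwise.
    """
    if len(matrix.strains) < 2:
        raise ValidationError("pearson_similarity requires at least two strains")
    if len(matrix.families) < 1:
        raise ValidationError("pearson_similarity requires at least one family")
    x = matrix.cells.astype(float)
    n = x.shape[0]
    sim = np.empty((n, n))
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    for i in range(n):
        for j in range(i, n):
            if norms[i] == 0.0 or norms[j] == 0.0:
                r = 1.0 if np.array_equal(x[i], x[j]) else 0.0
            else:
                r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            sim[i, j] = sim[j, i] = 100.0 * r
        sim[i, i] = 100.0
    return SimilarityMatrix(list(matrix.strains), sim)


@dataclass
class UpgmaNode:
    """Node of an ultrametric UPGMA tree; leaves have height 0."""

    height: float = 0.0
    name: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def min_leaf(self) -> str:
        return self.name if self.is_leaf else min(c.min_leaf for c in self.children)

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]

    def cophenetic_distances(self) -> dict[tuple[str, str], float]:
        """Tree-induced distances between all leaf pairs (2 × merge height)."""
        out: dict[tuple[str, str], float] = {}

        def walk(node):
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            key = (a, b) if a <= b else (b, a)
                            out[key] = 2.0 * node.height
            return [leaf for g in groups for leaf in g]

        walk(self)
        return out


def upgma(similarity: SimilarityMatrix) -> UpgmaNode:
    """Standard UPGMA on distance d = 100 − similarity.

    Clusters merge at height d/2 with size-weighted arithmetic-mean updates.
    Strains are ordered by sorted strain_id first; ties for the minimal pair
    are broken by the lowest (row, column) index in the current cluster list,
    where merged clusters are appended at the end. This makes the tree a
    deterministic function of the matrix.
    """
    if len(similarity.strains) < 2:
        raise ValidationError("upgma requires at least two leaves")
    order = sorted(range(len(similarity.strains)), key=lambda i: similarity.strains[i])
    names = [similarity.strains[i] for i in order]
    d = 100.0 - similarity.entries[np.ix_(order, order)]

    nodes = [UpgmaNode(name=nm) for nm in names]
    sizes = [1] * len(nodes)
    dist = d.tolist()
    while len(nodes) > 1:
        k = len(nodes)
        best = None
        bi = bj = -1
        for i in range(k):
            for j in range(i + 1, k):
                if best is None or dist[i][j] < best:
                    best = dist[i][j]
                    bi, bj = i, j
        # children ordered by smallest descendant leaf for a canonical tree
        pair = sorted((nodes[bi], nodes[bj]), key=lambda nd: nd.min_leaf)
        new_node = UpgmaNode(height=best / 2.0, children=tuple(pair))
        new_size = sizes[bi] + sizes[bj]
        new_row = [
            (sizes[bi] * dist[bi][t] + sizes[bj] * dist[bj][t]) / new_size
            for t in range(k)
            if t not in (bi, bj)
        ]
        keep = [t for t in range(k) if t not in (bi, bj)]
        nodes = [nodes[t] for t in keep] + [new_node]
        sizes = [sizes[t] for t in keep] + [new_size]
        dist = [[dist[a][b] for b in keep] for a in keep]
        for row, v in zip(dist, new_row):
            row.append(v)
        dist.append(new_row + [0.0])
    return nodes[0]


def roman(n: int) -> str:
    """Roman numeral for a positive integer (type labels I, II, ...)."""
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


@dataclass
class TypingResult:
    matrix: SimilarityMatrix
    tree: UpgmaNode
    cutoff_pct: float
    type_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_types(self) -> int:
        return len(set(self.type_of.values()))

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("strain_id\tfgi_type\n")
            for s in sorted(self.type_of):
                fh.write(f"{s}\t{self.type_of[s]}\n")


def assign_types(
    tree: UpgmaNode,
    cutoff_pct: float,
    matrix: SimilarityMatrix | None = None,
) -> TypingResult:
    """Cut the dendrogram at a similarity cutoff and label the clusters.

    A cluster is a maximal subtree whose internal merges all happened at
    similarity >= cutoff, i.e. at height <= (100 − cutoff)/2. Labels are
    Roman numerals by decreasing cluster size, ties broken by the
    lexicographically first strain in the cluster.
    """
    if not (-100.0 < cutoff_pct <= 100.0):
        raise ValidationError("cutoff_pct must lie in (-100, 100]")
    h_star = (100.0 - cutoff_pct) / 2.0 + 1e-9
    clusters: list[list[str]] = []

    def walk(node: UpgmaNode) -> None:
        if node.height <= h_star:
            clusters.append(sorted(node.leaves()))
        else:
            for c in node.children:
                walk(c)

    walk(tree)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    type_of = {}
    for k, cluster in enumerate(clusters):
        label = roman(k + 1)
        for strain in cluster:
            type_of[strain] = label
    return TypingResult(matrix=matrix, tree=tree, cutoff_pct=cutoff_pct, type_of=type_of)


def _newick_label(name: str) -> str:
    if any(c in name for c in " ()[]:;,'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: UpgmaNode, parent_height: float | None) -> str:
    if node.is_leaf:
        body = _newick_label(node.name)
    else:
        body = "(" + ",".join(_newick_node(c, node.height) for c in node.children) + ")"
    if parent_height is None:
        return body
    return f"{body}:{parent_height - node.height:.12g}"


def to_newick(tree: UpgmaNode) -> str:
    """Newick string with branch lengths in distance/2 (height) units."""
    return "(" + ",".join(_newick_node(c, tree.height) for c in tree.children) + ");" \
        if not tree.is_leaf else _newick_label(tree.name) + ";"


def write_newick(tree: UpgmaNode, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree) + "\n")


def read_newick(path_or_handle) -> UpgmaNode:
    """Read an ultrametric Newick tree back into UpgmaNode form.

    Heights are reconstructed from branch lengths assuming leaves sit at
    height 0 (true for any tree written by :func:`write_newick`).
    """
    from io import StringIO

    from Bio import Phylo

    if hasattr(path_or_handle, "read"):
        clade = Phylo.read(path_or_handle, "newick").root
    else:
        text = open(path_or_handle, encoding="utf-8").read()
        clade = Phylo.read(StringIO(text), "newick").root

    def depth_of_first_leaf(c) -> float:
        depth = 0.0
        while c.clades:
            child = c.clades[0]
            depth += child.branch_length or 0.0
            c = child
        return depth

    root_height = depth_of_first_leaf(clade)

    def convert(c, height):
        if not c.clades:
            return UpgmaNode(name=c.name, height=0.0)
        children = tuple(
            convert(ch, height - (ch.branch_length or 0.0)) for ch in c.clades
        )
        return UpgmaNode(height=height, children=children)

    return convert(clade, root_height)
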