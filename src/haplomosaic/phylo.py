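"""Marker-based genetic distances, UPGMA dendrograms and bootstrap support.

Genotype relationships are summarised from a character matrix (one aligned
column per polymorphic site), with p-distance or Tamura-Nei (TN93)
distances under pairwise deletion of ambiguous positions, agglomerated by
UPGMA (size-weighted average linkage, ultrametric output) and annotated
with clade bootstrap supports from column resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .simgenome import substream

VALID_BASES = "ACGT"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class CharacterMatrix:
    """Taxa x aligned positions; anything outside ACGT is gap/ambiguous."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        if len(self.rows) != len(set(self.rows)):
            raise ValueError("duplicate taxon names")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.rows)

    @property
    def n_positions(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def resample_positions(self, rng: np.random.Generator) -> "CharacterMatrix":
        n = self.n_positions
        idx = rng.integers(0, n, size=n)
        return CharacterMatrix(
            {t: "".join(s[i] for i in idx) for t, s in self.rows.items()})


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.taxa),) * 2:
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric, zero diagonal")
        if (v < 0).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


class SaturationError(ValueError):
    """TN93 logarithm argument fell to zero or below for a pair."""


def _pair_counts(s1: str, s2: str) -> tuple[int, int, int, int, dict[str, int]]:
    """Valid positions, A<->G transitions, C<->T transitions, transversions,
    and pooled base counts under pairwise deletion."""
    n = p1 = p2 = q = 0
    freq = {b: 0 for b in VALID_BASES}
    for a, b in zip(s1, s2):
        if a not in VALID_BASES or b not in VALID_BASES:
            continue
        n += 1
        freq[a] += 1
        freq[b] += 1
        if a != b:
            pair = frozenset((a, b))
            if pair == frozenset("AG"):
                p1 += 1
            elif pair == frozenset("CT"):
                p2 += 1
            else:
                q += 1
    return n, p1, p2, q, freq


def p_distance(s1: str, s2: str) -> float:
    n, p1, p2, q, _ = _pair_counts(s1, s2)
    if n == 0:
        raise ValueError("no valid positions for this pair")
    return (p1 + p2 + q) / n


def tn93_distance(s1: str, s2: str) -> float:
    """Tamura-Nei (1993) distance, base substitutions per site.

    Base frequencies are estimated from the pair itself (pooled over both
    sequences, pairwise-deleted positions only).
    """
    n, np1, np2, nq, freq = _pair_counts(s1, s2)
    if n == 0:
        raise ValueError("no valid positions for this pair")
    total = sum(freq.values())
    pi = {b: c / total for b, c in freq.items()}
    pa, pc, pg, pt = pi["A"], pi["C"], pi["G"], pi["T"]
    pr, py = pa + pg, pc + pt
    P1, P2, Q = np1 / n, np2 / n, nq / n
    if P1 + P2 + Q == 0:
        return 0.0
    if min(pr, py) == 0:
        raise SaturationError("degenerate base composition")
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pt * pc / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    w1 = 1.0 - (P1 / k1 if k1 > 0 else 0.0) - Q / (2.0 * pr)
    w2 = 1.0 - (P2 / k2 if k2 > 0 else 0.0) - Q / (2.0 * py)
    w3 = 1.0 - Q / (2.0 * pr * py)
    if min(w1, w2, w3) <= 0:
        raise SaturationError("substitution saturation for this pair")
    d = 0.0
    if k1 > 0:
        d -= k1 * math.log(w1)
    if k2 > 0:
        d -= k2 * math.log(w2)
    if k3 != 0:
        d -= k3 * math.log(w3)
    return d


def pairwise_distance(matrix: CharacterMatrix,
                      method: str = "tn93") -> DistanceMatrix:
    """All-pairs distance matrix ('p' or 'tn93'), pairwise deletion."""
    fn = {"p": p_distance, "p-distance": p_distance,
          "tn93": tn93_distance, "TN93": tn93_distance}[method]
    taxa = matrix.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(matrix.rows[taxa[i]], matrix.rows[taxa[j]])
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """Node of an ultrametric merge tree (heights in distance units / 2)."""

    height: float
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class UltrametricTree:
    root: TreeNode

    def leaves(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(n: TreeNode) -> None:
            if not n.is_leaf:
                out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> set[frozenset[str]]:
        return {n.leaf_names() for n in self.internal_nodes()}

    def total_branch_length(self) -> float:
        total = 0.0
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                total += n.height - c.height
                stack.append(c)
        return total

    def cophenetic(self) -> DistanceMatrix:
        """Tree-implied distances: twice the height of the lowest common
        ancestor of each leaf pair."""
        taxa = self.leaves()
        n = len(taxa)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> None:
            for i, a in enumerate(node.children):
                for b in node.children[i + 1:]:
                    for la in a.leaf_names():
                        for lb in b.leaf_names():
                            ia, ib = taxa.index(la), taxa.index(lb)
                            d[ia, ib] = d[ib, ia] = 2.0 * node.height
            for c in node.children:
                walk(c)

        walk(self.root)
        return DistanceMatrix(taxa, d)


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """Size-weighted average-linkage agglomeration (the classic UPGMA).

    The closest pair of clusters merges at node height d/2; distances to
    the merged cluster are member-count-weighted averages. Ties are broken
    by the lexicographically smallest (minimum taxon name, maximum taxon
    name) pair of cluster representatives, making output unique.
    """
    if len(dist.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    clusters: dict[str, TreeNode] = {
        t: TreeNode(0.0, name=t) for t in dist.taxa}
    sizes = {t: 1 for t in dist.taxa}
    d: dict[frozenset[str], float] = {}
    for i, a in enumerate(dist.taxa):
        for b in dist.taxa[i + 1:]:
            d[frozenset((a, b))] = dist.values[i, dist.taxa.index(b)]
    reps = set(dist.taxa)  # cluster representative = smallest member name
    while len(reps) > 1:
        best_pair, best_val = None, math.inf
        for pair, val in d.items():
            a, b = sorted(pair)
            key = (val, a, b)
            if best_pair is None or key < best_key:
                best_pair, best_val, best_key = (a, b), val, key
        a, b = best_pair
        node = TreeNode(best_val / 2.0, children=[clusters[a], clusters[b]])
        new_rep = min(a, b)
        other = max(a, b)
        for c in reps:
            if c in (a, b):
                continue
            da = d[frozenset((a, c))]
            db = d[frozenset((b, c))]
            w = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            d[frozenset((new_rep, c))] = w
        for c in list(d):
            if other in c:
                del d[c]
        reps.discard(other)
        sizes[new_rep] = sizes[a] + sizes[b]
        clusters[new_rep] = node
        del clusters[other]
    return UltrametricTree(clusters[next(iter(reps))])


def bootstrap_support(matrix: CharacterMatrix, replicates: int = 1000,
                      seed: int = 0, method: str = "p") -> UltrametricTree:
    """UPGMA tree with clade supports from position resampling.

    Positions are resampled with replacement `replicates` times; each
    replicate tree's clades are matched to the original tree's clades by
    leaf-set identity, and support is the percentage of replicates
    containing the clade. Pairs saturating the TN93 transform in a
    replicate fall back to p-distance for that replicate.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = substream(seed, "bootstrap")
    base = upgma(pairwise_distance(matrix, method))
    counts: dict[frozenset[str], int] = {c: 0 for c in base.clades()}
    for _ in range(replicates):
        rep = matrix.resample_positions(rng)
        try:
            dm = pairwise_distance(rep, method)
        except SaturationError:
            dm = pairwise_distance(rep, "p")
        for clade in upgma(dm).clades():
            if clade in counts:
                counts[clade] += 1
    for node in base.internal_nodes():
        node.support = 100.0 * counts[node.leaf_names()] / replicates
    return base


# ---------------------------------------------------------------------------
# newick I/O


def to_newick(tree: UltrametricTree, decimals: int = 6) -> str:
    """Newick text with branch lengths and integer supports as internal
    node labels (root support omitted)."""

    def fmt(x: float) -> str:
        s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
        return s if s else "0"

    def walk(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(walk(c, node.height) for c in node.children)
            label = ("" if node.support is None
                     else str(int(round(node.support))))
            body = f"({inner}){label}"
        if parent_height is None:
            return body
        return f"{body}:{fmt(parent_height - node.height)}"

    return walk(tree.root, None) + ";"


def from_newick(text: str) -> UltrametricTree:
    """Parse Newick produced by :func:`to_newick` back into a tree.

    Heights are reconstructed from root-to-leaf branch lengths (leaves sit
    at height 0); internal node labels are read as integer supports.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def depth_above(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    leaf_depths = [depth_above(l) for l in dtree.leaf_node_iter()]
    h_root = max(leaf_depths)

    def convert(node, depth: float) -> TreeNode:
        if node.is_leaf():
            return TreeNode(0.0, name=node.taxon.label)
        children = [convert(c, depth + (c.edge.length or 0.0))
                    for c in node.child_nodes()]
        label = node.label
        support = float(label) if label not in (None, "") else None
        return TreeNode(h_root - depth, children=children, support=support)

    return UltrametricTree(convert(dtree.seed_node, 0.0))


def genotype_character_matrix(allele_calls: dict[str, list[str | None]]
                              ) -> CharacterMatrix:
    """Concatenate per-site marker alleles into an aligned matrix.

    Missing calls become 'N' (removed pairwise during distance
    computation). Multi-base alleles are padded per column to equal width
    with 'N'.
    """
    taxa = sorted(allele_calls)
    n_sites = {len(v) for v in allele_calls.values()}
    if len(n_sites) != 1:
        raise ValueError("taxa have different numbers of sites")
    cols = []
    for i in range(n_sites.pop()):
        alleles = [allele_calls[t][i] for t in taxa]
        width = max(len(a) for a in alleles if a is not None)
        cols.append([("N" * width if a is None else a.ljust(width, "N"))
                     for a in alleles])
    rows = {t: "".join(c[k] for c in cols) for k, t in enumerate(taxa)}
    return CharacterMatrix(rows)
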