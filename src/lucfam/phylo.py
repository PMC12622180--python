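"""Synonymous-distance neighbor-joining trees with codon bootstrap.

Because intron sequences cannot be aligned across deeply diverged paralog
families, trees are built from synonymous sites only: pairwise synonymous
proportions come from the modified Nei-Gojobori machinery (transition
weighting R, pathway-averaged differences) and are converted to distances
with a gamma-rate Jukes-Cantor correction.  Topologies are inferred with
the Saitou-Nei neighbor-joining algorithm and assessed by resampling whole
codons with replacement (the distance is codon-based, so the codon -- not
the single column -- is the natural exchangeable unit).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .popgen import jc_gamma, ng_differences, ng_sites, _codon_ok, SaturationError
from .seq import AlignedSet, SiteClassMap


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    R: float = 2.0
    gamma_a: float = 1.0
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode  # trifurcating root = unrooted tree
    raw_negative_branches: int = 0

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each named by the leaf set of the edge's
        subtree side, normalized to the side excluding the alphabetically
        first leaf (unrooted convention)."""
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def total_length(self) -> float:
        acc = [0.0]

        def walk(node: TreeNode) -> None:
            for c in node.children:
                acc[0] += c.length
                walk(c)

        walk(self.root)
        return acc[0]

    def to_newick(self, support_as_label: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if support_as_label and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = f"{self.root.support:g}" if self.root.support is not None else ""
        return f"({inner}){label};"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pair_codon_arrays(
    aln: AlignedSet, site_map: SiteClassMap, R: float
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Per-pair, per-codon synonymous difference and site arrays.

    Returns (pair index list, sd[pair, codon], ss[pair, codon]); codons
    unusable in a pair (gap/N/stop) carry zero sites and differences.
    """
    codons = site_map.codons()
    seqs = [m.residues for m in aln.members]
    n = len(seqs)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    sd = np.zeros((len(pairs), len(codons)))
    ss = np.zeros((len(pairs), len(codons)))
    codon_strs = [
        [s[c1 - 1] + s[c2 - 1] + s[c3 - 1] for (c1, c2, c3) in codons] for s in seqs
    ]
    for p, (i, j) in enumerate(pairs):
        for k in range(len(codons)):
            ca, cb = codon_strs[i][k], codon_strs[j][k]
            if not (_codon_ok(ca) and _codon_ok(cb)):
                continue
            sa, _ = ng_sites(ca, R)
            sb, _ = ng_sites(cb, R)
            s_d, _ = ng_differences(ca, cb)
            ss[p, k] = (sa + sb) / 2.0
            sd[p, k] = s_d
    return pairs, sd, ss


def syn_distance_matrix(
    aln: AlignedSet,
    site_map: SiteClassMap,
    R: float = 2.0,
    gamma_a: float = 1.0,
) -> DistanceMatrix:
    """Pairwise synonymous distances, gamma-JC corrected.

    Saturated pairs (p >= 0.75) are flagged and set to NaN.
    """
    pairs, sd, ss = _pair_codon_arrays(aln, site_map, R)
    n = len(aln)
    mat = np.zeros((n, n))
    saturated = []
    labels = aln.ids
    for p, (i, j) in enumerate(pairs):
        sites = ss[p].sum()
        if sites <= 0:
            mat[i, j] = mat[j, i] = np.nan
            saturated.append((labels[i], labels[j]))
            continue
        prop = sd[p].sum() / sites
        try:
            d = jc_gamma(prop, gamma_a)
        except SaturationError:
            d = np.nan
            saturated.append((labels[i], labels[j]))
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat, R, gamma_a, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    At each step the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined; exact Q ties are broken by the label pair, in lexicographic
    order.  Negative branch lengths are clamped to zero for output (count
    retained on the tree).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if np.isnan(dm.matrix).any():
        raise ValueError("distance matrix contains saturated/undefined entries")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    names: list[str] = list(dm.labels)
    D = dm.matrix.copy()
    negatives = 0

    def clamp(x: float) -> float:
        nonlocal negatives
        if x < 0:
            negatives += 1
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        new_name = f"({min(names[i], names[j])}+{max(names[i], names[j])})"
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D2[r - 2, : r - 2] = D2[: r - 2, r - 2] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [new_name]
    # resolve the final three nodes around a central (unrooted) vertex
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    return Tree(root, raw_negative_branches=negatives)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    tree: Tree  # reference tree with supports attached (percent)
    n_replicates: int
    n_dropped: int  # replicates with a saturated matrix
    supports: dict[frozenset[str], float]


def bootstrap(
    aln: AlignedSet,
    site_map: SiteClassMap,
    n_reps: int = 1000,
    seed: int = 0,
    R: float = 2.0,
    gamma_a: float = 1.0,
) -> BootstrapResult:
    """Codon bootstrap of the synonymous-distance NJ tree.

    Codons are resampled with replacement; each replicate rebuilds the
    distance matrix and tree; support of an internal edge is the percentage
    of usable replicates containing its bipartition.  Replicates with any
    saturated pair are dropped and counted.
    """
    if len(aln) < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    rng = np.random.default_rng(seed)
    pairs, sd, ss = _pair_codon_arrays(aln, site_map, R)
    n = len(aln)
    n_codons = sd.shape[1]

    def matrix_from(idx: np.ndarray) -> DistanceMatrix | None:
        mat = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            sites = ss[p, idx].sum()
            if sites <= 0:
                return None
            prop = sd[p, idx].sum() / sites
            if prop >= 0.75:
                return None
            mat[i, j] = mat[j, i] = jc_gamma(prop, gamma_a)
        return DistanceMatrix(aln.ids, mat, R, gamma_a)

    ref_dm = syn_distance_matrix(aln, site_map, R, gamma_a)
    ref_tree = nj_tree(ref_dm)
    ref_bips = ref_tree.bipartitions()
    counts: dict[frozenset[str], int] = {b: 0 for b in ref_bips}
    dropped = 0
    for _ in range(n_reps):
        idx = rng.integers(n_codons, size=n_codons)
        dm = matrix_from(idx)
        if dm is None:
            dropped += 1
            continue
        for bip in nj_tree(dm).bipartitions():
            if bip in counts:
                counts[bip] += 1
    used = n_reps - dropped
    supports = {
        b: (100.0 * c / used if used else 0.0) for b, c in counts.items()
    }
    _attach_supports(ref_tree, supports)
    return BootstrapResult(ref_tree, n_reps, dropped, supports)


def _attach_supports(tree: Tree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = set(tree.leaf_names)
    anchor = min(all_leaves)

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for c in node.children:
            below |= walk(c)
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            if frozenset(side) in supports:
                node.support = supports[frozenset(side)]
        return below

    walk(tree.root)


def clade_support(result: BootstrapResult, leaves: set[str]) -> float | None:
    """Bootstrap support (percent) for the bipartition isolating ``leaves``."""
    all_leaves = set(result.tree.leaf_names)
    anchor = min(all_leaves)
    side = leaves if anchor not in leaves else all_leaves - leaves
    return result.supports.get(frozenset(side))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: Tree, path: str | Path, support_as_label: bool = True) -> None:
    Path(path).write_text(tree.to_newick(support_as_label) + "\n")


def read_newick(path: str | Path) -> Tree:
    """Parse Newick (internal node labels read as bootstrap supports)."""
    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )

    def convert(dnode) -> TreeNode:
        node = TreeNode()
        if dnode.is_leaf():
            node.name = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.name = dnode.label
            node.children = [convert(c) for c in dnode.child_nodes()]
        node.length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return node

    return Tree(convert(dtree.seed_node))
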